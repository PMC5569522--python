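import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    # toy_track is a stateless builder, safe to share across generated inputs
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("default")


@pytest.fixture
def toy_track():
    """Build a single-chromosome p-value track from a list of p-values."""

    def build(pvals, chrom="chr1", window=100):
        n = len(pvals)
        return pd.DataFrame(
            {
                "chrom": chrom,
                "start": np.arange(n, dtype=np.int64) * window,
                "end": np.arange(1, n + 1, dtype=np.int64) * window,
                "p_value": np.asarray(pvals, dtype=float),
            }
        )

    return build
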