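"""Set-level comparison and validation utilities.

Covers overlap of DMR sets between analyses, within-population pairwise
validation (every 1-vs-1 pool comparison inside a group, re-using the
between-group dispersion), and the small statistics the study design needs:
Pearson chi-square on category tables, Bonferroni adjustment, and two-sample
t-test power via the noncentral t distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .caller import DMR, MULTIPLE_WINDOW, call_dmrs
from .config import DEFAULT_CONFIG, PipelineConfig
from .diffmethyl import normalize_libsizes, test_all_windows
from .windows import CountMatrix


@dataclass(frozen=True)
class DMRSet:
    label: str
    dmrs: tuple[DMR, ...]

    def __len__(self) -> int:
        return len(self.dmrs)


@dataclass(frozen=True)
class OverlapResult:
    """Partition of two DMR sets into shared and set-exclusive members.

    ``n_shared_a`` counts A's DMRs that overlap some DMR of B, and vice
    versa; the two shared counts can differ when overlaps are not 1:1.
    ``n_a_only + n_shared_a == len(A)`` and likewise for B.
    """

    n_a_only: int
    n_b_only: int
    n_shared_a: int
    n_shared_b: int


def _overlaps_any(d: DMR, others: Sequence[DMR], min_overlap: int) -> bool:
    return any(
        o.chrom == d.chrom
        and min(d.end, o.end) - max(d.start, o.start) >= min_overlap
        for o in others
    )


def overlap_sets(
    set_a: Sequence[DMR] | DMRSet,
    set_b: Sequence[DMR] | DMRSet,
    min_overlap: int = 1,
) -> OverlapResult:
    """Count shared vs exclusive DMRs between two analyses.

    A DMR is shared iff it overlaps at least ``min_overlap`` bp with any DMR
    of the other set (both sets must use the same genome coordinates).
    """
    a = set_a.dmrs if isinstance(set_a, DMRSet) else list(set_a)
    b = set_b.dmrs if isinstance(set_b, DMRSet) else list(set_b)
    shared_a = sum(_overlaps_any(d, b, min_overlap) for d in a)
    shared_b = sum(_overlaps_any(d, a, min_overlap) for d in b)
    return OverlapResult(
        n_a_only=len(a) - shared_a,
        n_b_only=len(b) - shared_b,
        n_shared_a=shared_a,
        n_shared_b=shared_b,
    )


@dataclass
class PairwiseResult:
    """Within-group 1-vs-1 pool comparisons and their overlap with the
    between-group DMR set."""

    pair_dmrs: dict[tuple[str, str], list[DMR]]
    summary: pd.DataFrame


def pairwise_within_group(
    counts: CountMatrix,
    group: str,
    phi: float,
    config: PipelineConfig = DEFAULT_CONFIG,
    between_dmrs: Sequence[DMR] | None = None,
    multiple_window_only: bool = True,
) -> PairwiseResult:
    """Run every unordered 1-vs-1 pool comparison within one group.

    Each pair of pools is tested and DMR-called with the same configuration
    as the between-group analysis, using the supplied dispersion (a single
    pool per side cannot estimate its own). If ``between_dmrs`` is given,
    each pair's DMRs are intersected with it, quantifying how often the
    between-group signal could arise from within-group variation alone.
    """
    cols = counts.group_columns(group)
    if len(cols) < 2:
        raise ValueError(f"group {group!r} has fewer than 2 pools")
    pair_dmrs: dict[tuple[str, str], list[DMR]] = {}
    rows = []
    for i, j in combinations(cols, 2):
        si, sj = counts.samples[int(i)], counts.samples[int(j)]
        sub = CountMatrix(
            counts.grid,
            [
                type(si)(si.pool_id, "A", si.library_size),
                type(sj)(sj.pool_id, "B", sj.library_size),
            ],
            counts.counts[:, [int(i), int(j)]],
        )
        track = test_all_windows(normalize_libsizes(sub), phi=phi)
        dmrs = call_dmrs(track, config)
        if multiple_window_only:
            dmrs = [d for d in dmrs if d.dmr_class == MULTIPLE_WINDOW]
        key = (si.pool_id, sj.pool_id)
        pair_dmrs[key] = dmrs
        row = {"pool_1": si.pool_id, "pool_2": sj.pool_id, "n_dmrs": len(dmrs)}
        if between_dmrs is not None:
            ov = overlap_sets(between_dmrs, dmrs)
            row["n_between_also_in_pair"] = ov.n_shared_a
        rows.append(row)
    summary = pd.DataFrame(rows)
    return PairwiseResult(pair_dmrs=pair_dmrs, summary=summary)


def fraction_between_found_within(
    between_dmrs: Sequence[DMR], pairwise: PairwiseResult
) -> float:
    """Fraction of between-group DMRs recovered by any within-group pair."""
    if not between_dmrs:
        return 0.0
    all_within = [d for dmrs in pairwise.pair_dmrs.values() for d in dmrs]
    ov = overlap_sets(between_dmrs, all_within)
    return ov.n_shared_a / len(between_dmrs)


def chisq_table(table) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on a count table.

    Returns ``(statistic, df, p)`` with ``df = (r-1)(c-1)``. Requires at
    least a 2x2 table of non-negative counts with strictly positive
    expected counts.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError(f"need a table with >= 2 rows and columns, got shape {t.shape}")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    res = stats.chi2_contingency(t, correction=False)
    if (res.expected_freq <= 0).any():
        raise ValueError("table has zero expected counts")
    return float(res.statistic), int(res.dof), float(res.pvalue)


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-adjusted p-value: min(1, m * p)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(1.0, m * p)


def power_two_sample_t(
    d: float, n1: int, n2: int, alpha: float = 0.05, alternative: str = "greater"
) -> float:
    """Power of the two-sample t-test at standardized effect size d (Cohen).

    Uses the noncentral t distribution with noncentrality
    ``delta = d / sqrt(1/n1 + 1/n2)`` and ``df = n1 + n2 - 2``.
    ``alternative`` is one of "greater", "less", "two-sided".
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n1, n2 >= 2")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    df = n1 + n2 - 2
    ncp = d / math.sqrt(1.0 / n1 + 1.0 / n2)
    if alternative == "greater":
        tcrit = stats.t.ppf(1 - alpha, df)
        return float(stats.nct.sf(tcrit, df, ncp))
    if alternative == "less":
        tcrit = stats.t.ppf(1 - alpha, df)
        return float(stats.nct.cdf(-tcrit, df, ncp))
    if alternative == "two-sided":
        tcrit = stats.t.ppf(1 - alpha / 2, df)
        return float(stats.nct.sf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp))
    raise ValueError(f"unknown alternative {alternative!r}")
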