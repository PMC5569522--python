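"""Pipeline configuration: every fixed threshold of the analysis in one place."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds for the windowed differential-methylation pipeline.

    Attributes
    ----------
    window_size:
        Width of the genomic tiling windows, bp.
    p_core:
        Per-window p-value below which a window counts as a DMR core window.
    p_extend:
        p-value threshold used when extending DMR edges: any window below
        this, near enough to a DMR, is absorbed into its span.
    extend_gap:
        Maximum edge-to-edge distance (bp, boundary-inclusive) between a
        sub-threshold window and a DMR span for the span to be extended.
    cluster_window:
        Width of the sliding window used to scan for DMR clusters, bp.
    cluster_step:
        Step of the cluster-scan sliding window, bp.
    gene_flank:
        Flank added to each side of a DMR before testing gene overlap, bp
        (captures promoter-proximal genes).
    cluster_alpha:
        Significance level for a cluster-scan window's Poisson tail test.
    merge_touching:
        Whether extension that makes two DMR spans touch merges them into one.
    """

    window_size: int = 100
    p_core: float = 1e-3
    p_extend: float = 0.1
    extend_gap: int = 1000
    cluster_window: int = 2_000_000
    cluster_step: int = 50_000
    gene_flank: int = 10_000
    cluster_alpha: float = 0.05
    merge_touching: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.p_core <= self.p_extend < 1.0):
            raise ValueError(
                f"need 0 < p_core <= p_extend < 1, got {self.p_core}, {self.p_extend}"
            )
        for name in ("window_size", "extend_gap", "cluster_window", "cluster_step"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.gene_flank < 0:
            raise ValueError("gene_flank must be non-negative")
        if not (0.0 < self.cluster_alpha < 1.0):
            raise ValueError("cluster_alpha must be in (0, 1)")


DEFAULT_CONFIG = PipelineConfig()
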