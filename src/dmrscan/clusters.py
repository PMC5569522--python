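"""Sliding-window scan for genomic regions over-represented in DMRs.

A fixed-width window (default 2 Mb) slides along each chromosome in fixed
steps (default 50 kb); the DMRs whose midpoints fall inside are counted and
compared against a genome-wide uniform rate with an exact Poisson upper-tail
test. Because thousands of overlapping positions are scanned, the per-window
p-value is Bonferroni-corrected (by default over the number of scanned
positions genome-wide — conservative, since overlapping windows are
correlated) before comparison with the family-wise level. Overlapping
significant windows are merged; a merged region is reported as a cluster when
it contains at least three member DMRs, with its span trimmed to the
first-to-last member extent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .caller import DMR
from .config import DEFAULT_CONFIG, PipelineConfig

MIN_CLUSTER_DMRS = 3


@dataclass(frozen=True)
class DMRCluster:
    chrom: str
    start: int
    end: int
    member_dmr_ids: tuple[int, ...]
    p_value: float

    @property
    def n_dmrs(self) -> int:
        return len(self.member_dmr_ids)

    @property
    def span_bp(self) -> int:
        return self.end - self.start


def cluster_pvalue(k: int, lam: float) -> float:
    """Exact Poisson upper tail P(X >= k) at rate lam."""
    if k < 0:
        raise ValueError("k must be non-negative")
    if lam <= 0:
        raise ValueError("lambda must be positive")
    if k == 0:
        return 1.0
    return float(stats.poisson.sf(k - 1, lam))


def scan_clusters(
    dmrs: Sequence[DMR],
    genome_lengths: Mapping[str, int],
    cluster_window: int = DEFAULT_CONFIG.cluster_window,
    cluster_step: int = DEFAULT_CONFIG.cluster_step,
    cluster_alpha: float = DEFAULT_CONFIG.cluster_alpha,
    min_dmrs: int = MIN_CLUSTER_DMRS,
    correction: str = "positions",
) -> list[DMRCluster]:
    """Scan for DMR clusters against a genome-wide uniform null rate.

    The null expectation per window is ``lambda = (total DMRs / total genome
    length) * cluster_window``, computed genome-wide (per-chromosome rates
    would be unstable at small DMR counts). Windows truncated at a chromosome
    end keep the full-window lambda, which is conservative there.

    ``correction`` controls the multiple-testing adjustment of the Poisson
    tail p-value before comparison with ``cluster_alpha``: "positions"
    (Bonferroni over all scanned window positions; the default), "windows"
    (over the number of disjoint windows), or "none" (raw per-window test,
    which at genome scale is an uncorrected scan and floods the output with
    chance aggregations). Reported cluster p-values carry the same
    adjustment.
    """
    if not dmrs:
        return []
    total_len = sum(genome_lengths.values())
    if total_len <= 0:
        raise ValueError("genome has no length")
    rate = len(dmrs) / total_len
    lam = rate * cluster_window
    if correction == "positions":
        m = sum(-(-length // cluster_step) for length in genome_lengths.values())
    elif correction == "windows":
        m = max(1, round(total_len / cluster_window))
    elif correction == "none":
        m = 1
    else:
        raise ValueError(f"unknown correction {correction!r}")

    mids = np.array([d.midpoint for d in dmrs], dtype=np.int64)
    chroms = np.array([d.chrom for d in dmrs])

    clusters: list[DMRCluster] = []
    for chrom, length in genome_lengths.items():
        on_chrom = np.nonzero(chroms == chrom)[0]
        if on_chrom.size < min_dmrs:
            continue
        mid = mids[on_chrom]
        order = np.argsort(mid)
        on_chrom, mid = on_chrom[order], mid[order]
        sig_intervals: list[tuple[int, int, float]] = []
        for pos in range(0, length, cluster_step):
            k = int(np.searchsorted(mid, pos + cluster_window) - np.searchsorted(mid, pos))
            if k == 0:
                continue
            p = min(1.0, cluster_pvalue(k, lam) * m)
            if p < cluster_alpha:
                sig_intervals.append((pos, min(pos + cluster_window, length), p))
        if not sig_intervals:
            continue
        merged: list[list] = []
        for lo, hi, p in sig_intervals:
            if merged and lo <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], hi)
                merged[-1][2] = min(merged[-1][2], p)
            else:
                merged.append([lo, hi, p])
        for lo, hi, p in merged:
            inside = on_chrom[(mid >= lo) & (mid < hi)]
            if inside.size < min_dmrs:
                continue
            members = tuple(int(i) for i in inside)
            clusters.append(
                DMRCluster(
                    chrom=chrom,
                    start=int(min(dmrs[i].start for i in members)),
                    end=int(max(dmrs[i].end for i in members)),
                    member_dmr_ids=members,
                    p_value=float(p),
                )
            )
    return clusters


def clusters_to_frame(clusters: Sequence[DMRCluster]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [c.chrom for c in clusters],
            "start": [c.start for c in clusters],
            "end": [c.end for c in clusters],
            "n_dmrs": [c.n_dmrs for c in clusters],
            "p_value": [c.p_value for c in clusters],
            "member_dmr_ids": [",".join(map(str, c.member_dmr_ids)) for c in clusters],
        }
    )
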