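"""DMR calling from the per-window p-value track.

Core windows are those with p below the core threshold (default 1e-3);
maximal runs of adjacent core windows seed DMRs, whose edges are then
extended until no window with p below the extension threshold (default 0.1)
remains within the allowed gap (default 1000 bp, edge-to-edge and
boundary-inclusive) of the span. Extension is iterated to a fixed point, so
chains of sub-threshold windows are absorbed; spans that come to touch or
overlap are merged. A DMR whose longest run of adjacent core windows is >= 2
is a "multiple-window" DMR, the high-confidence class used downstream.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import DEFAULT_CONFIG, PipelineConfig

SINGLE_WINDOW = "single_window"
MULTIPLE_WINDOW = "multiple_window"


@dataclass(frozen=True)
class CoreRun:
    """Maximal run of adjacent core-significant windows (local indices, inclusive)."""

    chrom: str
    lo: int
    hi: int


@dataclass
class DMR:
    chrom: str
    start: int
    end: int
    core_windows: list[int] = field(default_factory=list)  # local window indices
    min_p: float = 1.0
    max_adjacent_core_run: int = 1

    @property
    def n_core(self) -> int:
        return len(self.core_windows)

    @property
    def length_bp(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    @property
    def dmr_class(self) -> str:
        return MULTIPLE_WINDOW if self.max_adjacent_core_run >= 2 else SINGLE_WINDOW


def _track_by_chrom(track: pd.DataFrame):
    for chrom, sub in track.groupby("chrom", sort=False):
        yield (
            chrom,
            sub["start"].to_numpy(np.int64),
            sub["end"].to_numpy(np.int64),
            sub["p_value"].to_numpy(float),
        )


def find_core_runs(track: pd.DataFrame, p_core: float = DEFAULT_CONFIG.p_core) -> list[CoreRun]:
    """Maximal runs of strictly adjacent windows with p < p_core, per chromosome."""
    runs: list[CoreRun] = []
    for chrom, _, _, p in _track_by_chrom(track):
        sig = p < p_core
        if not sig.any():
            continue
        idx = np.nonzero(sig)[0]
        breaks = np.nonzero(np.diff(idx) > 1)[0]
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [len(idx) - 1]))
        runs.extend(CoreRun(chrom, int(idx[a]), int(idx[b])) for a, b in zip(starts, ends))
    return runs


def _max_adjacent_run(core_idx: Sequence[int]) -> int:
    if not core_idx:
        return 0
    best = cur = 1
    for prev, nxt in zip(core_idx, core_idx[1:]):
        cur = cur + 1 if nxt == prev + 1 else 1
        best = max(best, cur)
    return best


def extend_edges(
    core_runs: Iterable[CoreRun],
    track: pd.DataFrame,
    p_extend: float = DEFAULT_CONFIG.p_extend,
    extend_gap: int = DEFAULT_CONFIG.extend_gap,
    p_core: float = DEFAULT_CONFIG.p_core,
    merge_touching: bool = True,
) -> list[DMR]:
    """Grow each core run while sub-threshold windows remain within the gap.

    The gap is measured edge-to-edge (window's nearest edge to the span's
    nearest edge) and is boundary-inclusive: gap <= extend_gap extends.
    Iterates to a fixed point so chains of qualifying windows are absorbed;
    spans that touch or overlap after extension are merged (core windows
    pooled, longest adjacent core run recomputed). Extension never crosses
    a chromosome boundary.
    """
    by_chrom: dict[str, list[list[int]]] = {}
    for run in core_runs:
        by_chrom.setdefault(run.chrom, []).append([run.lo, run.hi])

    dmrs: list[DMR] = []
    for chrom, starts, ends, p in _track_by_chrom(track):
        spans = sorted(by_chrom.get(chrom, []))
        if not spans:
            continue
        cand = np.nonzero(p < p_extend)[0]
        changed = True
        while changed:
            changed = False
            for span in spans:
                lo, hi = span
                left = cand[(cand < lo) & (starts[lo] - ends[cand] <= extend_gap)]
                if left.size:
                    span[0] = int(left.min())
                    changed = True
                right = cand[(cand > hi) & (starts[cand] - ends[hi] <= extend_gap)]
                if right.size:
                    span[1] = int(right.max())
                    changed = True
            if merge_touching:
                spans.sort()
                merged = [spans[0]]
                for span in spans[1:]:
                    if span[0] <= merged[-1][1] + 1:  # touching or overlapping windows
                        merged[-1][1] = max(merged[-1][1], span[1])
                    else:
                        merged.append(span)
                if len(merged) != len(spans):
                    changed = True
                spans = merged
        for lo, hi in spans:
            core = [int(i) for i in range(lo, hi + 1) if p[i] < p_core]
            dmrs.append(
                DMR(
                    chrom=chrom,
                    start=int(starts[lo]),
                    end=int(ends[hi]),
                    core_windows=core,
                    min_p=float(p[lo : hi + 1].min()),
                    max_adjacent_core_run=_max_adjacent_run(core),
                )
            )
    return dmrs


def call_dmrs(track: pd.DataFrame, config: PipelineConfig = DEFAULT_CONFIG) -> list[DMR]:
    """Full caller: core runs -> edge extension -> merged, classified DMRs."""
    runs = find_core_runs(track, config.p_core)
    return extend_edges(
        runs,
        track,
        p_extend=config.p_extend,
        extend_gap=config.extend_gap,
        p_core=config.p_core,
        merge_touching=config.merge_touching,
    )


def multiple_window_sum(per_run_counts: Mapping[int, int]) -> int:
    """Sum of DMR counts over adjacent-core-run sizes >= 2.

    ``per_run_counts`` maps the longest-adjacent-core-run size (1, 2, 3, ...)
    to the number of DMRs with that run size.
    """
    return sum(n for run, n in per_run_counts.items() if run >= 2)


def classify_and_summarize(dmrs: Sequence[DMR], max_run: int = 5) -> pd.DataFrame:
    """DMR counts by longest adjacent core run (1..max_run, last bin open-ended)
    plus the multiple-window (run >= 2) total."""
    runs = Counter(min(d.max_adjacent_core_run, max_run) for d in dmrs)
    per_run = {k: runs.get(k, 0) for k in range(1, max_run + 1)}
    row = {f"windows_{k}" if k < max_run else f"windows_{k}plus": per_run[k] for k in per_run}
    row["multiple_window_sum"] = multiple_window_sum(
        Counter(d.max_adjacent_core_run for d in dmrs)
    )
    return pd.DataFrame([row])


def length_histogram(
    dmrs: Sequence[DMR], bin_edges_kb: Sequence[float] | None = None
) -> pd.DataFrame:
    """DMR counts per length bin in kb; bins are left-closed, right-open."""
    if bin_edges_kb is None:
        bin_edges_kb = [0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 5.0, 10.0]
    edges = np.asarray(bin_edges_kb, dtype=float)
    lengths_kb = np.array([d.length_bp / 1000.0 for d in dmrs])
    idx = np.searchsorted(edges, lengths_kb, side="right") - 1
    idx = idx[(idx >= 0) & (idx < len(edges) - 1)]
    counts = np.bincount(idx, minlength=len(edges) - 1)
    return pd.DataFrame(
        {"bin_left_kb": edges[:-1], "bin_right_kb": edges[1:], "n_dmrs": counts}
    )


def dmrs_to_frame(dmrs: Sequence[DMR]) -> pd.DataFrame:
    """BED-like table of called DMRs."""
    return pd.DataFrame(
        {
            "chrom": [d.chrom for d in dmrs],
            "start": [d.start for d in dmrs],
            "end": [d.end for d in dmrs],
            "name": [f"DMR{i + 1}" for i in range(len(dmrs))],
            "min_p": [d.min_p for d in dmrs],
            "dmr_class": [d.dmr_class for d in dmrs],
            "n_core": [d.n_core for d in dmrs],
            "max_adjacent_core_run": [d.max_adjacent_core_run for d in dmrs],
        }
    )
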