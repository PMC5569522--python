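"""Synthetic genomes, gene annotations and pooled MeDIP-like counts.

Emulates the study design the pipeline is built for: two groups (e.g. urban
vs rural) of pooled samples, three pools per group, window read counts that
are negative-binomially distributed around a CpG-density-dependent baseline,
and planted DMRs of known span (1-5 core windows) and fold change, optionally
arranged into megabase-scale clusters. Every generator is deterministic given
its seed, and the planted truth is serializable so downstream calls can be
scored against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .windows import CountMatrix, Sample, WindowGrid, make_windows

_A, _C, _G, _T = (np.frombuffer(b"ACGT", dtype="S1")[i] for i in range(4))


@dataclass(frozen=True)
class GenomeSpec:
    """A toy reference genome: chromosome lengths, optionally with sequence."""

    chromosomes: tuple[tuple[str, int], ...]
    sequence: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")
            if self.sequence is not None and len(self.sequence[name]) != length:
                raise ValueError(f"sequence length mismatch for {name!r}")

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def write_fasta(self, path, width: int = 60) -> None:
        with open(path, "w") as fh:
            for name, length in self.chromosomes:
                seq = self.sequence[name] if self.sequence else "N" * length
                fh.write(f">{name}\n")
                for i in range(0, length, width):
                    fh.write(seq[i : i + width] + "\n")

    @classmethod
    def from_fasta(cls, path) -> "GenomeSpec":
        import pyfaidx

        fa = pyfaidx.Fasta(str(path))
        seqs = {name: str(fa[name][:]) for name in fa.keys()}
        return cls(tuple((n, len(s)) for n, s in seqs.items()), seqs)


@dataclass(frozen=True)
class CpGSegment:
    """Directive to force a target CpG density over a genomic interval."""

    chrom: str
    start: int
    end: int
    cpg_per_100bp: float


@dataclass(frozen=True)
class PlantedDMR:
    chrom: str
    core_start: int
    n_core_windows: int
    log2_fold_change: float
    direction: str = "up"

    def __post_init__(self) -> None:
        if self.n_core_windows < 1:
            raise ValueError("n_core_windows must be >= 1")
        if self.direction not in ("up", "down"):
            raise ValueError("direction must be 'up' or 'down'")

    def core_end(self, window_size: int) -> int:
        return self.core_start + self.n_core_windows * window_size


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for the count simulation.

    Defaults mirror the pooled design the pipeline targets: 2 groups x 3
    pools per group, each pool combining 5 birds (metadata only); per-window
    depth around 100 reads so a 2-5-window DMR carries on the order of a few
    hundred to >1000 reads; NB dispersion 0.3 (moderate between-pool
    biological variability); MeDIP enrichment multiplying the baseline by
    ``cpg_effect`` per CpG-density unit.
    """

    pools_per_group: int = 3
    birds_per_pool: int = 5
    mean_depth_per_window: float = 100.0
    dispersion: float = 0.3
    cpg_effect: float = 1.2
    seed: int = 0
    planted: tuple[PlantedDMR, ...] = ()
    planted_clusters: tuple[tuple[str, int, int, int], ...] = ()
    size_factor_range: tuple[float, float] = (0.7, 1.4)

    def __post_init__(self) -> None:
        if self.pools_per_group < 1:
            raise ValueError("pools_per_group must be >= 1")
        if self.mean_depth_per_window <= 0:
            raise ValueError("mean_depth_per_window must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")


def _cpg_free_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    """Random nucleotides with every CG dinucleotide broken (G -> A)."""
    arr = rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=length)
    if length > 1:
        mask = (arr[:-1] == _C) & (arr[1:] == _G)
        arr[1:][mask] = _A
    return arr


def _plant_cpgs_even(arr: np.ndarray, n: int) -> None:
    """Place exactly n CG pairs at evenly spaced even offsets (in place)."""
    slots = len(arr) // 2
    if n > slots:
        raise ValueError(f"cannot place {n} CpGs in {len(arr)} bp")
    for k in range(n):
        pos = (k * slots // n) * 2
        arr[pos] = _C
        arr[pos + 1] = _G


def simulate_genome(
    chrom_lengths: Mapping[str, int],
    gc_profile: Sequence[CpGSegment] | None = None,
    seed: int = 0,
    background_cpg_per_100: float = 1.0,
) -> GenomeSpec:
    """Random genome with controlled CpG placement.

    The background sequence is CpG-free random nucleotides with CG pairs
    planted at random non-adjacent positions to hit ``background_cpg_per_100``
    on average; ``gc_profile`` segments are then overwritten with evenly
    spaced CG pairs at their target density, so CpG-dense and CpG-poor
    density classes are both populated. Deterministic given ``seed``.
    """
    if not chrom_lengths:
        raise ValueError("no chromosomes given")
    rng = np.random.default_rng(seed)
    seqs: dict[str, str] = {}
    for name, length in chrom_lengths.items():
        if length <= 0:
            raise ValueError(f"chromosome {name!r} has non-positive length")
        arr = _cpg_free_sequence(rng, length)
        slots = length // 2
        n_bg = min(int(round(length * background_cpg_per_100 / 100.0)), slots)
        if n_bg > 0:
            pos = rng.choice(slots, size=n_bg, replace=False) * 2
            arr[pos] = _C
            arr[pos + 1] = _G
        seqs[name] = arr.tobytes().decode("ascii")
    if gc_profile:
        for seg in gc_profile:
            if seg.chrom not in seqs:
                raise KeyError(f"segment on unknown chromosome {seg.chrom!r}")
            sub = np.frombuffer(seqs[seg.chrom].encode("ascii"), dtype="S1").copy()
            piece = _cpg_free_sequence(rng, seg.end - seg.start)
            n = int(round((seg.end - seg.start) * seg.cpg_per_100bp / 100.0))
            if n > 0:
                _plant_cpgs_even(piece, n)
            sub[seg.start : seg.end] = piece
            seqs[seg.chrom] = sub.tobytes().decode("ascii")
    return GenomeSpec(tuple((n, int(l)) for n, l in chrom_lengths.items()), seqs)


def window_cpg_density(genome: GenomeSpec, grid: WindowGrid) -> np.ndarray:
    """CpG sites per 100 bp for every window of the grid (0 if no sequence)."""
    dens = np.zeros(grid.n_windows)
    if genome.sequence is None:
        return dens
    off = 0
    for chrom in grid.chroms:
        arr = np.frombuffer(genome.sequence[chrom].encode("ascii"), dtype="S1")
        n_win = grid.n_windows_chrom(chrom)
        starts, ends = grid.coords(chrom)
        cg = np.zeros(len(arr), dtype=np.int64)
        if len(arr) > 1:
            cg[:-1] = ((arr[:-1] == _C) & (arr[1:] == _G)).astype(np.int64)
        csum = np.concatenate(([0], np.cumsum(cg)))
        # CG pair at position i belongs to the window containing i
        counts = csum[np.minimum(ends, len(arr))] - csum[starts]
        # a pair straddling a window boundary is credited to the left window;
        # exclude it to match per-window substring counting
        boundary = ends[:-1] - 1
        counts[:-1] -= cg[boundary]
        dens[off : off + n_win] = counts * 100.0 / (ends - starts)
        off += n_win
    return dens


def expand_clusters(
    planted_clusters: Iterable[tuple[str, int, int, int]],
    window_size: int,
    log2_fold_change: float = 3.0,
    n_core_windows: int = 2,
) -> list[PlantedDMR]:
    """Turn (chrom, start, n_dmrs, span_bp) cluster directives into planted
    DMRs evenly spaced across the span."""
    out: list[PlantedDMR] = []
    for chrom, start, n_dmrs, span_bp in planted_clusters:
        if not 3 <= n_dmrs <= 10:
            raise ValueError("clusters must contain 3-10 DMRs")
        for k in range(n_dmrs):
            pos = start + (k * span_bp // n_dmrs)
            pos = (pos // window_size) * window_size
            out.append(PlantedDMR(chrom, pos, n_core_windows, log2_fold_change, "up"))
    return out


def simulate_counts(
    genome: GenomeSpec, grid: WindowGrid, cfg: SimConfig
) -> tuple[CountMatrix, list[PlantedDMR]]:
    """Pooled MeDIP-like window counts with planted DMRs.

    Counts are NB with variance ``mu + phi mu^2`` around a per-window baseline
    ``mean_depth * cpg_effect**density`` scaled by a pool size factor drawn
    log-uniformly from ``size_factor_range`` (so the normalization stage has
    work to do). Planted windows have their mean multiplied by
    ``2**log2_fold_change`` (or its inverse for direction "down") in group B
    only. Returns the count matrix and the full truth table.
    """
    rng = np.random.default_rng(cfg.seed)
    w = grid.window_size
    truth = list(cfg.planted) + expand_clusters(cfg.planted_clusters, w)
    lengths = genome.lengths
    for d in truth:
        if d.chrom not in lengths:
            raise ValueError(f"planted DMR on unknown chromosome {d.chrom!r}")
        if d.core_start % w != 0:
            raise ValueError(f"planted core at {d.core_start} not aligned to {w}-bp grid")
        if d.core_start < 0 or d.core_end(w) > lengths[d.chrom]:
            raise ValueError(f"planted core outside chromosome {d.chrom!r}")

    density = window_cpg_density(genome, grid)
    mu = cfg.mean_depth_per_window * np.power(cfg.cpg_effect, density)

    effect = np.ones(grid.n_windows)
    for d in truth:
        off = grid.chrom_offset(d.chrom)
        first = off + d.core_start // w
        mult = 2.0 ** (d.log2_fold_change if d.direction == "up" else -d.log2_fold_change)
        effect[first : first + d.n_core_windows] *= mult

    n = cfg.pools_per_group
    lo, hi = cfg.size_factor_range
    size_factors = np.exp(rng.uniform(np.log(lo), np.log(hi), size=2 * n))
    pool_ids = [f"A{i + 1}" for i in range(n)] + [f"B{i + 1}" for i in range(n)]
    groups = ["A"] * n + ["B"] * n

    counts = np.empty((grid.n_windows, 2 * n), dtype=np.int64)
    for j in range(2 * n):
        mu_j = mu * size_factors[j]
        if groups[j] == "B":
            mu_j = mu_j * effect
        if cfg.dispersion == 0:
            counts[:, j] = rng.poisson(mu_j)
        else:
            r = 1.0 / cfg.dispersion
            counts[:, j] = rng.negative_binomial(r, r / (r + mu_j))
    samples = [
        Sample(pid, grp, int(counts[:, j].sum()))
        for j, (pid, grp) in enumerate(zip(pool_ids, groups))
    ]
    return CountMatrix(grid, samples, counts), truth


def truth_to_frame(truth: Sequence[PlantedDMR]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [d.chrom for d in truth],
            "core_start": [d.core_start for d in truth],
            "n_core_windows": [d.n_core_windows for d in truth],
            "log2_fold_change": [d.log2_fold_change for d in truth],
            "direction": [d.direction for d in truth],
        }
    )


def truth_from_frame(df: pd.DataFrame) -> list[PlantedDMR]:
    return [
        PlantedDMR(r.chrom, int(r.core_start), int(r.n_core_windows),
                   float(r.log2_fold_change), r.direction)
        for r in df.itertuples()
    ]


@dataclass(frozen=True)
class GeneModelSpec:
    """Placement parameters for the toy gene annotation."""

    length_range: tuple[int, int] = (200, 2000)


def simulate_genes(genome: GenomeSpec, n_genes: int, seed: int = 0,
                   length_range: tuple[int, int] = (200, 2000)):
    """Non-overlapping gene intervals placed uniformly across the genome.

    Genes are distributed over chromosomes proportionally to length and
    placed by rejection; raises when the requested number cannot fit.
    Deterministic given ``seed``. Returns ``GeneModel`` records.
    """
    from .annotate import GeneModel

    if n_genes < 0:
        raise ValueError("n_genes must be >= 0")
    if n_genes == 0:
        return []
    rng = np.random.default_rng(seed)
    lengths = genome.lengths
    total = sum(lengths.values())
    if n_genes * length_range[0] > total:
        raise ValueError(f"{n_genes} genes of >= {length_range[0]} bp do not fit")
    # proportional allocation, remainders to the largest chromosomes
    names = list(lengths)
    quota = {c: n_genes * lengths[c] // total for c in names}
    for c in sorted(names, key=lambda c: -lengths[c]):
        if sum(quota.values()) >= n_genes:
            break
        quota[c] += 1
    genes = []
    counter = 1
    for chrom in names:
        need = quota[chrom]
        if need == 0:
            continue
        placed: list[tuple[int, int]] = []
        for _ in range(500):
            if len(placed) >= need:
                break
            glen = int(rng.integers(length_range[0], min(length_range[1], lengths[chrom]) + 1))
            start = int(rng.integers(0, lengths[chrom] - glen + 1))
            if all(start + glen <= s or start >= e for s, e in placed):
                placed.append((start, start + glen))
        if len(placed) < need:
            raise ValueError(f"could not fit {need} genes on {chrom!r}")
        for s, e in sorted(placed):
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneModel(chrom, s, e, strand, f"gene{counter:04d}"))
            counter += 1
    return genes


def generate_reads(
    counts: CountMatrix, read_len: int = 50, seed: int = 0
) -> dict[str, list[tuple[str, int, int, str]]]:
    """Reads-mode output: per pool, BED-style reads whose midpoints land in
    the window that produced them (count with extension 0 to recover the
    matrix exactly)."""
    rng = np.random.default_rng(seed)
    grid = counts.grid
    half = read_len // 2
    win = grid.to_frame()
    out: dict[str, list[tuple[str, int, int, str]]] = {}
    for j, sample in enumerate(counts.samples):
        reads: list[tuple[str, int, int, str]] = []
        nz = np.nonzero(counts.counts[:, j])[0]
        for widx in nz:
            chrom = win.at[widx, "chrom"]
            length = grid.chrom_length(chrom)
            lo = max(win.at[widx, "start"], half)
            hi = min(win.at[widx, "end"], length - (read_len - half))
            if hi <= lo:  # window too close to a chromosome end
                lo, hi = half, max(half + 1, length - (read_len - half))
            for _ in range(int(counts.counts[widx, j])):
                mid = int(rng.integers(lo, hi))
                strand = "+" if rng.random() < 0.5 else "-"
                reads.append((chrom, mid - half, mid - half + read_len, strand))
        out[sample.pool_id] = reads
    return out


def write_reads_bed(reads: Sequence[tuple[str, int, int, str]], path) -> None:
    pd.DataFrame(
        {
            "chrom": [r[0] for r in reads],
            "start": [r[1] for r in reads],
            "end": [r[2] for r in reads],
            "name": [f"read{i + 1}" for i in range(len(reads))],
            "score": [0] * len(reads),
            "strand": [r[3] for r in reads],
        }
    ).to_csv(path, sep="\t", index=False, header=False)
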