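"""Fixed-width window grids and read-to-window counting.

The genome is tiled into consecutive ``window_size``-bp windows (0-based,
half-open); aligned reads are extended to the sonication fragment length from
their 5' end and assigned to the single window containing the fragment
midpoint, producing an integer window x pool count matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

DEFAULT_EXTENSION = 300  # bp; sonication fragment peak


@dataclass(frozen=True)
class WindowGrid:
    """Ordered fixed-width tiling of a genome.

    Windows tile each chromosome without gaps or overlaps; every window has
    length ``window_size`` except possibly the last one per chromosome, which
    is truncated at the chromosome end (and kept, so that read counts are
    conserved).
    """

    chrom_lengths: tuple[tuple[str, int], ...]
    window_size: int

    def __post_init__(self) -> None:
        if self.window_size <= 0:
            raise ValueError("window_size must be positive")
        names = [c for c, _ in self.chrom_lengths]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        for name, length in self.chrom_lengths:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")

    @property
    def chroms(self) -> list[str]:
        return [c for c, _ in self.chrom_lengths]

    def chrom_length(self, chrom: str) -> int:
        for name, length in self.chrom_lengths:
            if name == chrom:
                return length
        raise KeyError(f"unknown chromosome {chrom!r}")

    def n_windows_chrom(self, chrom: str) -> int:
        length = self.chrom_length(chrom)
        return -(-length // self.window_size)  # ceil division

    @property
    def n_windows(self) -> int:
        return sum(self.n_windows_chrom(c) for c in self.chroms)

    def chrom_offset(self, chrom: str) -> int:
        """Global index of the first window of ``chrom``."""
        off = 0
        for name, _ in self.chrom_lengths:
            if name == chrom:
                return off
            off += self.n_windows_chrom(name)
        raise KeyError(f"unknown chromosome {chrom!r}")

    def coords(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """(starts, ends) arrays for one chromosome's windows."""
        length = self.chrom_length(chrom)
        starts = np.arange(0, length, self.window_size, dtype=np.int64)
        ends = np.minimum(starts + self.window_size, length)
        return starts, ends

    def to_frame(self) -> pd.DataFrame:
        """All windows as a (chrom, start, end) DataFrame in grid order."""
        parts = []
        for chrom in self.chroms:
            starts, ends = self.coords(chrom)
            parts.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
        return pd.concat(parts, ignore_index=True)


def make_windows(chrom_lengths: Mapping[str, int], window_size: int = 100) -> WindowGrid:
    """Tile chromosomes into consecutive ``window_size``-bp windows.

    Window ``i`` on a chromosome of length L spans ``[i*w, min((i+1)*w, L))``;
    the trailing partial window is retained.
    """
    if not chrom_lengths:
        raise ValueError("no chromosomes given")
    return WindowGrid(tuple((str(c), int(l)) for c, l in chrom_lengths.items()), int(window_size))


@dataclass(frozen=True)
class Sample:
    pool_id: str
    group: str
    library_size: int = 0


@dataclass
class CountMatrix:
    """Integer read counts per window (rows) x pool (columns), with group labels."""

    grid: WindowGrid
    samples: list[Sample]
    counts: np.ndarray
    norm_factors: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (self.grid.n_windows, len(self.samples)):
            raise ValueError(
                f"counts shape {self.counts.shape} != (n_windows={self.grid.n_windows}, "
                f"n_samples={len(self.samples)})"
            )
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def groups(self) -> list[str]:
        seen: list[str] = []
        for s in self.samples:
            if s.group not in seen:
                seen.append(s.group)
        return seen

    def group_columns(self, group: str) -> np.ndarray:
        idx = [j for j, s in enumerate(self.samples) if s.group == group]
        if not idx:
            raise KeyError(f"no samples in group {group!r}")
        return np.asarray(idx)

    def library_sizes(self) -> np.ndarray:
        return np.array([s.library_size for s in self.samples], dtype=np.int64)

    def to_frame(self) -> pd.DataFrame:
        df = self.grid.to_frame()
        for j, s in enumerate(self.samples):
            df[s.pool_id] = self.counts[:, j]
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, groups: Mapping[str, str], window_size: int | None = None) -> "CountMatrix":
        """Load a counts TSV (chrom, start, end, one column per pool).

        ``groups`` maps each pool column name to its group label.
        """
        df = pd.read_csv(path, sep="\t")
        pool_cols = [c for c in df.columns if c not in ("chrom", "start", "end")]
        if window_size is None:
            window_size = int((df["end"] - df["start"]).max())
        lengths = df.groupby("chrom", sort=False)["end"].max().to_dict()
        grid = make_windows(lengths, window_size)
        counts = df[pool_cols].to_numpy(dtype=np.int64)
        samples = [
            Sample(c, groups[c], int(counts[:, j].sum())) for j, c in enumerate(pool_cols)
        ]
        return cls(grid, samples, counts)


def assign_read(
    read: tuple[str, int, int, str], grid: WindowGrid, extension_bp: int = DEFAULT_EXTENSION
) -> int | None:
    """Window index (global) receiving one aligned read, or None if unassignable.

    The read is extended to ``extension_bp`` from its 5' end in read
    orientation (extension 0 keeps the alignment span); the fragment is
    clipped to the chromosome and assigned to the window containing its
    midpoint. A midpoint exactly on a window boundary belongs to the
    right-hand window.
    """
    chrom, start, end, strand = read
    length = grid.chrom_length(chrom)  # raises KeyError for unknown chrom
    if end <= start:
        raise ValueError(f"read end {end} <= start {start}")
    if extension_bp > 0:
        if strand == "-":
            fstart, fend = end - extension_bp, end
        else:
            fstart, fend = start, start + extension_bp
    else:
        fstart, fend = start, end
    fstart = max(0, fstart)
    fend = min(length, fend)
    if fend <= fstart:
        return None
    mid = (fstart + fend) // 2
    local = min(mid // grid.window_size, grid.n_windows_chrom(chrom) - 1)
    return grid.chrom_offset(chrom) + local


def count_matrix_from_reads(
    reads_per_pool: Mapping[str, Iterable[tuple[str, int, int, str]]],
    grid: WindowGrid,
    groups: Mapping[str, str],
    extension_bp: int = DEFAULT_EXTENSION,
) -> CountMatrix:
    """Build the window x pool count matrix from per-pool aligned reads.

    Each pool's column sum equals its number of assigned reads. A pool with
    zero reads triggers a warning but is retained with library size 0.
    """
    pool_ids = list(reads_per_pool)
    for pid in pool_ids:
        if pid not in groups:
            raise KeyError(f"pool {pid!r} has no group label")
    counts = np.zeros((grid.n_windows, len(pool_ids)), dtype=np.int64)
    for j, pid in enumerate(pool_ids):
        n = 0
        for read in reads_per_pool[pid]:
            w = assign_read(read, grid, extension_bp)
            if w is not None:
                counts[w, j] += 1
                n += 1
        if n == 0:
            warnings.warn(f"pool {pid!r} has zero assigned reads", stacklevel=2)
    samples = [Sample(pid, groups[pid], int(counts[:, j].sum())) for j, pid in enumerate(pool_ids)]
    return CountMatrix(grid, samples, counts)


def read_bed_reads(path) -> list[tuple[str, int, int, str]]:
    """Load reads from a BED6 file as (chrom, start, end, strand) tuples."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        usecols=[0, 1, 2, 3, 4, 5],
    )
    return list(zip(df["chrom"], df["start"].astype(int), df["end"].astype(int), df["strand"]))


def read_sam_reads(path) -> list[tuple[str, int, int, str]]:
    """Load mapped primary alignments from a SAM/BAM file."""
    import pysam

    out: list[tuple[str, int, int, str]] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as f:
        for aln in f:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            strand = "-" if aln.is_reverse else "+"
            out.append((aln.reference_name, aln.reference_start, aln.reference_end, strand))
    return out
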