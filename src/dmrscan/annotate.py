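"""CpG-density and gene-proximity annotation of called DMRs.

CpG density is the count of CG dinucleotides per 100 bp of the DMR span,
binned into integer density classes with everything below 1 CpG/100 bp in
class 0 (the "CpG desert" class). Gene association adds a symmetric flank
(default 10 kb, to capture promoters) to each DMR and lists every gene whose
body overlaps the flanked interval by at least 1 bp.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .caller import DMR
from .config import DEFAULT_CONFIG


@dataclass(frozen=True)
class GeneModel:
    chrom: str
    start: int
    end: int
    strand: str = "+"
    name: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"gene {self.name!r}: end {self.end} <= start {self.start}")


@dataclass
class AnnotatedDMR:
    dmr: DMR
    cpg_count: int = 0
    associated_genes: list[str] = field(default_factory=list)

    @property
    def cpg_density(self) -> float:
        """CpG sites per 100 bp of the DMR span."""
        return self.cpg_count * 100.0 / self.dmr.length_bp

    @property
    def density_class(self) -> int:
        """Integer density bin; densities below 1 CpG/100 bp fall in class 0."""
        return math.floor(self.cpg_density)


def cpg_count(sequence: str) -> int:
    """Number of CG dinucleotides (case-insensitive; N never matches)."""
    return sequence.upper().count("CG")


def density_profile(
    dmrs: Sequence[DMR] | Sequence[AnnotatedDMR],
    sequences: Mapping[str, str],
) -> list[AnnotatedDMR]:
    """Attach CpG count/density/class to each DMR from genome sequence.

    ``sequences`` maps chromosome name to its nucleotide string (a dict or a
    ``pyfaidx.Fasta`` both work). CG pairs are counted within the DMR span;
    a pair straddling the span edge is not counted.
    """
    out: list[AnnotatedDMR] = []
    for item in dmrs:
        ann = item if isinstance(item, AnnotatedDMR) else AnnotatedDMR(item)
        d = ann.dmr
        seq = sequences[d.chrom]
        chrom_len = len(seq)
        if d.start < 0 or d.end > chrom_len:
            raise ValueError(
                f"DMR {d.chrom}:{d.start}-{d.end} outside sequence of length {chrom_len}"
            )
        ann.cpg_count = cpg_count(str(seq[d.start : d.end]))
        out.append(ann)
    return out


def associate_genes(
    dmrs: Sequence[DMR] | Sequence[AnnotatedDMR],
    genes: Sequence[GeneModel],
    gene_flank: int = DEFAULT_CONFIG.gene_flank,
) -> list[AnnotatedDMR]:
    """List genes whose body overlaps each DMR's flanked interval.

    The flanked interval is ``[start - flank, end + flank)`` clipped at 0;
    association requires >= 1 bp overlap with the gene body (strand ignored:
    the flank is symmetric). DMRs with no gene get an empty list.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    out: list[AnnotatedDMR] = []
    for item in dmrs:
        ann = item if isinstance(item, AnnotatedDMR) else AnnotatedDMR(item)
        d = ann.dmr
        fstart = max(0, d.start - gene_flank)
        fend = d.end + gene_flank
        ann.associated_genes = [
            g.name for g in by_chrom.get(d.chrom, []) if g.start < fend and g.end > fstart
        ]
        out.append(ann)
    return out


def density_class_histogram(annotated: Sequence[AnnotatedDMR], max_class: int = 8) -> pd.Series:
    """DMR counts per CpG-density class (last class open-ended)."""
    counts = {k: 0 for k in range(max_class + 1)}
    for a in annotated:
        counts[min(a.density_class, max_class)] += 1
    return pd.Series(counts, name="n_dmrs")


def annotated_to_frame(annotated: Sequence[AnnotatedDMR]) -> pd.DataFrame:
    """Export table: one row per DMR with position, class, CpG and gene fields."""
    return pd.DataFrame(
        {
            "name": [f"DMR{i + 1}" for i in range(len(annotated))],
            "chrom": [a.dmr.chrom for a in annotated],
            "start": [a.dmr.start for a in annotated],
            "length_bp": [a.dmr.length_bp for a in annotated],
            "n_core": [a.dmr.n_core for a in annotated],
            "min_p": [a.dmr.min_p for a in annotated],
            "cpg_count": [a.cpg_count for a in annotated],
            "cpg_density": [a.cpg_density for a in annotated],
            "density_class": [a.density_class for a in annotated],
            "genes": [";".join(a.associated_genes) if a.associated_genes else "NA"
                      for a in annotated],
        }
    )


def read_genes_bed(path) -> list[GeneModel]:
    """Load gene models from a BED6 file."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        usecols=[0, 1, 2, 3, 4, 5],
    )
    return [
        GeneModel(r.chrom, int(r.start), int(r.end), r.strand, r.name)
        for r in df.itertuples()
    ]


def write_genes_bed(genes: Sequence[GeneModel], path) -> None:
    pd.DataFrame(
        {
            "chrom": [g.chrom for g in genes],
            "start": [g.start for g in genes],
            "end": [g.end for g in genes],
            "name": [g.name for g in genes],
            "score": 0,
            "strand": [g.strand for g in genes],
        }
    ).to_csv(path, sep="\t", index=False, header=False)
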