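"""Shared domain types for introgression-line genotyping and mapping.

Coordinates follow the GFF3 convention throughout: 1-based, inclusive on
both ends. Conversion to BED (0-based, half-open) happens only at write
time in :mod:`introgmap.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import pandas as pd


class Zygosity(str, Enum):
    """Zygosity of a locus in a diploid introgression line.

    Encodes the recurrent-parent allele dosage ``a`` (2, 1 or 0); the
    donor dosage is ``b = 2 - a``.
    """

    HOM_RECURRENT = "HOM_RECURRENT"
    HET = "HET"
    HOM_DONOR = "HOM_DONOR"
    AMBIGUOUS = "AMBIGUOUS"

    @property
    def recurrent_dose(self) -> int:
        if self is Zygosity.AMBIGUOUS:
            raise ValueError("AMBIGUOUS carries no allele dosage")
        return {"HOM_RECURRENT": 2, "HET": 1, "HOM_DONOR": 0}[self.value]

    @property
    def donor_dose(self) -> int:
        return 2 - self.recurrent_dose


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene: coordinates, strand, species of origin, functional flag."""

    gene_id: str
    species: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str = "+"
    functional: bool = True

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class AnchorPair:
    """A reciprocal-best ortholog pair anchoring the two genomes.

    ``rank_r`` / ``rank_d`` are 0-based ordinal positions of the genes
    along their respective chromosomes (rank space is the coordinate
    system of the collinearity chainer).
    """

    gene_recurrent: str
    gene_donor: str
    score: float
    rank_r: Optional[int] = None
    rank_d: Optional[int] = None
    chrom_r: Optional[str] = None
    chrom_d: Optional[str] = None


@dataclass
class SyntenyBlock:
    """An ordered chain of anchor pairs in conserved (possibly inverted) order."""

    block_id: int
    pairs: list[AnchorPair]
    orientation: str  # "+" or "-"
    chain_score: float

    def __post_init__(self) -> None:
        ranks_r = [p.rank_r for p in self.pairs]
        if any(b <= a for a, b in zip(ranks_r, ranks_r[1:])):
            raise ValueError("rank_r must strictly increase along a block")

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class CountTable:
    """Per-gene fragment counts for one sequenced sample.

    ``counts`` columns: gene_id, species, chrom, start, end, length_bp,
    count. ``total_mapped`` is the library's total assigned fragments
    (>= the column sum; unassigned fragments are allowed).
    """

    sample_id: str
    counts: pd.DataFrame
    total_mapped: int

    def __post_init__(self) -> None:
        if (self.counts["count"] < 0).any():
            raise ValueError("negative fragment count")
        if self.total_mapped < int(self.counts["count"].sum()):
            raise ValueError("total_mapped smaller than the column sum")


@dataclass(frozen=True)
class ZygosityCall:
    """Per-gene-pair zygosity from the recurrent/donor FPKM ratio."""

    pair: AnchorPair
    ratio: float
    call: Zygosity
    fpkm_recurrent: float = float("nan")
    fpkm_donor: float = float("nan")


@dataclass
class IntrogressionSegment:
    """A contiguous run of genes sharing one zygosity call."""

    sample_id: str
    chrom: str
    zygosity: Zygosity
    first_gene: str
    last_gene: str
    start_bp: int
    end_bp: int
    n_genes: int
    fraction_concordant: float

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError("segment start_bp > end_bp")


@dataclass
class ProgenyRecord:
    """One plant from a selfed-heterozygote progeny population.

    Marker calls use the standard codes A (homozygous recurrent),
    H (heterozygous), B (homozygous donor), "-" (missing). ``dtf`` is
    days from germination to the first open flower; plants that never
    flowered carry ``flowered=False`` and ``dtf=None``.
    """

    plant_id: str
    marker_calls: dict[str, str]
    dtf: Optional[float]
    flowered: bool

    def __post_init__(self) -> None:
        if self.flowered and (self.dtf is None or self.dtf <= 0):
            raise ValueError(f"{self.plant_id}: flowered plants need dtf > 0")
        if not self.flowered and self.dtf is not None:
            raise ValueError(f"{self.plant_id}: non-flowered plants carry no dtf")


@dataclass(frozen=True)
class SegregationResult:
    """Chi-square goodness-of-fit of genotype counts to a Mendelian ratio."""

    observed: tuple[int, ...]
    expected_ratio: tuple[float, ...]
    chi2: float
    df: int
    p: float


@dataclass
class CandidateInterval:
    """Locus interval delimited by flanking markers from recombinant analysis.

    ``left_marker`` / ``right_marker`` of ``None`` denote a chromosome
    end (the recombinants only bound the locus on one side).
    """

    chrom: str
    left_marker: Optional[str]
    right_marker: Optional[str]
    span_bp: Optional[int]
    supporting_recombinants: list[str] = field(default_factory=list)
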