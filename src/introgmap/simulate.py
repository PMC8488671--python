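"""Synthetic data generator for the pooled-reference coverage design.

Emulates the statistical structure of whole-genome sequencing of a
diploid introgression line mapped against the pooled genomes of its two
parent species:

* two mostly collinear parental gene annotations, optionally with
  donor-specific tandem gene insertions between conserved flank genes
  (the MAR-like presence/absence variant);
* per-gene fragment counts under a Poisson (optionally gamma-Poisson)
  coverage model with a cross-mapping fraction ``f``: a fragment from one
  species' allele is counted on the other species' gene copy with
  probability ``f``.  With recurrent dosage ``a`` and donor dosage
  ``b = 2 - a``, the expected count on the recurrent copy of a gene of
  length ``L`` is ``lambda * (L/1000) * (a*(1-f) + b*f)`` and on the
  donor copy ``lambda * (L/1000) * (b*(1-f) + a*f)``.  At the default
  ``f = 1/3`` the expected recurrent/donor FPKM ratio is 2, 1 and 0.5
  for the three zygosity classes;
* a selfed-heterozygote progeny population segregating 1:2:1 at a
  codominant flowering-time locus, with marker genotypes transmitted
  through two independent gametes recombining under the Haldane map
  function, and phenotype DTF = mu + a_effect * (donor dose - 1) + noise.

All randomness flows from ``SimConfig.seed`` through independent
substreams, so every output is reproducible byte-for-byte and
``simulate_counts`` for one sample does not depend on what else was
drawn before it.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import CountTable, GeneAnnotation, ProgenyRecord, Zygosity

__all__ = [
    "SimConfig",
    "MosaicSpec",
    "generate_parents",
    "simulate_counts",
    "simulate_progeny",
    "ortholog_id_map",
]

RECURRENT = "recurrent"
DONOR = "donor"


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Parameters
    ----------
    seed
        Master seed; fixes every downstream draw.
    n_chrom, genes_per_chrom
        Genome layout of the recurrent parent (the donor is collinear
        apart from configured insertions).
    mean_gene_length, min_gene_length
        Gene lengths (bp) are drawn as ``min + Exponential(mean - min)``;
        the floor avoids near-zero-length FPKM denominators.
    mean_intergenic
        Mean intergenic gap (bp).
    depth_lambda
        Expected fragments per allele copy per kb of gene.
    crossmap_f
        Cross-mapping fraction ``f`` in [0, 0.5): probability that a
        fragment from one species' allele is counted on the other
        species' homologous copy. Must stay below 0.5 or the three
        zygosity classes' expected ratios collapse.
    overdispersion
        Extra-Poisson variance: counts are gamma-Poisson with
        ``Var = mu + overdispersion * mu**2``; 0 gives pure Poisson.
    donor_specific_insertions
        List of ``(chrom_index, gene_index)`` (both 0-based): a 2-gene
        donor-only tandem is inserted between ortholog ``gene_index``
        and ``gene_index + 1`` on that donor chromosome.
    recomb_cM_per_interval
        Map distance (cM) between adjacent markers in the progeny
        simulation.
    locus_effect_a
        Additive days-to-flower effect per donor allele dose at the
        causal locus (het is exactly intermediate: codominant).
    pheno_mu, pheno_sigma
        Baseline DTF (days; the heterozygote mean) and residual SD.
    nf_threshold
        Optional DTF above which a plant is scored "not flowered by the
        end of the experiment" (flowered=False, dtf dropped); None
        disables censoring.
    """

    seed: int = 0
    n_chrom: int = 2
    genes_per_chrom: int = 400
    mean_gene_length: float = 2000.0
    min_gene_length: int = 300
    mean_intergenic: float = 2000.0
    depth_lambda: float = 100.0
    crossmap_f: float = 1.0 / 3.0
    overdispersion: float = 0.0
    donor_specific_insertions: list[tuple[int, int]] = field(default_factory=list)
    recomb_cM_per_interval: float = 5.0
    locus_effect_a: float = 30.0
    pheno_mu: float = 60.0
    pheno_sigma: float = 3.0
    nf_threshold: Optional[float] = None
    # population sizes for pipeline runs
    n_progeny: int = 200
    n_markers: int = 12
    n_parent_controls: int = 12

    def __post_init__(self) -> None:
        if not 0.0 <= self.crossmap_f < 0.5:
            raise ValueError("crossmap_f must lie in [0, 0.5)")
        for name in ("mean_gene_length", "min_gene_length", "mean_intergenic",
                     "depth_lambda", "pheno_sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.mean_gene_length <= self.min_gene_length:
            raise ValueError("mean_gene_length must exceed min_gene_length")
        if self.n_chrom < 1 or self.genes_per_chrom < 2:
            raise ValueError("need at least 1 chromosome with 2 genes")
        if self.overdispersion < 0:
            raise ValueError("overdispersion must be >= 0")

    def rng(self, *stream: int | str) -> np.random.Generator:
        """Independent substream keyed by (seed, *stream)."""
        key = [self.seed % (2**31)]
        for s in stream:
            key.append(zlib.crc32(str(s).encode()) % (2**31))
        return np.random.default_rng(key)


@dataclass
class MosaicSpec:
    """The true diploid mosaic of one introgression line.

    ``segments`` are ``(chrom, start_gene_index, end_gene_index,
    zygosity)`` with inclusive 0-based gene indices; per chromosome they
    must be sorted, non-overlapping, and tile every gene index.
    """

    sample_id: str
    segments: list[tuple[str, int, int, Zygosity]]

    def validate(self, n_genes: dict[str, int]) -> None:
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, s, e, z in self.segments:
            if chrom not in n_genes:
                raise ValueError(f"mosaic references unknown chromosome {chrom}")
            if z is Zygosity.AMBIGUOUS:
                raise ValueError("mosaic segments must carry a definite zygosity")
            by_chrom.setdefault(chrom, []).append((s, e))
        for chrom, n in n_genes.items():
            ivs = sorted(by_chrom.get(chrom, []))
            covered = [i for s, e in ivs for i in range(s, e + 1)]
            if covered != list(range(n)):
                raise ValueError(
                    f"segments on {chrom} must tile gene indices 0..{n - 1} "
                    "without overlap"
                )

    def dosage(self, chrom: str, gene_index: int) -> int:
        """Recurrent-allele dosage a at one gene; donor dosage is 2 - a."""
        for c, s, e, z in self.segments:
            if c == chrom and s <= gene_index <= e:
                return z.recurrent_dose
        raise KeyError(f"gene index {gene_index} on {chrom} not covered by mosaic")


def _chrom_name(i: int) -> str:
    return f"chr{i + 1}"


def generate_parents(
    config: SimConfig,
) -> tuple[list[GeneAnnotation], list[GeneAnnotation], pd.DataFrame]:
    """Generate the two parental annotations and a gene-similarity table.

    The recurrent and donor genomes are collinear 1:1 orthologs sharing
    gene lengths (near-isogenic homologs), except that each configured
    insertion adds a 2-gene donor-only tandem between two conserved
    flank genes. The similarity table assigns the highest scores to true
    ortholog pairs plus low-score off-target noise, so reciprocal-best
    pairing recovers the truth.

    Returns
    -------
    (annotation_recurrent, annotation_donor, similarity)
        Annotations sorted by (chrom, start); similarity has columns
        ``gene_a`` (recurrent), ``gene_b`` (donor), ``score``.
    """
    rng = config.rng("parents")
    insertions_by_chrom: dict[int, list[int]] = {}
    for ci, gi in config.donor_specific_insertions:
        if not (0 <= ci < config.n_chrom):
            raise ValueError(f"insertion chromosome index {ci} out of range")
        if not (0 <= gi < config.genes_per_chrom - 1):
            raise ValueError(
                f"insertion gene index {gi} needs conserved flanks on both "
                f"sides (0 <= index < {config.genes_per_chrom - 1})"
            )
        insertions_by_chrom.setdefault(ci, []).append(gi)

    ann_r: list[GeneAnnotation] = []
    ann_d: list[GeneAnnotation] = []
    sim_rows: list[tuple[str, str, float]] = []

    for ci in range(config.n_chrom):
        chrom = _chrom_name(ci)
        n = config.genes_per_chrom
        lengths = (
            config.min_gene_length
            + rng.exponential(config.mean_gene_length - config.min_gene_length, n)
        ).astype(int)
        strands = rng.choice(["+", "-"], n)
        gaps_r = rng.exponential(config.mean_intergenic, n).astype(int) + 50
        gaps_d = rng.exponential(config.mean_intergenic, n).astype(int) + 50

        # recurrent chromosome
        pos = 1
        rec_ids = []
        for i in range(n):
            pos += gaps_r[i]
            gid = f"R{ci + 1:02d}G{i + 1:05d}"
            rec_ids.append(gid)
            ann_r.append(GeneAnnotation(gid, RECURRENT, chrom, pos,
                                        pos + int(lengths[i]) - 1, strands[i]))
            pos += int(lengths[i])

        # donor chromosome: same gene order with tandems spliced in
        ins_here = sorted(insertions_by_chrom.get(ci, []))
        pos = 1
        for i in range(n):
            pos += gaps_d[i]
            gid = f"D{ci + 1:02d}G{i + 1:05d}"
            ann_d.append(GeneAnnotation(gid, DONOR, chrom, pos,
                                        pos + int(lengths[i]) - 1, strands[i]))
            pos += int(lengths[i])
            if i in ins_here:
                for t in (1, 2):
                    tlen = int(config.min_gene_length
                               + rng.exponential(config.mean_gene_length
                                                 - config.min_gene_length))
                    pos += int(rng.exponential(config.mean_intergenic)) + 50
                    tid = f"D{ci + 1:02d}INS{i + 1:05d}T{t}"
                    ann_d.append(GeneAnnotation(tid, DONOR, chrom, pos,
                                                pos + tlen - 1, "+"))
                    pos += tlen

        # similarity: true orthologs score high, plus off-target noise
        true_scores = rng.uniform(90.0, 100.0, n)
        for i in range(n):
            sim_rows.append((rec_ids[i], f"D{ci + 1:02d}G{i + 1:05d}",
                             float(true_scores[i])))
        n_noise = max(1, n // 4)
        noise_a = rng.integers(0, n, n_noise)
        noise_b = rng.integers(0, n, n_noise)
        noise_s = rng.uniform(20.0, 60.0, n_noise)
        for a, b, s in zip(noise_a, noise_b, noise_s):
            if a != b:
                sim_rows.append((rec_ids[a], f"D{ci + 1:02d}G{b + 1:05d}", float(s)))
        # inserted tandems: weak spurious hits only
        for i in ins_here:
            for t in (1, 2):
                j = int(rng.integers(0, n))
                sim_rows.append((rec_ids[j], f"D{ci + 1:02d}INS{i + 1:05d}T{t}",
                                 float(rng.uniform(20.0, 55.0))))

    ann_r.sort(key=lambda g: (g.chrom, g.start))
    ann_d.sort(key=lambda g: (g.chrom, g.start))
    similarity = (
        pd.DataFrame(sim_rows, columns=["gene_a", "gene_b", "score"])
        .drop_duplicates(subset=["gene_a", "gene_b"])
        .reset_index(drop=True)
    )
    return ann_r, ann_d, similarity


def ortholog_id_map(
    annotation_recurrent: Sequence[GeneAnnotation],
    annotation_donor: Sequence[GeneAnnotation],
) -> dict[str, str]:
    """True recurrent -> donor ortholog mapping encoded in generated ids."""
    donor_ids = {g.gene_id for g in annotation_donor}
    out = {}
    for g in annotation_recurrent:
        did = "D" + g.gene_id[1:]
        if did in donor_ids:
            out[g.gene_id] = did
    return out


def _counts_from_mu(mu: np.ndarray, config: SimConfig,
                    rng: np.random.Generator) -> np.ndarray:
    if config.overdispersion > 0:
        shape = 1.0 / config.overdispersion
        rate = np.where(mu > 0, shape / np.maximum(mu, 1e-300), 0.0)
        lam = np.where(mu > 0, rng.gamma(shape, 1.0 / np.maximum(rate, 1e-300)), 0.0)
        return rng.poisson(lam)
    return rng.poisson(mu)


def simulate_counts(
    mosaic: MosaicSpec,
    parents: tuple,
    config: SimConfig,
) -> CountTable:
    """Draw per-gene fragment counts for one introgression line.

    ``parents`` is the tuple returned by :func:`generate_parents` (only
    the two annotations are used). For every ortholog pair the recurrent
    copy receives ``Poisson(lambda * L/1000 * (a(1-f) + b f))`` fragments
    and the donor copy ``Poisson(lambda * L/1000 * (b(1-f) + a f))``.
    Donor-only genes draw ``Poisson(lambda * L/1000 * b (1-f))``: the
    cross-mapped fraction of their fragments has no recurrent homolog to
    land on and is treated as unassigned.
    """
    ann_r, ann_d = parents[0], parents[1]
    n_genes = {}
    for g in ann_r:
        n_genes[g.chrom] = n_genes.get(g.chrom, 0) + 1
    mosaic.validate(n_genes)

    rng = config.rng("counts", mosaic.sample_id)
    f = config.crossmap_f
    lam = config.depth_lambda

    # gene index of each recurrent gene along its chromosome (annotation order)
    idx_on_chrom: dict[str, int] = {}
    seen: dict[str, int] = {}
    for g in ann_r:
        idx_on_chrom[g.gene_id] = seen.get(g.chrom, 0)
        seen[g.chrom] = seen.get(g.chrom, 0) + 1

    orth = ortholog_id_map(ann_r, ann_d)
    donor_by_id = {g.gene_id: g for g in ann_d}

    rows = []
    mus = []
    for g in ann_r:
        a = mosaic.dosage(g.chrom, idx_on_chrom[g.gene_id])
        b = 2 - a
        kb = g.length / 1000.0
        mus.append(lam * kb * (a * (1 - f) + b * f))
        rows.append((g.gene_id, RECURRENT, g.chrom, g.start, g.end, g.length))
        d = donor_by_id[orth[g.gene_id]]
        mus.append(lam * kb * (b * (1 - f) + a * f))
        rows.append((d.gene_id, DONOR, d.chrom, d.start, d.end, d.length))

    paired_donor = set(orth.values())
    for d in ann_d:
        if d.gene_id in paired_donor:
            continue
        # donor-only insertion: dosage follows the left flank ortholog
        i = int(d.gene_id.split("INS")[1].split("T")[0]) - 1
        b = 2 - mosaic.dosage(d.chrom, i)
        mus.append(lam * (d.length / 1000.0) * b * (1 - f))
        rows.append((d.gene_id, DONOR, d.chrom, d.start, d.end, d.length))

    counts = _counts_from_mu(np.asarray(mus), config, rng)
    df = pd.DataFrame(rows, columns=["gene_id", "species", "chrom",
                                     "start", "end", "length_bp"])
    df["count"] = counts
    df = df.sort_values(["species", "chrom", "start"],
                        ascending=[False, True, True]).reset_index(drop=True)
    return CountTable(mosaic.sample_id, df, int(df["count"].sum()))


def _haldane_r(cm: float) -> float:
    """Haldane map function: recombination fraction from map distance."""
    return 0.5 * (1.0 - np.exp(-2.0 * cm / 100.0))


def simulate_progeny(
    parent_mosaic: MosaicSpec,
    markers: Sequence[tuple[str, str, int]],
    n: int,
    config: SimConfig,
    annotation: Sequence[GeneAnnotation],
    locus_pos_bp: Optional[int] = None,
) -> list[ProgenyRecord]:
    """Self the line and genotype/phenotype ``n`` progeny.

    ``markers`` are ``(marker_id, chrom, position_bp)`` sorted by
    position within each chromosome; adjacent markers on the locus
    chromosome are ``recomb_cM_per_interval`` cM apart, with the causal
    locus splitting its interval proportionally by bp. The parent must
    be heterozygous for exactly one segment, which harbours the locus
    (default position: the segment's bp midpoint). Each progeny receives
    two independently recombined gametes; the locus genotype is therefore
    1:2:1 and its phenotype is codominant additive:
    ``DTF = mu + a_effect * (donor_dose - 1) + Normal(0, sigma^2)``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    het = [(c, s, e) for c, s, e, z in parent_mosaic.segments if z is Zygosity.HET]
    if len(het) != 1:
        raise ValueError("parent mosaic must contain exactly one HET segment")
    het_chrom, het_s, het_e = het[0]

    genes_on = [g for g in annotation if g.chrom == het_chrom]
    genes_on.sort(key=lambda g: g.start)
    het_start_bp = genes_on[het_s].start
    het_end_bp = genes_on[het_e].end
    if locus_pos_bp is None:
        locus_pos_bp = (het_start_bp + het_end_bp) // 2
    if not (het_start_bp <= locus_pos_bp <= het_end_bp):
        raise ValueError(
            f"locus at {locus_pos_bp} bp lies outside the HET segment "
            f"[{het_start_bp}, {het_end_bp}]"
        )

    def seg_zyg(chrom: str, pos: int) -> Zygosity:
        """Parental zygosity at a bp position (segment of the nearest gene)."""
        genes = [g for g in annotation if g.chrom == chrom]
        genes.sort(key=lambda g: g.start)
        idx = int(np.searchsorted([g.start for g in genes], pos, side="right")) - 1
        idx = min(max(idx, 0), len(genes) - 1)
        for c, s, e, z in parent_mosaic.segments:
            if c == chrom and s <= idx <= e:
                return z
        raise KeyError(f"position {pos} on {chrom} outside mosaic")

    # positions walked per chromosome; the locus is inserted on its chromosome
    by_chrom: dict[str, list[tuple[str, int]]] = {}
    for mid, chrom, pos in markers:
        by_chrom.setdefault(chrom, []).append((mid, pos))
    for chrom in by_chrom:
        by_chrom[chrom].sort(key=lambda t: t[1])

    LOCUS = "__locus__"
    locus_chrom_points = list(by_chrom.get(het_chrom, []))
    locus_chrom_points.append((LOCUS, int(locus_pos_bp)))
    locus_chrom_points.sort(key=lambda t: t[1])
    by_chrom[het_chrom] = locus_chrom_points

    # map distances between consecutive walked points
    cm_between: dict[str, list[float]] = {}
    for chrom, pts in by_chrom.items():
        marker_pos = [p for name, p in pts if name != LOCUS]
        gaps = np.diff(marker_pos) if len(marker_pos) > 1 else np.array([1.0])
        bp_per_cm = (float(np.median(gaps)) / config.recomb_cM_per_interval
                     if len(marker_pos) > 1 and config.recomb_cM_per_interval > 0
                     else np.inf)
        cms = []
        for (na, pa), (nb, pb) in zip(pts, pts[1:]):
            if LOCUS in (na, nb):
                cms.append((pb - pa) / bp_per_cm if np.isfinite(bp_per_cm) else 0.0)
            else:
                cms.append(config.recomb_cM_per_interval)
        cm_between[chrom] = cms

    # parental haplotypes: h0 carries recurrent in HET segments, h1 donor;
    # HOM segments are identical on both haplotypes.
    def alleles(chrom: str, pos: int) -> tuple[int, int]:
        z = seg_zyg(chrom, pos)
        if z is Zygosity.HOM_RECURRENT:
            return (0, 0)
        if z is Zygosity.HOM_DONOR:
            return (1, 1)
        return (0, 1)  # HET: donor allele rides haplotype 1

    # parental alleles are fixed per walked point: precompute once
    alleles_at = {chrom: [alleles(chrom, pos) for _name, pos in pts]
                  for chrom, pts in by_chrom.items()}
    r_between = {chrom: [_haldane_r(c) for c in cms]
                 for chrom, cms in cm_between.items()}

    rng = config.rng("progeny", parent_mosaic.sample_id)
    records: list[ProgenyRecord] = []
    code = {0: "A", 1: "H", 2: "B"}

    for k in range(n):
        dose: dict[str, int] = {}
        locus_dose = 0
        for chrom, pts in by_chrom.items():
            rs = r_between[chrom]
            for _gamete in range(2):
                hap = int(rng.integers(0, 2))
                for j, (name, pos) in enumerate(pts):
                    if j > 0 and rng.random() < rs[j - 1]:
                        hap = 1 - hap
                    al = alleles_at[chrom][j][hap]
                    if name == LOCUS:
                        locus_dose += al
                    else:
                        dose[name] = dose.get(name, 0) + al
        dtf = float(config.pheno_mu
                    + config.locus_effect_a * (locus_dose - 1)
                    + rng.normal(0.0, config.pheno_sigma))
        flowered = True
        if config.nf_threshold is not None and dtf > config.nf_threshold:
            flowered = False
        records.append(ProgenyRecord(
            plant_id=f"{parent_mosaic.sample_id}-P{k + 1:04d}",
            marker_calls={mid: code[dose[mid]] for mid, _c, _p in markers},
            dtf=dtf if flowered else None,
            flowered=flowered,
        ))
        records[-1].locus_genotype = code[locus_dose]  # truth attribute for recovery tests
    return records
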