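"""Zygosity genotyping from pooled-reference gene coverage.

An introgression line sequenced against the pooled genomes of its two
parent species distributes each gene's fragments between the recurrent
and donor copies in proportion to allele dosage. After FPKM
normalisation (fragments per kilobase per million mapped,
``C * 1e9 / (L * N)``) the recurrent/donor ratio R of a syntenic gene
pair is expected near 2 when the line is homozygous recurrent, 1 when
heterozygous and 0.5 when homozygous donor. Per-gene calls are made by
thresholding R (defaults at the geometric midpoints sqrt(2) and
1/sqrt(2), symmetric on the log scale), denoised by a centred
majority-vote window, and merged into introgression segments with bp
extents.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import (AnchorPair, CountTable, GeneAnnotation,
                    IntrogressionSegment, SyntenyBlock, Zygosity, ZygosityCall)

__all__ = ["GenotypingParams", "compute_fpkm", "classify_pair",
           "call_segments", "genotype_sample", "GenotypeResult"]


@dataclass
class GenotypingParams:
    """Tunables of the ratio classifier and segment caller.

    pseudocount
        FPKM added to numerator and denominator; stabilises
        zero-coverage denominators without moving deep-coverage ratios.
    low_threshold, high_threshold
        R below/above these calls HOM_DONOR / HOM_RECURRENT; between
        them, HET. Must satisfy 0 < low < 1 < high.
    min_count
        Combined raw fragments below which a pair is AMBIGUOUS.
    smoothing_window
        Odd width of the centred majority-vote window (1 = no smoothing).
    min_segment_genes
        Runs shorter than this are absorbed or reported as gaps.
    min_presence_count
        Fragments needed to declare an unpaired (single-species) gene
        present in the line.
    """

    pseudocount: float = 0.1
    low_threshold: float = 1.0 / math.sqrt(2.0)
    high_threshold: float = math.sqrt(2.0)
    min_count: int = 10
    smoothing_window: int = 5
    min_segment_genes: int = 3
    min_presence_count: int = 5

    def __post_init__(self) -> None:
        if not (0 < self.low_threshold < 1 < self.high_threshold):
            raise ValueError("need 0 < low_threshold < 1 < high_threshold")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ValueError("smoothing_window must be odd and >= 1")


def compute_fpkm(
    counts: CountTable,
    annotations: Sequence[GeneAnnotation],
) -> pd.DataFrame:
    """FPKM per gene: ``C * 1e9 / (L * N)`` with L in bp, N total mapped.

    Returns a frame with columns gene_id, length_bp, count, fpkm in
    annotation order. Every counted gene must be annotated; N must be
    positive; counts must be non-negative.
    """
    if counts.total_mapped <= 0:
        raise ValueError("total_mapped must be > 0")
    lengths = {g.gene_id: g.length for g in annotations}
    missing = set(counts.counts["gene_id"]) - set(lengths)
    if missing:
        raise KeyError(f"no annotation for gene(s): {sorted(missing)[:3]}...")
    by_id = dict(zip(counts.counts["gene_id"], counts.counts["count"]))
    rows = []
    N = counts.total_mapped
    for g in annotations:
        if g.gene_id not in by_id:
            continue
        C = int(by_id[g.gene_id])
        if C < 0:
            raise ValueError(f"negative count for {g.gene_id}")
        rows.append((g.gene_id, g.length, C, C * 1e9 / (g.length * N)))
    return pd.DataFrame(rows, columns=["gene_id", "length_bp", "count", "fpkm"])


def classify_pair(
    fpkm_recurrent: float,
    fpkm_donor: float,
    raw_counts: int,
    params: GenotypingParams = GenotypingParams(),
    pair: Optional[AnchorPair] = None,
) -> ZygosityCall:
    """Call one syntenic gene pair from its recurrent/donor FPKM ratio.

    R = (FPKM_r + eps) / (FPKM_d + eps); R > high_threshold calls
    HOM_RECURRENT, R < low_threshold HOM_DONOR, otherwise HET. Pairs
    whose combined raw fragment count is below ``min_count`` are
    AMBIGUOUS regardless of R. Monotone in R by construction.
    """
    if not (np.isfinite(fpkm_recurrent) and np.isfinite(fpkm_donor)):
        raise ValueError("non-finite FPKM input")
    eps = params.pseudocount
    R = (fpkm_recurrent + eps) / (fpkm_donor + eps)
    if raw_counts < params.min_count:
        call = Zygosity.AMBIGUOUS
    elif R > params.high_threshold:
        call = Zygosity.HOM_RECURRENT
    elif R < params.low_threshold:
        call = Zygosity.HOM_DONOR
    else:
        call = Zygosity.HET
    return ZygosityCall(pair or AnchorPair("?", "?", 0.0), float(R), call,
                        float(fpkm_recurrent), float(fpkm_donor))


def _majority_smooth(calls: list[Zygosity], window: int) -> list[Zygosity]:
    """Centred sliding-window majority vote; ties keep the original call.

    Windows are truncated at the chromosome ends.
    """
    h = window // 2
    out = []
    for i, c in enumerate(calls):
        win = calls[max(0, i - h): i + h + 1]
        counts: dict[Zygosity, int] = {}
        for w in win:
            counts[w] = counts.get(w, 0) + 1
        top = max(counts.values())
        winners = [z for z, n in counts.items() if n == top]
        out.append(winners[0] if len(winners) == 1 else c)
    return out


def call_segments(
    calls: Sequence[ZygosityCall],
    genes: Sequence[GeneAnnotation],
    params: GenotypingParams = GenotypingParams(),
    sample_id: str = "",
    chrom: str = "",
) -> list[IntrogressionSegment]:
    """Merge ordered per-gene calls on one chromosome into segments.

    ``calls[i]`` belongs to ``genes[i]`` (the recurrent-genome gene),
    both sorted by position. AMBIGUOUS calls are dropped before
    smoothing; maximal runs of identical smoothed calls become
    segments. A run shorter than ``min_segment_genes`` is absorbed when
    its two flanking runs agree (the three merge); otherwise it is
    omitted as an ambiguous gap. ``fraction_concordant`` is the share
    of member genes whose raw call equals the segment call.
    """
    if len(calls) == 0:
        raise ValueError("empty call list")
    if len(calls) != len(genes):
        raise ValueError("calls and genes must align")

    keep = [(c, g) for c, g in zip(calls, genes) if c.call is not Zygosity.AMBIGUOUS]
    if not keep:
        return []
    raw = [c.call for c, _ in keep]
    smoothed = _majority_smooth(raw, params.smoothing_window)

    # run-length encode: (call, start_idx, end_idx) inclusive over `keep`
    runs: list[list] = []
    for i, c in enumerate(smoothed):
        if runs and runs[-1][0] is c:
            runs[-1][2] = i
        else:
            runs.append([c, i, i])

    def run_len(r) -> int:
        return r[2] - r[1] + 1

    changed = True
    while changed:
        changed = False
        for k, r in enumerate(runs):
            if run_len(r) >= params.min_segment_genes:
                continue
            left = runs[k - 1] if k > 0 else None
            right = runs[k + 1] if k + 1 < len(runs) else None
            if left is not None and right is not None and left[0] is right[0]:
                runs[k - 1] = [left[0], left[1], right[2]]
                del runs[k: k + 2]
                changed = True
                break

    segments = []
    for c, s, e in runs:
        if e - s + 1 < params.min_segment_genes:
            continue  # unabsorbable short run -> ambiguous gap
        member_raw = raw[s: e + 1]
        member_genes = [g for _cc, g in keep[s: e + 1]]
        segments.append(IntrogressionSegment(
            sample_id=sample_id,
            chrom=chrom or member_genes[0].chrom,
            zygosity=c,
            first_gene=member_genes[0].gene_id,
            last_gene=member_genes[-1].gene_id,
            start_bp=member_genes[0].start,
            end_bp=member_genes[-1].end,
            n_genes=len(member_genes),
            fraction_concordant=float(np.mean([m is c for m in member_raw])),
        ))
    return segments


@dataclass
class GenotypeResult:
    """End-to-end genotyping output for one sample."""

    sample_id: str
    calls: pd.DataFrame          # per-gene-pair: chrom, rank, gene ids, FPKMs, R, call
    segments: list[IntrogressionSegment]
    unpaired: pd.DataFrame       # single-species genes: gene_id, species, count, present

    def gene_calls_from_segments(self) -> pd.DataFrame:
        """Per-gene zygosity after segmentation (gene takes its segment's call)."""
        rows = []
        seg_by_chrom: dict[str, list[IntrogressionSegment]] = {}
        for s in self.segments:
            seg_by_chrom.setdefault(s.chrom, []).append(s)
        for row in self.calls.itertuples(index=False):
            call = Zygosity.AMBIGUOUS
            for s in seg_by_chrom.get(row.chrom, []):
                if s.start_bp <= row.start and row.end <= s.end_bp:
                    call = s.zygosity
                    break
            rows.append((row.gene_recurrent, row.chrom, call.value))
        return pd.DataFrame(rows, columns=["gene_recurrent", "chrom", "call"])


def genotype_sample(
    counts: CountTable,
    annotations: tuple[Sequence[GeneAnnotation], Sequence[GeneAnnotation]],
    blocks: Sequence[SyntenyBlock],
    params: GenotypingParams = GenotypingParams(),
) -> GenotypeResult:
    """FPKM -> per-pair zygosity -> per-chromosome segments, one sample.

    Genes in no block (single-species genes) are reported with a
    coverage presence/absence status instead of a ratio: a donor-only
    gene with ``count >= min_presence_count`` marks the donor allele as
    present in the line.
    """
    ann_r, ann_d = annotations
    fpkm = compute_fpkm(counts, list(ann_r) + list(ann_d))
    fpkm_by_id = dict(zip(fpkm["gene_id"], fpkm["fpkm"]))
    count_by_id = dict(zip(fpkm["gene_id"], fpkm["count"]))
    gene_by_id = {g.gene_id: g for g in ann_r}

    pair_rows = []
    for b in blocks:
        for p in b.pairs:
            fr = fpkm_by_id.get(p.gene_recurrent)
            fd = fpkm_by_id.get(p.gene_donor)
            if fr is None or fd is None:
                raise KeyError(f"no counts for pair {p.gene_recurrent}/{p.gene_donor}")
            rawsum = int(count_by_id[p.gene_recurrent] + count_by_id[p.gene_donor])
            zc = classify_pair(fr, fd, rawsum, params, pair=p)
            g = gene_by_id[p.gene_recurrent]
            pair_rows.append((g.chrom, p.rank_r, g.start, g.end,
                              p.gene_recurrent, p.gene_donor,
                              zc.fpkm_recurrent, zc.fpkm_donor, zc.ratio,
                              zc.call, zc))
    calls_df = pd.DataFrame(
        pair_rows,
        columns=["chrom", "rank", "start", "end", "gene_recurrent",
                 "gene_donor", "fpkm_r", "fpkm_d", "ratio", "call", "_zc"],
    ).sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)

    segments: list[IntrogressionSegment] = []
    for chrom, sub in calls_df.groupby("chrom", sort=True):
        zcs = list(sub["_zc"])
        genes = [gene_by_id[g] for g in sub["gene_recurrent"]]
        segments.extend(call_segments(zcs, genes, params,
                                      sample_id=counts.sample_id, chrom=chrom))

    paired = {p.gene_recurrent for b in blocks for p in b.pairs} | \
             {p.gene_donor for b in blocks for p in b.pairs}
    unp_rows = []
    for g in list(ann_r) + list(ann_d):
        if g.gene_id in paired or g.gene_id not in count_by_id:
            continue
        c = int(count_by_id[g.gene_id])
        unp_rows.append((g.gene_id, g.species, g.chrom, c,
                         c >= params.min_presence_count))
    unpaired = pd.DataFrame(
        unp_rows, columns=["gene_id", "species", "chrom", "count", "present"])

    calls_out = calls_df.drop(columns="_zc").copy()
    calls_out["call"] = [c.value for c in calls_out["call"]]
    return GenotypeResult(counts.sample_id, calls_out, segments, unpaired)
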