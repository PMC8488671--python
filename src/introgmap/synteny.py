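"""Ortholog pairing and collinear chaining into syntenic blocks.

Candidate orthologs are reciprocal best hits (RBH) in a pairwise
gene-similarity table (e.g. whole-proteome BLAST bit scores); anchors
are then chained by a sparse dynamic program over gene-rank space,
separately for the forward and inverted orientations, with a linear
penalty per skipped gene rank. This mirrors the classic anchor-chaining
design (DAGChainer-style) at gene-level resolution: ordinal ranks, not
bp midpoints, are the DP coordinates, which keeps the chainer robust to
gene-length heterogeneity.
"""

from __future__ import annotations

from typing import Optional, Sequence

import pandas as pd

from .model import AnchorPair, GeneAnnotation, SyntenyBlock

__all__ = ["gene_ranks", "best_hit_pairs", "chain_collinear", "unpaired_genes"]


def gene_ranks(
    annotations: Sequence[GeneAnnotation],
) -> dict[str, tuple[str, int]]:
    """Map gene_id -> (chrom, 0-based ordinal rank along its chromosome)."""
    out: dict[str, tuple[str, int]] = {}
    per_chrom: dict[str, int] = {}
    for g in sorted(annotations, key=lambda g: (g.chrom, g.start)):
        r = per_chrom.get(g.chrom, 0)
        out[g.gene_id] = (g.chrom, r)
        per_chrom[g.chrom] = r + 1
    return out


def best_hit_pairs(
    similarity: pd.DataFrame,
    min_score: float = 0.0,
    annotation_recurrent: Optional[Sequence[GeneAnnotation]] = None,
    annotation_donor: Optional[Sequence[GeneAnnotation]] = None,
) -> list[AnchorPair]:
    """Reciprocal-best-hit anchor pairs from a similarity table.

    Parameters
    ----------
    similarity
        Columns ``gene_a`` (recurrent genome), ``gene_b`` (donor
        genome), ``score``. Duplicate (gene_a, gene_b) rows must agree
        on the score.
    min_score
        Pairs below this score are discarded (>= 0).
    annotation_recurrent, annotation_donor
        If given, each pair is annotated with chromosome and ordinal
        rank, which the chainer requires.

    Ties for "best" are broken toward the lexicographically smallest
    partner id, so the result is deterministic.
    """
    if min_score < 0:
        raise ValueError("min_score must be >= 0")
    if similarity.empty:
        return []
    df = similarity[["gene_a", "gene_b", "score"]].copy()
    dup = df.groupby(["gene_a", "gene_b"])["score"].nunique()
    if (dup > 1).any():
        bad = dup[dup > 1].index[0]
        raise ValueError(f"conflicting scores for pair {bad}")
    df = df.drop_duplicates(["gene_a", "gene_b"])

    def best(by: str, partner: str) -> pd.Series:
        d = df.sort_values(["score", partner], ascending=[False, True],
                           kind="mergesort")
        return d.groupby(by, sort=False)[partner].first()

    best_of_a = best("gene_a", "gene_b")
    best_of_b = best("gene_b", "gene_a")

    score_map = {(a, b): s for a, b, s in df.itertuples(index=False)}
    ranks_r = gene_ranks(annotation_recurrent) if annotation_recurrent else {}
    ranks_d = gene_ranks(annotation_donor) if annotation_donor else {}

    pairs = []
    for a, b in best_of_a.items():
        if best_of_b.get(b) != a:
            continue
        s = score_map[(a, b)]
        if s < min_score:
            continue
        cr, rr = ranks_r.get(a, (None, None))
        cd, rd = ranks_d.get(b, (None, None))
        pairs.append(AnchorPair(a, b, float(s), rr, rd, cr, cd))
    pairs.sort(key=lambda p: (p.chrom_r or "", p.rank_r if p.rank_r is not None
                              else 0, p.gene_recurrent))
    return pairs


def _best_chain(
    anchors: list[AnchorPair],
    orientation: str,
    max_gap: int,
    gap_penalty: float,
) -> tuple[float, list[int]]:
    """Highest-scoring single chain among ``anchors`` (indices returned).

    Classic sparse chaining recurrence: anchors sorted by rank_r; a
    predecessor j extends i when rank_r and rank_d both advance in the
    required direction by at most ``max_gap`` ranks, at a cost of
    ``gap_penalty`` per skipped rank on either genome. Exact, because
    the gap constraint binds only consecutive chain members.
    """
    order = sorted(range(len(anchors)), key=lambda i: anchors[i].rank_r)
    best = [anchors[i].score for i in range(len(anchors))]
    prev: list[Optional[int]] = [None] * len(anchors)
    first_rank = [anchors[i].rank_r for i in range(len(anchors))]
    for oi, i in enumerate(order):
        ai = anchors[i]
        for j in order[:oi]:
            aj = anchors[j]
            dr = ai.rank_r - aj.rank_r
            dd = (ai.rank_d - aj.rank_d) if orientation == "+" else (aj.rank_d - ai.rank_d)
            if dr < 1 or dd < 1 or dr > max_gap or dd > max_gap:
                continue
            cand = best[j] + ai.score - gap_penalty * ((dr - 1) + (dd - 1))
            if cand > best[i] or (cand == best[i] and first_rank[j] < first_rank[i]):
                best[i] = cand
                prev[i] = j
                first_rank[i] = first_rank[j]
    if not anchors:
        return float("-inf"), []
    end = max(range(len(anchors)),
              key=lambda i: (best[i], -first_rank[i], -anchors[i].rank_r))
    chain = []
    k: Optional[int] = end
    while k is not None:
        chain.append(k)
        k = prev[k]
    chain.reverse()
    return best[end], chain


def chain_collinear(
    anchors: Sequence[AnchorPair],
    max_gap: int = 5,
    gap_penalty: float = 1.0,
    min_block_size: int = 3,
) -> list[SyntenyBlock]:
    """Chain anchors into syntenic blocks, per chromosome pair.

    Repeatedly extracts the highest-scoring chain (forward or inverted;
    score ties broken toward the chain with the smaller first recurrent
    rank, then toward "+"), removes its anchors, and stops once the best
    remaining chain is shorter than ``min_block_size``. Each anchor
    therefore lands in at most one block. Blocks are returned sorted by
    (recurrent chromosome, first recurrent rank).
    """
    if max_gap < 0 or gap_penalty < 0:
        raise ValueError("max_gap and gap_penalty must be >= 0")
    if any(p.rank_r is None or p.rank_d is None for p in anchors):
        raise ValueError("anchors need rank_r/rank_d (pass annotations to "
                         "best_hit_pairs)")

    groups: dict[tuple, list[AnchorPair]] = {}
    for p in anchors:
        groups.setdefault((p.chrom_r, p.chrom_d), []).append(p)
    for key, grp in groups.items():
        if len({p.rank_r for p in grp}) != len(grp) or \
           len({p.rank_d for p in grp}) != len(grp):
            raise ValueError(f"duplicate anchor ranks in group {key}")

    blocks: list[SyntenyBlock] = []
    for key in sorted(groups, key=lambda k: (k[0] or "", k[1] or "")):
        remaining = sorted(groups[key], key=lambda p: p.rank_r)
        while remaining:
            cands = []
            for orient in ("+", "-"):
                score, chain = _best_chain(remaining, orient, max_gap, gap_penalty)
                if chain:
                    cands.append((score, -remaining[chain[0]].rank_r,
                                  orient == "+", orient, chain))
            if not cands:
                break
            score, _negrank, _plus, orient, chain = max(cands)
            if len(chain) < min_block_size:
                break
            members = [remaining[i] for i in chain]
            if len(members) == 1:
                orient = "+"
            blocks.append(SyntenyBlock(0, members, orient, float(score)))
            used = set(chain)
            remaining = [p for i, p in enumerate(remaining) if i not in used]
    blocks.sort(key=lambda b: (b.pairs[0].chrom_r or "", b.pairs[0].rank_r))
    for i, b in enumerate(blocks):
        b.block_id = i + 1
    return blocks


def unpaired_genes(
    annotations: tuple[Sequence[GeneAnnotation], Sequence[GeneAnnotation]],
    blocks: Sequence[SyntenyBlock],
) -> list[GeneAnnotation]:
    """Genes of either species absent from every syntenic block.

    Donor-specific insertions (and any recurrent genes deleted in the
    donor) surface here; downstream genotyping reports their
    presence/absence from coverage rather than a ratio.
    """
    in_blocks = set()
    for b in blocks:
        for p in b.pairs:
            in_blocks.add(p.gene_recurrent)
            in_blocks.add(p.gene_donor)
    out = []
    for ann in annotations:
        out.extend(g for g in ann if g.gene_id not in in_blocks)
    out.sort(key=lambda g: (g.species, g.chrom, g.start))
    return out
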