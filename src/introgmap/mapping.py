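"""Genetic mapping of a codominant flowering-time locus in progeny.

Downstream of genotyping: (i) chi-square goodness-of-fit of genotype
counts to a Mendelian ratio (1:2:1 for a selfed heterozygote at a
single codominant locus, df = 2); (ii) per-marker one-way ANOVA of
days-to-flowering across the A/H/B genotype classes, reporting F, p,
variance explained (R^2 = SS_between / SS_total) and a Bonferroni
adjustment; (iii) localisation of the causal locus to an interval
between flanking markers by intersecting the constraints that each
informative recombinant's phenotype class places on where the locus
can sit along its marker vector.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import CandidateInterval, ProgenyRecord, SegregationResult

__all__ = ["segregation_test", "marker_association", "classify_phenotype",
           "localize_interval", "IntervalConflictError"]

LATE, EARLY, AMBIG = "LATE", "EARLY", "AMBIGUOUS"


def segregation_test(
    observed: Sequence[int],
    ratio: Sequence[float] = (1, 2, 1),
) -> SegregationResult:
    """Chi-square goodness-of-fit of genotype class counts to a ratio.

    ``expected_i = total * r_i / sum(r)``; the statistic is
    ``sum((obs - exp)^2 / exp)`` on ``len(observed) - 1`` degrees of
    freedom, with an upper-tail p-value.
    """
    obs = np.asarray(observed, dtype=float)
    r = np.asarray(ratio, dtype=float)
    if obs.shape != r.shape:
        raise ValueError("observed and ratio lengths differ")
    if (obs < 0).any():
        raise ValueError("negative counts")
    if (r <= 0).any():
        raise ValueError("ratio components must be > 0")
    total = obs.sum()
    if total <= 0:
        raise ValueError("zero total count")
    exp = total * r / r.sum()
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    df = len(obs) - 1
    p = float(stats.chi2.sf(chi2, df))
    return SegregationResult(tuple(int(o) for o in obs), tuple(r), chi2, df, p)


def _anova(groups: list[np.ndarray]) -> tuple[float, float, float]:
    """One-way fixed-effects ANOVA: (F, p, R^2) from sums of squares."""
    all_vals = np.concatenate(groups)
    n = len(all_vals)
    grand = all_vals.mean()
    ss_total = float(((all_vals - grand) ** 2).sum())
    ss_between = float(sum(len(g) * (g.mean() - grand) ** 2 for g in groups))
    if ss_total == 0:
        return 0.0, 1.0, 0.0
    k = len(groups)
    ss_within = ss_total - ss_between
    df_b, df_w = k - 1, n - k
    if df_w <= 0 or ss_within <= 0:
        # saturated or zero residual: all between-group
        return float("inf"), 0.0, ss_between / ss_total
    F = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(F, df_b, df_w))
    return float(F), p, ss_between / ss_total


def marker_association(
    progeny: Sequence[ProgenyRecord],
    marker_ids: Optional[Sequence[str]] = None,
    marker_positions: Optional[dict[str, int]] = None,
    method: str = "anova",
) -> tuple[pd.DataFrame, Optional[str]]:
    """Associate each marker's genotype classes with days-to-flowering.

    Non-flowered (NF) plants are excluded from the phenotype means (they
    carry no DTF) and counted separately. A marker is testable when at
    least two genotype classes each contain >= 2 flowered plants.
    ``method="kruskal"`` swaps the ANOVA for a Kruskal-Wallis test
    (R^2 then reports the ANOVA-style SS ratio on ranks' groups means
    of the raw DTF for comparability).

    Returns (table, most_associated) where the table has one row per
    marker (marker_id, n, n_nf, classes, statistic, p, r2,
    p_bonferroni, testable) and ``most_associated`` minimises p, ties
    broken toward larger R^2 then the leftmost position (input order if
    no positions are given).
    """
    if marker_ids is None:
        marker_ids = list(progeny[0].marker_calls.keys()) if progeny else []
    rows = []
    for m in marker_ids:
        groups: dict[str, list[float]] = {}
        n_nf = 0
        for p in progeny:
            g = p.marker_calls.get(m, "-")
            if g == "-":
                continue
            if not p.flowered:
                n_nf += 1
                continue
            groups.setdefault(g, []).append(float(p.dtf))
        usable = [np.asarray(v) for v in groups.values() if len(v) >= 2]
        testable = len(usable) >= 2
        if testable:
            if method == "kruskal":
                try:
                    stat, pval = stats.kruskal(*usable)
                except ValueError:  # all values identical
                    stat, pval = 0.0, 1.0
                _f, _p, r2 = _anova(usable)
            else:
                stat, pval, r2 = _anova(usable)
        else:
            stat, pval, r2 = float("nan"), float("nan"), float("nan")
        rows.append((m, int(sum(len(g) for g in usable)), n_nf, len(usable),
                     stat, pval, r2, testable))
    table = pd.DataFrame(rows, columns=["marker_id", "n", "n_nf", "classes",
                                        "statistic", "p", "r2", "testable"])
    n_tests = int(table["testable"].sum())
    if n_tests == 0:
        raise ValueError("no testable marker")
    table["p_bonferroni"] = np.minimum(table["p"] * n_tests, 1.0)

    t = table[table["testable"]].copy()
    if marker_positions:
        t["pos"] = [marker_positions.get(m, i) for i, m in enumerate(t["marker_id"])]
    else:
        t["pos"] = range(len(t))
    t = t.sort_values(["p", "r2", "pos"], ascending=[True, False, True],
                      kind="mergesort")
    most = str(t.iloc[0]["marker_id"])
    return table, most


def classify_phenotype(
    parent_early_dtf: Sequence[float],
    parent_late_dtf: Sequence[float],
    progeny: Sequence[ProgenyRecord],
    k: float = 1.0,
) -> dict[str, str]:
    """Assign each plant LATE / EARLY / AMBIGUOUS from its DTF.

    Thresholds sit at the midpoint between the two parental control
    means, +/- ``k`` pooled SDs; plants inside the closed band are
    AMBIGUOUS (so at k = 0 a plant exactly at the midpoint is still
    AMBIGUOUS). Plants that never flowered are the extreme phenotype:
    LATE.
    """
    e = np.asarray(parent_early_dtf, dtype=float)
    l = np.asarray(parent_late_dtf, dtype=float)
    if len(e) == 0 or len(l) == 0:
        raise ValueError("both parental control distributions must be non-empty")
    if e.mean() > l.mean():
        e, l = l, e
    mid = (e.mean() + l.mean()) / 2.0
    dof = max(len(e) + len(l) - 2, 1)
    pooled_sd = float(np.sqrt(((len(e) - 1) * e.var(ddof=1) if len(e) > 1 else 0.0)
                              + ((len(l) - 1) * l.var(ddof=1) if len(l) > 1 else 0.0))
                      / np.sqrt(dof))
    lo, hi = mid - k * pooled_sd, mid + k * pooled_sd

    out = {}
    for p in progeny:
        if not p.flowered:
            out[p.plant_id] = LATE
        elif p.dtf > hi:
            out[p.plant_id] = LATE
        elif p.dtf < lo:
            out[p.plant_id] = EARLY
        else:
            out[p.plant_id] = AMBIG
    labels = [v for pid, v in out.items()]
    if labels and all(v == AMBIG for v in labels):
        import warnings
        warnings.warn("parental distributions overlap: every plant is AMBIGUOUS")
    return out


class IntervalConflictError(ValueError):
    """Recombinant constraints exclude every interval (phenotype/genotype
    inconsistency); carries the conflicting plant ids."""

    def __init__(self, plant_ids: list[str]):
        self.plant_ids = plant_ids
        super().__init__(
            f"no interval consistent with all informative plants: {plant_ids}")


def localize_interval(
    progeny: Sequence[ProgenyRecord],
    marker_positions: Sequence[tuple[str, str, int]],
    phenotype_classes: dict[str, str],
) -> CandidateInterval:
    """Intersect recombinant half-interval constraints to bound the locus.

    Under single-locus codominant inheritance the phenotype class bounds
    the donor-allele dose at the locus: a LATE plant carries at least
    one donor allele (genotype H or B there) and an EARLY plant at most
    one (A or H); AMBIGUOUS plants are ignored. The dose-bound (rather
    than exact-genotype) reading keeps heterozygotes that leak through
    the phenotype band consistent on either side. For each informative
    plant the locus may lie in an inter-marker interval only if a
    flanking marker's genotype satisfies the bound (inside the plant's
    breakpoint interval either allele is possible). The candidate
    interval is the intersection over plants; flanking markers of
    ``None`` denote a chromosome end.

    Raises :class:`IntervalConflictError` when the intersection is empty,
    listing the plants involved.
    """
    chroms = {c for _m, c, _p in marker_positions}
    if len(chroms) != 1:
        raise ValueError("markers must lie on a single chromosome")
    chrom = chroms.pop()
    mk = sorted(marker_positions, key=lambda t: t[2])
    ids = [m for m, _c, _p in mk]
    pos = {m: p for m, _c, p in mk}
    M = len(ids)
    # intervals 0..M: interval i lies between marker i-1 and marker i
    full = set(range(M + 1))

    allowed_all = set(full)
    informative: list[str] = []
    recombinants: list[str] = []
    for plant in progeny:
        cls = phenotype_classes.get(plant.plant_id, AMBIG)
        if cls == AMBIG:
            continue
        compatible = {"H", "B"} if cls == LATE else {"A", "H"}
        geno = [plant.marker_calls.get(m, "-") for m in ids]
        known = [g for g in geno if g != "-"]
        if not known:
            continue
        allowed = set()
        for i in range(M + 1):
            flanks = []
            if i > 0 and geno[i - 1] != "-":
                flanks.append(geno[i - 1])
            if i < M and geno[i] != "-":
                flanks.append(geno[i])
            if not flanks or any(g in compatible for g in flanks):
                allowed.add(i)
        if allowed == full:
            continue  # uninformative for localisation
        informative.append(plant.plant_id)
        if len(set(known)) > 1:
            recombinants.append(plant.plant_id)
        allowed_all &= allowed
        if not allowed_all:
            raise IntervalConflictError(informative)

    if not informative:
        raise ValueError("no informative plant (need >= 1 classified recombinant)")

    lo, hi = min(allowed_all), max(allowed_all)
    left = ids[lo - 1] if lo > 0 else None
    right = ids[hi] if hi < M else None
    span = (pos[right] - pos[left]) if (left is not None and right is not None) \
        else None
    return CandidateInterval(chrom, left, right, span, recombinants)
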