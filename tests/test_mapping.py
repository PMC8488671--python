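"""Segregation chi-square, marker ANOVA and recombinant localization."""

import numpy as np
import pytest
from scipy import stats
from scipy.special import gammaincc

from introgmap import (IntervalConflictError, MosaicSpec, ProgenyRecord,
                       SimConfig, Zygosity, classify_phenotype,
                       generate_parents, localize_interval,
                       marker_association, segregation_test,
                       simulate_progeny)


def chi2_oracle(observed, ratio):
    """Direct summation + regularized upper incomplete gamma tail."""
    obs = np.asarray(observed, float)
    r = np.asarray(ratio, float)
    exp = obs.sum() * r / r.sum()
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    df = len(obs) - 1
    return chi2, gammaincc(df / 2.0, chi2 / 2.0)


class TestSegregationTest:
    def test_exact_1_2_1_fit_gives_zero_statistic(self):
        res = segregation_test((25, 50, 25))
        assert res.chi2 == 0.0 and res.df == 2 and res.p == 1.0

    def test_hand_computed_statistic(self):
        # n=70, expected (17.5, 35, 17.5): 2*(0.25/17.5) + 1/35
        res = segregation_test((17, 36, 17))
        assert res.chi2 == pytest.approx(0.0571428571, abs=1e-9)

    def test_df_is_two_for_any_three_class_input(self):
        for obs in [(1, 1, 1), (100, 5, 3), (0, 10, 0)]:
            assert segregation_test(obs).df == 2

    def test_matches_incomplete_gamma_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            obs = tuple(int(x) for x in rng.integers(0, 200, 3))
            if sum(obs) == 0:
                continue
            ratio = tuple(float(x) for x in rng.integers(1, 5, 3))
            res = segregation_test(obs, ratio)
            chi2, p = chi2_oracle(obs, ratio)
            assert res.chi2 == pytest.approx(chi2, rel=1e-10, abs=1e-12)
            assert res.p == pytest.approx(p, rel=1e-10, abs=1e-12)

    def test_textbook_quantile(self):
        assert stats.chi2.sf(5.991, 2) == pytest.approx(0.0500, abs=1e-4)
        res = segregation_test((1, 2, 1))
        assert 0 <= res.p <= 1

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            segregation_test((0, 0, 0))
        with pytest.raises(ValueError):
            segregation_test((-1, 2, 1))
        with pytest.raises(ValueError):
            segregation_test((1, 2, 1), (1, 0, 1))


def _plant(pid, calls, dtf, flowered=True):
    return ProgenyRecord(pid, calls, dtf if flowered else None, flowered)


class TestMarkerAssociation:
    def test_constant_phenotype_gives_null_everywhere(self):
        plants = [_plant(f"p{i}", {"m1": "AHB"[i % 3], "m2": "A"}, 50.0)
                  for i in range(12)]
        table, _ = marker_association(plants, ["m1"])
        row = table.iloc[0]
        assert row["r2"] == 0.0 and row["p"] == 1.0

    def test_two_equal_classes_give_zero_f(self):
        plants = ([_plant(f"a{i}", {"m": "A"}, 40.0 + i) for i in range(4)]
                  + [_plant(f"b{i}", {"m": "B"}, 40.0 + i) for i in range(4)])
        table, _ = marker_association(plants, ["m"])
        assert table.iloc[0]["statistic"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(5)
        plants = [_plant(f"p{i}", {"m": "AHB"[int(rng.integers(3))]},
                         float(rng.normal(60, 5))) for i in range(60)]
        table, _ = marker_association(plants, ["m"])
        groups = {}
        for p in plants:
            groups.setdefault(p.marker_calls["m"], []).append(p.dtf)
        F, pval = stats.f_oneway(*groups.values())
        assert table.iloc[0]["statistic"] == pytest.approx(F, rel=1e-10)
        assert table.iloc[0]["p"] == pytest.approx(pval, rel=1e-10)

    def test_nf_plants_excluded_from_means_but_counted(self):
        plants = ([_plant(f"p{i}", {"m": "A"}, 30.0) for i in range(5)]
                  + [_plant(f"q{i}", {"m": "B"}, 90.0) for i in range(5)]
                  + [_plant("nf", {"m": "B"}, None, flowered=False)])
        table, _ = marker_association(plants, ["m"])
        assert table.iloc[0]["n"] == 10 and table.iloc[0]["n_nf"] == 1

    def test_recovers_causal_region_on_simulated_progeny(self):
        cfg = SimConfig(seed=23, n_chrom=1, genes_per_chrom=100)
        ann_r, _d, _s = generate_parents(cfg)
        mosaic = MosaicSpec("il", [("chr1", 0, 39, Zygosity.HOM_RECURRENT),
                                   ("chr1", 40, 59, Zygosity.HET),
                                   ("chr1", 60, 99, Zygosity.HOM_RECURRENT)])
        lo, hi = ann_r[0].start, ann_r[-1].end
        markers = [(f"M{i:02d}", "chr1", int(p))
                   for i, p in enumerate(np.linspace(lo, hi, 12).astype(int))]
        prog = simulate_progeny(mosaic, markers, 200, cfg, ann_r)
        _table, most = marker_association(
            prog, marker_positions={m: p for m, _c, p in markers})
        pos = dict((m, p) for m, _c, p in markers)
        het_lo, het_hi = ann_r[40].start, ann_r[59].end
        # most-associated marker must fall inside (or adjacent to) the
        # heterozygous introgression carrying the locus
        gap = pos["M01"] - pos["M00"]
        assert het_lo - gap <= pos[most] <= het_hi + gap

    def test_permutation_pvalues_uniform_under_null(self):
        """Permuting phenotypes across plants must give U(0,1) p-values."""
        rng = np.random.default_rng(11)
        genos = ["AHB"[int(rng.integers(3))] for _ in range(40)]
        dtf = rng.normal(60, 5, 40)
        pvals = []
        for _ in range(500):
            perm = rng.permutation(dtf)
            plants = [_plant(f"p{i}", {"m": genos[i]}, float(perm[i]))
                      for i in range(40)]
            table, _ = marker_association(plants, ["m"])
            pvals.append(table.iloc[0]["p"])
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_no_testable_marker_raises(self):
        plants = [_plant("p0", {"m": "A"}, 40.0)]
        with pytest.raises(ValueError):
            marker_association(plants, ["m"])


class TestClassifyPhenotype:
    def test_clear_extremes_and_nf_rule(self):
        early, late = [30.0, 31.0, 29.0], [90.0, 91.0, 89.0]
        plants = [_plant("a", {}, 95.0), _plant("b", {}, 28.0),
                  _plant("c", {}, 60.0), _plant("nf", {}, None, False)]
        cls = classify_phenotype(early, late, plants)
        assert cls == {"a": "LATE", "b": "EARLY", "c": "AMBIGUOUS",
                       "nf": "LATE"}

    def test_midpoint_with_zero_band_is_ambiguous(self):
        cls = classify_phenotype([40.0, 40.0], [80.0, 80.0],
                                 [_plant("x", {}, 60.0)], k=0.0)
        assert cls["x"] == "AMBIGUOUS"

    def test_fully_overlapping_parents_warn_all_ambiguous(self):
        plants = [_plant("x", {}, 60.0)]
        with pytest.warns(UserWarning):
            cls = classify_phenotype([59.0, 61.0], [58.0, 62.0], plants, k=5.0)
        assert cls["x"] == "AMBIGUOUS"

    def test_empty_controls_rejected(self):
        with pytest.raises(ValueError):
            classify_phenotype([], [50.0], [])


def _mk(n):
    return [(f"M{i}", "chr1", 1000 * (i + 1)) for i in range(n)]


class TestLocalizeInterval:
    def test_alternating_breakpoints_pin_unique_interval(self):
        """Four recombinants with breakpoints on alternating sides of the
        locus narrow it to the interval between markers 3 and 4."""
        markers = _mk(6)
        plants = [
            _plant("r1", dict(zip([m for m, _, _ in markers], "AAABBB")), 95.0),
            _plant("r2", dict(zip([m for m, _, _ in markers], "BBBBAA")), 94.0),
            _plant("r3", dict(zip([m for m, _, _ in markers], "AAABAA")), 96.0),
            _plant("r4", dict(zip([m for m, _, _ in markers], "BBBAAA")), 93.0),
        ]
        classes = {p.plant_id: "LATE" for p in plants}
        iv = localize_interval(plants, markers, classes)
        assert (iv.left_marker, iv.right_marker) == ("M2", "M3")
        assert iv.span_bp == 1000

    def test_single_recombinant_gives_half_open_interval(self):
        markers = _mk(6)
        p = _plant("r1", dict(zip([m for m, _, _ in markers], "ABBBBB")), 95.0)
        iv = localize_interval([p], markers, {"r1": "LATE"})
        assert iv.left_marker == "M0" and iv.right_marker is None

    def test_conflict_reports_plant_ids(self):
        markers = _mk(4)
        # LATE but homozygous recurrent everywhere: impossible under a
        # single codominant locus
        p = _plant("bad", dict(zip([m for m, _, _ in markers], "AAAA")), 95.0)
        with pytest.raises(IntervalConflictError) as e:
            localize_interval([p], markers, {"bad": "LATE"})
        assert "bad" in e.value.plant_ids

    def test_ambiguous_plants_ignored(self):
        markers = _mk(4)
        plants = [
            _plant("r1", dict(zip([m for m, _, _ in markers], "ABBB")), 95.0),
            _plant("x", dict(zip([m for m, _, _ in markers], "AAAA")), 60.0),
        ]
        classes = {"r1": "LATE", "x": "AMBIGUOUS"}
        iv = localize_interval(plants, markers, classes)
        assert iv.left_marker == "M0"

    def test_interval_never_excludes_true_locus_without_conflicts(self):
        """Repeated-simulation recovery: the reported interval contains
        the true simulated locus position."""
        hits = 0
        for seed in range(15):
            cfg = SimConfig(seed=seed, n_chrom=1, genes_per_chrom=100)
            ann_r, _d, _s = generate_parents(cfg)
            mosaic = MosaicSpec("il", [
                ("chr1", 0, 39, Zygosity.HOM_RECURRENT),
                ("chr1", 40, 59, Zygosity.HET),
                ("chr1", 60, 99, Zygosity.HOM_RECURRENT)])
            lo, hi = ann_r[0].start, ann_r[-1].end
            markers = [(f"M{i:02d}", "chr1", int(p)) for i, p in
                       enumerate(np.linspace(lo, hi, 12).astype(int))]
            prog = simulate_progeny(mosaic, markers, 150, cfg, ann_r)
            rng = cfg.rng("controls")
            classes = classify_phenotype(
                list(30 + rng.normal(0, 3, 12)),
                list(90 + rng.normal(0, 3, 12)), prog)
            truth = (ann_r[40].start + ann_r[59].end) // 2
            pos = {m: p for m, _c, p in markers}
            iv = localize_interval(prog, markers, classes)
            left = pos.get(iv.left_marker, lo - 1)
            right = pos.get(iv.right_marker, hi + 1)
            hits += left <= truth <= right
        assert hits == 15
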