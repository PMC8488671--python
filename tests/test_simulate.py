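"""The coverage and progeny simulator must reproduce the diploid
pooled-reference model it claims: dosage-driven expected counts with
cross-mapping, 1:2:1 codominant segregation, Haldane-linked markers."""

import numpy as np
import pandas as pd
import pytest

from introgmap import (MosaicSpec, SimConfig, Zygosity, generate_parents,
                       simulate_counts, simulate_progeny)
from introgmap.simulate import ortholog_id_map


def _hom(zyg, n=60, chrom="chr1"):
    return MosaicSpec("m", [(chrom, 0, n - 1, zyg)])


class TestConfig:
    def test_crossmap_fraction_must_stay_below_half(self):
        with pytest.raises(ValueError):
            SimConfig(crossmap_f=0.5)
        with pytest.raises(ValueError):
            SimConfig(crossmap_f=-0.01)

    def test_scales_must_be_positive(self):
        with pytest.raises(ValueError):
            SimConfig(depth_lambda=0)
        with pytest.raises(ValueError):
            SimConfig(pheno_sigma=-1)


class TestGenerateParents:
    def test_identity_layout_gives_one_to_one_orthologs(self):
        cfg = SimConfig(seed=5, n_chrom=1, genes_per_chrom=10)
        ann_r, ann_d, sim = generate_parents(cfg)
        assert len(ann_r) == len(ann_d) == 10
        assert len(ortholog_id_map(ann_r, ann_d)) == 10

    def test_tandem_insertion_adds_two_donor_only_genes(self):
        cfg = SimConfig(seed=5, n_chrom=1, genes_per_chrom=10,
                        donor_specific_insertions=[(0, 4)])
        ann_r, ann_d, _ = generate_parents(cfg)
        assert len(ann_r) == 10 and len(ann_d) == 12
        orth = ortholog_id_map(ann_r, ann_d)
        donor_only = {g.gene_id for g in ann_d} - set(orth.values())
        assert len(donor_only) == 2

    def test_flank_genes_separated_by_exactly_two_in_donor(self):
        cfg = SimConfig(seed=5, n_chrom=1, genes_per_chrom=10,
                        donor_specific_insertions=[(0, 4)])
        ann_r, ann_d, _ = generate_parents(cfg)
        order = [g.gene_id for g in sorted(ann_d, key=lambda g: g.start)]
        left, right = order.index("D01G00005"), order.index("D01G00006")
        assert right - left == 3  # two tandem genes between the flanks

    def test_insertion_position_out_of_range_rejected(self):
        cfg = SimConfig(seed=5, n_chrom=1, genes_per_chrom=10,
                        donor_specific_insertions=[(0, 9)])
        with pytest.raises(ValueError):
            generate_parents(cfg)

    def test_annotations_sorted_and_similarity_favours_true_pairs(self):
        cfg = SimConfig(seed=8, n_chrom=2, genes_per_chrom=30)
        ann_r, ann_d, sim = generate_parents(cfg)
        for ann in (ann_r, ann_d):
            keys = [(g.chrom, g.start) for g in ann]
            assert keys == sorted(keys)
        true_pairs = set(ortholog_id_map(ann_r, ann_d).items())
        best = sim.sort_values("score", ascending=False).groupby("gene_a").first()
        for a, row in best.iterrows():
            assert (a, row["gene_b"]) in true_pairs


class TestSimulateCounts:
    def test_no_crossmap_hom_donor_leaves_recurrent_empty(self, small_parents):
        cfg = SimConfig(seed=1, n_chrom=1, genes_per_chrom=60, crossmap_f=0.0)
        ct = simulate_counts(_hom(Zygosity.HOM_DONOR), small_parents, cfg)
        rec = ct.counts[ct.counts["species"] == "recurrent"]
        assert (rec["count"] == 0).all()

    @pytest.mark.parametrize("zyg,expected_ratio", [
        (Zygosity.HOM_DONOR, 0.5),
        (Zygosity.HET, 1.0),
        (Zygosity.HOM_RECURRENT, 2.0),
    ])
    def test_expected_count_ratio_under_f_third(self, zyg, expected_ratio):
        """(a(1-f)+bf)/(b(1-f)+af) at f=1/3 gives the 2 / 1 / 0.5 ladder."""
        cfg = SimConfig(seed=3, n_chrom=1, genes_per_chrom=400,
                        mean_gene_length=4000)
        parents = generate_parents(cfg)
        ct = simulate_counts(_hom(zyg, 400), parents, cfg)
        by_species = ct.counts.groupby("species")["count"].sum()
        ratio = by_species["recurrent"] / by_species["donor"]
        assert ratio == pytest.approx(expected_ratio, rel=0.03)

    def test_mean_het_ratio_within_two_percent_over_10000_genes(self):
        cfg = SimConfig(seed=9, n_chrom=1, genes_per_chrom=10000)
        parents = generate_parents(cfg)
        ct = simulate_counts(_hom(Zygosity.HET, 10000), parents, cfg)
        piv = ct.counts.pivot_table(index=ct.counts["gene_id"].str[3:],
                                    columns="species", values="count")
        piv = piv[piv["donor"] > 0]
        mean_ratio = (piv["recurrent"] / piv["donor"]).mean()
        assert abs(mean_ratio - 1.0) < 0.02

    def test_doubling_lambda_doubles_expected_totals(self, small_parents):
        cfg1 = SimConfig(seed=2, n_chrom=1, genes_per_chrom=60)
        cfg2 = SimConfig(seed=2, n_chrom=1, genes_per_chrom=60,
                         depth_lambda=200.0)
        t1 = simulate_counts(_hom(Zygosity.HET), small_parents, cfg1)
        t2 = simulate_counts(_hom(Zygosity.HET), small_parents, cfg2)
        assert t2.total_mapped / t1.total_mapped == pytest.approx(2.0, rel=0.05)

    def test_determinism_same_seed_identical_counts(self, small_parents,
                                                    thirds_mosaic, small_cfg):
        a = simulate_counts(thirds_mosaic, small_parents, small_cfg)
        b = simulate_counts(thirds_mosaic, small_parents, small_cfg)
        pd.testing.assert_frame_equal(a.counts, b.counts)
        assert a.total_mapped == b.total_mapped

    def test_mosaic_must_tile_chromosome(self, small_parents, small_cfg):
        bad = MosaicSpec("m", [("chr1", 0, 30, Zygosity.HET)])
        with pytest.raises(ValueError):
            simulate_counts(bad, small_parents, small_cfg)

    def test_donor_only_genes_covered_only_with_donor_dosage(self):
        cfg = SimConfig(seed=4, n_chrom=1, genes_per_chrom=20,
                        donor_specific_insertions=[(0, 9)])
        parents = generate_parents(cfg)
        ins = [g.gene_id for g in parents[1] if "INS" in g.gene_id]
        for zyg, expect_cov in [(Zygosity.HOM_RECURRENT, False),
                                (Zygosity.HOM_DONOR, True)]:
            ct = simulate_counts(_hom(zyg, 20), parents, cfg)
            cov = ct.counts.set_index("gene_id").loc[ins, "count"]
            assert (cov > 0).all() == expect_cov


@pytest.fixture(scope="module")
def setup():
    cfg = SimConfig(seed=21, n_chrom=1, genes_per_chrom=90)
    ann_r, ann_d, _ = generate_parents(cfg)
    mosaic = MosaicSpec("IL41", [
        ("chr1", 0, 29, Zygosity.HOM_RECURRENT),
        ("chr1", 30, 59, Zygosity.HET),
        ("chr1", 60, 89, Zygosity.HOM_RECURRENT)])
    lo, hi = ann_r[0].start, ann_r[-1].end
    markers = [(f"M{i:02d}", "chr1", int(p))
               for i, p in enumerate(np.linspace(lo, hi, 10).astype(int))]
    return cfg, ann_r, mosaic, markers


class TestSimulateProgeny:

    def test_locus_classes_within_3se_of_1_2_1(self, setup):
        cfg, ann_r, mosaic, markers = setup
        prog = simulate_progeny(mosaic, markers, 4000, cfg, ann_r)
        counts = {g: sum(p.locus_genotype == g for p in prog) for g in "AHB"}
        for g, expected in zip("AHB", (0.25, 0.5, 0.25)):
            se = np.sqrt(expected * (1 - expected) / 4000)
            assert abs(counts[g] / 4000 - expected) < 3 * se

    def test_null_effect_equalises_class_means(self, setup):
        cfg, ann_r, mosaic, markers = setup
        cfg0 = SimConfig(**{**cfg.__dict__, "locus_effect_a": 0.0})
        prog = simulate_progeny(mosaic, markers, 2000, cfg0, ann_r)
        means = {g: np.mean([p.dtf for p in prog if p.locus_genotype == g])
                 for g in "AHB"}
        spread = max(means.values()) - min(means.values())
        assert spread < 4 * cfg.pheno_sigma / np.sqrt(400)

    def test_zero_recombination_gives_constant_marker_vectors(self, setup):
        cfg, ann_r, mosaic, markers = setup
        cfg0 = SimConfig(**{**cfg.__dict__, "recomb_cM_per_interval": 1e-9})
        # restrict to markers inside the HET segment so all loci segregate
        s, e = ann_r[30].start, ann_r[59].end
        inside = [(m, c, p) for m, c, p in markers if s <= p <= e]
        prog = simulate_progeny(mosaic, inside, 50, cfg0, ann_r)
        for p in prog:
            assert len(set(p.marker_calls.values())) == 1

    def test_phenotype_is_codominant_additive(self, setup):
        cfg, ann_r, mosaic, markers = setup
        prog = simulate_progeny(mosaic, markers, 3000, cfg, ann_r)
        m = {g: np.mean([p.dtf for p in prog if p.locus_genotype == g])
             for g in "AHB"}
        assert m["H"] == pytest.approx((m["A"] + m["B"]) / 2, abs=0.5)
        assert m["B"] - m["A"] == pytest.approx(2 * cfg.locus_effect_a, abs=1.0)

    def test_locus_must_sit_in_het_segment(self, setup):
        cfg, ann_r, mosaic, markers = setup
        with pytest.raises(ValueError):
            simulate_progeny(mosaic, markers, 10, cfg, ann_r,
                             locus_pos_bp=ann_r[0].start)
        with pytest.raises(ValueError):
            simulate_progeny(mosaic, markers, 0, cfg, ann_r)

    def test_exactly_one_het_segment_required(self, setup):
        cfg, ann_r, _m, markers = setup
        hom = MosaicSpec("x", [("chr1", 0, 89, Zygosity.HOM_RECURRENT)])
        with pytest.raises(ValueError):
            simulate_progeny(hom, markers, 10, cfg, ann_r)
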