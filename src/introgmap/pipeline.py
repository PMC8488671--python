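"""End-to-end pipeline: simulate -> synteny -> genotype -> mapping.

Every run writes its artifacts plus a manifest (sha256 of inputs and
outputs, parameters, seed, package version) so a rerun with the same
config and seed is bit-exact and verifiably so.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from .config import PipelineConfig
from .genotyping import genotype_sample
from .mapping import (classify_phenotype, localize_interval,
                      marker_association, segregation_test)
from .model import Zygosity
from .simulate import (MosaicSpec, generate_parents, simulate_counts,
                       simulate_progeny)
from .synteny import best_hit_pairs, chain_collinear, unpaired_genes

log = logging.getLogger("introgmap")


def default_mosaic(config, sample_id: str = "IL") -> MosaicSpec:
    """A single-introgression line: one HET segment on chr1 (middle
    fifth of the gene ranks), homozygous recurrent elsewhere."""
    n = config.genes_per_chrom
    s, e = int(n * 0.4), int(n * 0.6) - 1
    segments = [("chr1", 0, s - 1, Zygosity.HOM_RECURRENT),
                ("chr1", s, e, Zygosity.HET),
                ("chr1", e + 1, n - 1, Zygosity.HOM_RECURRENT)]
    for c in range(1, config.n_chrom):
        segments.append((f"chr{c + 1}", 0, n - 1, Zygosity.HOM_RECURRENT))
    return MosaicSpec(sample_id, segments)


def default_markers(annotation, config, chrom: str = "chr1"):
    """Evenly bp-spaced markers spanning one chromosome."""
    genes = sorted((g for g in annotation if g.chrom == chrom),
                   key=lambda g: g.start)
    lo, hi = genes[0].start, genes[-1].end
    pos = np.linspace(lo, hi, config.n_markers).astype(int)
    return [(f"M{i + 1:02d}", chrom, int(p)) for i, p in enumerate(pos)]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns {artifact name: path}.

    With a ``simulate`` block the parental genomes, line coverage and
    progeny are generated from the seed; otherwise annotations, counts
    and similarity (and optionally progeny + markers) are read from the
    configured paths. Any stage failure aborts with a stage-named error.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    inputs: dict[str, Path] = {}

    # ------------------------------------------------------- simulate
    if config.simulate is not None:
        sim = dataclasses.replace(config.simulate, seed=config.seed)
        ann_r, ann_d, similarity = generate_parents(sim)
        mosaic = default_mosaic(sim)
        counts_tables = [simulate_counts(mosaic, (ann_r, ann_d), sim)]
        markers = default_markers(ann_r, sim)
        progeny = simulate_progeny(mosaic, markers, sim.n_progeny, sim, ann_r)
        rngc = sim.rng("controls")
        controls_early = list(sim.pheno_mu - sim.locus_effect_a
                              + rngc.normal(0, sim.pheno_sigma,
                                            sim.n_parent_controls))
        controls_late = list(sim.pheno_mu + sim.locus_effect_a
                             + rngc.normal(0, sim.pheno_sigma,
                                           sim.n_parent_controls))

        io.write_gff3(ann_r, out / "recurrent.gff3")
        io.write_gff3(ann_d, out / "donor.gff3")
        io.write_similarity(similarity, out / "similarity.tsv")
        io.write_counts(counts_tables[0], out / f"counts_{mosaic.sample_id}.tsv")
        io.write_mosaic(mosaic.segments, mosaic.sample_id, out / "truth_mosaic.tsv")
        io.write_markers(markers, out / "markers.tsv")
        io.write_progeny(progeny, out / "progeny.tsv")
        for name in ("recurrent.gff3", "donor.gff3", "similarity.tsv",
                     f"counts_{mosaic.sample_id}.tsv", "truth_mosaic.tsv",
                     "markers.tsv", "progeny.tsv"):
            artifacts[name] = out / name
        log.info("simulate: %d + %d genes, %d counts rows, %d progeny",
                 len(ann_r), len(ann_d), len(counts_tables[0].counts),
                 len(progeny))
    else:
        try:
            ann_r = io.read_gff3(config.annotation_recurrent, species="recurrent")
            ann_d = io.read_gff3(config.annotation_donor, species="donor")
            similarity = io.read_similarity(config.similarity)
            counts_tables = [io.read_counts(p) for p in config.counts]
            progeny = io.read_progeny(config.progeny) if config.progeny else None
            markers = io.read_markers(config.markers) if config.markers else None
            controls_early = controls_late = None
            for attr in ("annotation_recurrent", "annotation_donor",
                         "similarity", "progeny", "markers"):
                if getattr(config, attr):
                    inputs[attr] = Path(getattr(config, attr))
            inputs.update({f"counts_{i}": Path(p)
                           for i, p in enumerate(config.counts)})
        except Exception as exc:
            raise RuntimeError(f"stage input: {exc}") from exc

    # -------------------------------------------------------- synteny
    try:
        anchors = best_hit_pairs(similarity, config.synteny.min_score,
                                 annotation_recurrent=ann_r,
                                 annotation_donor=ann_d)
        blocks = chain_collinear(anchors, config.synteny.max_gap,
                                 config.synteny.gap_penalty,
                                 config.synteny.min_block_size)
        unpaired = unpaired_genes((ann_r, ann_d), blocks)
        io.write_blocks(blocks, out / "blocks.tsv")
        pd.DataFrame([(g.gene_id, g.species, g.chrom, g.start, g.end)
                      for g in unpaired],
                     columns=["gene_id", "species", "chrom", "start", "end"]
                     ).to_csv(out / "unpaired_genes.tsv", sep="\t", index=False,
                              lineterminator="\n")
        artifacts["blocks.tsv"] = out / "blocks.tsv"
        artifacts["unpaired_genes.tsv"] = out / "unpaired_genes.tsv"
        log.info("synteny: %d anchors, %d blocks, %d unpaired genes",
                 len(anchors), len(blocks), len(unpaired))
    except Exception as exc:
        raise RuntimeError(f"stage synteny: {exc}") from exc

    # ------------------------------------------------------- genotype
    try:
        for ct in counts_tables:
            res = genotype_sample(ct, (ann_r, ann_d), blocks, config.genotyping)
            base = f"calls_{ct.sample_id}"
            io.write_tsv(res.calls, out / f"{base}.tsv")
            io.write_segments_bed(res.segments, out / f"segments_{ct.sample_id}.bed")
            io.write_tsv(res.unpaired, out / f"unpaired_status_{ct.sample_id}.tsv")
            io.write_json(io.segment_summary(res.segments),
                          out / f"summary_{ct.sample_id}.json")
            for name in (f"{base}.tsv", f"segments_{ct.sample_id}.bed",
                         f"unpaired_status_{ct.sample_id}.tsv",
                         f"summary_{ct.sample_id}.json"):
                artifacts[name] = out / name
            log.info("genotype %s: %d gene calls, %d segments",
                     ct.sample_id, len(res.calls), len(res.segments))
    except Exception as exc:
        raise RuntimeError(f"stage genotype: {exc}") from exc

    # -------------------------------------------------------- mapping
    if progeny:
        try:
            pos_map = {m: p for m, _c, p in markers} if markers else None
            table, most = marker_association(
                progeny, marker_positions=pos_map,
                method=config.mapping.association_method)
            io.write_tsv(table, out / "association.tsv")
            artifacts["association.tsv"] = out / "association.tsv"

            counts3 = [0, 0, 0]
            for p in progeny:
                g = p.marker_calls.get(most, "-")
                if g in "AHB":
                    counts3["AHB".index(g)] += 1
            seg = segregation_test(counts3, config.mapping.segregation_ratio)
            io.write_json({"marker": most, "observed_AHB": list(seg.observed),
                           "expected_ratio": list(seg.expected_ratio),
                           "chi2": seg.chi2, "df": seg.df, "p": seg.p},
                          out / "segregation.json")
            artifacts["segregation.json"] = out / "segregation.json"

            interval_obj = None
            if markers and controls_early is not None:
                classes = classify_phenotype(controls_early, controls_late,
                                             progeny,
                                             k=config.mapping.phenotype_band_k)
                interval_obj = localize_interval(progeny, markers, classes)
                io.write_json({"chrom": interval_obj.chrom,
                               "left_marker": interval_obj.left_marker,
                               "right_marker": interval_obj.right_marker,
                               "span_bp": interval_obj.span_bp,
                               "supporting_recombinants":
                                   interval_obj.supporting_recombinants},
                              out / "candidate_interval.json")
                artifacts["candidate_interval.json"] = out / "candidate_interval.json"
            log.info("mapping: most-associated %s, chi2=%.4f (df=%d)",
                     most, seg.chi2, seg.df)
        except Exception as exc:
            raise RuntimeError(f"stage mapping: {exc}") from exc

    # ------------------------------------------------------- manifest
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "simulate": dataclasses.asdict(config.simulate)
            if config.simulate else None,
            "synteny": dataclasses.asdict(config.synteny),
            "genotyping": dataclasses.asdict(config.genotyping),
            "mapping": dataclasses.asdict(config.mapping),
        },
        "inputs": {k: _sha256(v) for k, v in sorted(inputs.items())},
        "artifacts": {k: _sha256(v) for k, v in sorted(artifacts.items())},
    }
    manifest["parameters"]["mapping"]["segregation_ratio"] = list(
        manifest["parameters"]["mapping"]["segregation_ratio"])
    io.write_json(manifest, out / "manifest.json")
    artifacts["manifest.json"] = out / "manifest.json"
    return {k: str(v) for k, v in artifacts.items()}
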