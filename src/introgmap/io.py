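"""Readers and writers for the pipeline's on-disk formats.

GFF3 for gene annotations (1-based inclusive, strict: 9 tab-separated
columns, ID attribute required, duplicate IDs rejected, line numbers in
error messages); TSV for every table (gene attributes may contain
commas); BED6 for introgression segments (converted to 0-based
half-open); JSON for machine-readable summaries. All writers emit a
final newline and a stable column order; readers tolerate LF and CRLF.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .model import (GeneAnnotation, CountTable, IntrogressionSegment,
                    ProgenyRecord, SyntenyBlock, AnchorPair)

PathLike = Union[str, Path]


# ---------------------------------------------------------------- GFF3

def read_gff3(path: PathLike, species: str = "") -> list[GeneAnnotation]:
    """Parse gene features from a GFF3 file.

    Only rows of type ``gene`` are kept. Coordinates stay 1-based
    inclusive; output is sorted by (chrom, start). Malformed rows
    (wrong column count, end < start, missing ID, duplicate ID) raise
    ``ValueError`` naming the offending line number.
    """
    genes: list[GeneAnnotation] = []
    seen: set[str] = set()
    with open(path, "r", newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, "
                    f"got {len(cols)}")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = cols
            if ftype != "gene":
                continue
            start_i, end_i = int(start), int(end)
            if end_i < start_i:
                raise ValueError(f"{path}:{lineno}: end {end_i} < start {start_i}")
            attr_map = {}
            for kv in attrs.strip(";").split(";"):
                if "=" in kv:
                    k, v = kv.split("=", 1)
                    attr_map[k.strip()] = v.strip()
            if "ID" not in attr_map:
                raise ValueError(f"{path}:{lineno}: gene feature lacks ID attribute")
            gid = attr_map["ID"]
            if gid in seen:
                raise ValueError(f"{path}:{lineno}: duplicate gene ID {gid!r}")
            seen.add(gid)
            functional = attr_map.get("functional", "true").lower() != "false"
            genes.append(GeneAnnotation(
                gid, attr_map.get("species", species), chrom,
                start_i, end_i, strand if strand in "+-" else "+", functional))
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes


def write_gff3(genes: Sequence[GeneAnnotation], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
            attrs = f"ID={g.gene_id};species={g.species}"
            if not g.functional:
                attrs += ";functional=false"
            fh.write("\t".join([g.chrom, "introgmap", "gene", str(g.start),
                                str(g.end), ".", g.strand, ".", attrs]) + "\n")


# ----------------------------------------------------------------- TSV

def write_tsv(df: pd.DataFrame, path: PathLike, header_comment: str = "") -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def write_counts(table: CountTable, path: PathLike) -> None:
    write_tsv(table.counts, path,
               f"sample_id={table.sample_id}\ttotal_mapped={table.total_mapped}")


def read_counts(path: PathLike) -> CountTable:
    with open(path, "r", newline="") as fh:
        first = fh.readline().strip()
    sample_id, total = "sample", None
    if first.startswith("#"):
        for field in first.lstrip("# ").split("\t"):
            if field.startswith("sample_id="):
                sample_id = field.split("=", 1)[1]
            elif field.startswith("total_mapped="):
                total = int(field.split("=", 1)[1])
    df = pd.read_csv(path, sep="\t", comment="#")
    if total is None:
        total = int(df["count"].sum())
    return CountTable(sample_id, df, total)


def write_similarity(df: pd.DataFrame, path: PathLike) -> None:
    write_tsv(df[["gene_a", "gene_b", "score"]], path)


def read_similarity(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_blocks(blocks: Sequence[SyntenyBlock], path: PathLike) -> None:
    rows = [(b.block_id, b.orientation, round(b.chain_score, 6),
             p.gene_recurrent, p.gene_donor, p.chrom_r, p.rank_r, p.rank_d,
             p.score)
            for b in blocks for p in b.pairs]
    write_tsv(pd.DataFrame(rows, columns=[
        "block_id", "orientation", "chain_score", "gene_recurrent",
        "gene_donor", "chrom", "rank_r", "rank_d", "score"]), path)


def read_blocks(path: PathLike) -> list[SyntenyBlock]:
    df = pd.read_csv(path, sep="\t", comment="#")
    blocks = []
    for bid, sub in df.groupby("block_id", sort=True):
        pairs = [AnchorPair(r.gene_recurrent, r.gene_donor, float(r.score),
                            int(r.rank_r), int(r.rank_d), str(r.chrom),
                            str(r.chrom))
                 for r in sub.itertuples(index=False)]
        blocks.append(SyntenyBlock(int(bid), pairs,
                                   str(sub["orientation"].iloc[0]),
                                   float(sub["chain_score"].iloc[0])))
    return blocks


def write_progeny(records: Sequence[ProgenyRecord], path: PathLike) -> None:
    """Progeny TSV: plant_id, one column per marker (A/H/B/-), dtf, flowered.

    NF plants carry ``dtf=NA`` and ``flowered=false``.
    """
    markers = list(records[0].marker_calls.keys()) if records else []
    rows = []
    for r in records:
        rows.append([r.plant_id] + [r.marker_calls.get(m, "-") for m in markers]
                    + ["NA" if r.dtf is None else f"{r.dtf:.3f}",
                       "true" if r.flowered else "false"])
    write_tsv(pd.DataFrame(rows, columns=["plant_id"] + markers
                            + ["dtf", "flowered"]), path)


def read_progeny(path: PathLike) -> list[ProgenyRecord]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    markers = [c for c in df.columns if c not in ("plant_id", "dtf", "flowered")]
    out = []
    for r in df.itertuples(index=False):
        flowered = str(r.flowered).lower() in ("true", "1", "yes")
        dtf = None if (not flowered or str(r.dtf) in ("NA", "nan")) \
            else float(r.dtf)
        out.append(ProgenyRecord(str(r.plant_id),
                                 {m: getattr(r, m) for m in markers},
                                 dtf, flowered))
    return out


def write_markers(markers: Sequence[tuple[str, str, int]], path: PathLike) -> None:
    write_tsv(pd.DataFrame(markers, columns=["marker_id", "chrom",
                                              "position_bp"]), path)


def read_markers(path: PathLike) -> list[tuple[str, str, int]]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return [(str(r.marker_id), str(r.chrom), int(r.position_bp))
            for r in df.itertuples(index=False)]


def write_mosaic(segments: Sequence[tuple], sample_id: str,
                 path: PathLike) -> None:
    """Truth file of a simulated mosaic (chrom, start/end gene index, zygosity)."""
    rows = [(sample_id, c, s, e, getattr(z, "value", str(z)))
            for c, s, e, z in segments]
    write_tsv(pd.DataFrame(rows, columns=[
        "sample_id", "chrom", "start_gene_index", "end_gene_index",
        "zygosity"]), path)


# ----------------------------------------------------------------- BED

def write_segments_bed(segments: Sequence[IntrogressionSegment],
                       path: PathLike) -> None:
    """BED6 (0-based half-open): name=sample:zygosity,
    score=round(1000 * fraction_concordant), strand="."."""
    with open(path, "w") as fh:
        for s in sorted(segments, key=lambda s: (s.chrom, s.start_bp)):
            fh.write("\t".join([
                s.chrom, str(s.start_bp - 1), str(s.end_bp),
                f"{s.sample_id}:{s.zygosity.value}",
                str(int(round(1000 * s.fraction_concordant))), "."]) + "\n")


# ---------------------------------------------------------------- JSON

def _json_default(o):
    # numpy scalars leak out of pandas-derived records
    if hasattr(o, "item"):
        return o.item()
    raise TypeError(f"not JSON serializable: {type(o)}")


def write_json(obj, path: PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def segment_summary(segments: Sequence[IntrogressionSegment]) -> dict:
    """Sample-level summary: counts and introgressed bp by zygosity."""
    by_z: dict[str, dict] = {}
    for s in segments:
        d = by_z.setdefault(s.zygosity.value, {"n_segments": 0, "total_bp": 0,
                                               "n_genes": 0})
        d["n_segments"] += 1
        d["total_bp"] += s.end_bp - s.start_bp + 1
        d["n_genes"] += s.n_genes
    introgressed = sum(v["total_bp"] for z, v in by_z.items()
                       if z in ("HET", "HOM_DONOR"))
    return {"segments_by_zygosity": by_z, "total_introgressed_bp": introgressed,
            "n_segments": sum(v["n_segments"] for v in by_z.values())}
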