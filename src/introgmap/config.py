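"""Strict pipeline configuration (YAML or JSON).

Unknown keys are rejected so typos fail fast, and every referenced
input path must exist at load time — the run aborts before any
computation starts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Optional

import yaml

from .genotyping import GenotypingParams
from .simulate import SimConfig


@dataclass
class SyntenyParams:
    min_score: float = 0.0
    max_gap: int = 5
    gap_penalty: float = 1.0
    min_block_size: int = 3


@dataclass
class MappingParams:
    phenotype_band_k: float = 1.0
    segregation_ratio: tuple[float, float, float] = (1.0, 2.0, 1.0)
    association_method: str = "anova"


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs; see the stage dataclasses."""

    seed: int = 0
    outdir: str = "introgmap_out"
    log_level: str = "INFO"
    simulate: Optional[SimConfig] = None
    synteny: SyntenyParams = field(default_factory=SyntenyParams)
    genotyping: GenotypingParams = field(default_factory=GenotypingParams)
    mapping: MappingParams = field(default_factory=MappingParams)
    # input paths (unused in pure-simulation runs)
    annotation_recurrent: Optional[str] = None
    annotation_donor: Optional[str] = None
    counts: list[str] = field(default_factory=list)
    similarity: Optional[str] = None
    progeny: Optional[str] = None
    markers: Optional[str] = None


def _build(cls, data: dict, where: str):
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ValueError(f"unknown config key(s) in {where}: {sorted(unknown)}")
    kwargs = {}
    for k, v in data.items():
        if k == "segregation_ratio":
            v = tuple(float(x) for x in v)
        if k == "donor_specific_insertions":
            v = [tuple(t) for t in v]
        kwargs[k] = v
    return cls(**kwargs)


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML/JSON pipeline config."""
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")

    nested = {"simulate": SimConfig, "synteny": SyntenyParams,
              "genotyping": GenotypingParams, "mapping": MappingParams}
    kwargs: dict = {}
    for k, v in data.items():
        if k in nested:
            kwargs[k] = _build(nested[k], v or {}, k)
        else:
            kwargs[k] = v
    cfg = _build(PipelineConfig, kwargs, "top level")

    for attr in ("annotation_recurrent", "annotation_donor", "similarity",
                 "progeny", "markers"):
        p = getattr(cfg, attr)
        if p is not None and not Path(p).exists():
            raise FileNotFoundError(f"config {attr}: no such file {p}")
    for p in cfg.counts:
        if not Path(p).exists():
            raise FileNotFoundError(f"config counts: no such file {p}")
    return cfg
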