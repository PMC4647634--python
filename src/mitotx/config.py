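"""Pipeline configuration: every numeric threshold of the analysis in one
place, with a flat key=value text format for run manifests."""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, fields
from pathlib import Path


@dataclass
class PipelineConfig:
    """Defaults mirror the published analysis thresholds.

    Units: window/step/margins in nt, depths in reads-per-position (x),
    fractions as proportions.
    """

    mrna_window: int = 500
    mrna_step: int = 250
    smallrna_window: int = 50
    smallrna_step: int = 25
    region_depth_floor: float = 100.0
    tail_fraction: float = 0.05
    orf_min_length: int = 201
    orf_distance: int = 2000
    orf_top_fraction: float = 0.05
    smallrna_min_length: int = 17
    smallrna_max_length: int = 25
    stack_min_depth: int = 50
    max_neighbor_overlap: int = 1
    edit_min_depth: int = 100
    edit_min_frequency: float = 0.20
    end_trim: int = 5
    intron_edge_exclusion: int = 20
    utr_margin: int = 2000
    crossmap_k: int = 50
    enrichment_fold: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name == "seed":
                continue
            if v <= 0:
                raise ValueError(f"config value {f.name} must be positive, got {v}")
        for name in ("tail_fraction", "orf_top_fraction", "edit_min_frequency"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.smallrna_min_length > self.smallrna_max_length:
            raise ValueError("smallrna_min_length exceeds smallrna_max_length")

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for f in fields(self):
                fh.write(f"{f.name} = {json.dumps(getattr(self, f.name))}\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        values = {}
        casts = {f.name: f.type for f in fields(cls)}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, raw = line.partition("=")
                key = key.strip()
                if key not in casts:
                    raise ValueError(f"unknown config key {key!r}")
                v = json.loads(raw.strip())
                if casts[key] == "int":
                    v = int(v)
                elif casts[key] == "float":
                    v = float(v)
                values[key] = v
        cfg = cls(**values)
        cfg.validate()
        return cfg

    def asdict(self) -> dict:
        return asdict(self)
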