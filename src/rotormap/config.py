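"""Experiment configuration: plain-text (YAML) serialisable, with the
standard mapping thresholds of the workflow as defaults."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class ExperimentConfig:
    """Everything that defines one 2D AF mapping/ablation experiment."""

    # tissue / preset
    preset: str = "peaf"           # 'control' | 'peaf'
    nx: int = 600
    ny: int = 600
    dx_mm: float = 0.25
    deff: float = 0.1              # mm^2/ms
    dt_ms: float = 0.05

    # protocol
    pacing_cl_ms: float = 600.0
    pacing_count: int = 2
    reset_at_row_fraction: float = 0.5
    reset_mode: str = "front"          # 'front' | 'tail' (against the tail)
    af_duration_ms: float = 10000.0   # post-initiation fibrillation time
    sampling_ms: float = 1.0

    # analysis
    map_window_ms: float = 6000.0
    df_threshold_hz: float = 9.0      # DF "area" cut
    area_percentile: float = 2.5      # ShEn upper / CFAE lower area
    cross_percentile: float = 10.0    # parameter-vs-parameter overlap areas
    egm_spacing_mm: float = 2.0

    # ablation
    ablation_fraction: float = 0.05
    ps_lesion_radius_mm: float = 1.0
    follow_up_ms: float = 6000.0      # post-ablation observation
    strategies: tuple = ("PS", "DF", "ShEn", "CFAE")

    # bookkeeping
    seed: int = 0
    out_dir: str = "results/run"
    save_movie: bool = False

    def validate(self) -> None:
        if self.preset not in ("control", "peaf"):
            raise ValueError(f"unknown preset {self.preset!r}")
        if self.map_window_ms > self.af_duration_ms:
            raise ValueError("mapping window longer than the AF episode")
        for name in ("df_threshold_hz", "area_percentile", "cross_percentile",
                     "ablation_fraction"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    # -- serialisation ----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["strategies"] = list(self.strategies)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "strategies" in d:
            d["strategies"] = tuple(d["strategies"])
        return cls(**d)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).parent.mkdir(parents=True, exist_ok=True)
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path_or_text) -> "ExperimentConfig":
        p = Path(str(path_or_text))
        text = p.read_text() if p.exists() else str(path_or_text)
        return cls.from_dict(yaml.safe_load(text))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def scaled_config(n: int = 200, af_s: float = 10.0, deff: float = 0.015,
                  **overrides) -> ExperimentConfig:
    """The scaled study sheet: n x n nodes with diffusivity reduced so the
    domain spans the same number of pacing wavelengths as the full-size
    600 x 600 / 150 mm configuration (see docs/methods.md; the reduced
    diffusivity also coarsens the effective front resolution, which is
    what limits how far the sheet can shrink)."""
    cfg = ExperimentConfig(nx=n, ny=n, deff=deff,
                           af_duration_ms=af_s * 1000.0,
                           map_window_ms=min(6000.0, af_s * 1000.0),
                           **overrides)
    cfg.validate()
    return cfg
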