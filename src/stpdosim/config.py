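"""Run configuration for the end-to-end pipeline."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .soe import ALL_MODEL_IDS, INDIUM111_HALF_LIFE_H


@dataclass
class RunConfig:
    """Everything a pipeline run needs; all randomness flows from ``seed``."""

    models: list = field(default_factory=lambda: list(ALL_MODEL_IDS))
    seed: int = 0
    multistarts: int = 10
    alpha_scale: str = "lognormal"
    gate_threshold_percent: float = 50.0
    jackknife_threshold_percent: float = 1.0
    run_jackknife: bool = True
    stp_time_label: str = "T4"
    stp_mode: str = "refit"
    stp_comparison_model: Optional[str] = "f3d"
    t_end_min: float = 1e5
    sd_convention: str = "population"
    nuclide_half_life_h: float = INDIUM111_HALF_LIFE_H
    simulate: bool = False
    n_patients: int = 8

    def __post_init__(self):
        if not 0 < self.gate_threshold_percent <= 100:
            raise ValueError("gate threshold must be in (0, 100]")
        if not 0 < self.jackknife_threshold_percent <= 100:
            raise ValueError("jackknife threshold must be in (0, 100]")
        if self.t_end_min <= 0:
            raise ValueError("t_end_min must be > 0")
        if self.stp_time_label not in ("T1", "T2", "T3", "T4", "T5"):
            raise ValueError("stp_time_label must be one of T1..T5")
        unknown = [m for m in self.models if m not in ALL_MODEL_IDS]
        if unknown:
            raise ValueError(f"unknown model id(s): {unknown}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
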