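"""Pipeline configuration.

All scale constants live here with their defaults (SSA L=15/k=2 with a
k=6 override for the finger-to-nose motion so tremor is preserved;
random forest with 100 trees and 6 features per split; rule thresholds
lambda1=1/3, lambda2=2/3; SPARC 10 Hz cutoff / 0.05 amplitude
threshold; 0.15 m wrist-nose reach threshold) rather than being
hard-coded in the logic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

from .preprocess import SSAConfig
from .scoring import (LAMBDA1, LAMBDA2, NOSE_REACH_THRESHOLD_M, RFConfig)


@dataclass(frozen=True)
class PipelineConfig:
    ssa: SSAConfig = field(default_factory=SSAConfig)
    #: per-motion SSA overrides; motion XV keeps more components so the
    #: tremor band survives denoising
    ssa_overrides: dict = field(
        default_factory=lambda: {"XV": SSAConfig(L=15, k=6)})
    rf: RFConfig = field(default_factory=RFConfig)
    lambda1: float = LAMBDA1
    lambda2: float = LAMBDA2
    sparc_cutoff_hz: float = 10.0
    sparc_amp_threshold: float = 0.05
    nose_reach_threshold_m: float = NOSE_REACH_THRESHOLD_M
    seed: int = 0

    def with_seed(self, seed: int) -> "PipelineConfig":
        cfg = asdict(self)
        cfg["ssa"] = SSAConfig(**cfg["ssa"])
        cfg["ssa_overrides"] = {m: SSAConfig(**v)
                                for m, v in cfg["ssa_overrides"].items()}
        rf = cfg["rf"]
        rf["seed"] = seed
        cfg["rf"] = RFConfig(**rf)
        cfg["seed"] = seed
        return PipelineConfig(**cfg)

    def ssa_for(self, motion: str) -> SSAConfig:
        return self.ssa_overrides.get(motion, self.ssa)

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(Path(path), "r", encoding="utf-8") as fh:
            raw = json.load(fh)
        if "ssa" in raw:
            raw["ssa"] = SSAConfig(**raw["ssa"])
        if "ssa_overrides" in raw:
            raw["ssa_overrides"] = {m: SSAConfig(**v)
                                    for m, v in raw["ssa_overrides"].items()}
        if "rf" in raw:
            raw["rf"] = RFConfig(**raw["rf"])
        return cls(**raw)
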