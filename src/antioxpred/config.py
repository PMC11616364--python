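"""JSON-serializable pipeline configuration tying all stages together."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .errors import InputError
from .evaluate import GbtParams, PipelineStageConfig
from .pssm_features import BackgroundFrequencies
from .resampling import SmoteConfig
from .vfc import VfcConfig


@dataclass
class PipelineConfig:
    smote: SmoteConfig = field(default_factory=SmoteConfig)
    vfc: VfcConfig = field(default_factory=VfcConfig)
    gbt: GbtParams = field(default_factory=GbtParams)
    background_frequencies: list[float] | None = None
    motif: str = "bab"
    cv_k: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.motif not in ("bab", "aba"):
            raise InputError(f"motif must be 'bab' or 'aba', got {self.motif!r}")

    def bf(self) -> BackgroundFrequencies:
        if self.background_frequencies is None:
            return BackgroundFrequencies.default()
        return BackgroundFrequencies(bf=np.asarray(self.background_frequencies))

    def stage_config(self) -> PipelineStageConfig:
        return PipelineStageConfig(smote=self.smote, vfc=self.vfc, gbt=self.gbt)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["vfc"]["hidden_dims"] = list(self.vfc.hidden_dims)
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "smote" in d and isinstance(d["smote"], dict):
            d["smote"] = SmoteConfig(**d["smote"])
        if "vfc" in d and isinstance(d["vfc"], dict):
            v = dict(d["vfc"])
            if "hidden_dims" in v:
                v["hidden_dims"] = tuple(v["hidden_dims"])
            d["vfc"] = VfcConfig(**v)
        if "gbt" in d and isinstance(d["gbt"], dict):
            d["gbt"] = GbtParams(**d["gbt"])
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))
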