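"""Experiment configuration: dataclass defaults and YAML round-trip.

The shipped defaults reproduce the study conditions the toolkit
emulates: 24 subjects, two reading-localizer versions with two runs
each, a 24×24×24 voxel grid at 2 mm with five language and four MD
spherical parcels, top-10% fROIs in the five language parcels, a
128-s high-pass / AR(0.2) GLM, and the default noise and effect
amplitudes of the synthetic-subject module.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .firstlevel import GLMOptions, HRFParams
from .froi import FROIConfig
from .synthsubject import DEFAULT_EFFECTS, NoiseSpec

__all__ = ["ExperimentConfig", "load_config", "save_config"]


def _default_effects() -> dict:
    return {k: dict(v) for k, v in DEFAULT_EFFECTS.items()}


@dataclass(frozen=True)
class ExperimentConfig:
    n_subjects: int = 24
    versions: tuple[str, ...] = ("standard", "speeded")
    runs_per_version: int = 2
    include_wm: bool = False
    grid_shape: tuple[int, int, int] = (24, 24, 24)
    voxel_size_mm: float = 2.0
    tr_s: float = 2.0
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    effects: dict = field(default_factory=_default_effects)
    selective_fraction: float = 0.2
    jitter_sd_mm: float = 4.0
    version_jitter_sd_mm: float = 1.0
    subject_gain_sd: float = 0.15
    froi: FROIConfig = field(default_factory=FROIConfig)
    glm: GLMOptions = field(default_factory=GLMOptions)
    dice_fractions: tuple[float, ...] = (0.1, 0.2, 0.3)
    seed: int = 0

    def __post_init__(self) -> None:
        known = {"sentences", "nonwords", "hard", "easy"}
        for table in self.effects.values():
            for cond, _version in table:
                if cond not in known:
                    raise ValueError(f"effect config references unknown condition {cond!r}")
        if self.runs_per_version != 2:
            raise ValueError("the cross-validated design requires exactly 2 runs")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["noise"] = dataclasses.asdict(self.noise)
        d["glm"] = dataclasses.asdict(self.glm)
        d["froi"] = dataclasses.asdict(self.froi)
        d["effects"] = {
            net: {f"{c}|{v}": amp for (c, v), amp in table.items()}
            for net, table in self.effects.items()
        }
        return d

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "noise" in d and isinstance(d["noise"], dict):
            d["noise"] = NoiseSpec(**d["noise"])
        if "glm" in d and isinstance(d["glm"], dict):
            g = dict(d["glm"])
            if isinstance(g.get("hrf"), dict):
                g["hrf"] = HRFParams(**g["hrf"])
            d["glm"] = GLMOptions(**g)
        if "froi" in d and isinstance(d["froi"], dict):
            f = dict(d["froi"])
            if "parcel_names" in f:
                f["parcel_names"] = tuple(f["parcel_names"])
            d["froi"] = FROIConfig(**f)
        if "effects" in d:
            d["effects"] = {
                net: {
                    tuple(key.split("|")): amp for key, amp in table.items()
                }
                for net, table in d["effects"].items()
            }
        for key in ("versions", "grid_shape", "dice_fractions"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def load_config(path: str | Path) -> ExperimentConfig:
    with open(path) as f:
        return ExperimentConfig.from_dict(yaml.safe_load(f))


def save_config(config: ExperimentConfig, path: str | Path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(config.to_dict(), f, sort_keys=True)
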