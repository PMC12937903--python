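"""Pipeline configuration: strict, defaulted, hashable.

Every field has a default; unknown keys (at any nesting level) are
rejected with a field-level message.  The canonical JSON form of a
config is hashed so that every artifact can record the exact
configuration that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class SimulateConfig:
    n_healthy: int = 20
    n_ischemic: int = 20
    n_cycles: int = 10
    sampling_rate: float = 1000.0
    morphology: dict = field(default_factory=dict)


@dataclass
class PreprocessConfig:
    band_low: float = 0.5
    band_high: float = 150.0
    notch: float = 50.0
    median_window: int = 5
    smooth_window: int = 5


@dataclass
class ChaosConfig:
    max_lag: int | None = None
    m_max: int = 8
    r0: float = 15.0
    max_subjects: int | None = 5
    run_surrogates: bool = False
    n_surrogates: int = 19


@dataclass
class RenderConfig:
    height: int = 256
    width: int = 256
    cycle_index: int | None = None  # None -> middle cycle


@dataclass
class AugmentConfig:
    expansion_factor: int = 4
    families: list = field(
        default_factory=lambda: ["rotate", "translate", "noise", "contrast"]
    )


@dataclass
class FeaturesConfig:
    hog_cell: int = 8
    hog_block: int = 2
    hog_bins: int = 9
    lbp_p: int = 8
    lbp_r: float = 1.0


@dataclass
class ClassifyConfig:
    test_fraction: float = 0.2
    grid: dict = field(
        default_factory=lambda: {"n_estimators": [100, 200, 500],
                                 "max_depth": [None, 10, 20]}
    )
    cv: int = 5
    augment_before_split: bool = False  # True reproduces the 1600/320 bookkeeping


_SECTIONS = {
    "simulate": SimulateConfig,
    "preprocess": PreprocessConfig,
    "chaos": ChaosConfig,
    "render": RenderConfig,
    "augment": AugmentConfig,
    "features": FeaturesConfig,
    "classify": ClassifyConfig,
}


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "mcdm_out"
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    chaos: ChaosConfig = field(default_factory=ChaosConfig)
    render: RenderConfig = field(default_factory=RenderConfig)
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    features: FeaturesConfig = field(default_factory=FeaturesConfig)
    classify: ClassifyConfig = field(default_factory=ClassifyConfig)

    @classmethod
    def from_dict(cls, data: Mapping[str, Any] | None) -> "PipelineConfig":
        data = dict(data or {})
        kwargs: dict[str, Any] = {}
        for key in list(data):
            if key in _SECTIONS:
                section_cls = _SECTIONS[key]
                section_data = dict(data.pop(key) or {})
                valid = {f.name for f in dataclasses.fields(section_cls)}
                unknown = set(section_data) - valid
                if unknown:
                    raise ValueError(
                        f"unknown config key(s) {sorted(unknown)} in section {key!r}"
                    )
                kwargs[key] = section_cls(**section_data)
            elif key in ("seed", "out_dir"):
                kwargs[key] = data.pop(key)
        if data:
            raise ValueError(f"unknown config key(s) {sorted(data)}")
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def canonical_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, separators=(",", ":"))

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load and validate a YAML config file; None yields the defaults."""
    if path is None:
        return PipelineConfig()
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return PipelineConfig.from_dict(data)
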