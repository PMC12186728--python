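"""Analysis configuration.

A single :class:`AnalysisConfig` object carries every tunable parameter of
the pipeline: the channel map, pixel size, per-channel segmentation
parameters, dynamics frame times, morphology-classifier rules and texture
settings.  It loads from a flat YAML file and rejects unknown keys, so a
typo in a config file fails loudly instead of silently using a default.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml


class ConfigError(ValueError):
    """Raised for invalid or inconsistent configuration."""


@dataclass
class SegmentationParams:
    """Parameters of the puncta masking recipe.

    The recipe is Gaussian blur -> optional despeckle (3x3 median) ->
    constant intensity threshold -> connected components -> strict area
    filter.  Thresholds are in raw intensity units and are meant to be held
    constant across all images of an experiment.
    """

    blur_sigma_px: float = 1.5
    despeckle: bool = True
    threshold_low: Optional[float] = None
    threshold_high: Optional[float] = None
    min_area_um2: float = 0.01
    connectivity: int = 8

    def __post_init__(self) -> None:
        if self.min_area_um2 < 0:
            raise ConfigError("min_area_um2 must be >= 0")
        if self.blur_sigma_px < 0:
            raise ConfigError("blur_sigma_px must be >= 0")
        if self.connectivity not in (4, 8):
            raise ConfigError("connectivity must be 4 or 8")
        if (
            self.threshold_low is not None
            and self.threshold_high is not None
            and not self.threshold_low < self.threshold_high
        ):
            raise ConfigError("threshold_low must be < threshold_high")

    def threshold(self, which: str) -> float:
        value = {"low": self.threshold_low, "high": self.threshold_high}.get(which)
        if which not in ("low", "high"):
            raise ConfigError(f"threshold must be 'low' or 'high', got {which!r}")
        if value is None:
            raise ConfigError(f"threshold_{which} is not set")
        return value


@dataclass
class NucleiParams:
    """Nucleus segmentation: blur + Otsu + hole fill + optional watershed split."""

    blur_sigma_px: float = 2.0
    min_area_um2: float = 5.0
    ring_width_um: float = 2.0
    split_touching: bool = True
    exclude_border: bool = True


@dataclass
class ClassifierRules:
    """Rule thresholds for punctate/bouquet nucleus classification."""

    area_thresh_um2: float = 1.0
    circ_thresh: float = 0.8
    lobe_thresh: int = 3


@dataclass
class TextureParams:
    offset: tuple[int, int] = (0, 1)
    n_levels: int = 256
    average_offsets: bool = False
    log_base: str = "e"  # "e", "2" or "10"
    channel: str = "aggregate"

    def __post_init__(self) -> None:
        self.offset = tuple(int(v) for v in self.offset)  # type: ignore[assignment]
        if not 2 <= self.n_levels <= 256:
            raise ConfigError("n_levels must be in [2, 256]")
        if self.log_base not in ("e", "2", "10"):
            raise ConfigError("log_base must be 'e', '2' or '10'")


@dataclass
class AnalysisConfig:
    """Full pipeline configuration; validates on construction."""

    channels: dict[str, int] = field(
        default_factory=lambda: {"nuclei": 0, "aggregate": 1, "mrna": 2}
    )
    pixel_size_um: float = 0.1
    frame_interval_s: Optional[float] = None
    nuclei: NucleiParams = field(default_factory=NucleiParams)
    aggregate: SegmentationParams = field(
        default_factory=lambda: SegmentationParams(
            blur_sigma_px=1.5, despeckle=True, threshold_low=120.0, threshold_high=650.0
        )
    )
    mrna: SegmentationParams = field(
        default_factory=lambda: SegmentationParams(
            blur_sigma_px=1.0, despeckle=False, threshold_low=15.0
        )
    )
    dynamics_times_s: tuple[float, float, float] = (0.0, 130.0, 260.0)
    dynamics_colored: str = "union"  # or "nonwhite"
    classifier: ClassifierRules = field(default_factory=ClassifierRules)
    texture: TextureParams = field(default_factory=TextureParams)
    groups: list[str] = field(default_factory=list)
    seed: int = 0
    out_dir: str = "results"

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ConfigError("pixel_size_um must be > 0")
        for name in ("nuclei", "aggregate"):
            if name not in self.channels:
                raise ConfigError(f"channel map must include {name!r}")
        if self.dynamics_colored not in ("union", "nonwhite"):
            raise ConfigError("dynamics_colored must be 'union' or 'nonwhite'")
        self.dynamics_times_s = tuple(float(t) for t in self.dynamics_times_s)  # type: ignore[assignment]

    # -- (de)serialisation -------------------------------------------------

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "AnalysisConfig":
        return _dataclass_from_dict(cls, data, path="config")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(self.to_dict())), fh, sort_keys=False)

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _dataclass_from_dict(cls: type, data: dict[str, Any], path: str) -> Any:
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a mapping, got {type(data).__name__}")
    field_map = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(field_map)
    if unknown:
        raise ConfigError(f"{path}: unknown keys {sorted(unknown)}")
    kwargs: dict[str, Any] = {}
    for name, value in data.items():
        if name in ("nuclei",):
            kwargs[name] = _dataclass_from_dict(NucleiParams, value, f"{path}.{name}")
        elif name in ("aggregate", "mrna"):
            kwargs[name] = _dataclass_from_dict(SegmentationParams, value, f"{path}.{name}")
        elif name == "classifier":
            kwargs[name] = _dataclass_from_dict(ClassifierRules, value, f"{path}.{name}")
        elif name == "texture":
            kwargs[name] = _dataclass_from_dict(TextureParams, value, f"{path}.{name}")
        else:
            kwargs[name] = value
    return cls(**kwargs)
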