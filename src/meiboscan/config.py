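"""Pipeline configuration.

Every numeric threshold of the automated profiling algorithm lives here with
its published default, so a run can be reproduced from the config snapshot
echoed into each analysis report.  Configs load from TOML or JSON files whose
tables mirror the dataclass nesting (``[preprocess]``, ``[profiles]``,
``[peaks]``, ``[tracing]``, ``[metrics]``).
"""

from __future__ import annotations

import dataclasses
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

from .errors import InputError


@dataclass
class PreprocessConfig:
    """Contrast-enhancement chain parameters.

    Defaults are the published operating point: histogram centered at gray
    value 100, saturation floor 250 for specular-reflection detection, dark
    cutoff 50, CLAHE clip 12 (OpenCV convention, i.e. a multiple of the mean
    histogram bin count) over a 20x20 tile grid, and a closing disc of
    diameter 5 px.
    """

    center_target: int = 100
    center_only_dark: bool = True  # brighten dark images; leave bright ones alone
    canny_aperture: int = 3
    canny_low: int = 0
    canny_high: int = 255
    saturation_floor: int = 250
    dark_threshold: int = 50
    dark_strict: bool = True  # blacken values strictly below the threshold
    clahe_clip_limit: float = 12.0
    clahe_grid: tuple[int, int] = (20, 20)
    closing_diameter: int = 5
    equalize_method: str = "stretch"  # final full-range stage: "stretch" | "histogram"
    # per-stage toggles for ablation
    enable_center: bool = True
    enable_reflections: bool = True
    enable_dark: bool = True
    enable_clahe: bool = True
    enable_closing: bool = True
    enable_equalize: bool = True


@dataclass
class ProfileConfig:
    """Profile-line construction: 5 vertical zones, 4 depth fractions."""

    depths: tuple[float, ...] = (0.10, 0.45, 0.55, 0.75)
    n_zones: int = 5


@dataclass
class PeakConfig:
    """Peak detection on the normalized [0, 1] gray-value profiles."""

    smoothing: str = "savgol"  # or "moving_average" (exploratory variant)
    smooth_window: int = 11
    smooth_order: int = 1
    moving_average_window: int = 200
    prominence: float = 0.1
    min_width: float = 2.0
    fuse_separation: float = 10.0  # peaks strictly closer than this are fused
    max_width: float = 90.0  # peaks strictly wider than this are dropped
    fused_height: str = "max"  # or "mean"
    width_on_raw: bool = True  # measure 50%-height width on the unsmoothed profile


@dataclass
class TraceConfig:
    """Layered-graph gland extraction thresholds (pixel units)."""

    full_max_len: float = 100.0  # accept a multi-layer path while length <= this
    pair_max_len: float = 60.0  # a 2-node edge is a gland while weight < this
    accept: str = "leq"  # "leq": accept path length <= full_max_len; "lt": strict


@dataclass
class MetricsConfig:
    gland_width: str = "mean"  # summary of a gland's per-layer widths; or "median"


@dataclass
class PipelineConfig:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    profiles: ProfileConfig = field(default_factory=ProfileConfig)
    peaks: PeakConfig = field(default_factory=PeakConfig)
    tracing: TraceConfig = field(default_factory=TraceConfig)
    metrics: MetricsConfig = field(default_factory=MetricsConfig)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        cfg = cls()
        for section_name, section in data.items():
            if not hasattr(cfg, section_name):
                raise InputError(f"unknown config section: {section_name!r}")
            target = getattr(cfg, section_name)
            for key, value in section.items():
                if not hasattr(target, key):
                    raise InputError(
                        f"unknown config key: {section_name}.{key!r}"
                    )
                if isinstance(getattr(target, key), tuple):
                    value = tuple(value)
                setattr(target, key, value)
        return cfg

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        if not path.exists():
            raise InputError(f"config file not found: {path}")
        if path.suffix.lower() == ".json":
            data = json.loads(path.read_text())
        else:
            with open(path, "rb") as fh:
                data = tomllib.load(fh)
        return cls.from_dict(data)
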