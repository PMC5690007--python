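"""Configuration for phantom geometry, tolerances, ROI layout and run paths.

All tunables live in dataclasses with QC-practice defaults; a YAML (or JSON)
file can override any subset, and CLI flags override the file.  Tolerances are
engineering action limits, not statistical tests: a KPI outside its band is a
finding, regardless of how many KPIs are evaluated per session.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

LOG = logging.getLogger("ctqc")


def configure_logging(verbosity: int = 0) -> None:
    """Route package logs to stderr; reports go to files only."""
    level = logging.WARNING
    if verbosity == 1:
        level = logging.INFO
    elif verbosity >= 2:
        level = logging.DEBUG
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("ctqc")
    root.handlers.clear()
    root.addHandler(handler)
    root.setLevel(level)


@dataclass(frozen=True)
class MarkerLayout:
    """Longitudinal positioning markers of the phantom's reference section.

    Two opposed 45-degree ramp markers sit on the vertical axis at
    ``radius_mm`` from the phantom center.  A longitudinal (Z) offset moves
    their in-plane images apart or together, so the Z offset is decoded as
    half the deviation of the marker separation from its nominal value
    (2 * radius_mm).  The layout is configurable for phantoms with other
    marker geometries.
    """

    radius_mm: float = 60.0
    marker_hu: float = 900.0
    diameter_mm: float = 5.0
    max_dz_mm: float = 10.0  # dynamic range of the ramps


@dataclass(frozen=True)
class PhantomModel:
    """Geometry and materials of the cylindrical water QA phantom.

    ``water_diameter_mm`` is *the* phantom diameter D that every
    percentage-based ROI rule refers to; the detected diameter is used only
    as a sanity check so that ROI sizes stay constant and reproducible
    across sessions.
    """

    water_diameter_mm: float = 150.0
    shell_thickness_mm: float = 10.0
    shell_hu: float = 120.0
    markers: MarkerLayout = field(default_factory=MarkerLayout)

    def __post_init__(self) -> None:
        if self.water_diameter_mm <= 0:
            raise ValueError("water_diameter_mm must be > 0")
        if self.shell_thickness_mm < 0:
            raise ValueError("shell_thickness_mm must be >= 0")

    @property
    def outer_diameter_mm(self) -> float:
        return self.water_diameter_mm + 2.0 * self.shell_thickness_mm


@dataclass(frozen=True)
class ToleranceSet:
    """Action limits for each KPI.

    positioning_mm   half-width for |X|, |Y|, |Z| offsets (mm)
    noise_rel        allowed relative deviation of noise from its base value
    water_hu         half-width around 0 HU for the CT number of water
    air_hu           half-width around -1000 HU for the CT number of air
    uniformity_hu    max |peripheral - center| ROI mean difference
    homogeneity_hu   max tile-mean spread inside the 85% circle
    """

    positioning_mm: float = 2.0
    noise_rel: float = 0.05
    water_hu: float = 2.0
    air_hu: float = 10.0
    uniformity_hu: float = 3.0
    homogeneity_hu: float = 5.0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"tolerance {f.name} must be > 0")


@dataclass(frozen=True)
class ROILayout:
    """ROI sizing rules, all as fractions of the phantom (water) diameter D.

    noise_frac            diameter of the centered noise ROI (0.40 D)
    ct_frac               diameter of the water/air CT-number ROIs (0.10 D)
    peripheral_edge_frac  distance of peripheral ROI centers from the water
                          edge (0.15 D), i.e. centers at radius D/2 - 0.15 D
    homogeneity_frac      diameter of the circle tiled for homogeneity (0.85 D)
    tile_px               homogeneity tile side in pixels (fixed pixels; the
                          physical tile size therefore varies with FOV)
    air_offset_frac       air-ROI center distance from the phantom center,
                          as a fraction of D (0.75 D = 0.25 D outside the
                          water edge), placed on the image-left horizontal
    area_check_frac       allowed relative deviation of the detected object
                          area from the model expectation
    """

    noise_frac: float = 0.40
    ct_frac: float = 0.10
    peripheral_edge_frac: float = 0.15
    homogeneity_frac: float = 0.85
    tile_px: int = 32
    air_offset_frac: float = 0.75
    area_check_frac: float = 0.20


@dataclass
class RunConfig:
    """Everything a QC run needs: geometry, limits, model constants, paths."""

    phantom: PhantomModel = field(default_factory=PhantomModel)
    tolerances: ToleranceSet = field(default_factory=ToleranceSet)
    roi: ROILayout = field(default_factory=ROILayout)
    kvp_exponent: float = 2.6  # kilovoltage dependency factor n, dose ~ kVp^n
    trend_dir: Path = Path("qc_trend")
    baseline_path: Path = Path("qc_baselines.json")
    output_dir: Path = Path("qc_reports")


def _build(cls, data: Mapping[str, Any]):
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name in data:
            kwargs[f.name] = data[f.name]
    return cls(**kwargs)


def load_config(path: str | Path | None = None) -> RunConfig:
    """Build a RunConfig from built-in defaults overridden by a YAML/JSON file."""
    cfg = RunConfig()
    if path is None:
        return cfg
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    if not data:
        return cfg
    if "phantom" in data:
        pdata = dict(data["phantom"])
        if "markers" in pdata:
            pdata["markers"] = _build(MarkerLayout, pdata["markers"])
        cfg.phantom = _build(PhantomModel, pdata)
    if "tolerances" in data:
        cfg.tolerances = _build(ToleranceSet, data["tolerances"])
    if "roi" in data:
        cfg.roi = _build(ROILayout, data["roi"])
    if "kvp_exponent" in data:
        cfg.kvp_exponent = float(data["kvp_exponent"])
    for key in ("trend_dir", "baseline_path", "output_dir"):
        if key in data:
            setattr(cfg, key, Path(data[key]))
    return cfg
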