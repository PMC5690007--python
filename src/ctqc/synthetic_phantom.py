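"""Seeded synthetic phantom sessions with known ground truth.

Emulates DICOM images of a cylindrical water QA phantom: a water disk at
0 HU inside a PMMA shell (~120 HU) surrounded by air (-1000 HU), with
white Gaussian noise whose magnitude follows the Brooks-formula technique
scaling relative to a reference technique.  Controlled degradations cover
every KPI: global HU drift (calibration error), radial quadratic cupping
(beam hardening), a narrow ring artifact, a tile-aligned local defect, and
in-plane/longitudinal miscentering with ramp markers for the Z offset.

Material edges are mixed by area fraction (linear partial volume over one
pixel) so peripheral ROIs see realistic soft edges, and pixels are rounded
to integer HU exactly as DICOM storage would, making in-memory slices
identical to a write/read round trip.  Reconstruction texture (correlated
noise), scatter and photon starvation are not modelled; the KPIs here use
first and second moments only.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .brooks_model import sigma_scale
from .config import PhantomModel
from .dicom_io import AcquisitionParams, ImageSlice, write_series
from .qc_engine import ProtocolSpec, protocol_for_level

# The standard daily technique (Level-0 water scan): 120 kVp, 260 mA, 1 s.
REFERENCE_TECHNIQUE = AcquisitionParams(
    kvp=120.0,
    tube_current=260.0,
    rotation_time=1.0,
    slice_thickness=5.0,
    collimation="64x0.625",
    sfov="head",
    fov_mm=250.0,
    kernel="std",
    part="water",
    station="CT1",
)


@dataclass
class SyntheticConfig:
    """Generator settings; defaults are the nominal daily-QC conditions.

    ``base_sigma`` is the noise SD (HU) at ``reference_technique``; every
    generated slice scales it by the Brooks-formula ratio for its own
    technique.  ``offset`` is the phantom (dx, dy, dz) miscentering in mm;
    ``ring`` is (radius_mm, amplitude_hu, width_px); ``tile_defect`` is
    (tile_row, tile_col, delta_hu) in homogeneity-tile indices relative to
    the phantom center.
    """

    phantom: PhantomModel = field(default_factory=PhantomModel)
    matrix: int = 512
    fov_mm: float = 250.0
    base_sigma: float = 5.0
    technique: AcquisitionParams = REFERENCE_TECHNIQUE
    reference_technique: AcquisitionParams = REFERENCE_TECHNIQUE
    n_exponent: float = 2.6
    offset: tuple[float, float, float] = (0.0, 0.0, 0.0)
    drift_hu: float = 0.0
    cupping_k: float = 0.0
    ring: Optional[tuple[float, float, float]] = None
    tile_defect: Optional[tuple[int, int, float]] = None
    tile_px: int = 32
    seed: int = 0
    scanner_id: str = "CT1"
    acquired_at: _dt.datetime = field(
        default_factory=lambda: _dt.datetime(2024, 1, 2, 7, 0, tzinfo=_dt.timezone.utc)
    )

    def __post_init__(self) -> None:
        if self.matrix <= 0 or self.fov_mm <= 0:
            raise ValueError("matrix and fov_mm must be > 0")
        if self.base_sigma < 0:
            raise ValueError("base_sigma must be >= 0")


def _rng_for(cfg: SyntheticConfig, stream: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(cfg.seed), int(stream)]))


def _target_sigma(cfg: SyntheticConfig, params: AcquisitionParams) -> float:
    if cfg.base_sigma == 0:
        return 0.0
    return cfg.base_sigma * sigma_scale(params, cfg.reference_technique, cfg.n_exponent)


def _frac_inside(r: np.ndarray, radius: float, px: float) -> np.ndarray:
    """Area fraction of each pixel inside a circle (linear edge over 1 px)."""
    return np.clip((radius - r) / px + 0.5, 0.0, 1.0)


def generate_water_slice(
    cfg: SyntheticConfig,
    slice_location: float = 0.0,
    params: AcquisitionParams | None = None,
    rng: np.random.Generator | None = None,
) -> ImageSlice:
    """One water-section slice with the configured degradations applied."""
    params = params or cfg.technique
    rng = rng if rng is not None else _rng_for(cfg)
    model = cfg.phantom
    if model.outer_diameter_mm >= cfg.fov_mm:
        raise ValueError("phantom does not fit inside the FOV")

    n = cfg.matrix
    px = cfg.fov_mm / n
    dx, dy, _ = cfg.offset
    coords = (np.arange(n) - (n - 1) / 2.0) * px
    yy, xx = np.meshgrid(coords, coords, indexing="ij")
    r = np.hypot(xx - dx, yy - dy)

    r_water = model.water_diameter_mm / 2.0
    f_water = _frac_inside(r, r_water, px)
    f_object = _frac_inside(r, model.outer_diameter_mm / 2.0, px)

    water_field = np.full((n, n), cfg.drift_hu, dtype=np.float64)
    if cfg.cupping_k:
        water_field -= cfg.cupping_k * (r / r_water) ** 2
    if cfg.ring is not None:
        radius_mm, amplitude, width_px = cfg.ring
        water_field += amplitude * (np.abs(r - radius_mm) <= width_px * px / 2.0)
    if cfg.tile_defect is not None:
        ti, tj, delta = cfg.tile_defect
        t = cfg.tile_px
        anchor_r = int(round((n - 1) / 2.0 + dy / px))
        anchor_c = int(round((n - 1) / 2.0 + dx / px))
        r0, c0 = anchor_r + ti * t, anchor_c + tj * t
        defect = np.zeros((n, n), dtype=bool)
        defect[max(r0, 0): r0 + t, max(c0, 0): c0 + t] = True
        water_field += delta * defect

    hu = (
        -1000.0 * (1.0 - f_object)
        + model.shell_hu * (f_object - f_water)
        + water_field * f_water
    )

    sigma = _target_sigma(cfg, params)
    if sigma > 0:
        hu = hu + rng.normal(0.0, sigma, size=hu.shape)
    hu = np.rint(hu)  # integer HU, as DICOM storage would hold

    return ImageSlice(
        pixels=hu,
        pixel_spacing=(px, px),
        slice_location=slice_location,
        params=dataclasses.replace(
            params, fov_mm=cfg.fov_mm, station=cfg.scanner_id, acquired_at=cfg.acquired_at
        ),
    )


def generate_positioning_slice(
    cfg: SyntheticConfig,
    slice_location: float = -100.0,
    params: AcquisitionParams | None = None,
    rng: np.random.Generator | None = None,
) -> ImageSlice:
    """Positioning-section slice: displaced phantom plus two ramp markers.

    The markers sit on the vertical axis through the phantom center at
    +-(radius_mm + dz), so the in-plane separation encodes the longitudinal
    offset dz.  |dz| beyond the ramp dynamic range raises.
    """
    mk = cfg.phantom.markers
    dx, dy, dz = cfg.offset
    if abs(dz) > mk.max_dz_mm:
        raise ValueError(f"dz={dz} mm beyond marker dynamic range +-{mk.max_dz_mm} mm")
    if params is None:
        params = dataclasses.replace(cfg.technique, part="positioning", collimation="8x0.625")
    rng = rng if rng is not None else _rng_for(cfg, stream=1)

    # noiseless base field first; markers go in before noise and rounding
    quiet_cfg = dataclasses.replace(cfg, base_sigma=0.0)
    slice_ = generate_water_slice(quiet_cfg, slice_location, params)
    hu = slice_.pixels.astype(np.float64)

    n = cfg.matrix
    px = cfg.fov_mm / n
    coords = (np.arange(n) - (n - 1) / 2.0) * px
    yy, xx = np.meshgrid(coords, coords, indexing="ij")
    for sign in (+1.0, -1.0):
        my = dy + sign * (mk.radius_mm + dz)
        dist = np.hypot(xx - dx, yy - my)
        frac = _frac_inside(dist, mk.diameter_mm / 2.0, px)
        hu = hu * (1.0 - frac) + mk.marker_hu * frac

    sigma = _target_sigma(cfg, params)
    if sigma > 0:
        hu = hu + rng.normal(0.0, sigma, size=hu.shape)
    slice_.pixels = np.rint(hu)
    return slice_


def generate_session(
    level: int,
    cfg: SyntheticConfig,
    protocol: ProtocolSpec | None = None,
    out_dir: str | Path | None = None,
) -> list[ImageSlice] | list[Path]:
    """Generate a full Level-0 or Level-1 session per the protocol table.

    One slice per protocol row and slice count, technique tags set from the
    row, noise scaled by the Brooks formula.  Returns the in-memory slices,
    or the written DICOM file paths when ``out_dir`` is given.
    """
    protocol = protocol or protocol_for_level(level)
    slices: list[ImageSlice] = []
    counter = 0
    z_water = 0.0
    for row in protocol.rows:
        for _ in range(row.n_slices):
            params = row.params(station=cfg.scanner_id, acquired_at=cfg.acquired_at)
            rng = _rng_for(cfg, stream=100 + counter)
            if row.part == "positioning":
                slices.append(
                    generate_positioning_slice(cfg, slice_location=-100.0,
                                               params=params, rng=rng)
                )
            else:
                slices.append(
                    generate_water_slice(cfg, slice_location=z_water,
                                         params=params, rng=rng)
                )
                z_water += row.slice_thickness
            counter += 1
    if out_dir is not None:
        return write_series(slices, out_dir, series_tag=f"ctqc-l{level}-seed{cfg.seed}")
    return slices


# Scenario presets for the CLI `simulate` subcommand: each maps a named
# degradation mode onto a SyntheticConfig.
def scenario_config(scenario: str, seed: int = 0, **overrides) -> SyntheticConfig:
    presets: dict[str, dict] = {
        "nominal": {},
        "drift": {"drift_hu": 3.0},
        "ring": {"ring": (30.0, 12.0, 2.0)},
        "cupping": {"cupping_k": 8.0},
        "miscentered": {"offset": (3.0, -2.0, 1.5)},
        "tile-defect": {"tile_defect": (1, 1, 8.0)},
    }
    if scenario not in presets:
        raise ValueError(
            f"unknown scenario {scenario!r}; choose from {sorted(presets)}"
        )
    kwargs = dict(presets[scenario])
    kwargs.update(overrides)
    return SyntheticConfig(seed=seed, **kwargs)
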