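"""Image-based KPIs and tolerance evaluation.

Five KPIs are measured on each water-section slice:

* noise        SD of HU in a centered circular ROI of diameter 0.40 D,
               judged relative to a stored base value (+-5% by default)
* water        mean HU of a centered 0.10 D ROI, judged against 0 HU
* air          mean HU of a 0.10 D ROI outside the phantom, judged
               against -1000 HU
* uniformity   max |peripheral mean - center mean| over four peripheral
               0.10 D ROIs (beam hardening / cupping indicator)
* homogeneity  max - min of the means of contiguous 32x32-pixel tiles that
               lie wholly inside the circle of diameter 0.85 D, anchored at
               the phantom center (localized-artifact indicator)

Standard deviations are sample SDs (ddof=1), the CT-QC convention.  Circle
membership is by pixel-center distance.  Tolerances are engineering action
limits; no multiplicity correction is applied across KPIs or slices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .config import PhantomModel, ROILayout, ToleranceSet
from .dicom_io import ImageSlice

KPI_NAMES = (
    "positioning_x",
    "positioning_y",
    "positioning_z",
    "noise",
    "water",
    "air",
    "uniformity",
    "homogeneity",
)


class KPIError(RuntimeError):
    pass


class BaselineError(KPIError):
    """The noise KPI is undefined without a stored base value."""


@dataclass(frozen=True)
class ROISpec:
    """A placed region of interest, in pixel coordinates."""

    shape: str                 # "circle" | "square"
    center_row: float
    center_col: float
    diameter_or_side: float    # px
    label: str = ""


@dataclass(frozen=True)
class ROIStats:
    mean: float
    sd: float
    n_pixels: int


@dataclass(frozen=True)
class KPIResult:
    """One named KPI value with its band and pass/fail status.

    ``passed`` is None for purely informational values (e.g. noise measured
    at a technique that has no stored base value).
    """

    name: str
    value: float
    tolerance_low: float
    tolerance_high: float
    passed: Optional[bool]
    baseline: Optional[float] = None
    slice_index: int = 0
    details: dict = field(default_factory=dict)


def _roi_mask(slice_: ImageSlice, roi: ROISpec) -> np.ndarray:
    rows, cols = slice_.pixels.shape
    if roi.shape == "circle":
        radius = roi.diameter_or_side / 2.0
        if (
            roi.center_row - radius < -0.5
            or roi.center_col - radius < -0.5
            or roi.center_row + radius > rows - 0.5
            or roi.center_col + radius > cols - 0.5
        ):
            raise KPIError(f"ROI out of bounds: {roi.label or roi.shape}")
        rr, cc = np.ogrid[:rows, :cols]
        return (rr - roi.center_row) ** 2 + (cc - roi.center_col) ** 2 <= radius**2
    if roi.shape == "square":
        half = roi.diameter_or_side / 2.0
        r0 = int(math.ceil(roi.center_row - half))
        c0 = int(math.ceil(roi.center_col - half))
        r1 = int(math.floor(roi.center_row + half))
        c1 = int(math.floor(roi.center_col + half))
        if r0 < 0 or c0 < 0 or r1 >= rows or c1 >= cols:
            raise KPIError(f"ROI out of bounds: {roi.label or roi.shape}")
        mask = np.zeros((rows, cols), dtype=bool)
        mask[r0 : r1 + 1, c0 : c1 + 1] = True
        return mask
    raise ValueError(f"unknown ROI shape {roi.shape!r}")


def roi_stats(slice_: ImageSlice, roi: ROISpec) -> ROIStats:
    """Mean and sample SD over pixels whose centers lie inside the ROI."""
    values = slice_.pixels[_roi_mask(slice_, roi)]
    if values.size < 2:
        raise KPIError("ROI contains fewer than 2 pixels")
    return ROIStats(
        mean=float(values.mean()),
        sd=float(values.std(ddof=1)),
        n_pixels=int(values.size),
    )


# ---------------------------------------------------------------------------
# KPI computations (ROI placement is delegated to phantom_geometry)
# ---------------------------------------------------------------------------

def kpi_noise(
    slice_: ImageSlice,
    detection,
    baseline_sd: float | None,
    tol: ToleranceSet,
    model: PhantomModel,
    layout: ROILayout | None = None,
    slice_index: int = 0,
) -> KPIResult:
    """Noise KPI: SD in the 40% ROI, relative to the stored base value."""
    from .phantom_geometry import make_roi_spec

    roi = make_roi_spec(detection, "noise", slice_, model, layout)
    stats = roi_stats(slice_, roi)
    if baseline_sd is None or baseline_sd <= 0:
        raise BaselineError("no baseline for protocol")
    low = (1.0 - tol.noise_rel) * baseline_sd
    high = (1.0 + tol.noise_rel) * baseline_sd
    return KPIResult(
        name="noise",
        value=stats.sd,
        tolerance_low=low,
        tolerance_high=high,
        passed=bool(low <= stats.sd <= high),
        baseline=baseline_sd,
        slice_index=slice_index,
        details={"n_pixels": stats.n_pixels, "relative_deviation": stats.sd / baseline_sd - 1.0},
    )


def measure_noise_sd(
    slice_: ImageSlice, detection, model: PhantomModel, layout: ROILayout | None = None
) -> float:
    """SD of the 40% noise ROI without tolerance evaluation (diagnostics/fits)."""
    from .phantom_geometry import make_roi_spec

    return roi_stats(slice_, make_roi_spec(detection, "noise", slice_, model, layout)).sd


def kpi_ct_water(
    slice_: ImageSlice,
    detection,
    tol: ToleranceSet,
    model: PhantomModel,
    layout: ROILayout | None = None,
    slice_index: int = 0,
) -> KPIResult:
    from .phantom_geometry import make_roi_spec

    stats = roi_stats(slice_, make_roi_spec(detection, "ct_number", slice_, model, layout))
    return KPIResult(
        name="water",
        value=stats.mean,
        tolerance_low=-tol.water_hu,
        tolerance_high=tol.water_hu,
        passed=bool(abs(stats.mean) <= tol.water_hu),
        baseline=0.0,
        slice_index=slice_index,
        details={"n_pixels": stats.n_pixels},
    )


def kpi_ct_air(
    slice_: ImageSlice,
    detection,
    tol: ToleranceSet,
    model: PhantomModel,
    layout: ROILayout | None = None,
    slice_index: int = 0,
) -> KPIResult:
    """CT number of air: mean HU of the outside ROI, judged around -1000 HU."""
    from .phantom_geometry import make_roi_spec

    roi = make_roi_spec(detection, "air", slice_, model, layout)
    # the ROI must not touch the detected object (shell included)
    dr = (roi.center_row - detection.center_row) * slice_.pixel_spacing[0]
    dc = (roi.center_col - detection.center_col) * slice_.pixel_spacing[1]
    clearance = math.hypot(dr, dc) - roi.diameter_or_side / 2.0 * slice_.pixel_spacing[1]
    if clearance < detection.diameter_est / 2.0:
        raise KPIError("air ROI overlaps detected object")
    stats = roi_stats(slice_, roi)
    return KPIResult(
        name="air",
        value=stats.mean,
        tolerance_low=-1000.0 - tol.air_hu,
        tolerance_high=-1000.0 + tol.air_hu,
        passed=bool(abs(stats.mean + 1000.0) <= tol.air_hu),
        baseline=-1000.0,
        slice_index=slice_index,
        details={"deviation_hu": stats.mean + 1000.0, "n_pixels": stats.n_pixels},
    )


def kpi_uniformity(
    slice_: ImageSlice,
    detection,
    tol: ToleranceSet,
    model: PhantomModel,
    layout: ROILayout | None = None,
    slice_index: int = 0,
) -> KPIResult:
    from .phantom_geometry import make_roi_spec

    rois = make_roi_spec(detection, "uniformity", slice_, model, layout)
    center = roi_stats(slice_, rois[0])
    diffs = {r.label: abs(roi_stats(slice_, r).mean - center.mean) for r in rois[1:]}
    worst = max(diffs, key=diffs.get)
    value = diffs[worst]
    return KPIResult(
        name="uniformity",
        value=value,
        tolerance_low=0.0,
        tolerance_high=tol.uniformity_hu,
        passed=bool(value <= tol.uniformity_hu),
        slice_index=slice_index,
        details={"center_mean": center.mean, "worst_roi": worst, "differences": diffs},
    )


def homogeneity_tiles(
    slice_: ImageSlice,
    detection,
    model: PhantomModel,
    layout: ROILayout | None = None,
) -> list[tuple[int, int, float]]:
    """Means of the 32x32 tiles wholly inside the 85% circle.

    The tile grid is anchored at the detected phantom center (rounded to the
    nearest pixel) so the statistic is invariant to phantom translation.
    Returns (tile_row_index, tile_col_index, mean) triples; indices are
    relative to the anchor.
    """
    layout = layout or ROILayout()
    t = layout.tile_px
    sr, sc = slice_.pixel_spacing
    radius_px = layout.homogeneity_frac * model.water_diameter_mm / 2.0 / sc
    anchor_r = int(round(detection.center_row))
    anchor_c = int(round(detection.center_col))

    tiles: list[tuple[int, int, float]] = []
    span = int(math.ceil(radius_px / t)) + 1
    for ti in range(-span, span):
        for tj in range(-span, span):
            r0, c0 = anchor_r + ti * t, anchor_c + tj * t
            r1, c1 = r0 + t, c0 + t
            if r0 < 0 or c0 < 0 or r1 > slice_.rows or c1 > slice_.cols:
                continue
            # all four tile corners inside the circle (pixel-center coords)
            corners = ((r0, c0), (r0, c1 - 1), (r1 - 1, c0), (r1 - 1, c1 - 1))
            if any(
                (r - detection.center_row) ** 2 + (c - detection.center_col) ** 2 > radius_px**2
                for r, c in corners
            ):
                continue
            tiles.append((ti, tj, float(slice_.pixels[r0:r1, c0:c1].mean())))
    return tiles


def kpi_homogeneity(
    slice_: ImageSlice,
    detection,
    tol: ToleranceSet,
    model: PhantomModel,
    layout: ROILayout | None = None,
    slice_index: int = 0,
) -> KPIResult:
    tiles = homogeneity_tiles(slice_, detection, model, layout)
    if len(tiles) < 2:
        raise KPIError("phantom too small for tiling")
    hi = max(tiles, key=lambda x: x[2])
    lo = min(tiles, key=lambda x: x[2])
    value = hi[2] - lo[2]
    return KPIResult(
        name="homogeneity",
        value=value,
        tolerance_low=0.0,
        tolerance_high=tol.homogeneity_hu,
        passed=bool(value <= tol.homogeneity_hu),
        slice_index=slice_index,
        details={
            "n_tiles": len(tiles),
            "max_tile": {"index": hi[:2], "mean": hi[2]},
            "min_tile": {"index": lo[:2], "mean": lo[2]},
        },
    )


@dataclass(frozen=True)
class Verdict:
    overall: str                       # "pass" | "fail"
    failing: tuple[KPIResult, ...]

    @property
    def passed(self) -> bool:
        return self.overall == "pass"


def evaluate_tolerances(results: Sequence[KPIResult], tol: ToleranceSet | None = None) -> Verdict:
    """Session verdict: pass iff every evaluated KPI on every slice passes."""
    if not results:
        raise KPIError("no KPI results to evaluate")
    failing = tuple(r for r in results if r.passed is False)
    return Verdict(overall="pass" if not failing else "fail", failing=failing)
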