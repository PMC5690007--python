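"""Phantom detection, positioning offsets and ROI placement.

Segmentation is a simple air/object threshold: every material of the phantom
(water ~0 HU, PMMA shell ~120 HU) is far above air (-1000 HU), so pixels above
-500 HU form the object.  The phantom center is the centroid of the largest
4-connected component, and the diameter estimate is the equivalent-circle
diameter of its area.  All percentage-based ROI rules use the *configured*
water diameter D, not the noisy estimate, so ROI sizes are constant and
reproducible; the estimate only sanity-checks the detection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage import measure

from .config import PhantomModel, ROILayout
from .dicom_io import ImageSlice
from .kpi_core import ROISpec

OBJECT_THRESHOLD_HU = -500.0  # midpoint air/water; robust to +-50 HU drifts


class GeometryError(RuntimeError):
    pass


class MarkerError(GeometryError):
    """Positioning markers undetected (distinct from out-of-tolerance)."""


@dataclass(frozen=True)
class PhantomDetection:
    """Phantom center (mm relative to isocenter) and measured diameter."""

    center_x: float
    center_y: float
    center_row: float
    center_col: float
    diameter_est: float
    ok: bool
    reason: str = ""


@dataclass(frozen=True)
class PositioningResult:
    """X/Y/Z offsets (mm) with per-axis pass at +-tolerance."""

    dx: float
    dy: float
    dz: float
    tolerance: float
    passed_x: bool
    passed_y: bool
    passed_z: bool

    @property
    def passed(self) -> bool:
        return self.passed_x and self.passed_y and self.passed_z

    @classmethod
    def evaluate(cls, dx: float, dy: float, dz: float, tolerance: float) -> "PositioningResult":
        return cls(
            dx=float(dx), dy=float(dy), dz=float(dz), tolerance=float(tolerance),
            passed_x=bool(abs(dx) <= tolerance),
            passed_y=bool(abs(dy) <= tolerance),
            passed_z=bool(abs(dz) <= tolerance),
        )


def _to_mm(slice_: ImageSlice, row: float, col: float) -> tuple[float, float]:
    sr, sc = slice_.pixel_spacing
    x = (col - (slice_.cols - 1) / 2.0) * sc
    y = (row - (slice_.rows - 1) / 2.0) * sr
    return x, y


def detect_phantom(
    slice_: ImageSlice,
    model: PhantomModel,
    layout: ROILayout | None = None,
) -> PhantomDetection:
    """Locate the phantom and measure its center and diameter.

    Returns ``ok=False`` (with a reason) when no object is found, the object
    touches the image border, or its area deviates from the model expectation
    by more than ``layout.area_check_frac``.
    """
    layout = layout or ROILayout()
    mask = slice_.pixels > OBJECT_THRESHOLD_HU
    labels = measure.label(mask, connectivity=1)
    if labels.max() == 0:
        return PhantomDetection(0, 0, 0, 0, 0, ok=False, reason="no phantom")

    props = measure.regionprops(labels)
    max_area = max(p.area for p in props)
    best = [p for p in props if p.area == max_area]
    if len(best) > 1:
        # tie-break: centroid nearest the isocenter
        center = ((slice_.rows - 1) / 2.0, (slice_.cols - 1) / 2.0)
        best.sort(key=lambda p: (p.centroid[0] - center[0]) ** 2 + (p.centroid[1] - center[1]) ** 2)
    obj = best[0]

    row, col = obj.centroid
    x, y = _to_mm(slice_, row, col)
    sr, sc = slice_.pixel_spacing
    diameter = 2.0 * math.sqrt(obj.area * sr * sc / math.pi)

    r0, c0, r1, c1 = obj.bbox
    if r0 == 0 or c0 == 0 or r1 == slice_.rows or c1 == slice_.cols:
        return PhantomDetection(x, y, row, col, diameter, ok=False, reason="truncated")

    expected_area = math.pi * (model.outer_diameter_mm / 2.0) ** 2 / (sr * sc)
    if abs(obj.area - expected_area) > layout.area_check_frac * expected_area:
        return PhantomDetection(x, y, row, col, diameter, ok=False, reason="unexpected size")

    return PhantomDetection(x, y, row, col, diameter, ok=True)


def positioning_offsets(
    positioning_slice: ImageSlice,
    model: PhantomModel,
    tolerance_mm: float = 2.0,
    layout: ROILayout | None = None,
) -> PositioningResult:
    """Compute the X, Y, Z offsets from a positioning-section slice.

    X and Y come from the detected phantom center.  Z is decoded from the two
    opposed 45-degree ramp markers: their in-plane separation s relates to the
    longitudinal offset as dz = (s - 2*radius_mm) / 2.
    """
    det = detect_phantom(positioning_slice, model, layout)
    if not det.ok:
        raise GeometryError(f"phantom not detected on positioning slice: {det.reason}")

    mk = model.markers
    threshold = (mk.marker_hu + model.shell_hu) / 2.0
    mask = positioning_slice.pixels > threshold
    labels = measure.label(mask, connectivity=1)
    props = [p for p in measure.regionprops(labels) if p.area >= 2]
    if len(props) < 2:
        raise MarkerError("positioning markers undetected")
    props.sort(key=lambda p: p.area, reverse=True)
    m1, m2 = props[0], props[1]
    x1, y1 = _to_mm(positioning_slice, *m1.centroid)
    x2, y2 = _to_mm(positioning_slice, *m2.centroid)
    separation = math.hypot(x1 - x2, y1 - y2)
    dz = (separation - 2.0 * mk.radius_mm) / 2.0

    return PositioningResult.evaluate(det.center_x, det.center_y, dz, tolerance_mm)


def make_roi_spec(
    detection: PhantomDetection,
    kind: str,
    slice_: ImageSlice,
    model: PhantomModel,
    layout: ROILayout | None = None,
) -> ROISpec | list[ROISpec]:
    """Place the KPI ROIs relative to the detected phantom center.

    kind:
      noise                one centered circle, diameter 0.40 D
      ct_number            one centered circle, diameter 0.10 D
      uniformity           five circles of diameter 0.10 D: center plus four
                           peripherals at radius D/2 - 0.15 D, at 3, 6, 9 and
                           12 o'clock (returned center-first)
      air                  one circle of diameter 0.10 D outside the phantom,
                           on the image-left horizontal at 0.75 D from center

    D is the configured water diameter in mm.  Raises GeometryError when the
    detection is invalid or an ROI would leave the image.
    """
    if not detection.ok:
        raise GeometryError(f"invalid detection: {detection.reason or 'not ok'}")
    layout = layout or ROILayout()
    sr, sc = slice_.pixel_spacing
    if abs(sr - sc) > 1e-6:
        raise GeometryError("anisotropic pixels not supported for circular ROIs")
    d_mm = model.water_diameter_mm
    px = sc

    def roi(cx_mm_off: float, cy_mm_off: float, diam_mm: float, label: str) -> ROISpec:
        spec = ROISpec(
            shape="circle",
            center_row=detection.center_row + cy_mm_off / sr,
            center_col=detection.center_col + cx_mm_off / sc,
            diameter_or_side=diam_mm / px,
            label=label,
        )
        r = spec.diameter_or_side / 2.0
        if (
            spec.center_row - r < -0.5
            or spec.center_col - r < -0.5
            or spec.center_row + r > slice_.rows - 0.5
            or spec.center_col + r > slice_.cols - 0.5
        ):
            raise GeometryError(f"ROI out of bounds: {label}")
        return spec

    if kind == "noise":
        return roi(0.0, 0.0, layout.noise_frac * d_mm, "noise")
    if kind == "ct_number":
        return roi(0.0, 0.0, layout.ct_frac * d_mm, "water")
    if kind == "uniformity":
        radius = d_mm / 2.0 - layout.peripheral_edge_frac * d_mm
        diam = layout.ct_frac * d_mm
        out = [roi(0.0, 0.0, diam, "uniformity_center")]
        for name, ang in (("3oclock", 0.0), ("6oclock", 90.0), ("9oclock", 180.0), ("12oclock", 270.0)):
            a = math.radians(ang)
            out.append(roi(radius * math.cos(a), radius * math.sin(a), diam, f"uniformity_{name}"))
        return out
    if kind == "air":
        return roi(-layout.air_offset_frac * d_mm, 0.0, layout.ct_frac * d_mm, "air")
    raise ValueError(f"unknown ROI kind {kind!r}")
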