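"""Brooks-formula noise model and the Level-1 diagnostic fits.

The Brooks relation (as reformulated for CT QC) links image-noise variance to
the technique factors:

    sigma^2  ~  exp(-mu*d) / (D * b^2 * w * T)

with object attenuation exp(-mu*d), dose D, sampling distance b (pixel size),
beam collimation w and slice thickness T.  Expanding the dose in tube output,
D ~ mA * s * kVp^n with kilovoltage dependency factor n ~ 2.6, gives

    sigma = k * sqrt( exp(-mu*d) / (mA * s * kVp^n * b^2 * w * T) )

Two diagnostic fits mirror what a physicist extracts from a Level-1 series:
sigma = a * kVp^b + c (recovering n = -2b) over the kVp-varied scans, and
sigma = a / sqrt(mAs) over the mAs-varied scans.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .dicom_io import AcquisitionParams

DEFAULT_KVP_EXPONENT = 2.6
DEFAULT_MU_WATER = 0.019   # 1/mm, water at a typical effective CT energy
DEFAULT_PIXEL_MM = 250.0 / 512.0


class FitError(RuntimeError):
    pass


@dataclass(frozen=True)
class TechniqueFactors:
    """All factors entering the expanded Brooks formula; strictly positive.

    mu [1/mm] and d [mm] describe the object (water path), b [mm] the
    sampling distance at the rotation center (pixel size), w [mm] the total
    beam collimation and T [mm] the slice thickness.
    """

    kvp: float
    tube_current: float     # mA
    exposure_time: float    # s
    w: float                # mm
    T: float                # mm
    b: float = DEFAULT_PIXEL_MM
    mu: float = DEFAULT_MU_WATER
    d: float = 150.0
    n_exponent: float = DEFAULT_KVP_EXPONENT

    def __post_init__(self) -> None:
        for name in ("kvp", "tube_current", "exposure_time", "w", "T", "b", "mu", "d"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @classmethod
    def from_acquisition(
        cls,
        params: AcquisitionParams,
        pixel_mm: float = DEFAULT_PIXEL_MM,
        mu: float = DEFAULT_MU_WATER,
        d: float = 150.0,
        n_exponent: float = DEFAULT_KVP_EXPONENT,
    ) -> "TechniqueFactors":
        return cls(
            kvp=params.kvp,
            tube_current=params.tube_current,
            exposure_time=params.rotation_time,
            w=params.total_collimation_mm,
            T=params.slice_thickness,
            b=pixel_mm,
            mu=mu,
            d=d,
            n_exponent=n_exponent,
        )


def predicted_sigma(tf: TechniqueFactors, k: float = 1.0) -> float:
    """Image noise predicted by the expanded Brooks formula, up to scale k."""
    if k <= 0:
        raise ValueError("k must be > 0")
    denom = (
        tf.tube_current
        * tf.exposure_time
        * tf.kvp**tf.n_exponent
        * tf.b**2
        * tf.w
        * tf.T
    )
    return k * math.sqrt(math.exp(-tf.mu * tf.d) / denom)


def sigma_scale(
    technique: AcquisitionParams,
    reference: AcquisitionParams,
    n_exponent: float = DEFAULT_KVP_EXPONENT,
) -> float:
    """Ratio sigma(technique)/sigma(reference) for the same object and FOV.

    Attenuation and pixel size cancel, leaving the tube-output and beam
    geometry factors of the Brooks formula.
    """
    t = TechniqueFactors.from_acquisition(technique, n_exponent=n_exponent)
    r = TechniqueFactors.from_acquisition(reference, n_exponent=n_exponent)
    return predicted_sigma(t) / predicted_sigma(r)


def noise_ratio(d_old: float, d_new: float) -> float:
    """sigma_new / sigma_old = sqrt(D_old / D_new) for a dose change."""
    if d_old <= 0 or d_new <= 0:
        raise ValueError("doses must be > 0")
    return math.sqrt(d_old / d_new)


@dataclass(frozen=True)
class BrooksFit:
    """Fitted noise-vs-technique model with goodness of fit.

    For the kVp power model the fitted exponent b maps to the kilovoltage
    dependency factor as n = -2b (sigma ~ kVp^(-n/2)).
    """

    model: str                  # "kvp_power" | "mas_inverse_sqrt"
    a: float
    b_exp: float
    c: float
    r2: float
    n_points: int
    n_recovered: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "a": self.a,
            "b_exp": self.b_exp,
            "c": self.c,
            "r2": self.r2,
            "n_points": self.n_points,
            "n_recovered": self.n_recovered,
        }


def _r2(y: np.ndarray, fitted: np.ndarray) -> float:
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res == 0.0 else 0.0
    return 1.0 - ss_res / ss_tot


def fit_kvp_exponent(points: Sequence[tuple[float, float]]) -> BrooksFit:
    """Nonlinear least squares of sigma = a * kVp^b + c; n_recovered = -2b.

    Requires at least 4 points spanning at least 3 distinct kVp values
    (3 free parameters).  Initialization: b0 = -1.3 (the literature n = 2.6),
    c0 = 0, a0 from the first point.
    """
    pts = sorted((float(k), float(s)) for k, s in points)
    kvp = np.array([p[0] for p in pts])
    sig = np.array([p[1] for p in pts])
    if len(pts) < 4 or len(set(kvp.tolist())) < 3:
        raise FitError("need >= 4 points spanning >= 3 distinct kVp values")

    def f(x, a, b, c):
        return a * np.power(x, b) + c

    # degenerate flat data: a -> 0 leaves b unidentifiable; report the flat
    # solution (b = 0) rather than an arbitrary exponent
    if np.ptp(sig) < 1e-12 * max(1.0, float(np.abs(sig).max())):
        a, b, c = 0.0, 0.0, float(sig.mean())
    else:
        b0 = -1.3
        a0 = sig[0] / kvp[0] ** b0
        p0 = [a0, b0, 0.0]
        try:
            popt, _ = curve_fit(f, kvp, sig, p0=p0, maxfev=20000)
        except RuntimeError as exc:
            raise FitError(f"kVp fit did not converge (p0={p0}): {exc}") from exc
        a, b, c = (float(v) for v in popt)
    return BrooksFit(
        model="kvp_power",
        a=a,
        b_exp=b,
        c=c,
        r2=_r2(sig, f(kvp, a, b, c)),
        n_points=len(pts),
        n_recovered=-2.0 * b,
    )


def fit_mas_response(points: Sequence[tuple[float, float]]) -> BrooksFit:
    """Least squares of sigma = a / sqrt(mAs) (the Brooks dose dependence)."""
    pts = sorted((float(m), float(s)) for m, s in points)
    mas = np.array([p[0] for p in pts])
    sig = np.array([p[1] for p in pts])
    if len(pts) < 3 or len(set(mas.tolist())) < 3:
        raise FitError("need >= 3 points with distinct mAs values")
    if np.any(mas <= 0):
        raise FitError("mAs values must be > 0")

    x = 1.0 / np.sqrt(mas)
    a = float(np.sum(sig * x) / np.sum(x * x))
    return BrooksFit(
        model="mas_inverse_sqrt",
        a=a,
        b_exp=-0.5,
        c=0.0,
        r2=_r2(sig, a * x),
        n_points=len(pts),
    )
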