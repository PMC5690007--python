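"""KPI statistics against brute-force pixel-list oracles and tolerance logic."""

import dataclasses
import math
import statistics

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctqc import (
    PhantomModel,
    ROILayout,
    ROISpec,
    SyntheticConfig,
    ToleranceSet,
    detect_phantom,
    evaluate_tolerances,
    generate_water_slice,
    kpi_ct_air,
    kpi_ct_water,
    kpi_homogeneity,
    kpi_noise,
    kpi_uniformity,
    roi_stats,
)
from ctqc.kpi_core import KPIError, KPIResult, homogeneity_tiles


def brute_circle_values(slice_, center_row, center_col, diameter_px):
    """Independent ROI membership: explicit loop over pixel centers."""
    radius2 = (diameter_px / 2.0) ** 2
    vals = []
    for r in range(slice_.rows):
        for c in range(slice_.cols):
            if (r - center_row) ** 2 + (c - center_col) ** 2 <= radius2:
                vals.append(slice_.pixels[r, c])
    return vals


class TestRoiStats:
    def test_constant_image(self, make_slice):
        s = make_slice(np.zeros((64, 64)))
        st_ = roi_stats(s, ROISpec("circle", 31.5, 31.5, 20.0))
        assert st_.mean == 0.0 and st_.sd == 0.0

    def test_symmetric_plus_minus_one(self, make_slice):
        pixels = np.zeros((64, 64))
        pixels[:, ::2] = 1.0
        pixels[:, 1::2] = -1.0
        s = make_slice(pixels)
        st_ = roi_stats(s, ROISpec("square", 31.5, 31.5, 32))
        assert st_.mean == 0.0
        # sample SD of a balanced +-1 population: sqrt(n/(n-1))
        n = st_.n_pixels
        assert st_.sd == pytest.approx(math.sqrt(n / (n - 1)), rel=1e-12)

    def test_matches_bruteforce_on_noise_field(self, make_slice):
        rng = np.random.default_rng(123)
        s = make_slice(rng.normal(0.0, 5.0, size=(200, 200)))
        roi = ROISpec("circle", 99.5, 99.5, 160.0)
        st_ = roi_stats(s, roi)
        vals = brute_circle_values(s, 99.5, 99.5, 160.0)
        assert st_.n_pixels == len(vals)
        assert st_.mean == pytest.approx(statistics.fmean(vals), rel=1e-12, abs=1e-12)
        assert st_.sd == pytest.approx(statistics.stdev(vals), rel=1e-9)
        assert st_.sd == pytest.approx(5.0, rel=0.03)

    def test_out_of_bounds_roi_rejected(self, make_slice):
        s = make_slice(np.zeros((32, 32)))
        with pytest.raises(KPIError, match="out of bounds"):
            roi_stats(s, ROISpec("circle", 2.0, 2.0, 20.0))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(shift=st.floats(-100, 100), seed=st.integers(0, 10))
    def test_sd_invariant_mean_shifts_under_constant_offset(self, shift, seed):
        from ctqc import AcquisitionParams
        from ctqc.dicom_io import ImageSlice

        params = AcquisitionParams(kvp=120, tube_current=100, rotation_time=1.0,
                                   slice_thickness=5.0, collimation="1x1")
        rng = np.random.default_rng(seed)
        base = rng.normal(0, 3, size=(48, 48))
        roi = ROISpec("circle", 23.5, 23.5, 30.0)

        def stats(arr):
            return roi_stats(
                ImageSlice(pixels=arr, pixel_spacing=(0.5, 0.5),
                           slice_location=0.0, params=params), roi)

        a, b = stats(base), stats(base + shift)
        assert b.sd == pytest.approx(a.sd, abs=1e-9)
        assert b.mean - a.mean == pytest.approx(shift, abs=1e-9)


@pytest.fixture(scope="module")
def model():
    return PhantomModel()


@pytest.fixture(scope="module")
def tol():
    return ToleranceSet()


def _slice_and_det(model, **cfg_kwargs):
    cfg = SyntheticConfig(**cfg_kwargs)
    s = generate_water_slice(cfg)
    return s, detect_phantom(s, model)


class TestWaterAndAir:
    def test_noiseless_water_is_zero(self, model, tol):
        s, det = _slice_and_det(model, seed=0, base_sigma=0.0)
        res = kpi_ct_water(s, det, tol, model)
        assert res.value == 0.0 and res.passed

    def test_three_hu_drift_fails(self, model, tol):
        s, det = _slice_and_det(model, seed=1, base_sigma=0.0, drift_hu=3.0)
        res = kpi_ct_water(s, det, tol, model)
        assert res.value == pytest.approx(3.0, abs=0.01)
        assert not res.passed

    def test_small_drift_passes_default_fails_tight_config(self, model):
        s, det = _slice_and_det(model, seed=2, base_sigma=0.0, drift_hu=1.5)
        assert kpi_ct_water(s, det, ToleranceSet(), model).passed
        tight = ToleranceSet(water_hu=1.0)
        assert not kpi_ct_water(s, det, tight, model).passed

    def test_air_nominal_and_shifted(self, model, tol):
        s, det = _slice_and_det(model, seed=3, base_sigma=0.0)
        assert kpi_ct_air(s, det, tol, model).value == -1000.0
        assert kpi_ct_air(s, det, tol, model).passed

        for target, ok in ((-988.0, False), (-1005.0, True)):
            shifted = dataclasses.replace(
                s, pixels=np.where(s.pixels < -500.0, target, s.pixels)
            )
            res = kpi_ct_air(shifted, det, tol, model)
            assert res.value == pytest.approx(target)
            assert res.passed is ok


class TestUniformity:
    def test_uniform_phantom_is_zero(self, model, tol):
        s, det = _slice_and_det(model, seed=4, base_sigma=0.0)
        res = kpi_uniformity(s, det, tol, model)
        assert res.value == 0.0 and res.passed

    def test_cupping_matches_bruteforce_roi_average(self, model, tol):
        k = 5.0
        s, det = _slice_and_det(model, seed=5, base_sigma=0.0, cupping_k=k)
        res = kpi_uniformity(s, det, tol, model)

        from ctqc.phantom_geometry import make_roi_spec

        rois = make_roi_spec(det, "uniformity", s, model)
        means = [statistics.fmean(
            brute_circle_values(s, r.center_row, r.center_col, r.diameter_or_side)
        ) for r in rois]
        brute = max(abs(m - means[0]) for m in means[1:])
        assert res.value == pytest.approx(brute, rel=1e-9)
        # analytic field difference: k*(r_p/R_w)^2 with r_p = 0.35 D, up to
        # pixelation and integer-HU rounding
        analytic = k * 0.7**2
        assert res.value == pytest.approx(analytic, abs=0.3)
        assert res.passed  # 2.45 HU is inside the 3 HU action limit

    def test_strong_cupping_fails(self, model, tol):
        s, det = _slice_and_det(model, seed=6, base_sigma=0.0, cupping_k=8.0)
        res = kpi_uniformity(s, det, tol, model)
        assert res.value > tol.uniformity_hu and not res.passed

    def test_rotating_image_90_degrees_preserves_value(self, model, tol):
        s, det = _slice_and_det(model, seed=7, base_sigma=0.0, cupping_k=5.0)
        rotated = dataclasses.replace(s, pixels=np.rot90(s.pixels).copy())
        det_r = detect_phantom(rotated, model)
        a = kpi_uniformity(s, det, tol, model).value
        b = kpi_uniformity(rotated, det_r, tol, model).value
        assert a == pytest.approx(b, abs=1e-9)


class TestHomogeneity:
    def test_uniform_phantom_is_zero(self, model, tol):
        s, det = _slice_and_det(model, seed=8, base_sigma=0.0)
        res = kpi_homogeneity(s, det, tol, model)
        assert res.value == 0.0 and res.passed

    def test_aligned_tile_defect_recovered_exactly(self, model, tol):
        s, det = _slice_and_det(model, seed=9, base_sigma=0.0, tile_defect=(1, 1, 8.0))
        res = kpi_homogeneity(s, det, tol, model)
        assert res.value == pytest.approx(8.0)
        assert not res.passed
        assert res.details["max_tile"]["index"] == (1, 1)

    def test_ring_matches_bruteforce_tile_means(self, model, tol):
        s, det = _slice_and_det(model, seed=10, base_sigma=0.0, ring=(30.0, 4.0, 2.0))
        res = kpi_homogeneity(s, det, tol, model)

        # independent tiling: same anchor rule, explicit loops
        t = 32
        anchor_r, anchor_c = round(det.center_row), round(det.center_col)
        radius_px = 0.85 * model.water_diameter_mm / 2.0 / s.pixel_spacing[1]
        means = []
        for ti in range(-8, 8):
            for tj in range(-8, 8):
                r0, c0 = anchor_r + ti * t, anchor_c + tj * t
                corners = [(r0, c0), (r0, c0 + t - 1), (r0 + t - 1, c0), (r0 + t - 1, c0 + t - 1)]
                if any(
                    (r - det.center_row) ** 2 + (c - det.center_col) ** 2 > radius_px**2
                    for r, c in corners
                ):
                    continue
                vals = [s.pixels[r, c] for r in range(r0, r0 + t) for c in range(c0, c0 + t)]
                means.append(statistics.fmean(vals))
        assert res.details["n_tiles"] == len(means)
        assert res.value == pytest.approx(max(means) - min(means), rel=1e-9)
        assert res.value > 0  # the ring crosses tile boundaries

    def test_too_few_tiles_is_an_error(self, model, tol):
        s, det = _slice_and_det(model, seed=11, base_sigma=0.0)
        big_tiles = ROILayout(tile_px=400)
        with pytest.raises(KPIError, match="too small"):
            kpi_homogeneity(s, det, tol, model, big_tiles)

    def test_uniformity_and_homogeneity_trend_together_on_cupping(self, model, tol):
        u_vals, h_vals = [], []
        for k in (0.0, 2.0, 4.0, 8.0):
            s, det = _slice_and_det(model, seed=12, base_sigma=0.0, cupping_k=k)
            u_vals.append(kpi_uniformity(s, det, tol, model).value)
            h_vals.append(kpi_homogeneity(s, det, tol, model).value)
        assert u_vals == sorted(u_vals)
        assert h_vals == sorted(h_vals)


class TestNoiseKPI:
    def test_relative_tolerance_boundaries(self, model, tol):
        s, det = _slice_and_det(model, seed=13)
        res = kpi_noise(s, det, baseline_sd=5.0, tol=tol, model=model)
        assert res.passed  # nominal sigma matches its base value
        # 6% above base fails, exact base passes: check band arithmetic
        assert res.tolerance_low == pytest.approx(4.75)
        assert res.tolerance_high == pytest.approx(5.25)
        failing = kpi_noise(s, det, baseline_sd=res.value / 1.06, tol=tol, model=model)
        assert not failing.passed

    def test_missing_baseline_is_an_error(self, model, tol):
        from ctqc.kpi_core import BaselineError

        s, det = _slice_and_det(model, seed=14)
        with pytest.raises(BaselineError, match="baseline"):
            kpi_noise(s, det, baseline_sd=None, tol=tol, model=model)

    def test_halved_diameter_phantom_raises_sd_sqrt2(self, tol):
        # same technique, attenuation path halved via a half-size phantom is
        # not modelled; instead check the Brooks dose rule on the generator:
        # halving mAs multiplies sigma by sqrt(2)
        import ctqc

        small = PhantomModel()
        base = ctqc.REFERENCE_TECHNIQUE
        half = dataclasses.replace(base, tube_current=130.0)
        s1 = generate_water_slice(SyntheticConfig(seed=15, technique=base))
        s2 = generate_water_slice(SyntheticConfig(seed=16, technique=half))
        d1, d2 = detect_phantom(s1, small), detect_phantom(s2, small)
        sd1 = kpi_noise(s1, d1, 5.0, tol, small).value
        sd2 = kpi_noise(s2, d2, 5.0 * math.sqrt(2), tol, small).value
        assert sd2 / sd1 == pytest.approx(math.sqrt(2), rel=0.03)


class TestEvaluateTolerances:
    def _result(self, name, value, low, high, idx=0):
        return KPIResult(name=name, value=value, tolerance_low=low,
                         tolerance_high=high, passed=low <= value <= high,
                         slice_index=idx)

    def test_all_nominal_passes(self):
        results = [self._result("water", 0.5, -2, 2), self._result("uniformity", 1.0, 0, 3)]
        assert evaluate_tolerances(results).overall == "pass"

    def test_single_slice_failure_fails_session(self):
        results = [self._result("water", 0.5, -2, 2, idx=i) for i in range(7)]
        results.append(self._result("water", 2.5, -2, 2, idx=7))
        verdict = evaluate_tolerances(results)
        assert verdict.overall == "fail"
        assert [r.slice_index for r in verdict.failing] == [7]

    def test_empty_results_rejected(self):
        with pytest.raises(KPIError):
            evaluate_tolerances([])

    def test_drift_session_fails_only_water(self, model, tol):
        s, det = _slice_and_det(model, seed=17, drift_hu=3.0)
        results = [
            kpi_noise(s, det, 5.0, tol, model),
            kpi_ct_water(s, det, tol, model),
            kpi_ct_air(s, det, tol, model),
            kpi_uniformity(s, det, tol, model),
            kpi_homogeneity(s, det, tol, model),
        ]
        verdict = evaluate_tolerances(results)
        assert verdict.overall == "fail"
        assert [r.name for r in verdict.failing] == ["water"]
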