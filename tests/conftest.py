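import numpy as np
import pytest

from ctqc import (
    AcquisitionParams,
    BaselineStore,
    PhantomModel,
    RunConfig,
    SyntheticConfig,
    TrendStore,
    REFERENCE_TECHNIQUE,
    generate_water_slice,
)
from ctqc.dicom_io import ImageSlice


@pytest.fixture(scope="session")
def phantom_model() -> PhantomModel:
    return PhantomModel()


@pytest.fixture(scope="session")
def dummy_params() -> AcquisitionParams:
    """Minimal valid technique for hand-built test images."""
    return AcquisitionParams(
        kvp=120.0, tube_current=100.0, rotation_time=1.0,
        slice_thickness=5.0, collimation="1x1",
    )


@pytest.fixture
def make_slice(dummy_params):
    """Build an ImageSlice from a raw pixel array (0.5 mm/px by default)."""

    def _make(pixels, spacing=0.5, slice_location=0.0, params=None):
        return ImageSlice(
            pixels=np.asarray(pixels, dtype=float),
            pixel_spacing=(spacing, spacing),
            slice_location=slice_location,
            params=params or dummy_params,
        )

    return _make


@pytest.fixture(scope="session")
def nominal_slice() -> "ImageSlice":
    """One nominal noisy water slice shared by read-only tests."""
    return generate_water_slice(SyntheticConfig(seed=11))


@pytest.fixture
def run_config(tmp_path) -> RunConfig:
    return RunConfig(
        trend_dir=tmp_path / "trend",
        baseline_path=tmp_path / "baselines.json",
        output_dir=tmp_path / "reports",
    )


@pytest.fixture
def baselines(run_config) -> BaselineStore:
    store = BaselineStore(run_config.baseline_path)
    store.set("CT1", REFERENCE_TECHNIQUE, 5.0)
    return store


@pytest.fixture
def trend_store(run_config) -> TrendStore:
    return TrendStore(run_config.trend_dir)
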