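"""DICOM input/output for phantom QC series.

Reads standard CT Image Storage objects, applies RescaleSlope/Intercept
exactly once to obtain Hounsfield units, and maps the acquisition-technique
tags into :class:`AcquisitionParams`.  Files are stored as signed 16-bit
integers with slope 1 / intercept -1024 (the common CT convention); in memory
pixels are float64 HU.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

LOG = logging.getLogger("ctqc.dicom_io")

_RESCALE_INTERCEPT = -1024.0
_ROOT_UID = "1.2.826.0.1.3680043.10.1463"  # fixed org root for deterministic UIDs


class DicomReadError(RuntimeError):
    """A file could not be parsed as a usable CT image; names the file."""


class DicomWriteError(RuntimeError):
    """The slice list cannot be represented losslessly as DICOM."""


@dataclass(frozen=True)
class AcquisitionParams:
    """Technique factors and identity tags of one acquisition.

    ``collimation`` uses the "NxW" notation, e.g. "8x0.625" for 8 detector
    rows of 0.625 mm (total beam width w = 5 mm).  ``part`` labels the
    scanned phantom section ("water" or "positioning", from the DICOM
    SeriesDescription).
    """

    kvp: float
    tube_current: float          # mA
    rotation_time: float         # s
    slice_thickness: float       # mm
    collimation: str             # "NxW" text
    sfov: str = "head"           # shaped-filter / scan-FOV label
    fov_mm: float = 250.0        # reconstruction FOV
    kernel: str = "std"
    part: str = "water"
    station: str = "unknown"
    acquired_at: _dt.datetime | None = None

    def __post_init__(self) -> None:
        for name in ("kvp", "tube_current", "rotation_time", "slice_thickness"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def mas(self) -> float:
        """Tube current-time product (mAs)."""
        return self.tube_current * self.rotation_time

    @property
    def collimation_parsed(self) -> tuple[int, float]:
        return parse_collimation(self.collimation)

    @property
    def total_collimation_mm(self) -> float:
        n, w = self.collimation_parsed
        return n * w

    @property
    def technique_key(self) -> tuple:
        """Grouping key: scanned part + the full technique tuple."""
        return (
            self.part,
            self.kvp,
            self.tube_current,
            self.rotation_time,
            self.slice_thickness,
            self.collimation,
            self.sfov,
            self.kernel,
        )

    def technique_label(self) -> str:
        return (
            f"{self.part}_{self.kvp:g}kVp_{self.tube_current:g}mA_"
            f"{self.rotation_time:g}s_{self.slice_thickness:g}mm_"
            f"{self.collimation}_{self.sfov}_{self.kernel}"
        )


def parse_collimation(text: str) -> tuple[int, float]:
    """Parse "NxW" collimation text into (n_rows, row_width_mm)."""
    t = text.lower().replace("×", "x")
    try:
        n_s, w_s = t.split("x")
        n, w = int(n_s), float(w_s)
    except ValueError as exc:
        raise ValueError(f"cannot parse collimation {text!r}") from exc
    if n <= 0 or w <= 0:
        raise ValueError(f"collimation {text!r} must be positive")
    return n, w


@dataclass
class ImageSlice:
    """One phantom image in HU with its geometry and technique metadata.

    In-plane physical coordinates are mm relative to the image center
    (taken as the isocenter); +x is to the image right (increasing column),
    +y down the image (increasing row).
    """

    pixels: np.ndarray           # 2-D float64, HU
    pixel_spacing: tuple[float, float]   # (row, col) mm/pixel
    slice_location: float        # mm
    params: AcquisitionParams

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or min(self.pixels.shape) == 0:
            raise ValueError("pixels must be a non-empty 2-D array")
        if min(self.pixel_spacing) <= 0:
            raise ValueError("pixel_spacing must be > 0")

    @property
    def rows(self) -> int:
        return self.pixels.shape[0]

    @property
    def cols(self) -> int:
        return self.pixels.shape[1]

    def mm_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """(y, x) mm coordinate grids of pixel centers, origin at image center."""
        sr, sc = self.pixel_spacing
        y = (np.arange(self.rows) - (self.rows - 1) / 2.0) * sr
        x = (np.arange(self.cols) - (self.cols - 1) / 2.0) * sc
        return np.meshgrid(y, x, indexing="ij")


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _params_from_dataset(ds: Dataset, path: Path) -> AcquisitionParams:
    def _get(tag, default=None):
        return getattr(ds, tag, default)

    coll = None
    single = _get("SingleCollimationWidth")
    total = _get("TotalCollimationWidth")
    if single and total:
        coll = f"{int(round(float(total) / float(single)))}x{float(single):g}"
    if coll is None:
        coll = str(_get("ProtocolName", "1x1")).split("|")[-1] or "1x1"

    exposure_ms = _get("ExposureTime")
    rotation = float(exposure_ms) / 1000.0 if exposure_ms else 1.0

    station = str(_get("StationName", "") or "")
    if not station:
        station = "unknown"
        LOG.warning("%s: missing StationName, using 'unknown'", path)
    acq = None
    date, time = _get("AcquisitionDate"), _get("AcquisitionTime", "000000")
    if date:
        try:
            acq = _dt.datetime.strptime(
                f"{date}{str(time)[:6]:0<6}", "%Y%m%d%H%M%S"
            ).replace(tzinfo=_dt.timezone.utc)
        except ValueError:
            acq = None
    if acq is None:
        acq = _dt.datetime.fromtimestamp(path.stat().st_mtime, _dt.timezone.utc)
        LOG.warning("%s: missing AcquisitionDate, using file mtime", path)

    return AcquisitionParams(
        kvp=float(_get("KVP", 0) or 0) or 120.0,
        tube_current=float(_get("XRayTubeCurrent", 0) or 0) or 1.0,
        rotation_time=rotation,
        slice_thickness=float(_get("SliceThickness", 0) or 0) or 1.0,
        collimation=coll,
        sfov=str(_get("FilterType", "head") or "head"),
        fov_mm=float(_get("ReconstructionDiameter", 250.0) or 250.0),
        kernel=str(_get("ConvolutionKernel", "std") or "std"),
        part=str(_get("SeriesDescription", "water") or "water"),
        station=station,
        acquired_at=acq,
    )


def read_series(path: str | Path | Sequence[str | Path]) -> list[ImageSlice]:
    """Read a DICOM CT series into HU slices sorted by slice location.

    ``path`` may be a directory or an explicit list of files.  Missing pixel
    spacing or rescale tags are hard errors (geometry/HU undefined); other
    missing tags fall back with a logged warning.
    """
    if isinstance(path, (str, Path)):
        p = Path(path)
        files = sorted(p.iterdir()) if p.is_dir() else [p]
    else:
        files = [Path(f) for f in path]
    files = [f for f in files if f.is_file()]
    if not files:
        raise DicomReadError(f"no files found under {path}")

    slices: list[ImageSlice] = []
    for f in files:
        try:
            ds = pydicom.dcmread(f)
            arr = ds.pixel_array
        except Exception as exc:
            raise DicomReadError(f"cannot read DICOM file {f}: {exc}") from exc
        if "PixelSpacing" not in ds:
            raise DicomReadError(f"{f}: missing PixelSpacing; geometry undefined")
        if "RescaleSlope" not in ds or "RescaleIntercept" not in ds:
            raise DicomReadError(f"{f}: missing rescale tags; HU undefined")
        hu = arr.astype(np.float64) * float(ds.RescaleSlope) + float(ds.RescaleIntercept)
        loc = ds.get("SliceLocation")
        if loc is None:
            ipp = ds.get("ImagePositionPatient")
            loc = float(ipp[2]) if ipp is not None else 0.0
        spacing = (float(ds.PixelSpacing[0]), float(ds.PixelSpacing[1]))
        slices.append(
            ImageSlice(
                pixels=hu,
                pixel_spacing=spacing,
                slice_location=float(loc),
                params=_params_from_dataset(ds, f),
            )
        )
    slices.sort(key=lambda s: s.slice_location)  # stable: file order breaks ties
    return slices


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def write_series(
    slices: Sequence[ImageSlice],
    path: str | Path,
    series_tag: str = "ctqc",
) -> list[Path]:
    """Write slices as CT Image Storage files; lossless for integer HU.

    The fixed rescale (slope 1, intercept -1024) represents any integer HU in
    [-1024, 31743] exactly; non-integer HU raise rather than being silently
    quantized.  UIDs and dates are derived deterministically from the slice
    content and ``series_tag`` so identical inputs produce identical files.
    """
    if not slices:
        raise DicomWriteError("empty slice list")
    shape = slices[0].pixels.shape
    spacing = slices[0].pixel_spacing
    for s in slices[1:]:
        if s.pixels.shape != shape or s.pixel_spacing != spacing:
            raise DicomWriteError("slices have mismatched shapes or spacing")

    out_dir = Path(path)
    out_dir.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid(prefix=_ROOT_UID + ".", entropy_srcs=[series_tag])
    study_uid = generate_uid(prefix=_ROOT_UID + ".", entropy_srcs=[series_tag, "study"])

    paths: list[Path] = []
    for i, s in enumerate(slices):
        stored = s.pixels - _RESCALE_INTERCEPT
        rounded = np.rint(stored)
        if not np.array_equal(stored, rounded):
            raise DicomWriteError(
                f"slice {i}: HU not integer-representable under slope 1 / "
                f"intercept {_RESCALE_INTERCEPT:g}; refusing to quantize"
            )
        if rounded.min() < np.iinfo(np.int16).min or rounded.max() > np.iinfo(np.int16).max:
            raise DicomWriteError(f"slice {i}: stored values exceed int16 range")

        ds = Dataset()
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = generate_uid(
            prefix=_ROOT_UID + ".", entropy_srcs=[series_tag, str(i)]
        )
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.Modality = "CT"
        ds.SeriesDescription = s.params.part
        ds.StationName = s.params.station
        ds.PatientName = "QA^Phantom"
        ds.PatientID = "QA"
        when = s.params.acquired_at or _dt.datetime(2000, 1, 1, tzinfo=_dt.timezone.utc)
        ds.AcquisitionDate = when.strftime("%Y%m%d")
        ds.AcquisitionTime = when.strftime("%H%M%S")
        ds.StudyDate = ds.AcquisitionDate
        ds.StudyTime = ds.AcquisitionTime

        ds.KVP = f"{s.params.kvp:g}"
        ds.XRayTubeCurrent = int(round(s.params.tube_current))
        ds.ExposureTime = int(round(s.params.rotation_time * 1000))
        ds.Exposure = int(round(s.params.mas))
        ds.SliceThickness = f"{s.params.slice_thickness:g}"
        n_rows, row_w = s.params.collimation_parsed
        ds.SingleCollimationWidth = row_w
        ds.TotalCollimationWidth = n_rows * row_w
        ds.FilterType = s.params.sfov
        ds.ConvolutionKernel = s.params.kernel
        ds.ReconstructionDiameter = f"{s.params.fov_mm:g}"
        ds.ProtocolName = f"ctqc|{s.params.collimation}"

        ds.Rows, ds.Columns = shape
        ds.PixelSpacing = [f"{spacing[0]:g}", f"{spacing[1]:g}"]
        ds.SliceLocation = f"{s.slice_location:g}"
        ds.ImagePositionPatient = [
            f"{-(shape[1] - 1) / 2 * spacing[1]:g}",
            f"{-(shape[0] - 1) / 2 * spacing[0]:g}",
            f"{s.slice_location:g}",
        ]
        ds.ImageOrientationPatient = ["1", "0", "0", "0", "1", "0"]
        ds.InstanceNumber = i + 1

        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1  # signed
        ds.RescaleSlope = "1"
        ds.RescaleIntercept = f"{_RESCALE_INTERCEPT:g}"
        ds.RescaleType = "HU"
        ds.PixelData = rounded.astype(np.int16).tobytes()

        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = CTImageStorage
        meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.file_meta = meta

        out = out_dir / f"slice_{i:03d}.dcm"
        ds.save_as(out, enforce_file_format=True)
        paths.append(out)
    return paths


def group_by_acquisition(
    slices: Iterable[ImageSlice],
) -> list[tuple[AcquisitionParams, list[ImageSlice]]]:
    """Partition slices by identical technique (and scanned part), order-preserving."""
    groups: dict[tuple, list[ImageSlice]] = {}
    reps: dict[tuple, AcquisitionParams] = {}
    for s in slices:
        key = s.params.technique_key
        if key not in groups:
            groups[key] = []
            reps[key] = s.params
        groups[key].append(s)
    return [(reps[k], groups[k]) for k in groups]
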