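"""Level-0 / Level-1 session orchestration, persistence and trend analysis.

Level 0 is the daily pass/fail test: one slice over the phantom's reference
markings (positioning KPI) plus one multi-slice scan over the homogeneous
water section (noise, water, air, uniformity, homogeneity on every slice).
Level 1 is the diagnostic protocol: the same positioning slice plus a series
of water scans in which technique factors (kVp, mA, rotation time, slice
thickness, collimation, SFOV, kernel) are varied one at a time, so a failing
KPI can be traced to the underlying parameter via the Brooks-formula fits.

A session verdict has three states: ``pass``, ``fail`` (a KPI is out of
tolerance) and ``invalid`` (the measurement itself cannot be trusted, e.g.
the phantom was not detected or a required slice is missing).  Results are
appended to a flat JSON-lines trend store, one record per KPI value; noise
base values live in a small JSON baseline store keyed by scanner and
technique.
"""

from __future__ import annotations

import csv
import dataclasses
import datetime as _dt
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from . import kpi_core
from .brooks_model import BrooksFit, FitError, fit_kvp_exponent, fit_mas_response
from .config import RunConfig
from .dicom_io import AcquisitionParams, ImageSlice, group_by_acquisition
from .kpi_core import BaselineError, KPIResult, evaluate_tolerances
from .phantom_geometry import GeometryError, detect_phantom, positioning_offsets

LOG = logging.getLogger("ctqc.qc_engine")


def _dumps(obj) -> str:
    """json.dumps tolerant of numpy scalars."""
    return json.dumps(obj, default=lambda o: o.item() if hasattr(o, "item") else str(o))


# ---------------------------------------------------------------------------
# protocol expectations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProtocolRow:
    part: str
    n_slices: int
    kvp: float
    sfov: str
    tube_current: float
    rotation_time: float
    fov_mm: float
    slice_thickness: float
    collimation: str
    kernel: str

    def params(self, station: str = "unknown",
               acquired_at: _dt.datetime | None = None) -> AcquisitionParams:
        return AcquisitionParams(
            kvp=self.kvp,
            tube_current=self.tube_current,
            rotation_time=self.rotation_time,
            slice_thickness=self.slice_thickness,
            collimation=self.collimation,
            sfov=self.sfov,
            fov_mm=self.fov_mm,
            kernel=self.kernel,
            part=self.part,
            station=station,
            acquired_at=acquired_at,
        )


@dataclass(frozen=True)
class ProtocolSpec:
    level: int
    rows: tuple[ProtocolRow, ...]

    @property
    def n_images(self) -> int:
        return sum(r.n_slices for r in self.rows)


def _row(part, n, kvp, sfov, ma, rot, thk, coll, kernel="std") -> ProtocolRow:
    return ProtocolRow(part, n, kvp, sfov, ma, rot, 250.0, thk, coll, kernel)


# Daily test: positioning slice + one 8-slice water scan at the standard
# technique (120 kVp, 260 mA, 1 s, head SFOV, 25 cm FOV, 5 mm, std kernel).
LEVEL0_PROTOCOL = ProtocolSpec(0, (
    _row("positioning", 1, 120, "head", 260, 1.0, 5.0, "8x0.625"),
    _row("water", 8, 120, "head", 260, 1.0, 5.0, "64x0.625"),
))

# Diagnostic test: one technique factor varied per scan (33 slices in all).
LEVEL1_PROTOCOL = ProtocolSpec(1, (
    _row("positioning", 1, 120, "head", 260, 1.0, 5.0, "8x0.625"),
    _row("water", 1, 80, "head", 260, 1.0, 5.0, "8x0.625"),
    _row("water", 1, 100, "head", 260, 1.0, 5.0, "8x0.625"),
    _row("water", 1, 120, "head", 100, 1.0, 5.0, "8x0.625"),
    _row("water", 1, 120, "head", 180, 1.0, 5.0, "8x0.625"),
    _row("water", 1, 120, "head", 260, 0.5, 5.0, "8x0.625"),
    _row("water", 1, 120, "head", 260, 1.0, 5.0, "8x0.625"),
    _row("water", 1, 120, "head", 260, 2.0, 5.0, "8x0.625"),
    _row("water", 8, 120, "head", 260, 1.0, 5.0, "64x0.625"),
    _row("water", 8, 120, "head", 260, 1.0, 2.5, "32x0.625"),
    _row("water", 4, 120, "head", 260, 1.0, 1.25, "16x0.625"),
    _row("water", 1, 120, "medium", 260, 1.0, 5.0, "8x0.625"),
    _row("water", 1, 120, "body", 260, 1.0, 5.0, "8x0.625"),
    _row("water", 1, 120, "head", 600, 1.0, 5.0, "8x0.625"),
    _row("water", 1, 120, "head", 600, 1.0, 5.0, "8x0.625", "edge"),
    _row("water", 1, 140, "head", 260, 1.0, 5.0, "8x0.625"),
))

# The Level-1 row all single-factor variations refer back to.
LEVEL1_STANDARD = _row("water", 1, 120, "head", 260, 1.0, 5.0, "8x0.625").params()


def protocol_for_level(level: int) -> ProtocolSpec:
    if level == 0:
        return LEVEL0_PROTOCOL
    if level == 1:
        return LEVEL1_PROTOCOL
    raise ValueError(f"unknown level {level!r}")


# KPI -> underlying QC parameters it mainly depends on; used as diagnostic
# hints when a KPI fails (the root-cause analysis itself stays with the
# medical physicist).
DEPENDENCY_MAP: dict[str, tuple[str, ...]] = {
    "positioning_x": ("Table top indexing", "Table top orientation", "Scan plane localization"),
    "positioning_y": ("Table top indexing", "Table top orientation", "Scan plane localization"),
    "positioning_z": ("Table top indexing", "Table top orientation", "Scan plane localization"),
    "noise": (
        "X-ray tube voltage", "CTDI_vol", "CTDI_air", "Spatial resolution", "HVL",
        "Low contrast resolution", "Collimation", "Slice thickness",
        "Geometric efficiency", "Z-dose profile", "Dose-noise response",
        "Detector response", "Inter-slice noise",
    ),
    "water": ("CT number of water", "CT number of air", "Calibration"),
    "air": ("CT number of water", "CT number of air", "Calibration"),
    "uniformity": ("Shaped filter", "Reconstruction", "Detector"),
    "homogeneity": ("Artifact evaluation",),
}


# ---------------------------------------------------------------------------
# protocol matching
# ---------------------------------------------------------------------------

_TECH_FIELDS = ("part", "kvp", "tube_current", "rotation_time",
                "slice_thickness", "collimation", "sfov", "kernel")


def _tech_diffs(params: AcquisitionParams, row: ProtocolRow) -> list[str]:
    expected = row.params()
    return [f for f in _TECH_FIELDS if getattr(params, f) != getattr(expected, f)]


@dataclass
class ProtocolMatchReport:
    matched: list[dict] = field(default_factory=list)
    missing: list[dict] = field(default_factory=list)
    mismatched: list[dict] = field(default_factory=list)
    extra: list[str] = field(default_factory=list)

    @property
    def full_match(self) -> bool:
        return not (self.missing or self.mismatched or self.extra)

    def to_dict(self) -> dict:
        return {
            "full_match": self.full_match,
            "matched": self.matched,
            "missing": self.missing,
            "mismatched": self.mismatched,
            "extra": self.extra,
        }


def check_protocol(slices: Sequence[ImageSlice], spec: ProtocolSpec) -> ProtocolMatchReport:
    """Match observed acquisition groups against the expected protocol rows."""
    report = ProtocolMatchReport()
    observed = [(p, list(group)) for p, group in group_by_acquisition(slices)]
    unclaimed = list(range(len(observed)))

    for row in spec.rows:
        exact = [
            i for i in unclaimed
            if not _tech_diffs(observed[i][0], row) and len(observed[i][1]) == row.n_slices
        ]
        if exact:
            i = exact[0]
            unclaimed.remove(i)
            report.matched.append({"row": dataclasses.asdict(row)})
            continue
        # nearest same-part group, for a field-level mismatch description
        candidates = [i for i in unclaimed if observed[i][0].part == row.part]
        if candidates:
            i = min(candidates, key=lambda j: len(_tech_diffs(observed[j][0], row)))
            diffs = _tech_diffs(observed[i][0], row)
            if len(observed[i][1]) != row.n_slices:
                diffs = diffs + ["n_slices"]
            unclaimed.remove(i)
            report.mismatched.append({
                "row": dataclasses.asdict(row),
                "found": observed[i][0].technique_label(),
                "fields": diffs,
            })
        else:
            report.missing.append({"row": dataclasses.asdict(row)})

    report.extra = [observed[i][0].technique_label() for i in unclaimed]
    return report


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

class BaselineStore:
    """Noise base values keyed by (scanner, technique); JSON file on disk.

    The base value is defined at acceptance testing and must not drift
    silently: overwriting requires an explicit ``force``.
    """

    def __init__(self, path: str | Path):
        self.path = Path(path)
        self._data: dict[str, dict[str, float]] = {}
        if self.path.exists():
            self._data = json.loads(self.path.read_text())

    def get(self, scanner_id: str, technique: AcquisitionParams | str) -> Optional[float]:
        key = technique if isinstance(technique, str) else technique.technique_label()
        return self._data.get(scanner_id, {}).get(key)

    def set(self, scanner_id: str, technique: AcquisitionParams | str,
            value: float, force: bool = False) -> None:
        if value <= 0:
            raise ValueError("baseline must be > 0")
        key = technique if isinstance(technique, str) else technique.technique_label()
        existing = self._data.get(scanner_id, {}).get(key)
        if existing is not None and not force:
            raise BaselineError(
                f"baseline already set for {scanner_id}/{key} "
                f"({existing:g}); use force to overwrite"
            )
        self._data.setdefault(scanner_id, {})[key] = float(value)
        self.path.parent.mkdir(parents=True, exist_ok=True)
        self.path.write_text(json.dumps(self._data, indent=2, sort_keys=True))

    def items(self):
        for scanner, entries in sorted(self._data.items()):
            for key, value in sorted(entries.items()):
                yield scanner, key, value


def set_baseline(store: BaselineStore, scanner_id: str,
                 technique: AcquisitionParams | str, value: float,
                 force: bool = False) -> None:
    store.set(scanner_id, technique, value, force=force)


class TrendStore:
    """Append-only JSON-lines store, one file per scanner, one line per KPI."""

    def __init__(self, directory: str | Path):
        self.directory = Path(directory)

    def _path(self, scanner_id: str) -> Path:
        return self.directory / f"{scanner_id}.jsonl"

    def append_session(self, session: "QCSession") -> None:
        self.directory.mkdir(parents=True, exist_ok=True)
        with self._path(session.scanner_id).open("a") as fh:
            for r in session.kpi_results:
                fh.write(_dumps({
                    "scanner_id": session.scanner_id,
                    "timestamp": session.timestamp.isoformat(),
                    "level": session.level,
                    "kpi": r.name,
                    "slice_index": r.slice_index,
                    "value": r.value,
                    "passed": r.passed,
                }) + "\n")

    def series(
        self,
        scanner_id: str,
        kpi: str,
        slice_index: int | None = None,
        window: tuple[_dt.datetime | None, _dt.datetime | None] = (None, None),
    ) -> list[tuple[_dt.datetime, float, Optional[bool]]]:
        """Chronological (timestamp, value, passed) series; bounds inclusive."""
        path = self._path(scanner_id)
        if not path.exists():
            return []
        start, end = window
        out = []
        with path.open() as fh:
            for line in fh:
                rec = json.loads(line)
                if rec["kpi"] != kpi:
                    continue
                if slice_index is not None and rec["slice_index"] != slice_index:
                    continue
                ts = _dt.datetime.fromisoformat(rec["timestamp"])
                if start is not None and ts < start:
                    continue
                if end is not None and ts > end:
                    continue
                out.append((ts, rec["value"], rec["passed"]))
        out.sort(key=lambda r: r[0])
        return out

    def export_csv(self, scanner_id: str, kpi: str, path: str | Path,
                   slice_index: int | None = None,
                   window=(None, None)) -> int:
        rows = self.series(scanner_id, kpi, slice_index, window)
        with Path(path).open("w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["timestamp", "value", "passed"])
            for ts, value, passed in rows:
                writer.writerow([ts.isoformat(), value, passed])
        return len(rows)


def trend_series(store: TrendStore, scanner_id: str, kpi: str,
                 slice_index: int | None = None,
                 window=(None, None)) -> list[tuple[_dt.datetime, float, Optional[bool]]]:
    return store.series(scanner_id, kpi, slice_index, window)


# ---------------------------------------------------------------------------
# sessions
# ---------------------------------------------------------------------------

@dataclass
class QCSession:
    scanner_id: str
    timestamp: _dt.datetime
    level: int
    n_slices: int
    kpi_results: list[KPIResult]
    verdict: str                            # "pass" | "fail" | "invalid"
    notes: list[str] = field(default_factory=list)
    recommendations: dict[str, tuple[str, ...]] = field(default_factory=dict)
    brooks_fits: dict[str, BrooksFit] = field(default_factory=dict)
    protocol_report: ProtocolMatchReport | None = None
    group_table: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "scanner_id": self.scanner_id,
            "timestamp": self.timestamp.isoformat(),
            "level": self.level,
            "n_slices": self.n_slices,
            "verdict": self.verdict,
            "kpi_results": [dataclasses.asdict(r) for r in self.kpi_results],
            "notes": self.notes,
            "recommendations": {k: list(v) for k, v in self.recommendations.items()},
            "brooks_fits": {k: f.to_dict() for k, f in self.brooks_fits.items()},
            "protocol_report": self.protocol_report.to_dict() if self.protocol_report else None,
            "group_table": self.group_table,
        }


def _session_timestamp(slices: Sequence[ImageSlice]) -> _dt.datetime:
    stamps = [s.params.acquired_at for s in slices if s.params.acquired_at]
    return max(stamps) if stamps else _dt.datetime.now(_dt.timezone.utc)


def _positioning_kpis(pos_slice: ImageSlice, config: RunConfig) -> list[KPIResult]:
    res = positioning_offsets(pos_slice, config.phantom,
                              config.tolerances.positioning_mm, config.roi)
    t = config.tolerances.positioning_mm
    return [
        KPIResult(name=f"positioning_{axis}", value=value, tolerance_low=-t,
                  tolerance_high=t, passed=passed, slice_index=-1)
        for axis, value, passed in (
            ("x", res.dx, res.passed_x),
            ("y", res.dy, res.passed_y),
            ("z", res.dz, res.passed_z),
        )
    ]


def _water_slice_kpis(
    slice_: ImageSlice,
    slice_index: int,
    config: RunConfig,
    baseline_sd: float | None,
    require_baseline: bool,
    evaluate: bool = True,
) -> list[KPIResult]:
    det = detect_phantom(slice_, config.phantom, config.roi)
    if not det.ok:
        raise GeometryError(f"phantom not detected on slice {slice_index}: {det.reason}")
    tol, model, layout = config.tolerances, config.phantom, config.roi
    results = []
    if baseline_sd is not None:
        results.append(kpi_core.kpi_noise(slice_, det, baseline_sd, tol, model,
                                          layout, slice_index))
    elif require_baseline:
        raise BaselineError(
            f"no baseline for protocol {slice_.params.technique_label()!r} "
            f"on scanner {slice_.params.station!r}"
        )
    else:
        sd = kpi_core.measure_noise_sd(slice_, det, model, layout)
        results.append(KPIResult(name="noise", value=sd, tolerance_low=float("nan"),
                                 tolerance_high=float("nan"), passed=None,
                                 slice_index=slice_index,
                                 details={"note": "no baseline for technique"}))
    results.append(kpi_core.kpi_ct_water(slice_, det, tol, model, layout, slice_index))
    results.append(kpi_core.kpi_ct_air(slice_, det, tol, model, layout, slice_index))
    results.append(kpi_core.kpi_uniformity(slice_, det, tol, model, layout, slice_index))
    results.append(kpi_core.kpi_homogeneity(slice_, det, tol, model, layout, slice_index))
    if not evaluate:
        # diagnostic technique: the daily action limits are not meaningful at
        # strongly elevated noise; record values without pass/fail
        results = [dataclasses.replace(r, passed=None) for r in results]
    return results


def _finalize(session: QCSession, invalid: bool,
              trend_store: TrendStore | None) -> QCSession:
    if invalid:
        session.verdict = "invalid"
    elif session.kpi_results:
        verdict = evaluate_tolerances(session.kpi_results)
        session.verdict = verdict.overall
        if verdict.overall == "fail":
            for r in verdict.failing:
                session.recommendations.setdefault(r.name, DEPENDENCY_MAP.get(r.name, ()))
                session.notes.append(
                    f"KPI {r.name} out of tolerance on slice {r.slice_index}: "
                    f"value {r.value:.3f} outside "
                    f"[{r.tolerance_low:.3f}, {r.tolerance_high:.3f}]"
                )
            if session.level == 0:
                session.notes.append("Level 0 failed: a Level 1 diagnostic test is recommended.")
    else:
        session.verdict = "invalid"
        session.notes.append("no KPI results produced")
    if trend_store is not None:
        trend_store.append_session(session)
    return session


def run_level0(
    slices: Sequence[ImageSlice],
    config: RunConfig,
    baselines: BaselineStore,
    trend_store: TrendStore | None = None,
    scanner_id: str | None = None,
) -> QCSession:
    """Analyze a Level-0 session: positioning + per-slice image KPIs."""
    scanner = scanner_id or (slices[0].params.station if slices else "unknown")
    session = QCSession(
        scanner_id=scanner,
        timestamp=_session_timestamp(slices),
        level=0,
        n_slices=len(slices),
        kpi_results=[],
        verdict="invalid",
        protocol_report=check_protocol(slices, LEVEL0_PROTOCOL),
    )
    if not session.protocol_report.full_match:
        session.notes.append("protocol deviations: see protocol_report")

    invalid = False
    pos = [s for s in slices if s.params.part == "positioning"]
    if not pos:
        session.notes.append("missing positioning slice")
        invalid = True
    else:
        try:
            session.kpi_results.extend(_positioning_kpis(pos[0], config))
        except GeometryError as exc:
            session.notes.append(str(exc))
            invalid = True

    water = sorted((s for s in slices if s.params.part != "positioning"),
                   key=lambda s: s.slice_location)
    if not water:
        session.notes.append("no water slices")
        invalid = True
    for i, s in enumerate(water):
        baseline = baselines.get(scanner, s.params)
        try:
            session.kpi_results.extend(
                _water_slice_kpis(s, i, config, baseline, require_baseline=True)
            )
        except GeometryError as exc:
            session.notes.append(str(exc))
            invalid = True
    return _finalize(session, invalid, trend_store)


def _varies_only_in(params: AcquisitionParams, reference: AcquisitionParams,
                    free: tuple[str, ...]) -> bool:
    fixed = [f for f in _TECH_FIELDS if f not in free and f != "part"]
    return all(getattr(params, f) == getattr(reference, f) for f in fixed)


def run_level1(
    slices: Sequence[ImageSlice],
    config: RunConfig,
    baselines: BaselineStore,
    trend_store: TrendStore | None = None,
    scanner_id: str | None = None,
) -> QCSession:
    """Analyze a Level-1 session: per-group KPIs plus the diagnostic fits.

    Noise pass/fail is evaluated only for techniques with a stored base
    value; for the rest the measured sigma is recorded as informational and
    feeds the kVp and mAs fits.
    """
    scanner = scanner_id or (slices[0].params.station if slices else "unknown")
    session = QCSession(
        scanner_id=scanner,
        timestamp=_session_timestamp(slices),
        level=1,
        n_slices=len(slices),
        kpi_results=[],
        verdict="invalid",
        protocol_report=check_protocol(slices, LEVEL1_PROTOCOL),
    )
    if not session.protocol_report.full_match:
        session.notes.append("protocol deviations: see protocol_report")

    invalid = False
    pos = [s for s in slices if s.params.part == "positioning"]
    if not pos:
        session.notes.append("missing positioning slice")
        invalid = True
    else:
        try:
            session.kpi_results.extend(_positioning_kpis(pos[0], config))
        except GeometryError as exc:
            session.notes.append(str(exc))
            invalid = True

    water_groups = [
        (p, grp) for p, grp in group_by_acquisition(slices) if p.part != "positioning"
    ]
    kvp_points: list[tuple[float, float]] = []
    mas_points: list[tuple[float, float]] = []
    slice_index = 0
    daily_key = LEVEL0_PROTOCOL.rows[1].params().technique_key
    for params, group in water_groups:
        baseline = baselines.get(scanner, params)
        # pass/fail applies at the daily (Level-0) technique; the varied
        # techniques are diagnostic data for the fits and the group table
        evaluate = params.technique_key == daily_key
        sigmas = []
        for s in sorted(group, key=lambda s: s.slice_location):
            try:
                results = _water_slice_kpis(s, slice_index, config, baseline,
                                            require_baseline=False,
                                            evaluate=evaluate)
            except GeometryError as exc:
                session.notes.append(str(exc))
                invalid = True
                slice_index += 1
                continue
            session.kpi_results.extend(results)
            sigmas.append(next(r.value for r in results if r.name == "noise"))
            slice_index += 1
        if not sigmas:
            continue
        sigma = sum(sigmas) / len(sigmas)
        session.group_table.append({
            "technique": params.technique_label(),
            "kvp": params.kvp,
            "mas": params.mas,
            "n_slices": len(group),
            "sigma": sigma,
        })
        if _varies_only_in(params, LEVEL1_STANDARD, ("kvp",)):
            kvp_points.append((params.kvp, sigma))
        if _varies_only_in(params, LEVEL1_STANDARD, ("tube_current", "rotation_time")):
            mas_points.append((params.mas, sigma))

    for name, points, fitter in (
        ("kvp_power", kvp_points, fit_kvp_exponent),
        ("mas_inverse_sqrt", mas_points, fit_mas_response),
    ):
        try:
            session.brooks_fits[name] = fitter(points)
        except FitError as exc:
            LOG.warning("%s fit omitted: %s", name, exc)
            session.notes.append(f"{name} fit omitted: {exc}")

    return _finalize(session, invalid, trend_store)
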