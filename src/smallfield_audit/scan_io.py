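"""Domain types and plain-text I/O for multi-institution beam datasets.

A *beam dataset* is everything one institution measured on one linac:
water-tank scan curves (percent-depth-dose along the beam axis, and lateral
off-center-ratio profiles), detector output-factor tables, and the detector
inventory. Institutional scanning systems export proprietary formats, so
this package defines a transparent text dialect instead:

* ``*.bscan`` — one curve per file: ``key: value`` header lines, a blank
  line, then two whitespace-separated numeric columns (position mm, value).
* ``output_factors.csv`` — detector output factors, one row per
  (detector, energy, filter, field side).
* ``dataset.yaml`` — per-institution manifest listing the files above plus
  the detector inventory.
* ``fleet.yaml`` — top-level manifest listing institution directories.

All positions and field sizes are millimetres; lateral positions are signed
mm from the collimator rotation axis (negative = left), depth is mm below
the water surface. Field sizes are MLC *setting* values throughout, not
FWHM-defined radiological sizes. Dose values are dimensionless and carry an
arbitrary scale until normalization.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import yaml

from .errors import ParseError, ValidationError

AXES = ("depth", "crossline", "inline")
FILTER_MODES = ("FF", "FFF")
DETECTOR_CLASSES = ("shielded_diode", "unshielded_diode", "ion_chamber", "diamond")
MACHINE_TYPES = ("HD120", "Millennium120")

#: smallest MLC field side (mm) each collimator model can set
MIN_FIELD_MM = {"HD120": 5.0, "Millennium120": 10.0}

_FMT = "%.10g"  # half-ulp ~5e-10 relative: below the 1e-9 round-trip tolerance


def _fmt(x: float) -> str:
    return _FMT % float(x)


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------
@dataclass(frozen=True)
class ScanCurve:
    """One measured 1-D curve (PDD or lateral profile) with its metadata.

    ``axis='depth'`` marks a PDD (positions are depths >= 0, ``depth_mm``
    absent); ``axis in ('crossline', 'inline')`` marks a profile measured at
    ``depth_mm``. ``step_mm`` is the nominal acquisition step, retained for
    provenance even after resampling.
    """

    axis: str
    positions: np.ndarray
    values: np.ndarray
    energy_mv: float
    filter_mode: str
    field_x_mm: float
    field_y_mm: float
    ssd_mm: float
    detector_id: str
    institution_id: str
    step_mm: float
    depth_mm: float | None = None

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        val = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "values", val)
        if self.axis not in AXES:
            raise ValidationError(f"axis: unknown value {self.axis!r}")
        if self.filter_mode not in FILTER_MODES:
            raise ValidationError(f"filter_mode: unknown value {self.filter_mode!r}")
        if pos.ndim != 1 or val.shape != pos.shape:
            raise ValidationError("positions/values: must be 1-D and equal length")
        if pos.size < 4:
            raise ValidationError("positions: need at least 4 samples")
        if not np.all(np.isfinite(pos)):
            raise ValidationError("positions: non-finite value")
        if np.any(np.diff(pos) <= 0):
            raise ValidationError("positions: must be strictly increasing")
        if not np.all(np.isfinite(val)):
            raise ValidationError("values: non-finite value")
        if np.any(val < 0):
            raise ValidationError("values: negative dose value")
        if self.axis == "depth":
            if pos[0] < 0:
                raise ValidationError("positions: PDD depths must be >= 0")
            if self.depth_mm is not None:
                raise ValidationError("depth_mm: must be absent for axis=depth")
        elif self.depth_mm is None:
            raise ValidationError("depth_mm: required for profile curves")
        for name in ("energy_mv", "field_x_mm", "field_y_mm", "ssd_mm", "step_mm"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name}: must be positive")

    # small conveniences used throughout the metrics module
    @property
    def span(self) -> tuple[float, float]:
        return float(self.positions[0]), float(self.positions[-1])

    def interp(self, x) -> np.ndarray:
        """Piecewise-linear interpolation; no extrapolation is ever done."""
        return np.interp(x, self.positions, self.values)

    def replace(self, **kw) -> "ScanCurve":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class DetectorSpec:
    """Detector identity, class, and effective lateral sensitive extent."""

    detector_id: str
    detector_class: str
    sensitive_extent_mm: float

    def __post_init__(self):
        if self.detector_class not in DETECTOR_CLASSES:
            raise ValidationError(
                f"detector_class: unknown value {self.detector_class!r}"
            )
        if not self.sensitive_extent_mm > 0:
            raise ValidationError("sensitive_extent_mm: must be positive")


@dataclass(frozen=True)
class OutputFactorSeries:
    """Detector output factors OF_det vs square MLC field side for one beam.

    ``entries`` maps field side (mm) to the reading ratio. Normalization
    (:func:`~smallfield_audit.output_factors.normalize_series`) requires
    the 100 mm reference field and pins its value to exactly 1.
    """

    institution_id: str
    detector_id: str
    energy_mv: float
    filter_mode: str
    entries: Mapping[float, float]

    def __post_init__(self):
        if self.filter_mode not in FILTER_MODES:
            raise ValidationError(f"filter_mode: unknown value {self.filter_mode!r}")
        ent = {float(k): float(v) for k, v in self.entries.items()}
        if len(ent) != len(self.entries):
            raise ValidationError("entries: duplicate field sides")
        object.__setattr__(self, "entries", dict(sorted(ent.items())))
        for side, of in ent.items():
            if not side > 0:
                raise ValidationError("entries: field side must be positive")
            if not of > 0 or not math.isfinite(of):
                raise ValidationError("entries: OF_det must be finite and positive")

    @property
    def sides(self) -> tuple[float, ...]:
        return tuple(self.entries)

    def replace(self, **kw) -> "OutputFactorSeries":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class BeamDataset:
    """Everything one institution contributed: curves, OF tables, detectors."""

    institution_id: str
    machine_type: str
    curves: tuple[ScanCurve, ...] = ()
    output_factors: tuple[OutputFactorSeries, ...] = ()
    detectors: tuple[DetectorSpec, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "curves", tuple(self.curves))
        object.__setattr__(self, "output_factors", tuple(self.output_factors))
        object.__setattr__(self, "detectors", tuple(self.detectors))
        if self.machine_type not in MACHINE_TYPES:
            raise ValidationError(f"machine_type: unknown value {self.machine_type!r}")
        known = {d.detector_id for d in self.detectors}
        if len(known) != len(self.detectors):
            raise ValidationError("detectors: duplicate detector_id")
        min_fs = MIN_FIELD_MM[self.machine_type]
        for c in self.curves:
            if c.detector_id not in known:
                raise ValidationError(
                    f"curves: detector_id {c.detector_id!r} not in detector inventory"
                )
            if min(c.field_x_mm, c.field_y_mm) < min_fs:
                raise ValidationError(
                    f"curves: field size below {min_fs} mm minimum of "
                    f"{self.machine_type}"
                )
        for s in self.output_factors:
            if s.detector_id not in known:
                raise ValidationError(
                    f"output_factors: detector_id {s.detector_id!r} not in "
                    "detector inventory"
                )
            if min(s.entries) < min_fs:
                raise ValidationError(
                    f"output_factors: field side below {min_fs} mm minimum of "
                    f"{self.machine_type}"
                )

    def detector(self, detector_id: str) -> DetectorSpec:
        for d in self.detectors:
            if d.detector_id == detector_id:
                return d
        raise KeyError(detector_id)


# --------------------------------------------------------------------------
# .bscan curve files
# --------------------------------------------------------------------------
_BSCAN_KEYS = {
    "axis": str,
    "energy_mv": float,
    "filter_mode": str,
    "field_x_mm": float,
    "field_y_mm": float,
    "ssd_mm": float,
    "depth_mm": float,
    "detector_id": str,
    "institution_id": str,
    "step_mm": float,
}


def read_curve(path) -> ScanCurve:
    """Read one ``.bscan`` file into a validated :class:`ScanCurve`."""
    path = Path(path)
    header: dict = {}
    positions: list[float] = []
    values: list[float] = []
    in_body = False
    try:
        lines = path.read_text().splitlines()
    except OSError as exc:
        raise ParseError(f"cannot read file: {exc}", path=path) from exc
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            if not line and header:
                in_body = True
            continue
        if not in_body and ":" in line and not _looks_numeric(line):
            key, _, val = line.partition(":")
            key = key.strip()
            if key not in _BSCAN_KEYS:
                raise ParseError(f"unknown header key {key!r}", path=path, line=lineno)
            if key in header:
                raise ParseError(f"duplicate header key {key!r}", path=path, line=lineno)
            try:
                header[key] = _BSCAN_KEYS[key](val.strip())
            except ValueError as exc:
                raise ParseError(
                    f"bad value for {key!r}: {val.strip()!r}", path=path, line=lineno
                ) from exc
        else:
            in_body = True
            parts = line.split()
            if len(parts) != 2:
                raise ParseError(
                    f"expected two numeric columns, got {len(parts)}",
                    path=path,
                    line=lineno,
                )
            try:
                positions.append(float(parts[0]))
                values.append(float(parts[1]))
            except ValueError as exc:
                raise ParseError(f"non-numeric data {line!r}", path=path, line=lineno) from exc
    missing = set(_BSCAN_KEYS) - {"depth_mm"} - set(header)
    if missing:
        raise ParseError(f"missing header keys: {sorted(missing)}", path=path)
    return ScanCurve(positions=np.array(positions), values=np.array(values), **header)


def _looks_numeric(line: str) -> bool:
    try:
        float(line.split()[0])
        return True
    except ValueError:
        return False


def write_curve(curve: ScanCurve, path) -> Path:
    """Write one curve as ``.bscan`` (10 significant digits, lossless)."""
    path = Path(path)
    out = ["# smallfield-audit scan curve v1"]
    out.append(f"axis: {curve.axis}")
    out.append(f"energy_mv: {_fmt(curve.energy_mv)}")
    out.append(f"filter_mode: {curve.filter_mode}")
    out.append(f"field_x_mm: {_fmt(curve.field_x_mm)}")
    out.append(f"field_y_mm: {_fmt(curve.field_y_mm)}")
    out.append(f"ssd_mm: {_fmt(curve.ssd_mm)}")
    if curve.depth_mm is not None:
        out.append(f"depth_mm: {_fmt(curve.depth_mm)}")
    out.append(f"detector_id: {curve.detector_id}")
    out.append(f"institution_id: {curve.institution_id}")
    out.append(f"step_mm: {_fmt(curve.step_mm)}")
    out.append("")
    for x, v in zip(curve.positions, curve.values):
        out.append(f"{_fmt(x)}  {_fmt(v)}")
    path.write_text("\n".join(out) + "\n")
    return path


# --------------------------------------------------------------------------
# output-factor CSV
# --------------------------------------------------------------------------
_OF_COLUMNS = [
    "institution_id",
    "detector_id",
    "energy_mv",
    "filter_mode",
    "field_side_mm",
    "of_det",
]


def read_output_factors(path) -> tuple[OutputFactorSeries, ...]:
    """Read an output-factor CSV, grouping rows into per-beam series."""
    import pandas as pd

    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pandas raises several parse error types
        raise ParseError(f"cannot parse CSV: {exc}", path=path) from exc
    if list(df.columns) != _OF_COLUMNS:
        raise ParseError(
            f"expected columns {_OF_COLUMNS}, got {list(df.columns)}", path=path
        )
    series = []
    keys = ["institution_id", "detector_id", "energy_mv", "filter_mode"]
    for (inst, det, energy, filt), grp in df.groupby(keys, sort=True):
        sides = grp["field_side_mm"].astype(float)
        if sides.duplicated().any():
            raise ValidationError(
                f"entries: duplicate field side for {det!r} {energy} MV {filt}"
            )
        series.append(
            OutputFactorSeries(
                institution_id=str(inst),
                detector_id=str(det),
                energy_mv=float(energy),
                filter_mode=str(filt),
                entries=dict(zip(sides, grp["of_det"].astype(float))),
            )
        )
    return tuple(series)


def write_output_factors(series: Iterable[OutputFactorSeries], path) -> Path:
    path = Path(path)
    rows = [",".join(_OF_COLUMNS)]
    for s in series:
        for side, of in s.entries.items():
            rows.append(
                f"{s.institution_id},{s.detector_id},{_fmt(s.energy_mv)},"
                f"{s.filter_mode},{_fmt(side)},{_fmt(of)}"
            )
    path.write_text("\n".join(rows) + "\n")
    return path


# --------------------------------------------------------------------------
# dataset / fleet manifests
# --------------------------------------------------------------------------
_DATASET_KEYS = {"format", "institution_id", "machine_type", "detectors", "curves",
                 "output_factors"}
_DATASET_FORMAT = "smallfield-audit-dataset-v1"
_FLEET_FORMAT = "smallfield-audit-fleet-v1"


def read_dataset(path) -> BeamDataset:
    """Read one institution directory (``dataset.yaml`` manifest) into a
    validated :class:`BeamDataset`."""
    path = Path(path)
    manifest = path / "dataset.yaml"
    if not manifest.exists():
        raise ParseError("dataset.yaml not found", path=path)
    try:
        doc = yaml.safe_load(manifest.read_text())
    except yaml.YAMLError as exc:
        raise ParseError(f"bad YAML: {exc}", path=manifest) from exc
    if not isinstance(doc, dict):
        raise ParseError("manifest must be a mapping", path=manifest)
    unknown = set(doc) - _DATASET_KEYS
    if unknown:
        raise ParseError(f"unknown manifest keys: {sorted(unknown)}", path=manifest)
    if doc.get("format") != _DATASET_FORMAT:
        raise ParseError(
            f"format: expected {_DATASET_FORMAT!r}, got {doc.get('format')!r}",
            path=manifest,
        )
    detectors = []
    for entry in doc.get("detectors", []) or []:
        unknown = set(entry) - {"detector_id", "detector_class", "sensitive_extent_mm"}
        if unknown:
            raise ParseError(f"unknown detector keys: {sorted(unknown)}", path=manifest)
        detectors.append(
            DetectorSpec(
                detector_id=str(entry["detector_id"]),
                detector_class=str(entry["detector_class"]),
                sensitive_extent_mm=float(entry["sensitive_extent_mm"]),
            )
        )
    curves = [read_curve(path / rel) for rel in doc.get("curves", []) or []]
    series: list[OutputFactorSeries] = []
    for rel in doc.get("output_factors", []) or []:
        series.extend(read_output_factors(path / rel))
    return BeamDataset(
        institution_id=str(doc["institution_id"]),
        machine_type=str(doc["machine_type"]),
        curves=tuple(curves),
        output_factors=tuple(series),
        detectors=tuple(detectors),
    )


def write_dataset(ds: BeamDataset, path, force: bool = False) -> Path:
    """Write one institution directory readable by :func:`read_dataset`.

    Refuses to overwrite an existing manifest unless ``force`` is set.
    """
    path = Path(path)
    manifest = path / "dataset.yaml"
    if manifest.exists() and not force:
        raise IOError(f"refusing to overwrite {manifest} without force=True")
    (path / "curves").mkdir(parents=True, exist_ok=True)
    curve_files = []
    for i, c in enumerate(ds.curves):
        tag = f"{c.axis}_{_fmt(c.energy_mv)}MV_{c.filter_mode}_{_fmt(c.field_x_mm)}mm"
        rel = f"curves/{i:03d}_{tag}.bscan"
        write_curve(c, path / rel)
        curve_files.append(rel)
    of_files = []
    if ds.output_factors:
        write_output_factors(ds.output_factors, path / "output_factors.csv")
        of_files.append("output_factors.csv")
    doc = {
        "format": _DATASET_FORMAT,
        "institution_id": ds.institution_id,
        "machine_type": ds.machine_type,
        "detectors": [
            {
                "detector_id": d.detector_id,
                "detector_class": d.detector_class,
                "sensitive_extent_mm": float(d.sensitive_extent_mm),
            }
            for d in ds.detectors
        ],
        "curves": curve_files,
        "output_factors": of_files,
    }
    manifest.write_text(yaml.safe_dump(doc, sort_keys=False))
    return path


def read_fleet(path) -> list[BeamDataset]:
    """Read a multi-institution collection via its ``fleet.yaml`` manifest."""
    path = Path(path)
    manifest = path / "fleet.yaml"
    if not manifest.exists():
        raise ParseError("fleet.yaml not found", path=path)
    try:
        doc = yaml.safe_load(manifest.read_text())
    except yaml.YAMLError as exc:
        raise ParseError(f"bad YAML: {exc}", path=manifest) from exc
    unknown = set(doc) - {"format", "institutions"}
    if unknown:
        raise ParseError(f"unknown manifest keys: {sorted(unknown)}", path=manifest)
    if doc.get("format") != _FLEET_FORMAT:
        raise ParseError(
            f"format: expected {_FLEET_FORMAT!r}, got {doc.get('format')!r}",
            path=manifest,
        )
    return [read_dataset(path / sub) for sub in doc.get("institutions", [])]


def write_fleet(datasets: Iterable[BeamDataset], path, force: bool = False) -> Path:
    path = Path(path)
    manifest = path / "fleet.yaml"
    if manifest.exists() and not force:
        raise IOError(f"refusing to overwrite {manifest} without force=True")
    path.mkdir(parents=True, exist_ok=True)
    subs = []
    for ds in datasets:
        write_dataset(ds, path / ds.institution_id, force=force)
        subs.append(ds.institution_id)
    manifest.write_text(
        yaml.safe_dump({"format": _FLEET_FORMAT, "institutions": subs}, sort_keys=False)
    )
    return path
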