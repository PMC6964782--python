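"""Field output factors from detector output factors.

The small-field formalism multiplies the detector reading ratio OF_det by
a detector- and field-size-specific output correction factor k to obtain
the field output factor Omega:

    Omega(FS) = OF_det(FS) * k~(FS),    k~(FS) = k(FS) / mean(k(20), k(40))

The division by the mean of the 20 and 40 mm entries renormalizes k to the
intermediate field sizes at which small-field detectors are daisy-chained
to a reference chamber, so corrections act only on the genuinely small
fields (5 and 10 mm by default). Correction tables are user-supplied; the
interpolation/extrapolation policy is:

* exact value at tabulated field sides;
* linear interpolation in field side between tabulated neighbours;
* linear extrapolation through the two smallest tabulated sides below the
  table range (how 5 mm values are obtained for detectors tabulated only
  from 8 mm up);
* constant continuation above the table range (corrections vanish for
  large fields).

A :class:`~smallfield_audit.errors.CorrectionMagnitudeWarning` is emitted
whenever |k - 1| > 5%, the limit codes of practice endorse; the value is
still returned, since extrapolated 5 mm corrections for some detectors
legitimately exceed it.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    CorrectionMagnitudeWarning,
    InsufficientEnsembleError,
    MissingIntermediateError,
    MissingReferenceError,
    ParseError,
    UnknownDetectorError,
    ValidationError,
)
from .scan_io import OutputFactorSeries
from .stats import MedianCI, median_ci

K_WARN_THRESHOLD = 0.05
RENORM_SIDES_MM = (20.0, 40.0)
DEFAULT_CORRECT_SIDES = (5.0, 10.0)

_CT_COLUMNS = ["detector_id", "energy_mv", "filter_mode", "field_side_mm", "k"]


@dataclass(frozen=True)
class CorrectionTable:
    """Output correction factors k indexed by detector and beam quality."""

    rows: pd.DataFrame
    provenance: str = ""

    def __post_init__(self):
        df = self.rows.copy()
        if list(df.columns) != _CT_COLUMNS:
            raise ValidationError(f"rows: expected columns {_CT_COLUMNS}")
        df["energy_mv"] = df["energy_mv"].astype(float)
        df["field_side_mm"] = df["field_side_mm"].astype(float)
        df["k"] = df["k"].astype(float)
        if not (df["k"] > 0).all():
            raise ValidationError("k: must be positive")
        key = ["detector_id", "energy_mv", "filter_mode"]
        if df.duplicated(subset=key + ["field_side_mm"]).any():
            raise ValidationError("rows: duplicate (detector, quality, field side)")
        if (df.groupby(key)["field_side_mm"].count() < 2).any():
            raise ValidationError(
                "rows: need >= 2 field sides per (detector, quality)"
            )
        df = df.sort_values(key + ["field_side_mm"]).reset_index(drop=True)
        object.__setattr__(self, "rows", df)

    @classmethod
    def from_csv(cls, path, provenance: str | None = None) -> "CorrectionTable":
        path = Path(path)
        text = path.read_text()
        note_lines = [
            ln[1:].strip() for ln in text.splitlines() if ln.startswith("#")
        ]
        body = "\n".join(ln for ln in text.splitlines() if not ln.startswith("#"))
        try:
            df = pd.read_csv(io.StringIO(body))
        except Exception as exc:
            raise ParseError(f"cannot parse CSV: {exc}", path=path) from exc
        if list(df.columns) != _CT_COLUMNS:
            raise ParseError(
                f"expected columns {_CT_COLUMNS}, got {list(df.columns)}", path=path
            )
        return cls(df, provenance or "; ".join(note_lines))

    def to_csv(self, path) -> Path:
        path = Path(path)
        lines = [f"# {ln}" for ln in self.provenance.splitlines() if ln]
        lines.append(",".join(_CT_COLUMNS))
        for _, r in self.rows.iterrows():
            lines.append(
                f"{r.detector_id},{r.energy_mv:.9g},{r.filter_mode},"
                f"{r.field_side_mm:.9g},{r.k:.9g}"
            )
        path.write_text("\n".join(lines) + "\n")
        return path

    def _key_rows(self, detector_id, energy_mv, filter_mode) -> pd.DataFrame:
        df = self.rows
        sel = df[
            (df["detector_id"] == detector_id)
            & (df["energy_mv"] == float(energy_mv))
            & (df["filter_mode"] == filter_mode)
        ]
        if sel.empty:
            raise UnknownDetectorError(
                f"no correction entries for {detector_id!r} at "
                f"{energy_mv} MV {filter_mode}"
            )
        return sel


def k_lookup(
    table: CorrectionTable,
    detector_id: str,
    energy_mv: float,
    filter_mode: str,
    field_side_mm: float,
) -> float:
    """Correction factor k at one field side, with the documented
    interpolation/extrapolation policy. Warns when |k - 1| > 5%."""
    sel = table._key_rows(detector_id, energy_mv, filter_mode)
    sides = sel["field_side_mm"].to_numpy()
    ks = sel["k"].to_numpy()
    s = float(field_side_mm)
    exact = np.flatnonzero(np.abs(sides - s) < 1e-9)
    if exact.size:
        k = float(ks[exact[0]])
    elif s < sides[0]:
        slope = (ks[1] - ks[0]) / (sides[1] - sides[0])
        k = float(ks[0] + slope * (s - sides[0]))
    elif s > sides[-1]:
        k = float(ks[-1])
    else:
        k = float(np.interp(s, sides, ks))
    if abs(k - 1.0) > K_WARN_THRESHOLD:
        warnings.warn(
            f"|k-1| = {abs(k - 1):.3f} > {K_WARN_THRESHOLD:.0%} for "
            f"{detector_id!r} at {s:g} mm ({energy_mv:g} MV {filter_mode})",
            CorrectionMagnitudeWarning,
            stacklevel=2,
        )
    return k


def renormalize_k(
    table: CorrectionTable,
    detector_id: str,
    energy_mv: float,
    filter_mode: str,
    field_side_mm: float,
) -> float:
    """k~ = k(FS) / mean(k(20), k(40)), the intermediate-field
    renormalization that matches how small-field detector readings are
    daisy-chained to a reference chamber."""
    sel = table._key_rows(detector_id, energy_mv, filter_mode)
    sides = set(sel["field_side_mm"])
    missing = [s for s in RENORM_SIDES_MM if s not in sides]
    if missing:
        raise MissingIntermediateError(
            f"correction table lacks {missing} mm entries for {detector_id!r} "
            f"at {energy_mv} MV {filter_mode}"
        )
    denom = np.mean(
        [k_lookup(table, detector_id, energy_mv, filter_mode, s) for s in RENORM_SIDES_MM]
    )
    return k_lookup(table, detector_id, energy_mv, filter_mode, field_side_mm) / denom


def normalize_series(series: OutputFactorSeries) -> OutputFactorSeries:
    """Normalize OF_det to the 100 x 100 mm^2 reference field."""
    if 100.0 not in series.entries:
        raise MissingReferenceError("series lacks the 100 mm reference entry")
    ref = series.entries[100.0]
    return series.replace(
        entries={s: of / ref for s, of in series.entries.items()}
    )


def apply_corrections(
    series: OutputFactorSeries,
    table: CorrectionTable,
    correct_sides: Iterable[float] = DEFAULT_CORRECT_SIDES,
) -> dict[float, float]:
    """Corrected field output factors: Omega = OF_det * k~ at the small
    field sides, Omega = OF_det elsewhere."""
    correct = {float(s) for s in correct_sides}
    omega = {}
    for side, of in series.entries.items():
        if side in correct:
            ktilde = renormalize_k(
                table, series.detector_id, series.energy_mv, series.filter_mode, side
            )
            omega[side] = of * ktilde
        else:
            omega[side] = of
    return omega


def relative_differences(
    ensemble: Sequence[Mapping[float, float]],
    reference: Sequence[Mapping[float, float]] | None = None,
) -> pd.DataFrame:
    """Per-entry relative difference (%) from the per-field-size median of
    ``reference`` (the *corrected* ensemble by convention; defaults to
    ``ensemble`` itself). Rows = ensemble index, columns = field side."""
    if reference is None:
        reference = ensemble
    sides = sorted({s for m in ensemble for s in m})
    out = {}
    for side in sides:
        ref_vals = [m[side] for m in reference if side in m]
        if len(ref_vals) < 3:
            raise InsufficientEnsembleError(
                f"only {len(ref_vals)} institutions at {side:g} mm (need >= 3)"
            )
        med = float(np.median(ref_vals))
        out[side] = {
            i: 100.0 * (m[side] - med) / med
            for i, m in enumerate(ensemble)
            if side in m
        }
    return pd.DataFrame(out)


def summarize_ensemble(
    ensemble: Sequence[Mapping[float, float]], level: float = 0.95
) -> pd.DataFrame:
    """Median and distribution-free 95% CI of Omega per field side."""
    sides = sorted({s for m in ensemble for s in m})
    records = []
    for side in sides:
        vals = [m[side] for m in ensemble if side in m]
        ci: MedianCI = median_ci(vals, level=level)
        records.append(
            {
                "field_side_mm": side,
                "n": len(vals),
                "median": ci.median,
                "ci_low": ci.low,
                "ci_high": ci.high,
                "achieved_coverage": ci.achieved_coverage,
            }
        )
    return pd.DataFrame.from_records(records)


@dataclass(frozen=True)
class FieldOutputFactorResult:
    """Corrected output factors and variability statistics for one beam."""

    energy_mv: float
    filter_mode: str
    institution_ids: tuple[str, ...]
    omega: tuple[dict, ...]  # per institution: side -> Omega
    of_det: tuple[dict, ...]  # per institution: side -> normalized OF_det
    rel_diff_uncorrected: pd.DataFrame = field(repr=False)
    rel_diff_corrected: pd.DataFrame = field(repr=False)
    summary: pd.DataFrame = field(repr=False)


def audit_output_factors(
    series_list: Sequence[OutputFactorSeries],
    table: CorrectionTable,
    correct_sides: Iterable[float] = DEFAULT_CORRECT_SIDES,
    level: float = 0.95,
) -> FieldOutputFactorResult:
    """Full output-factor analysis for one (energy, filter) ensemble.

    Normalizes every series to the 100 mm field, applies corrections at
    ``correct_sides``, and computes the relative differences of both the
    uncorrected and corrected values from the *corrected* median, plus the
    median + CI summary table.
    """
    if not series_list:
        raise InsufficientEnsembleError("empty ensemble")
    e, f = series_list[0].energy_mv, series_list[0].filter_mode
    for s in series_list:
        if (s.energy_mv, s.filter_mode) != (e, f):
            raise InsufficientEnsembleError("mixed beam qualities in ensemble")
    normed = [normalize_series(s) for s in series_list]
    of_det = [dict(s.entries) for s in normed]
    omega = [apply_corrections(s, table, correct_sides) for s in normed]
    return FieldOutputFactorResult(
        energy_mv=e,
        filter_mode=f,
        institution_ids=tuple(s.institution_id for s in series_list),
        omega=tuple(omega),
        of_det=tuple(of_det),
        rel_diff_uncorrected=relative_differences(of_det, reference=omega),
        rel_diff_corrected=relative_differences(omega, reference=omega),
        summary=summarize_ensemble(omega, level=level),
    )
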