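"""Curve processing for the dosimetry audit.

Implements the per-curve and ensemble operations the audit applies to
water-tank scans: resampling with linear interpolation (never smoothing),
PDD normalization at the depth of maximum dose, profile normalization at
the central axis, beam-center offset, FWHM, 20-80% penumbra widths,
per-point median/deviation curves across institutions, and
distance-to-agreement restricted to the penumbra region.

Conventions
-----------
* All crossings (50%, 20%, 80% levels) are located by inverse linear
  interpolation between the two bracketing samples — the same piecewise
  linear model used for resampling, so metrics are exact on piecewise
  linear data.
* The crossing search walks outward from the field center (sample of
  maximum value, ties broken toward the central axis). If noise creates
  several crossings of one level on one side, the outermost is used when
  all of them fall within a 3-sample window; otherwise
  :class:`~smallfield_audit.errors.MultipleCrossingError` is raised rather
  than silently picking one.
* No smoothing or fitting is ever applied; the depth of maximum dose is
  the argmax on a 0.5 mm resampled grid, with ties between non-adjacent
  samples reported as :class:`~smallfield_audit.errors.AmbiguousPeakError`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np

from .errors import (
    AmbiguousPeakError,
    CrossingNotFoundError,
    DegenerateCurveError,
    IncompatibleCurveError,
    MultipleCrossingError,
    NoPenumbraSamplesError,
    OutOfRangeError,
)
from .scan_io import ScanCurve

RESAMPLE_STEP_MM = 0.5  # audit-wide analysis grid


# --------------------------------------------------------------------------
# result containers
# --------------------------------------------------------------------------
@dataclass(frozen=True)
class ProfileMetrics:
    """Beam-center offset, FWHM and 20-80% penumbra widths of one profile."""

    offset_mm: float
    fwhm_mm: float
    penumbra_left_mm: float
    penumbra_right_mm: float

    @property
    def penumbra_mean_mm(self) -> float:
        return (self.penumbra_left_mm + self.penumbra_right_mm) / 2.0


@dataclass(frozen=True)
class CurveEnsembleSummary:
    """Per-point median curve and per-institution deviations from it.

    ``per_institution_diff`` values are in percentage points of the
    normalized dose scale (PDD curves are already on a 0-100% scale;
    unit-scale profiles are multiplied by 100).
    """

    grid: np.ndarray
    median_curve: np.ndarray
    per_institution_diff: Mapping[str, np.ndarray]
    max_abs_diff: Mapping[str, float]


class NormalizedPDD(NamedTuple):
    curve: ScanCurve
    d_max_mm: float


# --------------------------------------------------------------------------
# resampling and normalization
# --------------------------------------------------------------------------
def resample(curve: ScanCurve, step_mm: float = RESAMPLE_STEP_MM) -> ScanCurve:
    """Resample onto a uniform grid by piecewise-linear interpolation.

    The output grid starts at the first measured position and never extends
    beyond the measured range; no smoothing of any kind is applied.
    """
    if not step_mm > 0:
        raise ValueError("step_mm must be positive")
    lo, hi = curve.span
    if hi - lo < 2 * step_mm:
        raise DegenerateCurveError(
            f"span {hi - lo:.3g} mm < 2 x step {step_mm:.3g} mm"
        )
    n = int(np.floor((hi - lo) / step_mm + 1e-9))
    grid = lo + step_mm * np.arange(n + 1)
    return curve.replace(positions=grid, values=curve.interp(grid), step_mm=step_mm)


def normalize_pdd(curve: ScanCurve) -> NormalizedPDD:
    """Normalize a PDD to 100% at the depth of maximum dose (d_max).

    d_max is the argmax of the curve resampled to 0.5 mm; ties between
    non-adjacent grid samples (within 1e-9 relative) raise
    :class:`AmbiguousPeakError`, adjacent flat-top ties take the shallower
    depth.
    """
    if curve.axis != "depth":
        raise IncompatibleCurveError("normalize_pdd requires axis='depth'")
    fine = resample(curve, RESAMPLE_STEP_MM)
    v = fine.values
    vmax = float(v.max())
    ties = np.flatnonzero(v >= vmax - 1e-9 * abs(vmax))
    if np.any(np.diff(ties) > 1):
        raise AmbiguousPeakError(
            f"non-adjacent samples tie for the maximum at depths "
            f"{fine.positions[ties][:4]} mm"
        )
    d_max = float(fine.positions[ties[0]])
    scaled = curve.replace(values=curve.values * (100.0 / vmax))
    return NormalizedPDD(scaled, d_max)


def normalize_profile(curve: ScanCurve) -> ScanCurve:
    """Normalize a lateral profile to 1.0 at the central axis (x = 0)."""
    if curve.axis == "depth":
        raise IncompatibleCurveError("normalize_profile requires a profile curve")
    lo, hi = curve.span
    if not (lo <= 0.0 <= hi):
        raise OutOfRangeError("central axis (0 mm) outside the measured span")
    cax = float(curve.interp(0.0))
    if cax <= 0:
        raise OutOfRangeError("central-axis value is zero; cannot normalize")
    return curve.replace(values=curve.values / cax)


# --------------------------------------------------------------------------
# crossing search
# --------------------------------------------------------------------------
def _center_index(curve: ScanCurve) -> int:
    v = curve.values
    ties = np.flatnonzero(v >= v.max() * (1 - 1e-12))
    return int(ties[np.argmin(np.abs(curve.positions[ties]))])


def _crossing(curve: ScanCurve, level: float, side: str) -> float:
    """Position where the curve falls through ``level`` on one side.

    Walks outward from the field center collecting bracketing intervals
    where the value passes from >= level to < level (or back). Applies the
    outermost-within-3-samples rule for noise, else raises.
    """
    x, v = curve.positions, curve.values
    c = _center_index(curve)
    if side == "right":
        idx = range(c, len(x) - 1)
    else:
        idx = range(c, 0, -1)
    brackets: list[int] = []
    for i in idx:
        j = i + 1 if side == "right" else i - 1
        lo, hi = sorted((v[i], v[j]))
        if lo <= level <= hi and lo != hi:
            brackets.append(i)
        elif v[i] == level and v[j] == level:
            continue
    if not brackets:
        raise CrossingNotFoundError(
            f"level {level:.4g} not crossed on the {side} side"
        )
    if len(brackets) > 1:
        if abs(brackets[-1] - brackets[0]) > 3:
            raise MultipleCrossingError(
                f"{len(brackets)} well-separated crossings of level "
                f"{level:.4g} on the {side} side"
            )
        i = brackets[-1]  # outermost within the noise window
    else:
        i = brackets[0]
    j = i + 1 if side == "right" else i - 1
    # inverse linear interpolation inside the bracketing interval
    if v[j] == v[i]:
        return float(x[i])
    return float(x[i] + (level - v[i]) * (x[j] - x[i]) / (v[j] - v[i]))


def _cax_value(curve: ScanCurve) -> float:
    lo, hi = curve.span
    if not (lo <= 0.0 <= hi):
        raise OutOfRangeError("central axis (0 mm) outside the measured span")
    return float(curve.interp(0.0))


# --------------------------------------------------------------------------
# profile metrics
# --------------------------------------------------------------------------
def beam_center_offset(curve: ScanCurve) -> float:
    """Signed distance (mm) of the FWHM center from the central axis."""
    half = 0.5 * _cax_value(curve)
    left = _crossing(curve, half, "left")
    right = _crossing(curve, half, "right")
    return (left + right) / 2.0


def recenter(curve: ScanCurve) -> ScanCurve:
    """Shift positions so that the FWHM center sits on the central axis.

    A pure translation: FWHM and penumbra widths are unchanged.
    """
    return curve.replace(positions=curve.positions - beam_center_offset(curve))


def fwhm(curve: ScanCurve) -> float:
    """Full width at half maximum, half defined as 50% of the CAX value.

    The same central-axis normalization convention is used for flattened
    and FFF beams: at the 10 mm fields audited here the two profile shapes
    are nearly identical, so no FFF-specific renormalization is applied.
    """
    half = 0.5 * _cax_value(curve)
    return _crossing(curve, half, "right") - _crossing(curve, half, "left")


def penumbra(curve: ScanCurve) -> tuple[float, float, float]:
    """20-80% penumbra width per side and their mean, in mm."""
    cax = _cax_value(curve)
    widths = []
    for side in ("left", "right"):
        x20 = _crossing(curve, 0.2 * cax, side)
        x80 = _crossing(curve, 0.8 * cax, side)
        widths.append(abs(x20 - x80))
    return widths[0], widths[1], (widths[0] + widths[1]) / 2.0


def profile_metrics(curve: ScanCurve) -> ProfileMetrics:
    """Offset, FWHM and penumbra of one CAX-normalized profile."""
    left, right, _ = penumbra(curve)
    return ProfileMetrics(
        offset_mm=beam_center_offset(curve),
        fwhm_mm=fwhm(curve),
        penumbra_left_mm=left,
        penumbra_right_mm=right,
    )


# --------------------------------------------------------------------------
# ensembles
# --------------------------------------------------------------------------
def _common_grid(curves: Sequence[ScanCurve], step_mm: float) -> np.ndarray:
    lo = max(c.span[0] for c in curves)
    hi = min(c.span[1] for c in curves)
    start = np.ceil(lo / step_mm - 1e-9) * step_mm  # anchored at 0
    stop = np.floor(hi / step_mm + 1e-9) * step_mm
    if stop - start < 2 * step_mm:
        raise IncompatibleCurveError("curve spans barely overlap")
    n = int(round((stop - start) / step_mm))
    return start + step_mm * np.arange(n + 1)


def median_curve(
    curves: Sequence[ScanCurve], step_mm: float = RESAMPLE_STEP_MM
) -> CurveEnsembleSummary:
    """Per-point median across institutions and deviations from it.

    All curves are resampled onto the 0.5 mm grid spanning the intersection
    of the measured ranges (anchored at 0 so the central axis / surface is
    a grid point). Deviations are reported in percentage points: PDD curves
    are already on the 0-100% scale, unit-scale profiles are scaled by 100.
    """
    if len(curves) < 3:
        raise IncompatibleCurveError("need at least 3 curves for an ensemble")
    ref = curves[0]
    for c in curves[1:]:
        if (
            c.axis != ref.axis
            or c.energy_mv != ref.energy_mv
            or c.filter_mode != ref.filter_mode
            or c.field_x_mm != ref.field_x_mm
            or c.field_y_mm != ref.field_y_mm
        ):
            raise IncompatibleCurveError(
                "curves differ in axis/energy/filter/field size"
            )
    grid = _common_grid(curves, step_mm)
    mat = np.vstack([c.interp(grid) for c in curves])
    med = np.median(mat, axis=0)
    to_pct = 1.0 if ref.axis == "depth" else 100.0
    diffs = {
        c.institution_id: (row - med) * to_pct for c, row in zip(curves, mat)
    }
    max_abs = {k: float(np.max(np.abs(d))) for k, d in diffs.items()}
    return CurveEnsembleSummary(
        grid=grid,
        median_curve=med,
        per_institution_diff=diffs,
        max_abs_diff=max_abs,
    )


# --------------------------------------------------------------------------
# distance to agreement
# --------------------------------------------------------------------------
def dta_penumbra(
    eval_curve: ScanCurve,
    ref_curve: ScanCurve,
    granularity_mm: float = 1e-3,
) -> float:
    """Maximum distance-to-agreement over the 20-80% penumbra region.

    For every sample of ``eval_curve`` whose value lies within 20-80% of the
    reference central-axis value, find the minimum |dx| to a position where
    the (piecewise-linearly interpolated) reference attains the same value
    on the same side of the field, searching at ``granularity_mm``
    resolution. Returns the maximum of those minimum distances.
    """
    cax_ref = _cax_value(ref_curve)
    center = beam_center_offset(ref_curve)
    lo, hi = ref_curve.span
    dense_x = np.arange(lo, hi + granularity_mm / 2, granularity_mm)
    dense_v = ref_curve.interp(dense_x)

    mask = (eval_curve.values >= 0.2 * cax_ref) & (eval_curve.values <= 0.8 * cax_ref)
    if not np.any(mask):
        raise NoPenumbraSamplesError("no evaluated sample in the 20-80% region")

    worst = 0.0
    for xe, ve in zip(eval_curve.positions[mask], eval_curve.values[mask]):
        side = dense_x <= center if xe <= center else dense_x >= center
        xs, vs = dense_x[side], dense_v[side]
        d = vs - ve
        sign_change = np.flatnonzero(d[:-1] * d[1:] <= 0)
        if sign_change.size == 0:
            continue  # reference never reaches this value on this side
        cand = []
        for i in sign_change:
            if d[i + 1] == d[i]:
                cand.append(xs[i])
            else:
                cand.append(xs[i] - d[i] * (xs[i + 1] - xs[i]) / (d[i + 1] - d[i]))
        worst = max(worst, float(np.min(np.abs(np.asarray(cand) - xe))))
    return worst
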