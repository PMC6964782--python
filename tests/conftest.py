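"""Shared fixtures and independent brute-force oracles.

The oracle functions here deliberately avoid the library's outward-scan
crossing search: they evaluate the piecewise-linear interpolant of a curve
on a 1e-4 mm dense grid and locate levels/matches by exhaustive scan, so
they can cross-check the implementation without sharing its code path.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.special import erf

from smallfield_audit import default_correction_table, default_fleet_config
from smallfield_audit.scan_io import ScanCurve
from smallfield_audit.synthetic_data import generate_fleet

FLEET_SEED = 3

ORACLE_STEP_MM = 1e-4


# ---------------------------------------------------------------- fixtures
@pytest.fixture(scope="session")
def fleet_cfg():
    return default_fleet_config(FLEET_SEED)


@pytest.fixture(scope="session")
def fleet(fleet_cfg):
    return generate_fleet(fleet_cfg)


@pytest.fixture(scope="session")
def ktable():
    return default_correction_table()


# ----------------------------------------------------------- curve builders
def double_erf_values(x, a=5.0, sigma_l=1.5, sigma_r=None, shift=0.0):
    """Field edge model: product of two error-function shoulders, allowing
    unequal left/right penumbra widths."""
    sigma_r = sigma_l if sigma_r is None else sigma_r
    x = np.asarray(x, dtype=float) - shift
    left = 0.5 * (1.0 + erf((x + a) / (sigma_l * np.sqrt(2))))
    right = 0.5 * (1.0 + erf((a - x) / (sigma_r * np.sqrt(2))))
    return left + right - 1.0


def make_profile(
    positions, values, step_mm=0.5, axis="crossline", institution="instA",
    detector="EDGE", energy=6.0, filt="FF",
):
    return ScanCurve(
        axis=axis,
        positions=np.asarray(positions, dtype=float),
        values=np.asarray(values, dtype=float),
        energy_mv=energy,
        filter_mode=filt,
        field_x_mm=10.0,
        field_y_mm=10.0,
        ssd_mm=900.0,
        depth_mm=100.0,
        detector_id=detector,
        institution_id=institution,
        step_mm=step_mm,
    )


def make_pdd(positions, values, step_mm=0.5, institution="instA", detector="EDGE"):
    return ScanCurve(
        axis="depth",
        positions=np.asarray(positions, dtype=float),
        values=np.asarray(values, dtype=float),
        energy_mv=6.0,
        filter_mode="FF",
        field_x_mm=10.0,
        field_y_mm=10.0,
        ssd_mm=1000.0,
        detector_id=detector,
        institution_id=institution,
        step_mm=step_mm,
    )


def erf_profile_curve(a=5.0, sigma_l=1.5, sigma_r=None, shift=0.0, step=0.5,
                      span=None, **kw):
    span = span if span is not None else a + 10.0
    n = int(np.ceil(span / step))
    x = step * np.arange(-n, n + 1)
    return make_profile(x, double_erf_values(x, a, sigma_l, sigma_r, shift),
                        step_mm=step, **kw)


# ------------------------------------------------------------------ oracles
def _dense(curve):
    lo, hi = curve.positions[0], curve.positions[-1]
    x = np.arange(lo, hi + ORACLE_STEP_MM / 2, ORACLE_STEP_MM)
    return x, np.interp(x, curve.positions, curve.values)


def _level_crossings(x, v, level):
    d = v - level
    idx = np.flatnonzero(d[:-1] * d[1:] <= 0)
    out = []
    for i in idx:
        if d[i + 1] == d[i]:
            out.append(x[i])
        else:
            out.append(x[i] - d[i] * (x[i + 1] - x[i]) / (d[i + 1] - d[i]))
    return np.asarray(out)


def oracle_profile_metrics(curve):
    """Offset, FWHM and per-side 20-80% penumbra by exhaustive dense-grid
    scan of the curve's piecewise-linear interpolant."""
    x, v = _dense(curve)
    cax = np.interp(0.0, x, v)
    center = x[np.argmax(v)]

    def one_side(level, side):
        c = _level_crossings(x, v, level)
        c = c[c <= center] if side == "left" else c[c >= center]
        assert c.size, f"oracle: no {side} crossing at level {level}"
        # outermost crossing, matching the documented noise rule
        return c.min() if side == "left" else c.max()

    xl, xr = one_side(0.5 * cax, "left"), one_side(0.5 * cax, "right")
    pen_l = abs(one_side(0.2 * cax, "left") - one_side(0.8 * cax, "left"))
    pen_r = abs(one_side(0.2 * cax, "right") - one_side(0.8 * cax, "right"))
    return {
        "offset": (xl + xr) / 2.0,
        "fwhm": xr - xl,
        "penumbra_left": pen_l,
        "penumbra_right": pen_r,
    }


def oracle_dta_penumbra(eval_curve, ref_curve):
    """Exhaustive distance-to-agreement over the 20-80% region."""
    xr, vr = _dense(ref_curve)
    cax = np.interp(0.0, xr, vr)
    m = oracle_profile_metrics(ref_curve)
    center = m["offset"]
    worst = 0.0
    sel = (eval_curve.values >= 0.2 * cax) & (eval_curve.values <= 0.8 * cax)
    for xe, ve in zip(eval_curve.positions[sel], eval_curve.values[sel]):
        side = xr <= center if xe <= center else xr >= center
        cand = _level_crossings(xr[side], vr[side], ve)
        if cand.size:
            worst = max(worst, float(np.min(np.abs(cand - xe))))
    return worst


def oracle_wilcoxon_exact(diffs):
    """Two-sided exact signed-rank p-value by itertools enumeration."""
    import itertools

    from scipy.stats import rankdata

    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = rankdata(np.abs(d))
    w_obs = float(ranks[d > 0].sum())
    le = ge = total = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = float(sum(r for s, r in zip(signs, ranks) if s))
        total += 1
        if w <= w_obs + 1e-9:
            le += 1
        if w >= w_obs - 1e-9:
            ge += 1
    return min(1.0, 2.0 * min(le / total, ge / total))
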