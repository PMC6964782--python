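"""Curve metrics: resampling, normalization, FWHM/penumbra/offset, median
ensembles, and distance-to-agreement."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from smallfield_audit import scan_metrics as sm
from smallfield_audit.errors import (
    AmbiguousPeakError,
    CrossingNotFoundError,
    DegenerateCurveError,
    IncompatibleCurveError,
    OutOfRangeError,
)
from smallfield_audit.synthetic_data import BeamModel, true_pdd

from conftest import (
    double_erf_values,
    erf_profile_curve,
    make_pdd,
    make_profile,
    oracle_dta_penumbra,
    oracle_profile_metrics,
)


# ------------------------------------------------------------------ resample
def test_resample_idempotent_on_matching_grid():
    c = erf_profile_curve(step=0.5)
    r = sm.resample(c, 0.5)
    np.testing.assert_allclose(r.values, c.values, rtol=0, atol=1e-12)


def test_resample_exact_on_linear_ramp():
    x = np.arange(-10.0, 10.1, 2.0)
    c = make_profile(x, 5.0 + 0.3 * x, step_mm=2.0)
    r = sm.resample(c, 0.5)
    np.testing.assert_allclose(r.values, 5.0 + 0.3 * r.positions, atol=1e-12)
    assert r.positions[0] == x[0] and r.positions[-1] <= x[-1]


def test_resample_error_bounded_by_curvature():
    """Linear interpolation error <= step^2/8 * max|f''| on a smooth curve."""
    x = np.arange(-10.0, 10.001, 1.0)
    c = make_profile(x, 1.0 + 0.5 * np.sin(x), step_mm=1.0)
    r = sm.resample(c, 0.5)
    bound = (1.0**2 / 8.0) * 0.5
    assert np.max(np.abs(r.values - (1.0 + 0.5 * np.sin(r.positions)))) <= bound


def test_resample_degenerate_span():
    c = erf_profile_curve(step=0.5)
    with pytest.raises(DegenerateCurveError):
        sm.resample(c, 20.0)


# -------------------------------------------------------------- normalize_pdd
def test_normalize_pdd_scales_peak_to_100():
    z = np.arange(0.0, 60.5, 0.5)
    v = 200.0 * np.exp(-0.5 * ((z - 15.0) / 8.0) ** 2)
    curve, d_max = sm.normalize_pdd(make_pdd(z, v))
    assert d_max == pytest.approx(15.0, abs=0.25)
    assert curve.values.max() == pytest.approx(100.0)
    again, _ = sm.normalize_pdd(curve)
    np.testing.assert_allclose(again.values, curve.values, rtol=1e-12)


def test_normalize_pdd_dmax_matches_analytic_argmax():
    """Grid argmax lands within half a grid step of the closed-form
    d_max = ln((beta+mu)/mu)/beta of the build-up/attenuation model."""
    beam = BeamModel(6.0, "FF", 1.1, 0.26, 0.0055, {100.0: 1.0})
    z = np.arange(0.0, 300.5, 0.5)
    _, d_max = sm.normalize_pdd(make_pdd(z, true_pdd(beam, z) + 0.0))
    assert d_max == pytest.approx(beam.d_max_mm, abs=0.5)


def test_normalize_pdd_ambiguous_peak():
    z = np.arange(0.0, 20.5, 0.5)
    v = np.ones_like(z)
    v[10] = 2.0
    v[30] = 2.0  # two distant ties
    with pytest.raises(AmbiguousPeakError):
        sm.normalize_pdd(make_pdd(z, v))


# ---------------------------------------------------------- normalize_profile
def test_normalize_profile_sets_cax_to_one():
    c = erf_profile_curve()
    scaled = c.replace(values=c.values * 3.7)
    n = sm.normalize_profile(scaled)
    assert float(n.interp(0.0)) == pytest.approx(1.0, abs=1e-12)
    again = sm.normalize_profile(n)
    np.testing.assert_allclose(again.values, n.values, rtol=1e-12)


def test_normalize_profile_requires_cax_in_span():
    x = np.arange(2.0, 12.5, 0.5)
    c = make_profile(x, double_erf_values(x))
    with pytest.raises(OutOfRangeError):
        sm.normalize_profile(c)


def test_normalization_commutes_with_resample():
    c = erf_profile_curve(step=0.5).replace(values=erf_profile_curve(step=0.5).values * 2.5)
    a = sm.normalize_profile(sm.resample(c, 0.5))
    b = sm.resample(sm.normalize_profile(c), 0.5)
    np.testing.assert_allclose(a.values, b.values, atol=1e-6)


# ------------------------------------------------- offset / recenter / fwhm
def test_offset_zero_for_symmetric_profile():
    assert sm.beam_center_offset(erf_profile_curve()) == pytest.approx(0.0, abs=1e-6)


def test_offset_translation_equivariance():
    assert sm.beam_center_offset(erf_profile_curve(shift=0.7)) == pytest.approx(
        0.7, abs=0.01
    )


def test_offset_asymmetric_penumbras_matches_oracle():
    c = erf_profile_curve(sigma_l=1.0, sigma_r=2.0, step=0.5)
    oracle = oracle_profile_metrics(c)
    assert sm.beam_center_offset(c) == pytest.approx(oracle["offset"], abs=1e-3)


def _trapezoid(step=1.0):
    x = np.arange(-14.0, 14.0 + step / 2, step)
    v = np.clip((10.0 - np.abs(x)) / 6.0, 0.0, 1.0)  # flat 1 on [-4,4], 0 at +/-10
    return make_profile(x, v, step_mm=step)


def test_recenter_is_idempotent_and_width_preserving():
    c = erf_profile_curve(shift=0.4)
    r1 = sm.recenter(c)
    r2 = sm.recenter(r1)
    np.testing.assert_allclose(r2.positions, r1.positions, atol=1e-6)
    # the half-max level is 0.5x the CAX value, which moves by a few 1e-4
    # when a curved-top profile is shifted sub-sample; widths follow suit
    assert sm.fwhm(r1) == pytest.approx(sm.fwhm(c), abs=5e-3)
    # exact statements hold on an exactly flat-topped profile
    t = sm.recenter(_trapezoid())
    assert sm.beam_center_offset(t) == pytest.approx(0.0, abs=1e-9)
    assert sm.fwhm(t) == pytest.approx(sm.fwhm(_trapezoid()), abs=1e-9)


def test_fwhm_trapezoid_exact():
    """Piecewise-linear profile: flat 1.0 on [-4,4], linear to 0 at +/-10;
    the 50% points sit at +/-7, so FWHM is exactly 14."""
    assert sm.fwhm(_trapezoid()) == pytest.approx(14.0, abs=1e-12)


def test_fwhm_double_erf():
    c = erf_profile_curve(a=5.0, sigma_l=1.5, step=0.5)
    assert sm.fwhm(sm.normalize_profile(c)) == pytest.approx(10.0, abs=0.02)


def test_fwhm_gaussian_closed_form():
    x = np.arange(-15.0, 15.1, 0.25)
    c = make_profile(x, np.exp(-(x**2) / (2 * 4.0**2)), step_mm=0.25)
    assert sm.fwhm(c) == pytest.approx(2 * 4.0 * np.sqrt(2 * np.log(2)), abs=0.02)


def test_fwhm_missing_crossing():
    x = np.arange(-3.0, 3.1, 0.5)
    c = make_profile(x, double_erf_values(x, a=5.0))  # span inside the field
    with pytest.raises(CrossingNotFoundError):
        sm.fwhm(c)


# ------------------------------------------------------------------ penumbra
def test_penumbra_linear_ramp_exact():
    """0 -> 1 over 10 mm per side: the 20-80% band spans 6 mm exactly."""
    x = np.arange(-14.0, 14.5, 1.0)
    v = np.clip((12.0 - np.abs(x)) / 10.0, 0.0, 1.0)
    left, right, mean = sm.penumbra(make_profile(x, v, step_mm=1.0))
    assert left == pytest.approx(6.0, abs=1e-12)
    assert right == pytest.approx(6.0, abs=1e-12)
    assert mean == pytest.approx(6.0, abs=1e-12)


def test_penumbra_erf_edge_closed_form():
    """20-80% width of an erf edge is sigma*(z_0.8 - z_0.2) = 1.6833*sigma."""
    c = erf_profile_curve(a=8.0, sigma_l=1.5, step=0.25, span=20.0)
    left, right, _ = sm.penumbra(sm.normalize_profile(c))
    assert left == pytest.approx(1.5 * 1.6832938, abs=0.01)
    assert right == pytest.approx(1.5 * 1.6832938, abs=0.01)


def test_metrics_invariant_under_rescaling():
    c = erf_profile_curve(sigma_l=1.2, shift=0.3)
    m1 = sm.profile_metrics(sm.normalize_profile(c))
    m2 = sm.profile_metrics(sm.normalize_profile(c.replace(values=c.values * 41.7)))
    for a, b in zip(
        (m1.offset_mm, m1.fwhm_mm, m1.penumbra_left_mm, m1.penumbra_right_mm),
        (m2.offset_mm, m2.fwhm_mm, m2.penumbra_left_mm, m2.penumbra_right_mm),
    ):
        assert a == pytest.approx(b, abs=1e-12)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    sigma=st.floats(0.5, 4.0),
    a=st.floats(3.0, 8.0),
    shift=st.floats(-1.0, 1.0),
    step=st.floats(0.3, 1.0),
)
def test_metrics_match_dense_oracle(sigma, a, shift, step):
    """Outward crossing search equals the exhaustive 1e-4 mm dense-grid
    scan of the same interpolant, within 0.02 mm."""
    c = sm.normalize_profile(
        erf_profile_curve(a=a, sigma_l=sigma, shift=shift, step=step,
                          span=a + 6 * sigma + 2)
    )
    m = sm.profile_metrics(c)
    o = oracle_profile_metrics(c)
    assert m.offset_mm == pytest.approx(o["offset"], abs=0.02)
    assert m.fwhm_mm == pytest.approx(o["fwhm"], abs=0.02)
    assert m.penumbra_left_mm == pytest.approx(o["penumbra_left"], abs=0.02)
    assert m.penumbra_right_mm == pytest.approx(o["penumbra_right"], abs=0.02)


# -------------------------------------------------------------- median_curve
def test_median_curve_identical_inputs():
    curves = [erf_profile_curve(institution=f"i{k}") for k in range(3)]
    ens = sm.median_curve(curves)
    for d in ens.per_institution_diff.values():
        np.testing.assert_allclose(d, 0.0, atol=1e-9)


def test_median_curve_symmetric_perturbation():
    base = erf_profile_curve(institution="i0")
    delta = 0.01 * np.exp(-base.positions**2 / 20.0)
    up = base.replace(values=base.values + delta, institution_id="i1")
    dn = base.replace(values=np.clip(base.values - delta, 0, None),
                      institution_id="i2")
    ens = sm.median_curve([up, base, dn])
    np.testing.assert_allclose(
        ens.median_curve, base.interp(ens.grid), atol=1e-9
    )
    assert ens.max_abs_diff["i0"] == pytest.approx(0.0, abs=1e-9)


def test_median_curve_bounded_and_permutation_invariant():
    rng = np.random.default_rng(11)
    curves = []
    for k in range(5):
        c = erf_profile_curve(institution=f"i{k}")
        curves.append(c.replace(values=c.values * (1 + 0.01 * rng.standard_normal(c.values.shape))))
    ens = sm.median_curve(curves)
    mat = np.vstack([c.interp(ens.grid) for c in curves])
    assert np.all(ens.median_curve >= mat.min(axis=0) - 1e-12)
    assert np.all(ens.median_curve <= mat.max(axis=0) + 1e-12)
    ens2 = sm.median_curve(curves[::-1])
    np.testing.assert_allclose(ens2.median_curve, ens.median_curve, rtol=0)


def test_median_curve_rejects_mixed_beams():
    a = erf_profile_curve(institution="i0")
    b = erf_profile_curve(institution="i1", energy=10.0)
    with pytest.raises(IncompatibleCurveError):
        sm.median_curve([a, a.replace(institution_id="i2"), b])


# ------------------------------------------------------------------ DTA
def test_dta_self_is_zero():
    c = sm.normalize_profile(erf_profile_curve())
    assert sm.dta_penumbra(c, c) == pytest.approx(0.0, abs=1e-9)


def test_dta_pure_shift():
    """Translating the curve object (positions + d) moves its interpolant
    rigidly, so every penumbra sample is d away from its match."""
    ref = sm.normalize_profile(erf_profile_curve(step=0.5))
    ev = ref.replace(positions=ref.positions + 0.3)
    assert sm.dta_penumbra(ev, ref) == pytest.approx(0.3, abs=1e-3)


def test_dta_broadened_matches_bruteforce():
    ref = sm.normalize_profile(erf_profile_curve(sigma_l=1.5, step=0.5))
    ev = sm.normalize_profile(erf_profile_curve(sigma_l=2.0, step=0.5))
    assert sm.dta_penumbra(ev, ref) == pytest.approx(
        oracle_dta_penumbra(ev, ref), abs=1e-3
    )
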