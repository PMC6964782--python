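"""Output-factor correction: normalization, k lookup/renormalization,
corrected field output factors, and ensemble statistics."""

import numpy as np
import pandas as pd
import pytest

from smallfield_audit import output_factors as ofm
from smallfield_audit.errors import (
    CorrectionMagnitudeWarning,
    InsufficientEnsembleError,
    MissingIntermediateError,
    MissingReferenceError,
    UnknownDetectorError,
)
from smallfield_audit.scan_io import OutputFactorSeries
from smallfield_audit.synthetic_data import ktilde_true


def series(entries, inst="instA", det="EDGE", energy=6.0, filt="FF"):
    return OutputFactorSeries(inst, det, energy, filt, entries)


def table(rows, provenance="test"):
    return ofm.CorrectionTable(
        pd.DataFrame(rows, columns=["detector_id", "energy_mv", "filter_mode",
                                    "field_side_mm", "k"]),
        provenance,
    )


TWO_POINT = table([("D", 6.0, "FF", 8.0, 0.96), ("D", 6.0, "FF", 10.0, 0.97)])


# ----------------------------------------------------------- normalization
def test_normalize_series_divides_by_reference():
    s = series({5: 1.1, 10: 1.4, 100: 2.0})
    n = ofm.normalize_series(s)
    assert n.entries[100.0] == 1.0
    assert n.entries[5.0] == pytest.approx(0.55)
    again = ofm.normalize_series(n)
    assert again.entries == n.entries


def test_normalize_series_preserves_ratios():
    s = series({5: 1.1, 10: 1.4, 100: 2.0})
    n = ofm.normalize_series(s)
    assert n.entries[5.0] / n.entries[10.0] == pytest.approx(
        s.entries[5.0] / s.entries[10.0], rel=1e-15
    )


def test_normalize_series_missing_reference():
    with pytest.raises(MissingReferenceError):
        ofm.normalize_series(series({5: 1.1, 10: 1.4}))


# ----------------------------------------------------------------- k_lookup
def test_k_lookup_linear_midpoint():
    assert ofm.k_lookup(TWO_POINT, "D", 6.0, "FF", 9.0) == pytest.approx(0.965)


def test_k_lookup_extrapolates_below_range():
    """Straight line through (8, 0.96) and (10, 0.97) evaluated at 5."""
    with pytest.warns(CorrectionMagnitudeWarning):
        k = ofm.k_lookup(TWO_POINT, "D", 6.0, "FF", 5.0)
    assert k == pytest.approx(0.945, abs=1e-12)


def test_k_lookup_tabulated_exact_and_constant_above():
    assert ofm.k_lookup(TWO_POINT, "D", 6.0, "FF", 8.0) == 0.96
    assert ofm.k_lookup(TWO_POINT, "D", 6.0, "FF", 40.0) == 0.97


def test_k_lookup_unknown_detector():
    with pytest.raises(UnknownDetectorError):
        ofm.k_lookup(TWO_POINT, "nope", 6.0, "FF", 9.0)


def test_k_lookup_agrees_with_dense_tabulation_oracle():
    """Against an independently tabulated linear k(FS) = 1 - 0.004 (40-FS),
    lookups are exact at nodes and 1e-9-close between them."""
    sides = np.array([5.0, 8.0, 10.0, 15.0, 20.0, 30.0, 40.0])
    kfun = lambda s: 1.0 - 0.004 * (40.0 - s)
    t = table([("L", 6.0, "FF", s, kfun(s)) for s in sides])
    for s in sides:
        assert ofm.k_lookup(t, "L", 6.0, "FF", s) == pytest.approx(kfun(s), abs=1e-12)
    for s in [6.3, 9.1, 12.0, 27.5, 3.0]:  # includes below-range point
        assert ofm.k_lookup(t, "L", 6.0, "FF", s) == pytest.approx(kfun(s), abs=1e-9)


# ------------------------------------------------------------- renormalize_k
def test_renormalize_identity_when_intermediate_unity():
    t = table(
        [("D", 6.0, "FF", s, k) for s, k in
         [(5, 0.95), (10, 0.97), (20, 1.0), (40, 1.0)]]
    )
    assert ofm.renormalize_k(t, "D", 6.0, "FF", 5.0) == pytest.approx(0.95)


def test_renormalize_constant_k_is_unity():
    t = table([("D", 6.0, "FF", s, 0.98) for s in (5, 10, 20, 40)])
    for s in (5.0, 10.0, 20.0, 40.0):
        assert ofm.renormalize_k(t, "D", 6.0, "FF", s) == pytest.approx(1.0)


def test_renormalize_arithmetic():
    t = table(
        [("D", 6.0, "FF", s, k) for s, k in
         [(5, 1.05), (10, 1.02), (20, 0.99), (40, 1.01)]]
    )
    assert ofm.renormalize_k(t, "D", 6.0, "FF", 5.0) == pytest.approx(1.05, abs=1e-12)


def test_renormalize_requires_intermediate_sides():
    t = table([("D", 6.0, "FF", 5.0, 0.95), ("D", 6.0, "FF", 10.0, 0.97)])
    with pytest.raises(MissingIntermediateError):
        ofm.renormalize_k(t, "D", 6.0, "FF", 5.0)


# -------------------------------------------------------- apply_corrections
UNITY = table([("EDGE", 6.0, "FF", s, 1.0) for s in (5, 10, 20, 40)])


def test_unity_table_leaves_of_unchanged():
    s = ofm.normalize_series(series({5: 0.6, 10: 0.72, 20: 0.8, 40: 0.87, 100: 1.0}))
    omega = ofm.apply_corrections(s, UNITY)
    assert omega == pytest.approx(dict(s.entries))


def test_constructed_inverse_recovers_truth():
    """OF_det built as Omega_true / k~ is mapped back to Omega_true."""
    t = table(
        [("EDGE", 6.0, "FF", s, k) for s, k in
         [(5, 0.95), (10, 0.97), (20, 0.99), (40, 1.0)]]
    )
    omega_true = {5.0: 0.545, 10.0: 0.708, 20.0: 0.799, 40.0: 0.868, 100.0: 1.0}
    entries = {
        s: w / (ofm.renormalize_k(t, "EDGE", 6.0, "FF", s) if s in (5.0, 10.0) else 1.0)
        for s, w in omega_true.items()
    }
    omega = ofm.apply_corrections(ofm.normalize_series(series(entries)), t)
    for s in (5.0, 10.0):
        assert omega[s] == pytest.approx(omega_true[s], abs=1e-9)


def test_correcting_only_side_5_leaves_10():
    t = table(
        [("EDGE", 6.0, "FF", s, k) for s, k in
         [(5, 0.95), (10, 0.97), (20, 0.99), (40, 1.0)]]
    )
    s = ofm.normalize_series(series({5: 0.6, 10: 0.72, 20: 0.8, 40: 0.87, 100: 1.0}))
    omega = ofm.apply_corrections(s, t, correct_sides=(5.0,))
    assert omega[10.0] == s.entries[10.0]
    assert omega[5.0] != s.entries[5.0]


def test_apply_corrections_linear_in_of():
    t = table(
        [("EDGE", 6.0, "FF", s, k) for s, k in
         [(5, 0.95), (10, 0.97), (20, 0.99), (40, 1.0)]]
    )
    s1 = ofm.normalize_series(series({5: 0.6, 10: 0.72, 20: 0.8, 40: 0.87, 100: 1.0}))
    s2 = s1.replace(entries={k: 2 * v for k, v in s1.entries.items()})
    o1 = ofm.apply_corrections(s1, t)
    o2 = ofm.apply_corrections(s2, t)
    for side in o1:
        assert o2[side] == pytest.approx(2 * o1[side], rel=1e-12)


# --------------------------------------------------- ensemble statistics
def test_relative_differences_examples():
    m = {5.0: 0.5}
    ens = [{5.0: 0.45}, {5.0: 0.5}, {5.0: 0.55}]
    rd = ofm.relative_differences(ens, reference=[m, m, m])
    np.testing.assert_allclose(rd[5.0].to_numpy(), [-10.0, 0.0, 10.0], atol=1e-12)


def test_relative_differences_antisymmetry():
    m = {5.0: 0.5}
    x, mirrored = 0.47, 2 * 0.5 - 0.47
    rd = ofm.relative_differences([{5.0: x}, {5.0: mirrored}, m],
                                  reference=[m, m, m])
    assert rd[5.0][0] == pytest.approx(-rd[5.0][1], abs=1e-12)


def test_relative_differences_insufficient():
    with pytest.raises(InsufficientEnsembleError):
        ofm.relative_differences([{5.0: 0.5}, {5.0: 0.6}])


def test_summarize_ensemble_median_and_ci():
    rng = np.random.default_rng(0)
    ens = [{5.0: 0.545 * (1 + 0.01 * rng.standard_normal())} for _ in range(12)]
    out = ofm.summarize_ensemble(ens)
    row = out.iloc[0]
    assert row["n"] == 12
    vals = np.sort([e[5.0] for e in ens])
    assert row["ci_low"] == vals[2] and row["ci_high"] == vals[9]
    assert row["ci_low"] <= row["median"] <= row["ci_high"]


# ------------------------------------------------------ end-to-end recovery
def test_fleet_recovery_and_spread_reduction(fleet, ktable):
    """Corrections computed from the shipped table invert the generator's
    detector perturbations: per-beam median Omega lands within 1% of the
    ground truth at 5 and 10 mm, and the 5 mm inter-unit spread shrinks."""
    from smallfield_audit.synthetic_data import _OMEGA_TRUE

    for (energy, filt), omega_true in _OMEGA_TRUE.items():
        ser = [s for ds in fleet for s in ds.output_factors
               if s.energy_mv == energy and s.filter_mode == filt]
        with pytest.warns(CorrectionMagnitudeWarning):
            res = ofm.audit_output_factors(ser, ktable)
        med = res.summary.set_index("field_side_mm")["median"]
        for side in (5.0, 10.0):
            assert med[side] == pytest.approx(omega_true[side], rel=0.01)
        before = res.rel_diff_uncorrected[5.0].abs().max()
        after = res.rel_diff_corrected[5.0].abs().max()
        assert after < before

    # generator consistency: its k~ is unity away from the small fields
    assert ktilde_true("EDGE", 6.0, "FF", 30.0) == 1.0
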