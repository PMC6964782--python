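"""Correct detector output factors and watch the inter-unit spread shrink.

Runs the output-factor arm of the audit on the default synthetic fleet:
normalize each institution's OF_det to the 100 mm reference field, apply
the renormalized correction factors at 5 and 10 mm, and compare the
inter-institution spread before and after.
"""

import warnings

from smallfield_audit import default_correction_table, default_fleet_config, generate_fleet
from smallfield_audit.output_factors import audit_output_factors

fleet = generate_fleet(default_fleet_config(seed=1))
table = default_correction_table()

series = [s for ds in fleet for s in ds.output_factors
          if (s.energy_mv, s.filter_mode) == (6.0, "FF")]
with warnings.catch_warnings():
    warnings.simplefilter("ignore")  # extrapolated |k-1| > 5% is expected
    res = audit_output_factors(series, table)

print("6 MV flattened beam, 12 institutions\n")
print("median corrected field output factor (95% CI):")
for _, r in res.summary.iterrows():
    ci = ("-" if r.ci_low == r.ci_high
          else f"({r.ci_low:.3f}-{r.ci_high:.3f})")
    print(f"  {r.field_side_mm:>5.0f} mm  {r['median']:.3f}  {ci}  n={r.n:.0f}")

for side in (5.0, 10.0):
    before = res.rel_diff_uncorrected[side].abs().max()
    after = res.rel_diff_corrected[side].abs().max()
    print(f"\n{side:g} mm field: max |difference from median| "
          f"{before:.2f}% before correction -> {after:.2f}% after")

print("\nDiodes read high and chambers low in small fields; multiplying "
      "by the detector-specific correction collapses the spread, so the "
      "residual reflects genuine measurement noise, not detector choice.")
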