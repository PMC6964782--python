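"""Profile metrics on a small-field scan: FWHM, penumbra, offset, DTA.

Builds a 10 mm field profile as measured by two different detectors (a
point-like diode and a 2.9 mm ionization chamber) and shows how volume
averaging broadens the measured 20-80% penumbra while leaving the FWHM
nearly unchanged.
"""

import dataclasses

import numpy as np

from smallfield_audit import scan_metrics as sm
from smallfield_audit import synthetic_data as syn

cfg = dataclasses.replace(syn.default_fleet_config(seed=0), scan_noise_sigma=0.0)
beam = syn.default_beams()[0]  # 6 MV flattened

profiles = {}
for det in ("SFD", "PTW31016"):
    inst = syn.InstitutionConfig(
        institution_id="demo", machine_type="HD120", detector_id=det,
        kernel_width_mm=syn.DETECTOR_CATALOGUE[det].sensitive_extent_mm,
        center_offset_mm=0.1, scan_step_mm=0.5,
    )
    c = syn.measure_profile(cfg, inst, beam, 10.0, "crossline",
                            np.random.default_rng(0))
    profiles[det] = sm.normalize_profile(c)

print(f"{'detector':<10}{'extent mm':>10}{'offset mm':>11}{'FWHM mm':>9}"
      f"{'pen L mm':>10}{'pen R mm':>10}{'pen mean':>10}")
for det, c in profiles.items():
    m = sm.profile_metrics(c)
    w = syn.DETECTOR_CATALOGUE[det].sensitive_extent_mm
    print(f"{det:<10}{w:>10.2f}{m.offset_mm:>11.3f}{m.fwhm_mm:>9.3f}"
          f"{m.penumbra_left_mm:>10.3f}{m.penumbra_right_mm:>10.3f}"
          f"{m.penumbra_mean_mm:>10.3f}")

dta = sm.dta_penumbra(profiles["PTW31016"], profiles["SFD"])
print(f"\nmax DTA (chamber vs diode, 20-80% region): {dta:.3f} mm")
print("Both detectors see the same field edge position (offset, FWHM), "
      "but the chamber's finite volume widens the measured penumbra; the "
      "DTA quantifies the worst spatial disagreement in the penumbra.")
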