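# Methods

This note records the models, conventions and numerical choices behind
`smallfield_audit`, and what the synthetic fleet does and does not
emulate.

## Scan-curve processing

**Resampling.** All curves are piecewise-linearly resampled; the
analysis grid is 0.5 mm. No smoothing, fitting or filtering is ever
applied — the audit must expose measurement artifacts, not hide them.
Resampling never extrapolates beyond the measured span, and ensemble
grids are the intersection of spans, anchored at 0 so the central axis
(or water surface) is always a grid point.

**PDD normalization.** The depth of maximum dose is the argmax on the
0.5 mm resampled grid — deliberately not a parabolic fit, so the
reported d_max is a direct property of the data. Two non-adjacent grid
samples tying for the maximum (within 1e-9 relative) raise
`AmbiguousPeakError` rather than silently picking one; an adjacent
flat-top tie takes the shallower depth. Curves are scaled to 100% at
d_max.

**Profile conventions.** Profiles are normalized to 1.0 at the central
axis (x = 0). The half-maximum level is 0.5 × the CAX value, for FFF
beams too: at the 10 mm fields audited here flattened and FFF shapes are
nearly identical, so no cone renormalization is applied (renormalization
schemes for large FFF fields are out of scope). A consequence worth
knowing: for curved-top fields the CAX value changes by a few 1e-4 when
a profile is translated sub-sample, so FWHM is preserved under
recentring only to ~1e-3 mm rather than exactly; on flat-topped fields
it is exact.

**Crossing search.** All level crossings (50%, 20%, 80%) are located by
inverse linear interpolation inside the bracketing sample interval,
walking outward from the field center (sample of maximum value, ties
broken toward the axis). If noise produces several crossings of one
level on one side, the outermost is taken when all fall within a
3-sample window; wider separation raises `MultipleCrossingError`. This
is deterministic and noise-tolerant without smoothing. The beam-center
offset is the midpoint of the two 50% crossings; `recenter` translates
positions by its negative.

**Distance-to-agreement.** For every sample of the evaluated curve whose
value lies in 20–80% of the reference CAX value, the minimum |Δx| to a
position where the reference interpolant attains the same value is
found by scanning a 1e-3 mm dense grid (each candidate refined by
linear inversion), restricted to the same side of the field center so a
left-penumbra value can never match the right penumbra. The reported
DTA is the maximum over the region. The granularity is far below the
0.1 mm scale at which DTA differences are meaningful.

**Ensembles.** Per-point medians are computed across ≥ 3 institutions on
the common grid; per-institution deviations are reported in percentage
points of the normalized dose scale (PDDs are on 0–100, unit-scale
profiles are multiplied by 100). The median was chosen over the mean as
the reference because a single chamber-measured curve should not drag
the reference toward itself.

## Output factors

`OF_det` series are normalized to the 100 mm reference field. The
correction is `Ω = OF_det · k̃` at the correction sides (default
{5, 10} mm), `Ω = OF_det` elsewhere, with
`k̃(FS) = k(FS) / ½(k(20) + k(40))` — the intermediate-field
renormalization matching how small-field detectors are daisy-chained to
a reference chamber at 20–40 mm.

Lookup policy (the table states values only at discrete sides): exact at
tabulated sides; linear interpolation in field side between them; below
the table range, linear extrapolation through the two smallest tabulated
sides (the simplest reproducible choice — the functional form of k below
tabulation is not established); above the range, constant continuation
(corrections vanish for large fields). |k − 1| > 5% emits a warning, not
an error: extrapolated 5 mm corrections for some detectors legitimately
exceed the range codes of practice endorse, and the audit must still be
able to compute with them. Field sizes are MLC *setting* values
throughout; no equivalent-square or FWHM-based conversion is performed.

Relative differences are always taken against the median of the
*corrected* ensemble, including when differencing the uncorrected
`OF_det` — both panels of the before/after comparison then share one
reference.

## Statistics

**Wilcoxon signed-rank.** Zero differences are dropped before ranking
(the original treatment, matching common statistical software); tied
magnitudes get mid-ranks; the statistic is W = min(W⁺, W⁻). For n ≤ 20
the p-value is exact: all 2ⁿ sign assignments are enumerated (valid
under ties because mid-ranks are held fixed) and the smaller tail of W⁺
is doubled, capped at 1. Above n = 20 a tie- and continuity-corrected
normal approximation is used. The audit pairs values per (institution,
corrected field side), giving n ≈ 22 for a 12-institution fleet, so the
full audit reports the approximation while the exact path is exercised
directly in tests.

**Median CI.** The 95% interval is the innermost symmetric pair of order
statistics (x₍ᵣ₎, x₍ₙ₊₁₋ᵣ₎) whose binomial(n, ½) coverage
1 − 2·P(X ≤ r − 1) reaches the nominal level; the achieved (conservative)
coverage is reported alongside. For n = 12 this is ranks (3, 10) with
coverage 0.9614. The method is deterministic and assumption-free, which
suits n ≈ 12; a seeded percentile bootstrap is available behind a flag.
n ≤ 5 cannot reach 95% coverage and raises `SampleTooSmallError`.

## Synthetic fleet

The generator provides the statistical structure the analysis assumes,
with defaults chosen to mirror the audited conditions:

| parameter | default | meaning |
|---|---|---|
| institutions | 12 (10 HD120, 2 Millennium120) | fleet size; Millennium cannot set 5 mm |
| detectors | 7 EDGE, 2 Diode E, 1 Diode SRS, 1 CC01, 1 microDiamond | the published detector mix |
| kernel width | detector sensitive extent (0.6–2.9 mm) | top-hat volume-averaging kernel |
| scan step | {0.5, 1, 2} mm, weights 2:4:1 | steps institutions actually used (profiles; depth scans capped at 1 mm, since a 2 mm grid cannot resolve build-up) |
| center offset | U(−0.23, 0.23) mm | setup accuracy of the audited fleet |
| scan noise | 0.2% multiplicative i.i.d. | water-tank reading repeatability |
| OF noise | 0.5% multiplicative i.i.d. | output-factor reading repeatability |
| σ₀ | 1.0–1.3 mm per beam | intrinsic (detector-free) penumbra |
| β, μ | e.g. 0.26, 0.0055 /mm at 6 MV | build-up and attenuation; d_max = ln((β+μ)/μ)/β lands at textbook depths |
| chamber γ | 3e-4 /mm (z_ref 100 mm) | depth-response drift of chambers at the 5 mm field, sized to give ~2-percentage-point tail deviations |
| FFF cone | 0.006 /mm (~3% at a 10 mm field edge) | small enough that FF and FFF profile conventions coincide |
| Ω_true | per-beam published median output-factor table | ground truth the pipeline must recover |

Detector output factors are generated as
`OF_det = Ω_true / k̃_det · (1 + ε)` with k̃_det from a synthetic
correction table (diodes < 1 at 5 mm, chambers > 1, diamond mild) and
k̃_det ≡ 1 away from the small fields. The shipped table omits the EDGE
5 mm row — as the real tables do — and the EDGE 5 mm truth sits exactly
on the line through its 8 and 10 mm entries, so the documented linear
extrapolation recovers it; extrapolated EDGE and CC01 corrections exceed
the 5% warning threshold by construction, as they do in practice.

What the generator does **not** emulate: scanning-arm positional drift
and 1/f noise, source-occlusion and spectral physics, polarity and
recombination effects, detector orientation, TPR-based beam-quality
variation between units, and any machine-to-machine output difference —
the synthetic fleet's ground truth is identical across institutions by
design, so passing recovery tests demonstrates that the *pipeline*
removes detector effects, not that real fleets have no residual
machine-specific variation. Blur deconvolution is likewise a non-goal:
penumbra results are compared as measured.

Determinism: the fleet is a pure function of its configuration including
the RNG seed; per-institution draws (offsets, steps) are fixed in the
configuration itself, measurement noise comes from one seeded generator,
and file output uses fixed 10-significant-digit formatting, so repeated
generation and analysis are byte-identical.

## Problem sizes

Test and acceptance runs use the default 12-institution fleet (4 beams,
16 curves per HD120 institution), 50-configuration oracle sweeps for the
profile metrics, 2000 replicates for the null-rejection check, and 10⁴
draws for CI coverage — sizes at which every result above is stable from
run to run while the whole suite stays fast on a single core.

## Known limitations

* The curve metrics quantify a coarse scan faithfully, but a coarse scan
  itself biases penumbra and FWHM (linear interpolation across a curved
  20% toe); the audit reports what was measured, and the 2 mm-step
  behavior is documented rather than corrected.
* The exact Wilcoxon enumeration is O(2ⁿ); n > 20 falls back to the
  normal approximation.
* The order-statistic CI is conservative for small n (achieved coverage
  0.9614 at n = 12, not 0.95).
* `k_lookup` above the tabulated range returns the largest-side value;
  supplying tables that stop below 40 mm therefore flattens, not
  extrapolates, the large-field corrections (the renormalization sides
  20 and 40 mm are required in any case).
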