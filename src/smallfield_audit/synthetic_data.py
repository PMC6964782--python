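"""Synthetic multi-institution beam data with detector-dependent effects.

Raw institutional commissioning data are never published, so the audit
pipeline is exercised on a generated fleet that reproduces the statistical
structure the analysis assumes:

* a ground-truth beam per (energy, filter): a double-error-function field
  edge with intrinsic penumbra sigma0, an analytic build-up/attenuation
  depth-dose model D(z) = (1 - exp(-beta z)) exp(-mu z), and true field
  output factors Omega_true per field side (the published per-beam median
  output-factor table is used as the ground truth);
* per-institution detectors that blur profiles by convolution with a
  top-hat kernel matching the physical sensitive extent (volume
  averaging), tilt the depth-dose response linearly with depth for
  ionization chambers at the smallest field (under-response at shallow
  depths becomes over-response at depth after peak renormalization), and
  perturb output factors by the inverse of the detector's renormalized
  correction factor: OF_det(FS) = Omega_true(FS) / k~_det(FS) * (1 + eps);
* measurement nuisances: a beam-center offset drawn uniformly from
  +/-0.23 mm, scan steps drawn from {0.5, 1, 2} mm with weights 2:4:1
  (the steps institutions actually used), and i.i.d. multiplicative
  Gaussian reading noise.

Everything is a pure function of the configuration, including its RNG
seed: the same :class:`FleetConfig` always produces byte-identical files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy.special import erf

from .output_factors import CorrectionTable
from .scan_io import (
    BeamDataset,
    DetectorSpec,
    OutputFactorSeries,
    ScanCurve,
    write_fleet,
)

# ---------------------------------------------------------------------------
# detector catalogue (synthetic)
# ---------------------------------------------------------------------------
#: Fictitious but physically plausible correction factors k(FS) per detector
#: at the reference quality (6 MV flattened). Diodes over-respond in small
#: fields (k < 1), ionization chambers under-respond (k > 1), diamond is
#: mild. The EDGE 5 mm value lies exactly on the line through its 8 and
#: 10 mm entries, mirroring how a table starting at 8 mm is extrapolated.
#: These are synthetic stand-ins, NOT values from any code of practice.
_K_BASE: dict[str, dict[float, float]] = {
    "EDGE": {5: 0.943, 8: 0.958, 10: 0.968, 15: 0.980, 20: 0.988, 30: 0.995, 40: 0.999},
    "PTW60017": {5: 0.955, 8: 0.967, 10: 0.974, 15: 0.984, 20: 0.991, 30: 0.997, 40: 1.000},
    "PTW60018": {5: 0.959, 8: 0.970, 10: 0.976, 15: 0.985, 20: 0.992, 30: 0.997, 40: 1.000},
    "SFD": {5: 0.965, 8: 0.975, 10: 0.980, 15: 0.988, 20: 0.993, 30: 0.998, 40: 1.000},
    "PTW31016": {5: 1.062, 8: 1.028, 10: 1.018, 15: 1.008, 20: 1.004, 30: 1.001, 40: 1.000},
    "CC01": {5: 1.068, 8: 1.030, 10: 1.020, 15: 1.009, 20: 1.004, 30: 1.001, 40: 1.000},
    "PTW60019": {5: 0.981, 8: 0.989, 10: 0.992, 15: 0.996, 20: 0.998, 30: 0.999, 40: 1.000},
}

#: detector class and lateral sensitive extent (mm), after the published
#: detector inventory of the audited fleet
DETECTOR_CATALOGUE: dict[str, DetectorSpec] = {
    "EDGE": DetectorSpec("EDGE", "shielded_diode", 0.8),
    "PTW60017": DetectorSpec("PTW60017", "unshielded_diode", 1.13),
    "PTW60018": DetectorSpec("PTW60018", "unshielded_diode", 1.13),
    "SFD": DetectorSpec("SFD", "unshielded_diode", 0.6),
    "PTW31016": DetectorSpec("PTW31016", "ion_chamber", 2.9),
    "CC01": DetectorSpec("CC01", "ion_chamber", 2.0),
    "PTW60019": DetectorSpec("PTW60019", "diamond", 2.2),
}

#: beam-quality multipliers on (k - 1): corrections grow with energy and
#: shrink slightly without the flattening filter (softer spectrum)
_K_QUALITY_SCALE: dict[tuple[float, str], float] = {
    (6.0, "FF"): 1.00,
    (10.0, "FF"): 1.15,
    (6.0, "FFF"): 0.95,
    (10.0, "FFF"): 1.10,
}

#: depth-response drift (per mm) of ionization chambers at the smallest
#: field; zero for diodes and diamond
CHAMBER_PDD_GAMMA_PER_MM = 3e-4
PDD_GAMMA_REF_DEPTH_MM = 100.0
PDD_MAX_DEPTH_MM = 300.0

#: published per-beam median field output factors, used as Omega_true
_OMEGA_TRUE: dict[tuple[float, str], dict[float, float]] = {
    (6.0, "FF"): {5: 0.545, 10: 0.708, 20: 0.799, 30: 0.835, 40: 0.868,
                  60: 0.921, 80: 0.966, 100: 1.000},
    (10.0, "FF"): {5: 0.466, 10: 0.670, 20: 0.814, 30: 0.858, 40: 0.891,
                   60: 0.936, 80: 0.972, 100: 1.000},
    (6.0, "FFF"): {5: 0.568, 10: 0.718, 20: 0.806, 30: 0.842, 40: 0.879,
                   60: 0.929, 80: 0.970, 100: 1.000},
    (10.0, "FFF"): {5: 0.523, 10: 0.710, 20: 0.849, 30: 0.891, 40: 0.920,
                    60: 0.956, 80: 0.981, 100: 1.000},
}

#: depth-dose shape (build-up rate beta, attenuation mu, both per mm),
#: chosen so d_max = ln((beta+mu)/mu)/beta sits at textbook depths
#: (~15 mm at 6 MV, ~22 mm at 10 MV, slightly shallower for FFF)
_PDD_SHAPE: dict[tuple[float, str], tuple[float, float]] = {
    (6.0, "FF"): (0.26, 0.0055),
    (10.0, "FF"): (0.16, 0.0045),
    (6.0, "FFF"): (0.28, 0.0060),
    (10.0, "FFF"): (0.19, 0.0050),
}

#: intrinsic (detector-free) penumbra sigma0 (mm) per beam
_SIGMA0: dict[tuple[float, str], float] = {
    (6.0, "FF"): 1.1,
    (10.0, "FF"): 1.3,
    (6.0, "FFF"): 1.0,
    (10.0, "FFF"): 1.2,
}

#: FFF in-field cone slope (fraction per mm): ~3% dose drop at the edge of
#: a 10 mm field, small enough that FF and FFF small-field shapes agree
FFF_CONE_SLOPE_PER_MM = 0.006

OF_SIDES_HD120 = (5.0, 10.0, 20.0, 30.0, 40.0, 60.0, 80.0, 100.0)
OF_SIDES_MILLENNIUM = (10.0, 20.0, 30.0, 40.0, 60.0, 80.0, 100.0)

SCAN_STEP_CHOICES_MM = (0.5, 1.0, 2.0)
SCAN_STEP_WEIGHTS = (2 / 7, 4 / 7, 1 / 7)
MAX_CENTER_OFFSET_MM = 0.23

#: detector assignment of the default 12-institution fleet (seven EDGE,
#: two Diode E, one Diode SRS, one CC01 chamber, one microDiamond; the two
#: Millennium120 machines both used EDGE)
_DEFAULT_DETECTORS = (
    "EDGE", "EDGE", "EDGE", "EDGE", "EDGE",
    "PTW60017", "PTW60017", "PTW60018", "CC01", "PTW60019",
    "EDGE", "EDGE",
)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class BeamModel:
    energy_mv: float
    filter_mode: str
    sigma0_mm: float
    beta_per_mm: float
    mu_per_mm: float
    omega_true: Mapping[float, float]
    cone_slope_per_mm: float = 0.0  # nonzero only for FFF

    @property
    def d_max_mm(self) -> float:
        """Analytic argmax of D(z) = (1 - e^(-beta z)) e^(-mu z)."""
        b, m = self.beta_per_mm, self.mu_per_mm
        return float(np.log((b + m) / m) / b)


@dataclass(frozen=True)
class InstitutionConfig:
    institution_id: str
    machine_type: str
    detector_id: str
    kernel_width_mm: float  # top-hat width = detector sensitive extent
    center_offset_mm: float
    scan_step_mm: float


@dataclass(frozen=True)
class FleetConfig:
    beams: tuple[BeamModel, ...]
    institutions: tuple[InstitutionConfig, ...]
    scan_noise_sigma: float = 0.002  # relative, per scan sample
    of_noise_sigma: float = 0.005  # relative, per output-factor reading
    gaussian_kernel: bool = False  # top-hat by default
    rng_seed: int = 0

    @property
    def n_institutions(self) -> int:
        return len(self.institutions)


def default_beams() -> tuple[BeamModel, ...]:
    beams = []
    for key in _OMEGA_TRUE:
        e, f = key
        beta, mu = _PDD_SHAPE[key]
        beams.append(
            BeamModel(
                energy_mv=e,
                filter_mode=f,
                sigma0_mm=_SIGMA0[key],
                beta_per_mm=beta,
                mu_per_mm=mu,
                omega_true=dict(_OMEGA_TRUE[key]),
                cone_slope_per_mm=FFF_CONE_SLOPE_PER_MM if f == "FFF" else 0.0,
            )
        )
    return tuple(beams)


def default_fleet_config(seed: int = 0, n_institutions: int = 12) -> FleetConfig:
    """The default audited fleet: ten HD120 + two Millennium120 machines
    with the catalogue detector mix; per-institution offsets and scan
    steps drawn reproducibly from ``seed``."""
    rng = np.random.default_rng(seed)
    institutions = []
    for i in range(n_institutions):
        det = _DEFAULT_DETECTORS[i % len(_DEFAULT_DETECTORS)]
        machine = "Millennium120" if i % 12 >= 10 else "HD120"
        institutions.append(
            InstitutionConfig(
                institution_id=f"inst{i + 1:02d}",
                machine_type=machine,
                detector_id=det,
                kernel_width_mm=DETECTOR_CATALOGUE[det].sensitive_extent_mm,
                center_offset_mm=float(
                    rng.uniform(-MAX_CENTER_OFFSET_MM, MAX_CENTER_OFFSET_MM)
                ),
                scan_step_mm=float(
                    rng.choice(SCAN_STEP_CHOICES_MM, p=SCAN_STEP_WEIGHTS)
                ),
            )
        )
    return FleetConfig(
        beams=default_beams(), institutions=tuple(institutions), rng_seed=seed
    )


# ---------------------------------------------------------------------------
# detector response model
# ---------------------------------------------------------------------------
def k_true(detector_id: str, energy_mv: float, filter_mode: str,
           field_side_mm: float) -> float:
    """The generator's ground-truth correction factor for a detector."""
    base = _K_BASE[detector_id][float(field_side_mm)]
    scale = _K_QUALITY_SCALE[(float(energy_mv), filter_mode)]
    return 1.0 + scale * (base - 1.0)


def ktilde_true(detector_id: str, energy_mv: float, filter_mode: str,
                field_side_mm: float) -> float:
    """Renormalized ground-truth correction: unity outside the small
    fields (the daisy-chained mid/large fields are measured correctly)."""
    s = float(field_side_mm)
    if s not in (5.0, 10.0):
        return 1.0
    denom = 0.5 * (
        k_true(detector_id, energy_mv, filter_mode, 20.0)
        + k_true(detector_id, energy_mv, filter_mode, 40.0)
    )
    return k_true(detector_id, energy_mv, filter_mode, s) / denom


def default_correction_table() -> CorrectionTable:
    """The synthetic correction table shipped with the package.

    Mirrors the shape of a code-of-practice table: the EDGE rows start at
    8 mm (its 5 mm correction must be obtained by extrapolation), every
    other detector is tabulated from 5 mm. Values are the generator's own
    synthetic ground truth, not data from any published code of practice.
    """
    import pandas as pd

    records = []
    for det, base in _K_BASE.items():
        for (e, f) in _K_QUALITY_SCALE:
            for side in sorted(base):
                if det == "EDGE" and side == 5.0:
                    continue  # tabulated only from 8 mm, like the real table
                records.append(
                    {
                        "detector_id": det,
                        "energy_mv": e,
                        "filter_mode": f,
                        "field_side_mm": float(side),
                        "k": k_true(det, e, f, side),
                    }
                )
    return CorrectionTable(
        pd.DataFrame.from_records(records),
        provenance="synthetic illustrative correction factors generated by "
        "smallfield_audit.synthetic_data; not TRS-483 data",
    )


# ---------------------------------------------------------------------------
# beam models
# ---------------------------------------------------------------------------
def true_profile(
    beam: BeamModel,
    field_side_mm: float,
    positions_mm: np.ndarray,
    center_offset_mm: float = 0.0,
) -> np.ndarray:
    """Ideal (detector-free) lateral profile: a double-error-function field
    edge, with a mild linear cone inside the field for FFF beams."""
    a = field_side_mm / 2.0
    s = beam.sigma0_mm * np.sqrt(2.0)
    x = np.asarray(positions_mm, dtype=float) - center_offset_mm
    p = 0.5 * (erf((a - x) / s) + erf((a + x) / s))
    if beam.cone_slope_per_mm:
        p = p * (1.0 - beam.cone_slope_per_mm * np.minimum(np.abs(x), a))
    return p


def true_pdd(beam: BeamModel, depths_mm: np.ndarray) -> np.ndarray:
    """Ideal depth dose: build-up times exponential attenuation."""
    z = np.asarray(depths_mm, dtype=float)
    return (1.0 - np.exp(-beam.beta_per_mm * z)) * np.exp(-beam.mu_per_mm * z)


def _volume_average(
    beam: BeamModel,
    field_side_mm: float,
    positions_mm: np.ndarray,
    center_offset_mm: float,
    width_mm: float,
    gaussian: bool,
) -> np.ndarray:
    """Blur the ideal profile with the detector kernel (dense-grid box
    average via a cumulative integral; Gaussian kernel behind a flag)."""
    if width_mm <= 0:
        return true_profile(beam, field_side_mm, positions_mm, center_offset_mm)
    h = 0.005  # dense integration step, mm
    pad = width_mm * 2 + 4 * h
    lo = float(np.min(positions_mm)) - pad
    hi = float(np.max(positions_mm)) + pad
    xg = np.arange(lo, hi + h / 2, h)
    pg = true_profile(beam, field_side_mm, xg, center_offset_mm)
    if gaussian:
        # sigma chosen so the Gaussian has the same variance as the top-hat
        sigma = width_mm / np.sqrt(12.0)
        kx = np.arange(-4 * sigma, 4 * sigma + h / 2, h)
        kern = np.exp(-0.5 * (kx / sigma) ** 2)
        kern /= kern.sum()
        sm = np.convolve(pg, kern, mode="same")
        return np.interp(positions_mm, xg, sm)
    cumint = np.concatenate(([0.0], np.cumsum((pg[1:] + pg[:-1]) * h / 2)))
    half = width_mm / 2.0
    upper = np.interp(np.asarray(positions_mm) + half, xg, cumint)
    lower = np.interp(np.asarray(positions_mm) - half, xg, cumint)
    return (upper - lower) / width_mm


def _profile_positions(field_side_mm: float, beam: BeamModel,
                       width_mm: float, step_mm: float) -> np.ndarray:
    span = field_side_mm / 2.0 + max(8.0, 6.0 * (beam.sigma0_mm + width_mm))
    n = int(np.ceil(span / step_mm))
    return step_mm * np.arange(-n, n + 1)


def measure_profile(
    cfg: FleetConfig,
    inst: InstitutionConfig,
    beam: BeamModel,
    field_side_mm: float,
    axis: str,
    rng: np.random.Generator,
) -> ScanCurve:
    """One institution's measured off-center-ratio scan: volume-averaged,
    offset, sampled at the institution's step, with multiplicative noise."""
    pos = _profile_positions(field_side_mm, beam, inst.kernel_width_mm,
                             inst.scan_step_mm)
    vals = _volume_average(
        beam, field_side_mm, pos, inst.center_offset_mm,
        inst.kernel_width_mm, cfg.gaussian_kernel,
    )
    if cfg.scan_noise_sigma > 0:
        vals = vals * (1.0 + cfg.scan_noise_sigma * rng.standard_normal(vals.shape))
    return ScanCurve(
        axis=axis,
        positions=pos,
        values=np.clip(vals, 0.0, None),
        energy_mv=beam.energy_mv,
        filter_mode=beam.filter_mode,
        field_x_mm=field_side_mm,
        field_y_mm=field_side_mm,
        ssd_mm=900.0,
        depth_mm=100.0,
        detector_id=inst.detector_id,
        institution_id=inst.institution_id,
        step_mm=inst.scan_step_mm,
    )


def measure_pdd(
    cfg: FleetConfig,
    inst: InstitutionConfig,
    beam: BeamModel,
    field_side_mm: float,
    rng: np.random.Generator,
) -> ScanCurve:
    """One institution's measured depth-dose scan.

    Ionization chambers at the smallest field carry a linear depth-response
    drift (1 + gamma (z - z_ref)): under-response at shallow depths turns
    into over-response past the peak once the curve is renormalized at
    d_max downstream. The curve is returned unnormalized; peak
    normalization is the pipeline's job. Depth scans are acquired at no
    coarser than 1 mm (coarse steps are a lateral-profile phenomenon; a
    2 mm depth grid cannot resolve the build-up region).
    """
    step = min(inst.scan_step_mm, 1.0)
    z = step * np.arange(int(PDD_MAX_DEPTH_MM / step) + 1)
    vals = true_pdd(beam, z)
    det_class = DETECTOR_CATALOGUE[inst.detector_id].detector_class
    if det_class == "ion_chamber" and field_side_mm <= 5.0:
        vals = vals * (
            1.0 + CHAMBER_PDD_GAMMA_PER_MM * (z - PDD_GAMMA_REF_DEPTH_MM)
        )
    if cfg.scan_noise_sigma > 0:
        vals = vals * (1.0 + cfg.scan_noise_sigma * rng.standard_normal(vals.shape))
    return ScanCurve(
        axis="depth",
        positions=z,
        values=np.clip(vals, 0.0, None),
        energy_mv=beam.energy_mv,
        filter_mode=beam.filter_mode,
        field_x_mm=field_side_mm,
        field_y_mm=field_side_mm,
        ssd_mm=1000.0,
        detector_id=inst.detector_id,
        institution_id=inst.institution_id,
        step_mm=step,
    )


def measure_output_factors(
    cfg: FleetConfig,
    inst: InstitutionConfig,
    beam: BeamModel,
    rng: np.random.Generator,
) -> OutputFactorSeries:
    """One institution's detector output factors: the ground truth divided
    by the detector's renormalized correction, with reading noise, then
    normalized to the 100 mm reference field."""
    sides = OF_SIDES_HD120 if inst.machine_type == "HD120" else OF_SIDES_MILLENNIUM
    raw = {}
    for s in sides:
        kt = ktilde_true(inst.detector_id, beam.energy_mv, beam.filter_mode, s)
        eps = cfg.of_noise_sigma * rng.standard_normal() if cfg.of_noise_sigma else 0.0
        raw[s] = beam.omega_true[s] / kt * (1.0 + eps)
    ref = raw[100.0]
    return OutputFactorSeries(
        institution_id=inst.institution_id,
        detector_id=inst.detector_id,
        energy_mv=beam.energy_mv,
        filter_mode=beam.filter_mode,
        entries={s: v / ref for s, v in raw.items()},
    )


# ---------------------------------------------------------------------------
# fleet assembly
# ---------------------------------------------------------------------------
def generate_dataset(
    cfg: FleetConfig, inst: InstitutionConfig, rng: np.random.Generator
) -> BeamDataset:
    curves: list[ScanCurve] = []
    series: list[OutputFactorSeries] = []
    pdd_fields = (5.0, 10.0) if inst.machine_type == "HD120" else (10.0,)
    for beam in cfg.beams:
        for fs in pdd_fields:
            curves.append(measure_pdd(cfg, inst, beam, fs, rng))
        for axis in ("crossline", "inline"):
            curves.append(measure_profile(cfg, inst, beam, 10.0, axis, rng))
        series.append(measure_output_factors(cfg, inst, beam, rng))
    return BeamDataset(
        institution_id=inst.institution_id,
        machine_type=inst.machine_type,
        curves=tuple(curves),
        output_factors=tuple(series),
        detectors=(DETECTOR_CATALOGUE[inst.detector_id],),
    )


def ground_truth_record(cfg: FleetConfig) -> dict:
    """Everything needed for recovery tests, serializable to YAML."""
    return {
        "beams": [
            {
                "energy_mv": b.energy_mv,
                "filter_mode": b.filter_mode,
                "sigma0_mm": b.sigma0_mm,
                "beta_per_mm": b.beta_per_mm,
                "mu_per_mm": b.mu_per_mm,
                "d_max_mm": b.d_max_mm,
                "omega_true": {float(k): float(v) for k, v in b.omega_true.items()},
            }
            for b in cfg.beams
        ],
        "institutions": [dataclasses.asdict(i) for i in cfg.institutions],
        "scan_noise_sigma": cfg.scan_noise_sigma,
        "of_noise_sigma": cfg.of_noise_sigma,
        "rng_seed": cfg.rng_seed,
    }


def generate_fleet(
    cfg: FleetConfig, out_dir=None, force: bool = False
) -> list[BeamDataset]:
    """Generate every institution's dataset; optionally write the scan_io
    fleet layout plus ``ground_truth.yaml``. Deterministic in cfg.rng_seed."""
    rng = np.random.default_rng(cfg.rng_seed)
    datasets = [generate_dataset(cfg, inst, rng) for inst in cfg.institutions]
    if out_dir is not None:
        out_dir = Path(out_dir)
        write_fleet(datasets, out_dir, force=force)
        (out_dir / "ground_truth.yaml").write_text(
            yaml.safe_dump(ground_truth_record(cfg), sort_keys=True)
        )
        default_correction_table().to_csv(out_dir / "correction_factors.csv")
    return datasets
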