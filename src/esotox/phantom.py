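"""Synthetic esophagus phantom cohorts: CT texture, 3D dose, tubular mask,
clinical covariates and logistic outcome labels.

Each patient is a cylindrical esophagus (default radius 11.5 mm x length
90 mm on a 1 mm grid, ~37 cc) filled with a correlated Gaussian HU texture
(clipped to the soft-tissue range, with injected sub -150 HU cavity voxels),
irradiated by a prescription-scaled dose field with a lateral Gaussian
falloff, a longitudinal gradient and voxel noise.

Outcome labels are drawn from a logistic model on *planted features*: named
radiomic/dosiomic features actually measured on each generated case (by
default one GLCM contrast and one scale-invariant dose moment), standardized
against a Monte-Carlo calibration sample.  Between-patient variance in the
planted features comes from per-patient latent draws: the texture correlation
length drives GLCM contrast, the lateral dose falloff drives the eta moments.
Cohorts are fully deterministic given (config, seed): per-case seeds are
derived from the master seed by a counter scheme, so a cohort can be extended
without reshuffling existing patients.
"""

from __future__ import annotations

import functools
import re
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from scipy.special import expit, logit

from . import dosiomics as _dos
from . import radiomics as _rad
from .volume import EmptyMaskError, GeometryError, VolumeGrid, refine_mask_by_hu

__all__ = [
    "HuTextureModel",
    "DoseModel",
    "OutcomeModel",
    "PhantomConfig",
    "PhantomCase",
    "Cohort",
    "Calibration",
    "CalibrationError",
    "generate_phantom",
    "calibrate_intercept",
    "generate_cohort",
    "compute_planted_features",
    "encode_clinical",
    "CLINICAL_FEATURES",
]

HU_WINDOW = (-150.0, 180.0)
_BACKGROUND_HU = -50.0
_CAVITY_HU = -400.0
_BBOX_MARGIN = 8  # voxels of texture margin around the mask for filter support


class CalibrationError(RuntimeError):
    """Intercept calibration failed (target prevalence not bracketed)."""


@dataclass(frozen=True)
class HuTextureModel:
    """Correlated Gaussian HU texture inside the esophagus.

    ``correlation_cv`` is the log-scale SD of the per-patient correlation
    length; texture roughness is the latent that carries radiomic signal.
    """

    mean_hu: float = 40.0
    sd_hu: float = 30.0
    correlation_mm: float = 3.0
    correlation_cv: float = 0.35
    clip_hu: tuple[float, float] = (-100.0, 175.0)


@dataclass(frozen=True)
class DoseModel:
    """Prescription-scaled dose: lateral Gaussian falloff around an axis
    offset from the tube, a longitudinal gradient, and voxel noise.

    ``falloff_cv`` is the log-scale SD of the per-patient lateral falloff;
    it is the latent that carries dosiomic signal.  When
    ``prescription_from_clinical`` the per-patient prescribed dose (a
    clinical covariate) scales the field; otherwise ``prescription_gy`` is
    used for every patient.
    """

    prescription_gy: float = 60.0
    lateral_falloff_mm: float = 12.0
    falloff_cv: float = 0.30
    axis_offset_mm: float = 10.0
    longitudinal_gradient_gy_cm: float = 2.0
    noise_sd_gy: float = 1.0
    prescription_from_clinical: bool = True


@dataclass(frozen=True)
class OutcomeModel:
    """Logistic outcome on standardized planted features.

    ``planted`` maps feature names (exact extraction names) to log-odds
    coefficients per standard deviation.  If ``intercept`` is None it is
    calibrated so the Monte-Carlo prevalence matches ``target_prevalence``.
    """

    planted: tuple[tuple[str, float], ...] = (
        ("original_glcm_Contrast_bin20", 1.8),
        ("dose_moment_eta_200", 1.8),
    )
    intercept: float | None = None
    target_prevalence: float = 0.317

    def __post_init__(self) -> None:
        if not 0.0 < self.target_prevalence < 1.0:
            raise ValueError("target prevalence must lie in (0, 1)")

    @property
    def planted_dict(self) -> dict[str, float]:
        return dict(self.planted)

    @property
    def has_effects(self) -> bool:
        return any(c != 0.0 for _, c in self.planted)

    @classmethod
    def null(cls, target_prevalence: float = 0.317) -> "OutcomeModel":
        """No planted effects: labels are i.i.d. Bernoulli(target)."""
        return cls(planted=(), target_prevalence=target_prevalence)


@dataclass(frozen=True)
class PhantomConfig:
    n_patients: int = 161
    grid_shape: tuple[int, int, int] = (48, 48, 96)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    esophagus_radius_mm: float = 11.5
    esophagus_length_mm: float = 90.0
    hu_texture: HuTextureModel = field(default_factory=HuTextureModel)
    cavity_rate: float = 0.05
    dose_model: DoseModel = field(default_factory=DoseModel)
    outcome_model: OutcomeModel = field(default_factory=OutcomeModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be positive")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not 0.0 <= self.cavity_rate < 1.0:
            raise ValueError("cavity_rate must be in [0, 1)")
        ext = [n * s for n, s in zip(self.grid_shape, self.spacing_mm)]
        if (2 * self.esophagus_radius_mm > min(ext[0], ext[1])
                or self.esophagus_length_mm > ext[2]):
            raise GeometryError(
                f"esophagus tube (r={self.esophagus_radius_mm} mm, "
                f"L={self.esophagus_length_mm} mm) does not fit the "
                f"{self.grid_shape} grid at spacing {self.spacing_mm}"
            )

    @classmethod
    def small(cls, **overrides) -> "PhantomConfig":
        """Small geometry for quick tests (not the study conditions)."""
        defaults = dict(
            n_patients=40, grid_shape=(28, 28, 40), esophagus_radius_mm=6.0,
            esophagus_length_mm=30.0,
        )
        defaults.update(overrides)
        return cls(**defaults)

    @property
    def analytic_tube_volume_cc(self) -> float:
        return float(np.pi * self.esophagus_radius_mm**2 * self.esophagus_length_mm / 1000.0)


@dataclass
class PhantomCase:
    """One synthetic patient: CT (HU), dose (Gy), binary esophagus mask,
    clinical covariates, and the binary grade >= 2 outcome label."""

    ct: VolumeGrid
    dose: VolumeGrid
    mask: VolumeGrid
    clinical: dict[str, object]
    label: int | None = None

    def __post_init__(self) -> None:
        self.ct.require_same_geometry(self.dose, "CT and dose")
        self.ct.require_same_geometry(self.mask, "CT and mask")
        if not (self.mask.values > 0).any():
            raise EmptyMaskError("phantom mask is empty")
        if float(self.dose.values.min()) < 0:
            raise ValueError("dose must be non-negative everywhere")


# ---------------------------------------------------------------------------
# Geometry (deterministic per config)
# ---------------------------------------------------------------------------

@functools.lru_cache(maxsize=8)
def _geometry(config: PhantomConfig):
    nx, ny, nz = config.grid_shape
    sx, sy, sz = config.spacing_mm
    x = (np.arange(nx) + 0.5) * sx
    y = (np.arange(ny) + 0.5) * sy
    z = (np.arange(nz) + 0.5) * sz
    cx, cy, cz = nx * sx / 2, ny * sy / 2, nz * sz / 2
    X, Y = np.meshgrid(x, y, indexing="ij")
    radial2 = (X - cx) ** 2 + (Y - cy) ** 2
    in_disk = radial2 <= config.esophagus_radius_mm**2
    in_len = np.abs(z - cz) <= config.esophagus_length_mm / 2
    mask = in_disk[:, :, None] & in_len[None, None, :]
    idx = np.argwhere(mask)
    lo = np.maximum(idx.min(axis=0) - _BBOX_MARGIN, 0)
    hi = np.minimum(idx.max(axis=0) + 1 + _BBOX_MARGIN, config.grid_shape)
    bbox = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    return {
        "mask": mask,
        "bbox": bbox,
        "mask_block": mask[bbox],
        "center_mm": (cx, cy, cz),
        "block_origin_mm": tuple(float(l * s) for l, s in zip(lo, config.spacing_mm)),
    }


def _case_seed(master_seed: int, counter: int) -> int:
    """Counter-scheme per-case seed: extending a cohort never reshuffles."""
    return int(np.random.SeedSequence([master_seed, counter]).generate_state(1)[0])


_CHEMO = ("SCRT", "CCRT", "RT")
_CHEMO_P = (0.404, 0.540, 0.056)
_RT_DOSE_LOW = (45.0, 50.0, 55.0)
_RT_DOSE_HIGH = (62.0, 66.0, 70.0)
_RT_DOSE_P = (52 / 161, 81 / 161, 28 / 161)  # < 60 / = 60 / > 60 Gy


def _draw_clinical(rng: np.random.Generator) -> dict[str, object]:
    group = rng.choice(3, p=_RT_DOSE_P)
    if group == 0:
        rt_dose = float(rng.choice(_RT_DOSE_LOW))
    elif group == 1:
        rt_dose = 60.0
    else:
        rt_dose = float(rng.choice(_RT_DOSE_HIGH))
    return {
        "age": float(np.clip(rng.normal(62.0, 9.5), 29.0, 83.0)),
        "sex": "M" if rng.random() < 0.882 else "F",
        "smoking": "ever" if rng.random() < 0.764 else "never",
        "t_stage": int(rng.choice((1, 2, 3, 4), p=(0.062, 0.435, 0.217, 0.286))),
        "n_stage": int(rng.choice((0, 1, 2, 3), p=(0.056, 0.025, 0.528, 0.391))),
        "tnm": "IIIB" if rng.random() < 0.708 else "IIIA",
        "chemo": str(rng.choice(_CHEMO, p=_CHEMO_P)),
        "rt_dose_gy": rt_dose,
    }


CLINICAL_FEATURES = (
    "clinical_age", "clinical_sex_male", "clinical_smoking_ever",
    "clinical_t_stage", "clinical_n_stage", "clinical_tnm_IIIB",
    "clinical_chemo_CCRT", "clinical_chemo_SCRT", "clinical_rt_dose_gy",
)


def encode_clinical(clinical: Mapping[str, object]) -> dict[str, float]:
    """Numeric encoding of the clinical covariates (one-hot for chemo)."""
    return {
        "clinical_age": float(clinical["age"]),
        "clinical_sex_male": 1.0 if clinical["sex"] == "M" else 0.0,
        "clinical_smoking_ever": 1.0 if clinical["smoking"] == "ever" else 0.0,
        "clinical_t_stage": float(clinical["t_stage"]),
        "clinical_n_stage": float(clinical["n_stage"]),
        "clinical_tnm_IIIB": 1.0 if clinical["tnm"] == "IIIB" else 0.0,
        "clinical_chemo_CCRT": 1.0 if clinical["chemo"] == "CCRT" else 0.0,
        "clinical_chemo_SCRT": 1.0 if clinical["chemo"] == "SCRT" else 0.0,
        "clinical_rt_dose_gy": float(clinical["rt_dose_gy"]),
    }


# ---------------------------------------------------------------------------
# Case generation
# ---------------------------------------------------------------------------

def _case_blocks(config: PhantomConfig, case_seed: int):
    """Everything random about one case, computed on the mask bounding box.

    The bounding-box arrays are bit-identical to the corresponding region of
    the full volumes from :func:`generate_phantom`, which is what makes the
    cheap label/calibration path exact.
    """
    geom = _geometry(config)
    ss = np.random.SeedSequence(case_seed)
    r_lat, r_tex, r_cav, r_noise, r_clin, r_lab = [
        np.random.default_rng(s) for s in ss.spawn(6)
    ]
    tex = config.hu_texture
    dm = config.dose_model
    corr_len = tex.correlation_mm * float(np.exp(r_lat.normal(0.0, tex.correlation_cv)))
    if np.isfinite(dm.lateral_falloff_mm):
        falloff = dm.lateral_falloff_mm * float(np.exp(r_lat.normal(0.0, dm.falloff_cv)))
    else:
        falloff = np.inf
    clinical = _draw_clinical(r_clin)
    rx = float(clinical["rt_dose_gy"]) if dm.prescription_from_clinical else dm.prescription_gy

    mask_block = geom["mask_block"]
    shape = mask_block.shape

    # CT texture: smoothed white noise, renormalized to unit variance so the
    # amplitude stays fixed while the correlation length varies per patient.
    white = r_tex.standard_normal(shape)
    sigma_vox = [corr_len / s for s in config.spacing_mm]
    smooth = ndimage.gaussian_filter(white, sigma=sigma_vox)
    sd = smooth.std()
    if sd > 0:
        smooth /= sd
    ct_block = tex.mean_hu + tex.sd_hu * smooth
    np.clip(ct_block, *tex.clip_hu, out=ct_block)
    if config.cavity_rate > 0:
        cav = r_cav.random(int(mask_block.sum())) < config.cavity_rate
        vals = ct_block[mask_block]
        vals[cav] = _CAVITY_HU
        ct_block[mask_block] = vals

    dose_block = _analytic_dose(config, geom["bbox"], rx, falloff)
    if dm.noise_sd_gy > 0:
        dose_block = dose_block + r_noise.normal(0.0, dm.noise_sd_gy, shape)
    np.clip(dose_block, 0.0, None, out=dose_block)

    latents = {"correlation_mm": corr_len, "falloff_mm": falloff, "prescription_gy": rx}
    # float32 here so the bounding-box path is bit-identical to the stored case
    return (ct_block.astype(np.float32), dose_block.astype(np.float32),
            clinical, latents, r_lab)


def _analytic_dose(config: PhantomConfig, region: tuple[slice, ...], rx: float,
                   falloff: float) -> np.ndarray:
    geom = _geometry(config)
    cx, cy, cz = geom["center_mm"]
    dm = config.dose_model
    sx, sy, sz = config.spacing_mm
    ax_x, ax_y = cx + dm.axis_offset_mm, cy
    xs = (np.arange(region[0].start, region[0].stop) + 0.5) * sx
    ys = (np.arange(region[1].start, region[1].stop) + 0.5) * sy
    zs = (np.arange(region[2].start, region[2].stop) + 0.5) * sz
    if np.isfinite(falloff):
        lat = np.exp(-((xs[:, None] - ax_x) ** 2 + (ys[None, :] - ax_y) ** 2)
                     / (2.0 * falloff**2))
    else:
        lat = np.ones((len(xs), len(ys)))
    dose = rx * lat[:, :, None] * np.ones((1, 1, len(zs)))
    dose += dm.longitudinal_gradient_gy_cm * (zs[None, None, :] - cz) / 10.0
    return np.clip(dose, 0.0, None)


def _build_case(config: PhantomConfig, case_seed: int):
    """Assemble the full-grid case from its bounding-box blocks.  Returns the
    case together with its (fresh) label RNG stream."""
    geom = _geometry(config)
    ct_block, dose_block, clinical, latents, r_lab = _case_blocks(config, case_seed)
    full = tuple(config.grid_shape)
    ct = np.full(full, _BACKGROUND_HU, dtype=np.float32)
    ct[geom["bbox"]] = ct_block
    dose = _analytic_dose(config, tuple(slice(0, n) for n in full),
                          latents["prescription_gy"], latents["falloff_mm"])
    dose = dose.astype(np.float32)
    dose[geom["bbox"]] = dose_block
    mask = geom["mask"].astype(np.uint8)
    sp = config.spacing_mm
    case = PhantomCase(
        ct=VolumeGrid(ct, sp), dose=VolumeGrid(dose, sp),
        mask=VolumeGrid(mask, sp), clinical=clinical,
    )
    case.clinical["latents"] = latents
    return case, r_lab


def generate_phantom(config: PhantomConfig, case_seed: int) -> PhantomCase:
    """One synthetic patient, voxel-deterministic for fixed (config, case_seed).

    The label is left unset; :func:`generate_cohort` assigns it from the
    outcome model.
    """
    return _build_case(config, case_seed)[0]


# ---------------------------------------------------------------------------
# Planted features
# ---------------------------------------------------------------------------

_GLCM_RE = re.compile(r"^original_glcm_([A-Za-z]+)_bin(\d+)$")
_FO_RE = re.compile(r"^original_firstorder_([A-Za-z0-9]+)$")
_MOM_RE = re.compile(r"^dose_moment_eta_(\d)(\d)(\d)$")


def _planted_from_volumes(ct: VolumeGrid, dose: VolumeGrid, mask: VolumeGrid,
                          names: Sequence[str]) -> dict[str, float]:
    refined = refine_mask_by_hu(ct, mask, HU_WINDOW)
    m = refined.values > 0
    out: dict[str, float] = {}
    moments: dict[str, float] | None = None
    for name in names:
        if (match := _GLCM_RE.match(name)):
            feat, nbins = match.group(1), int(match.group(2))
            labels = np.zeros(ct.shape, dtype=np.int64)
            labels[m] = _rad.discretize(np.asarray(ct.values, dtype=float)[m], nbins)
            out[name] = _rad.glcm_features(labels, m)[feat]
        elif (match := _FO_RE.match(name)):
            out[name] = _rad.first_order_features(np.asarray(ct.values, dtype=float)[m])[match.group(1)]
        elif _MOM_RE.match(name):
            if moments is None:
                moments = _dos.dose_moments(dose, refined)
            out[name] = moments[name.removeprefix("dose_")]
        else:
            raise KeyError(f"unsupported planted feature {name!r}")
    return out


def compute_planted_features(case: PhantomCase, names: Sequence[str]) -> dict[str, float]:
    """Planted feature values of one case, via the same operators and HU-window
    refinement the extraction pipeline applies."""
    return _planted_from_volumes(case.ct, case.dose, case.mask, names)


def _planted_values_fast(config: PhantomConfig, case_seed: int,
                         names: Sequence[str]):
    """Bounding-box path: identical values to the full case at a fraction of
    the cost.  Returns (values, clinical, label_rng)."""
    geom = _geometry(config)
    ct_block, dose_block, clinical, _, r_lab = _case_blocks(config, case_seed)
    sp = config.spacing_mm
    origin = geom["block_origin_mm"]
    ct = VolumeGrid(ct_block, sp, origin)
    dose = VolumeGrid(dose_block, sp, origin)
    mask = VolumeGrid(geom["mask_block"].astype(np.uint8), sp, origin)
    return _planted_from_volumes(ct, dose, mask, names), clinical, r_lab


# ---------------------------------------------------------------------------
# Outcome calibration and cohort generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Calibration:
    """Intercept plus the standardization statistics of the planted features,
    estimated on a Monte-Carlo sample."""

    intercept: float
    feature_names: tuple[str, ...]
    means: tuple[float, ...]
    sds: tuple[float, ...]
    target_prevalence: float

    def linear_predictor(self, values: Mapping[str, float],
                         coefficients: Mapping[str, float]) -> float:
        lp = self.intercept
        for name, mean, sd in zip(self.feature_names, self.means, self.sds):
            lp += coefficients[name] * (values[name] - mean) / sd
        return lp


_CALIBRATION_COUNTER = 982_451_653  # counter namespace for calibration seeds


def calibrate_intercept(
    config: PhantomConfig,
    target_prevalence: float | None = None,
    n_mc: int = 2000,
    seed: int | None = None,
) -> Calibration:
    """Root-find the logistic intercept so the Monte-Carlo event prevalence
    matches the target.

    With no planted effects the closed form ``logit(target)`` is returned.
    Otherwise planted features are measured on ``n_mc`` simulated cases,
    standardized, and the intercept solved by bisection (Brent) on the mean
    predicted probability.
    """
    target = (config.outcome_model.target_prevalence
              if target_prevalence is None else float(target_prevalence))
    if not 0.0 < target < 1.0:
        raise CalibrationError(f"target prevalence {target} is not in (0, 1)")
    om = config.outcome_model
    if not om.has_effects:
        return Calibration(float(logit(target)), (), (), (), target)
    if n_mc < 1000:
        raise ValueError("calibration requires n_mc >= 1000")
    seed = config.seed if seed is None else seed
    names = tuple(om.planted_dict)
    coefs = np.array([om.planted_dict[n] for n in names])
    values = np.empty((n_mc, len(names)))
    for i in range(n_mc):
        cs = _case_seed(seed, _CALIBRATION_COUNTER + i)
        vals, _, _ = _planted_values_fast(config, cs, names)
        values[i] = [vals[n] for n in names]
    means = values.mean(axis=0)
    sds = values.std(axis=0, ddof=1)
    if np.any(sds <= 0):
        raise CalibrationError("a planted feature has zero Monte-Carlo variance")
    lp = (values - means) / sds @ coefs

    def gap(c: float) -> float:
        return float(np.mean(expit(c + lp))) - target

    lo, hi = -40.0, 40.0
    if gap(lo) > 0 or gap(hi) < 0:
        raise CalibrationError("intercept interval does not bracket the target prevalence")
    intercept = float(optimize.brentq(gap, lo, hi, xtol=1e-10))
    return Calibration(intercept, names, tuple(means), tuple(sds), target)


@dataclass
class Cohort:
    """A generated patient cohort with outcome labels."""

    config: PhantomConfig
    cases: list[PhantomCase]
    labels: np.ndarray
    calibration: Calibration

    @property
    def n_patients(self) -> int:
        return len(self.cases)

    @property
    def prevalence(self) -> float:
        return float(self.labels.mean())

    @property
    def clinical_frame(self) -> pd.DataFrame:
        rows = []
        for case, label in zip(self.cases, self.labels):
            row = {k: v for k, v in case.clinical.items() if k != "latents"}
            row["label"] = int(label)
            rows.append(row)
        return pd.DataFrame(rows)


def _draw_label(config: PhantomConfig, calibration: Calibration,
                values: Mapping[str, float], r_lab: np.random.Generator) -> int:
    om = config.outcome_model
    if om.has_effects:
        p = float(expit(calibration.linear_predictor(values, om.planted_dict)))
    else:
        p = float(expit(calibration.intercept))
    return int(r_lab.random() < p)


def generate_cohort(
    config: PhantomConfig,
    calibration: Calibration | None = None,
    n_mc: int = 2000,
    labels_only: bool = False,
) -> Cohort:
    """Generate ``config.n_patients`` cases with logistic outcome labels.

    ``labels_only`` skips full-volume assembly (labels and clinical data are
    unchanged); used for prevalence checks at scale.
    """
    om = config.outcome_model
    if calibration is None:
        if om.intercept is not None and not om.has_effects:
            calibration = Calibration(om.intercept, (), (), (), om.target_prevalence)
        else:
            calibration = calibrate_intercept(config, n_mc=n_mc)
            if om.intercept is not None:  # explicit intercept, MC standardization
                calibration = replace(calibration, intercept=om.intercept)
    names = tuple(om.planted_dict)
    cases: list[PhantomCase] = []
    labels = np.empty(config.n_patients, dtype=np.int64)
    for i in range(config.n_patients):
        cs = _case_seed(config.seed, i)
        if labels_only:
            values, clinical, r_lab = _planted_values_fast(config, cs, names)
            labels[i] = _draw_label(config, calibration, values, r_lab)
        else:
            case, r_lab = _build_case(config, cs)
            values = compute_planted_features(case, names) if names else {}
            case.label = _draw_label(config, calibration, values, r_lab)
            labels[i] = case.label
            cases.append(case)
    if labels_only:
        return Cohort(config, [], labels, calibration)
    return Cohort(config, cases, labels, calibration)
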