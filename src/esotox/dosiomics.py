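"""Dosiomics: scale-invariant 3D dose moments, DVH Vx/Dx metrics, and
original-image dose texture inside the esophagus mask.

The moment block uses central geometric moments of the dose field in
physical coordinates, volume-element weighted,

    mu_pqr = sum_v (x-cx)^p (y-cy)^q (z-cz)^r D(v) dV,

about the dose-weighted centroid ``c``, normalized to

    eta_pqr = mu_pqr / mu_000^(1 + (p+q+r)/3),

the 3D analogue of the classical 2D moment invariants.  eta is invariant
under spatial rescaling of the dose field (and hence, to discretization
error, under grid resampling); under dose rescaling ``D -> kD`` it transforms
exactly as ``eta -> k^(-(p+q+r)/3) eta``.  Orders 0..3 per axis give 64 index
combinations; (0,0,0) is identically 1 and excluded, leaving 63 features.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np

from .radiomics import first_order_features, texture_features_for_variant
from .volume import EmptyMaskError, VolumeGrid

__all__ = [
    "MOMENT_ORDER",
    "DosiomicsConfig",
    "DVHCurve",
    "VxResult",
    "UndefinedCentroidError",
    "moment_indices",
    "dose_moments",
    "dvh",
    "vx",
    "dx",
    "dose_texture",
    "extract_dosiomics",
    "expected_dosiomics_count",
]

MOMENT_ORDER = 3


class UndefinedCentroidError(ValueError):
    """Zero total in-mask dose: the dose-weighted centroid is undefined."""


def moment_indices(order: int = MOMENT_ORDER) -> list[tuple[int, int, int]]:
    """All (p, q, r) with each order in 0..order, excluding (0, 0, 0)."""
    return [
        (p, q, r)
        for p in range(order + 1)
        for q in range(order + 1)
        for r in range(order + 1)
        if (p, q, r) != (0, 0, 0)
    ]


def dose_moments(dose: VolumeGrid, mask: VolumeGrid) -> dict[str, float]:
    """The 63 scale-invariant moments ``eta_pqr`` of the in-mask dose field."""
    dose.require_same_geometry(mask, "dose and mask")
    m = mask.values > 0
    if not m.any():
        raise EmptyMaskError("dose moments require a non-empty mask")
    d = np.asarray(dose.values, dtype=float)[m]
    if np.any(d < 0):
        raise ValueError("dose must be non-negative")
    total = d.sum()
    if total <= 0:
        raise UndefinedCentroidError("total in-mask dose is zero")
    coords = np.argwhere(m).astype(float)
    for ax in range(3):
        coords[:, ax] = coords[:, ax] * dose.spacing_mm[ax] + dose.origin_mm[ax]
    centroid = (coords * d[:, None]).sum(axis=0) / total
    rel = coords - centroid
    dv = dose.voxel_volume_mm3
    # powers 0..3 per axis, computed once
    pows = [np.stack([np.ones_like(rel[:, ax]), rel[:, ax], rel[:, ax] ** 2, rel[:, ax] ** 3])
            for ax in range(3)]
    mu000 = total * dv
    out: dict[str, float] = {}
    for p, q, r in moment_indices():
        mu = float((pows[0][p] * pows[1][q] * pows[2][r] * d).sum() * dv)
        eta = mu / mu000 ** (1.0 + (p + q + r) / 3.0)
        out[f"moment_eta_{p}{q}{r}"] = eta
    return out


class VxResult(NamedTuple):
    pct: float
    cc: float


@dataclass(frozen=True)
class DVHCurve:
    """Cumulative dose-volume histogram of the in-mask dose.

    ``volume_cc[i]`` / ``volume_pct[i]`` is the absolute / relative volume
    receiving a dose strictly greater than ``dose_gy[i]``.  The exact sorted
    in-mask dose sample is retained so Vx/Dx queries interpolate on the data
    rather than on the binned curve.
    """

    dose_gy: np.ndarray
    volume_cc: np.ndarray
    volume_pct: np.ndarray
    sorted_doses: np.ndarray
    voxel_volume_mm3: float

    @property
    def total_cc(self) -> float:
        return len(self.sorted_doses) * self.voxel_volume_mm3 / 1000.0

    @property
    def min_dose(self) -> float:
        return float(self.sorted_doses[0])

    @property
    def max_dose(self) -> float:
        return float(self.sorted_doses[-1])

    def to_csv(self, path) -> None:
        """Two-column export: dose (Gy), cumulative volume (cc)."""
        import pandas as pd

        pd.DataFrame({"dose_gy": self.dose_gy,
                      "volume_cc": self.volume_cc}).to_csv(path, index=False)


def dvh(dose: VolumeGrid, mask: VolumeGrid, bin_gy: float = 0.01) -> DVHCurve:
    """Cumulative DVH with dose grid step ``bin_gy``; volume in cc is voxel
    count x voxel volume."""
    dose.require_same_geometry(mask, "dose and mask")
    m = mask.values > 0
    if not m.any():
        raise EmptyMaskError("DVH requires a non-empty mask")
    if bin_gy <= 0:
        raise ValueError("bin_gy must be positive")
    doses = np.sort(np.asarray(dose.values, dtype=float)[m])
    n = doses.size
    grid = np.arange(0.0, doses[-1] + 2 * bin_gy, bin_gy)
    # volume receiving a dose strictly larger than each grid value
    above = n - np.searchsorted(doses, grid, side="right")
    cc = above * dose.voxel_volume_mm3 / 1000.0
    return DVHCurve(
        dose_gy=grid,
        volume_cc=cc,
        volume_pct=100.0 * above / n,
        sorted_doses=doses,
        voxel_volume_mm3=dose.voxel_volume_mm3,
    )


def vx(curve: DVHCurve, x_gy: float) -> VxResult:
    """Volume (% and cc) receiving a dose larger than ``x_gy``."""
    n = curve.sorted_doses.size
    above = n - np.searchsorted(curve.sorted_doses, x_gy, side="right")
    frac = above / n
    return VxResult(pct=100.0 * frac, cc=frac * curve.total_cc)


def dx(curve: DVHCurve, x_percent: float) -> float:
    """Dose (Gy) received by the hottest ``x_percent`` of the volume.

    Inverse DVH query with linear interpolation on the dose sample:
    ``dx(100)`` is the minimum in-mask dose, ``dx(0)`` the maximum.
    """
    if not 0.0 <= x_percent <= 100.0:
        raise ValueError("x_percent must be in [0, 100]")
    return float(np.quantile(curve.sorted_doses, 1.0 - x_percent / 100.0))


def dose_texture(
    dose: VolumeGrid,
    mask: VolumeGrid,
    bin_count: int,
    families: Iterable[str] = ("GLCM", "GLRLM"),
) -> dict[str, float]:
    """First-order + texture features of the dose grid (original image only),
    reusing the radiomics operators."""
    dose.require_same_geometry(mask, "dose and mask")
    m = mask.values > 0
    if not m.any():
        raise EmptyMaskError("dose texture requires a non-empty mask")
    in_mask = np.asarray(dose.values, dtype=float)[m]
    out = {f"firstorder_{k}": v for k, v in first_order_features(in_mask).items()}
    out.update(texture_features_for_variant(np.asarray(dose.values, dtype=float), m, bin_count, tuple(families)))
    return out


# Default DVH query grids: Vx thresholds in Gy include the sub-Gy 0.99 level;
# Dx queries in % volume.
DEFAULT_VX_GY = (0.99, 1.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0, 35.0,
                 40.0, 45.0, 50.0, 55.0, 60.0, 65.0, 70.0)
DEFAULT_DX_PCT = (2.0, 5.0, 50.0, 95.0, 98.0)


@dataclass(frozen=True)
class DosiomicsConfig:
    """Dosiomics extraction profile.

    ``v099_interpretation`` selects the reading of the sub-unity V query:
    ``"gy"`` treats 0.99 as an absolute dose threshold in Gy; ``"relative"``
    treats it as a fraction of the maximum in-mask dose.
    """

    vx_grid_gy: tuple[float, ...] = DEFAULT_VX_GY
    dx_grid_pct: tuple[float, ...] = DEFAULT_DX_PCT
    texture_bin_counts: tuple[int, ...] = (20, 50)
    texture_families: tuple[str, ...] = ("GLCM", "GLRLM")
    v099_interpretation: str = "gy"

    def __post_init__(self) -> None:
        if self.v099_interpretation not in ("gy", "relative"):
            raise ValueError("v099_interpretation must be 'gy' or 'relative'")
        if any(not 0 <= p <= 100 for p in self.dx_grid_pct):
            raise ValueError("Dx grid must lie in [0, 100] %")

    @classmethod
    def fast(cls) -> "DosiomicsConfig":
        """Reduced profile for large simulated cohorts (GLCM-only texture)."""
        return cls(texture_bin_counts=(20,), texture_families=("GLCM",))


def extract_dosiomics(
    dose: VolumeGrid,
    mask: VolumeGrid,
    config: DosiomicsConfig | None = None,
) -> dict[str, float]:
    """Concatenated dosiomics vector: 63 moments + Vx/Dx grid + dose texture.

    All names carry the ``dose_`` prefix so they can never collide with CT
    radiomics features.
    """
    config = config or DosiomicsConfig()
    features: dict[str, float] = {}
    for k, v in dose_moments(dose, mask).items():
        features[f"dose_{k}"] = v
    curve = dvh(dose, mask)
    for x in config.vx_grid_gy:
        threshold = x
        if x < 1.0 and config.v099_interpretation == "relative":
            threshold = x * curve.max_dose
        res = vx(curve, threshold)
        features[f"dose_dvh_V{x:g}Gy_pct"] = res.pct
        features[f"dose_dvh_V{x:g}Gy_cc"] = res.cc
    for p in config.dx_grid_pct:
        features[f"dose_dvh_D{p:g}pct_Gy"] = dx(curve, p)
    for b in config.texture_bin_counts:
        for k, v in dose_texture(dose, mask, b, config.texture_families).items():
            # first-order stats are bin-independent; emit them once
            if k.startswith("firstorder_") and "bin" not in k:
                features.setdefault(f"dose_{k}", v)
            else:
                features[f"dose_{k}"] = v
    bad = [k for k, v in features.items() if not np.isfinite(v)]
    if bad:
        raise ValueError(f"non-finite dosiomics features: {bad[:5]}")
    return features


def expected_dosiomics_count(config: DosiomicsConfig | None = None) -> int:
    """Config-derived dosiomics feature count:

    ``63 moments + 2*|Vx grid| + |Dx grid| + 12 first-order
    + |texture bins| * (1 entropy + 6 GLCM? + 7 GLRLM?)``
    """
    config = config or DosiomicsConfig()
    per_bin = 1
    if "GLCM" in config.texture_families:
        per_bin += 6
    if "GLRLM" in config.texture_families:
        per_bin += 7
    return (
        63
        + 2 * len(config.vx_grid_gy)
        + len(config.dx_grid_pct)
        + 12
        + len(config.texture_bin_counts) * per_bin
    )
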