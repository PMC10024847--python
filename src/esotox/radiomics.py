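"""CT radiomics inside a region of interest: first-order and texture features.

Implements intensity discretization at fixed bin *count*, first-order
statistics, gray-level co-occurrence (GLCM) and run-length (GLRLM) texture
over the 13 unique 3D direction offsets, and single-level wavelet /
Laplacian-of-Gaussian image filters.  Feature names are stable and encode
``{variant}_{family}_{Feature}[_bin{n}]`` (e.g. ``wavelet-LLH_glcm_Contrast_bin50``).

Conventions follow the IBSI definitions: GLCM offsets are merged into one
symmetric matrix before normalization; GLRLM features are computed per
direction and averaged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pywt
from scipy import ndimage, stats

from .volume import VolumeGrid

__all__ = [
    "RadiomicsConfig",
    "TextureUndefinedError",
    "OFFSETS_3D",
    "discretize",
    "first_order_features",
    "glcm_matrix",
    "glcm_features",
    "glrlm_matrix",
    "glrlm_features",
    "wavelet_bands",
    "log_filter",
    "extract_radiomics",
    "expected_feature_count",
]

PAPER_BIN_COUNTS = (20, 30, 40, 50, 80, 100, 150, 200, 250, 300)

# 13 unique direction offsets of the 26-neighbourhood (one per +/- pair).
OFFSETS_3D: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)
assert len(OFFSETS_3D) == 13

GLCM_FEATURES = ("Contrast", "Correlation", "JointEntropy", "Idm", "Energy", "Dissimilarity")
GLRLM_FEATURES = ("Sre", "Lre", "Gln", "Rln", "Rp", "Lglre", "Hglre")
FIRST_ORDER_FEATURES = (
    "Mean", "Median", "Variance", "Skewness", "Kurtosis", "Energy",
    "Minimum", "Maximum", "Range", "Percentile10", "Percentile90", "Iqr",
)


class TextureUndefinedError(ValueError):
    """Texture requested on a region too small to define co-occurrence."""


@dataclass(frozen=True)
class RadiomicsConfig:
    """Extraction profile: which bin counts, image filters and texture families.

    Defaults reproduce the study conditions: ten bin counts, original +
    wavelet + LoG image variants, GLCM and GLRLM texture.
    """

    bin_counts: tuple[int, ...] = PAPER_BIN_COUNTS
    image_filters: tuple[str, ...] = ("original", "wavelet", "log_sigma")
    log_sigmas_mm: tuple[float, ...] = (1.0, 2.0, 3.0)
    texture_families: tuple[str, ...] = ("GLCM", "GLRLM")
    wavelet: str = "coif1"

    def __post_init__(self) -> None:
        if any(int(b) < 2 for b in self.bin_counts):
            raise ValueError("bin counts must be >= 2")
        if any(s <= 0 for s in self.log_sigmas_mm):
            raise ValueError("LoG sigmas must be positive")
        unknown = set(self.image_filters) - {"original", "wavelet", "log_sigma"}
        if unknown:
            raise ValueError(f"unknown image filters: {sorted(unknown)}")
        for fam in self.texture_families:
            if fam in ("GLSZM", "NGTDM"):
                raise NotImplementedError(f"texture family {fam} is not implemented")
            if fam not in ("GLCM", "GLRLM"):
                raise ValueError(f"unknown texture family {fam!r}")

    @classmethod
    def fast(cls) -> "RadiomicsConfig":
        """Reduced profile for large simulated cohorts (original image, two
        bin counts, GLCM only)."""
        return cls(bin_counts=(20, 50), image_filters=("original",),
                   texture_families=("GLCM",))


def discretize(values: np.ndarray, bin_count: int) -> np.ndarray:
    """Map intensities to integer bin labels 1..bin_count.

    Equal-width bins over the [min, max] of the supplied values; the maximum
    maps into the top bin, a constant region maps entirely to bin 1.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot discretize an empty value set")
    bin_count = int(bin_count)
    if bin_count < 2:
        raise ValueError("bin_count must be >= 2")
    vmin, vmax = float(values.min()), float(values.max())
    if vmax == vmin:
        return np.ones(values.shape, dtype=np.int64)
    labels = np.floor((values - vmin) / (vmax - vmin) * bin_count).astype(np.int64) + 1
    return np.clip(labels, 1, bin_count)


def first_order_features(values: np.ndarray) -> dict[str, float]:
    """First-order intensity statistics of the masked voxel values.

    Skewness and kurtosis are the standardized moment estimates (kurtosis
    non-excess, i.e. 3 for a normal distribution); both are defined as 0 for
    a constant region.  Discretized entropy is reported separately by
    :func:`entropy_feature` because it depends on the bin count.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("first-order features require at least one voxel")
    var = float(v.var())
    constant = var == 0.0
    return {
        "Mean": float(v.mean()),
        "Median": float(np.median(v)),
        "Variance": var,
        "Skewness": 0.0 if constant else float(stats.skew(v, bias=True)),
        "Kurtosis": 0.0 if constant else float(stats.kurtosis(v, bias=True, fisher=False)),
        "Energy": float(np.sum(v * v)),
        "Minimum": float(v.min()),
        "Maximum": float(v.max()),
        "Range": float(v.max() - v.min()),
        "Percentile10": float(np.percentile(v, 10)),
        "Percentile90": float(np.percentile(v, 90)),
        "Iqr": float(np.percentile(v, 75) - np.percentile(v, 25)),
    }


def entropy_feature(values: np.ndarray, bin_count: int) -> float:
    """Shannon entropy (bits) of the discretized intensity histogram.

    0 for a constant region (single occupied bin)."""
    labels = discretize(values, bin_count)
    p = np.bincount(labels)[1:].astype(float)
    p = p[p > 0]
    p /= p.sum()
    return float(-(p * np.log2(p)).sum())


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def glcm_matrix(
    bins: np.ndarray,
    mask: np.ndarray,
    distance: int = 1,
    offsets: Iterable[tuple[int, int, int]] = OFFSETS_3D,
) -> np.ndarray:
    """Normalized symmetric co-occurrence matrix over 3D direction offsets.

    Counts from all offsets (and both orientations of each) are accumulated
    into a single matrix and normalized to sum to 1.
    """
    bins = np.asarray(bins)
    mask = np.asarray(mask, dtype=bool)
    if bins.shape != mask.shape:
        raise ValueError("bins and mask shapes differ")
    if int(mask.sum()) < 2:
        raise TextureUndefinedError("GLCM requires at least two in-mask voxels")
    nb = int(bins[mask].max())
    counts = np.zeros((nb, nb), dtype=np.int64)
    for off in offsets:
        off = tuple(int(distance) * o for o in off)
        src, dst, msrc, mdst = _shifted_views(bins, mask, off)
        valid = msrc & mdst
        if not valid.any():
            continue
        i = src[valid] - 1
        j = dst[valid] - 1
        flat = np.bincount(i * nb + j, minlength=nb * nb).reshape(nb, nb)
        counts += flat + flat.T  # symmetric accumulation
    total = counts.sum()
    if total == 0:
        raise TextureUndefinedError("no in-mask voxel pairs at the requested distance")
    return counts / total


def _shifted_views(bins, mask, off):
    slabs_src, slabs_dst = [], []
    for o, n in zip(off, bins.shape):
        if o >= 0:
            slabs_src.append(slice(0, n - o))
            slabs_dst.append(slice(o, n))
        else:
            slabs_src.append(slice(-o, n))
            slabs_dst.append(slice(0, n + o))
    src = bins[tuple(slabs_src)]
    dst = bins[tuple(slabs_dst)]
    return src, dst, mask[tuple(slabs_src)], mask[tuple(slabs_dst)]


def glcm_features(
    bins: np.ndarray,
    mask: np.ndarray,
    distance: int = 1,
    offsets: Iterable[tuple[int, int, int]] = OFFSETS_3D,
) -> dict[str, float]:
    """Contrast, correlation, joint entropy, inverse difference moment,
    energy and dissimilarity from the merged co-occurrence matrix."""
    p = glcm_matrix(bins, mask, distance, offsets)
    nb = p.shape[0]
    i = np.arange(1, nb + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    diff = ii - jj
    px = p.sum(axis=1)
    mu = float((i * px).sum())
    sigma2 = float(((i - mu) ** 2 * px).sum())
    contrast = float((p * diff**2).sum())
    if sigma2 > 0:
        correlation = float(((ii - mu) * (jj - mu) * p).sum() / sigma2)
    else:
        correlation = 1.0  # degenerate single-level region
    pz = p[p > 0]
    return {
        "Contrast": contrast,
        "Correlation": correlation,
        "JointEntropy": float(-(pz * np.log2(pz)).sum()),
        "Idm": float((p / (1.0 + diff**2)).sum()),
        "Energy": float((p * p).sum()),
        "Dissimilarity": float((p * np.abs(diff)).sum()),
    }


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

def glrlm_matrix(
    bins: np.ndarray,
    mask: np.ndarray,
    direction: tuple[int, int, int],
) -> np.ndarray:
    """Run-length matrix ``R[g-1, l-1]`` for one direction.

    A run is a maximal sequence of in-mask voxels of equal bin label along
    lines in ``direction``; out-of-mask voxels break runs.
    """
    bins = np.asarray(bins)
    mask = np.asarray(mask, dtype=bool)
    if bins.shape != mask.shape:
        raise ValueError("bins and mask shapes differ")
    if not mask.any():
        raise TextureUndefinedError("GLRLM requires a non-empty mask")
    coords = np.argwhere(mask)
    vals = bins[mask]
    d = np.asarray(direction, dtype=np.int64)
    if not d.any():
        raise ValueError("direction must be non-zero")
    # Parameter t orders voxels along a line; (coords - t*d) is constant on it.
    axis = int(np.nonzero(d)[0][0])
    t = coords[:, axis] * int(np.sign(d[axis]))
    key = coords - t[:, None] * d
    order = np.lexsort((t, key[:, 2], key[:, 1], key[:, 0]))
    t_s, key_s, val_s = t[order], key[order], vals[order]
    same_line = np.all(key_s[1:] == key_s[:-1], axis=1) & (t_s[1:] == t_s[:-1] + 1)
    start = np.ones(len(t_s), dtype=bool)
    start[1:] = ~(same_line & (val_s[1:] == val_s[:-1]))
    starts = np.flatnonzero(start)
    lengths = np.diff(np.append(starts, len(t_s)))
    levels = val_s[starts]
    nb = int(vals.max())
    lmax = int(lengths.max())
    matrix = np.zeros((nb, lmax), dtype=np.int64)
    np.add.at(matrix, (levels - 1, lengths - 1), 1)
    return matrix


def _glrlm_features_from_matrix(matrix: np.ndarray, n_voxels: int) -> dict[str, float]:
    r = matrix.astype(float)
    nr = r.sum()
    g = np.arange(1, r.shape[0] + 1, dtype=float)
    l = np.arange(1, r.shape[1] + 1, dtype=float)
    rg = r.sum(axis=1)  # per gray level
    rl = r.sum(axis=0)  # per run length
    return {
        "Sre": float((rl / l**2).sum() / nr),
        "Lre": float((rl * l**2).sum() / nr),
        "Gln": float((rg**2).sum() / nr),
        "Rln": float((rl**2).sum() / nr),
        "Rp": float(nr / n_voxels),
        "Lglre": float((rg / g**2).sum() / nr),
        "Hglre": float((rg * g**2).sum() / nr),
    }


def glrlm_features(
    bins: np.ndarray,
    mask: np.ndarray,
    directions: Iterable[tuple[int, int, int]] = OFFSETS_3D,
) -> dict[str, float]:
    """Run-length features averaged over the 13 unique 3D directions.

    SRE/LRE: short/long-run emphasis; GLN/RLN: gray-level / run-length
    non-uniformity; RP: run percentage; LGLRE/HGLRE: low/high gray-level
    run emphasis.
    """
    mask = np.asarray(mask, dtype=bool)
    n_vox = int(mask.sum())
    if n_vox < 2:
        raise TextureUndefinedError("GLRLM requires at least two in-mask voxels")
    acc: dict[str, float] = {k: 0.0 for k in GLRLM_FEATURES}
    directions = tuple(directions)
    for d in directions:
        feats = _glrlm_features_from_matrix(glrlm_matrix(bins, mask, d), n_vox)
        for k, v in feats.items():
            acc[k] += v
    return {k: v / len(directions) for k, v in acc.items()}


# ---------------------------------------------------------------------------
# Image filters
# ---------------------------------------------------------------------------

_BAND_LETTER = {"a": "L", "d": "H"}


def wavelet_bands(volume: VolumeGrid, wavelet: str = "coif1") -> dict[str, VolumeGrid]:
    """Single-level separable 3D wavelet decomposition as 8 band volumes.

    Each band is reconstructed back to the original grid (all other bands
    zeroed), so masks apply unchanged.  Band names use L (low-pass) / H
    (high-pass) per axis in (x, y, z) order: LLL ... HHH.
    """
    v = np.asarray(volume.values, dtype=float)
    if min(v.shape) < 2:
        raise ValueError("volume too small for a wavelet decomposition")
    coeffs = pywt.dwtn(v, wavelet, mode="periodization")
    out: dict[str, VolumeGrid] = {}
    for key in coeffs:
        single = {k: (c if k == key else np.zeros_like(c)) for k, c in coeffs.items()}
        rec = pywt.idwtn(single, wavelet, mode="periodization")
        rec = rec[tuple(slice(0, n) for n in v.shape)]
        name = "".join(_BAND_LETTER[ch] for ch in key)
        out[name] = VolumeGrid(rec, volume.spacing_mm, volume.origin_mm)
    return out


def log_filter(volume: VolumeGrid, sigma_mm: float) -> VolumeGrid:
    """Laplacian-of-Gaussian response at physical scale ``sigma_mm``."""
    if sigma_mm <= 0:
        raise ValueError("sigma must be positive")
    sigma_vox = [sigma_mm / s for s in volume.spacing_mm]
    if min(volume.shape) < 4:
        raise ValueError("volume too small for the LoG filter support")
    v = np.asarray(volume.values, dtype=float)
    # filter the mean-free field: the truncated kernel has a small non-zero
    # sum, which would otherwise leak a DC bias proportional to the mean
    out = ndimage.gaussian_laplace(v - v.mean(), sigma=sigma_vox)
    return VolumeGrid(out, volume.spacing_mm, volume.origin_mm)


# ---------------------------------------------------------------------------
# Full extraction
# ---------------------------------------------------------------------------

def _image_variants(ct: VolumeGrid, config: RadiomicsConfig) -> dict[str, VolumeGrid]:
    variants: dict[str, VolumeGrid] = {}
    if "original" in config.image_filters:
        variants["original"] = ct
    if "wavelet" in config.image_filters:
        for name, band in wavelet_bands(ct, config.wavelet).items():
            variants[f"wavelet-{name}"] = band
    if "log_sigma" in config.image_filters:
        for s in config.log_sigmas_mm:
            variants[f"log-sigma-{s:g}mm"] = log_filter(ct, s)
    return variants


def texture_features_for_variant(
    values: np.ndarray,
    mask: np.ndarray,
    bin_count: int,
    families: Iterable[str],
) -> dict[str, float]:
    """Entropy + selected texture families at one bin count (shared with the
    dose-grid extractor)."""
    in_mask = values[mask]
    labels = np.zeros(values.shape, dtype=np.int64)
    labels[mask] = discretize(in_mask, bin_count)
    out: dict[str, float] = {f"firstorder_Entropy_bin{bin_count}": entropy_feature(in_mask, bin_count)}
    if "GLCM" in families:
        for k, v in glcm_features(labels, mask).items():
            out[f"glcm_{k}_bin{bin_count}"] = v
    if "GLRLM" in families:
        for k, v in glrlm_features(labels, mask).items():
            out[f"glrlm_{k}_bin{bin_count}"] = v
    return out


def extract_radiomics(
    ct: VolumeGrid,
    mask: VolumeGrid,
    config: RadiomicsConfig | None = None,
) -> dict[str, float]:
    """Full radiomics vector: filters x bin counts x texture families plus
    per-variant first-order statistics.  Deterministic and name-stable."""
    config = config or RadiomicsConfig()
    ct.require_same_geometry(mask, "CT and mask")
    m = mask.values > 0
    if not m.any():
        raise ValueError("refined mask is empty")
    features: dict[str, float] = {}
    for vname, variant in _image_variants(ct, config).items():
        in_mask = variant.values[m]
        try:
            for k, v in first_order_features(in_mask).items():
                features[f"{vname}_firstorder_{k}"] = v
            for b in config.bin_counts:
                for k, v in texture_features_for_variant(variant.values, m, b, config.texture_families).items():
                    features[f"{vname}_{k}"] = v
        except (ValueError, TextureUndefinedError) as exc:
            raise type(exc)(f"variant {vname!r}: {exc}") from exc
    bad = [k for k, v in features.items() if not np.isfinite(v)]
    if bad:
        raise ValueError(f"non-finite radiomics features: {bad[:5]}")
    return features


def expected_feature_count(config: RadiomicsConfig) -> int:
    """Config-derived radiomics feature count (documented formula):

    ``variants * (12 first-order + bins * (1 entropy + 6 GLCM? + 7 GLRLM?))``
    """
    n_variants = 0
    if "original" in config.image_filters:
        n_variants += 1
    if "wavelet" in config.image_filters:
        n_variants += 8
    if "log_sigma" in config.image_filters:
        n_variants += len(config.log_sigmas_mm)
    per_bin = 1  # entropy
    if "GLCM" in config.texture_families:
        per_bin += len(GLCM_FEATURES)
    if "GLRLM" in config.texture_families:
        per_bin += len(GLRLM_FEATURES)
    return n_variants * (len(FIRST_ORDER_FEATURES) + len(config.bin_counts) * per_bin)
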