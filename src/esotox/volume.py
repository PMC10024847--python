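"""Volumetric grids: I/O, isotropic resampling, and HU-window mask refinement.

A :class:`VolumeGrid` is a 3D scalar field on a regular grid with physical
spacing (mm) and origin.  Axis order is ``(x, y, z)`` with ``z`` the slice
axis; SimpleITK's native ``(z, y, x)`` array layout is transposed at the I/O
boundary.  The same container carries CT intensities (HU), dose (Gy) or
binary masks (0/1, stored as uint8 on disk).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import SimpleITK as sitk

__all__ = [
    "VolumeGrid",
    "GeometryError",
    "FormatError",
    "EmptyMaskError",
    "read_volume",
    "write_volume",
    "resample_isotropic",
    "refine_mask_by_hu",
]


class GeometryError(ValueError):
    """Grids do not share geometry, or an object does not fit the grid."""


class FormatError(ValueError):
    """Unsupported or malformed volume file."""


class EmptyMaskError(ValueError):
    """A mask contains no voxels where at least one is required."""


_SUFFIXES = {".nrrd": "NRRD", ".nii": "NIfTI", ".nii.gz": "NIfTI"}


@dataclass
class VolumeGrid:
    """3D scalar array with voxel spacing and origin in mm, axes ``(x, y, z)``."""

    values: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise GeometryError(f"expected a 3D array, got ndim={self.values.ndim}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise GeometryError(f"spacing must be three positive values, got {self.spacing_mm}")
        if np.issubdtype(self.values.dtype, np.floating) and not np.all(np.isfinite(self.values)):
            raise GeometryError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        """Physical edge lengths of the grid (voxel-count x spacing)."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing_mm))  # type: ignore[return-value]

    def same_geometry(self, other: "VolumeGrid", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and all(abs(a - b) <= tol for a, b in zip(self.spacing_mm, other.spacing_mm))
            and all(abs(a - b) <= tol for a, b in zip(self.origin_mm, other.origin_mm))
        )

    def require_same_geometry(self, other: "VolumeGrid", what: str = "volumes") -> None:
        if not self.same_geometry(other):
            raise GeometryError(
                f"{what} do not share grid geometry: "
                f"{self.shape}/{self.spacing_mm} vs {other.shape}/{other.spacing_mm}"
            )

    def copy(self) -> "VolumeGrid":
        return replace(self, values=self.values.copy())


def _detect_format(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(".nii.gz"):
        return "NIfTI"
    suffix = path.suffix.lower()
    if suffix in _SUFFIXES:
        return _SUFFIXES[suffix]
    raise FormatError(
        f"{path}: unsupported volume extension {suffix!r} (expected .nrrd, .nii or .nii.gz)"
    )


def _to_sitk(volume: VolumeGrid) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(volume.values.transpose(2, 1, 0)))
    img.SetSpacing(volume.spacing_mm)
    img.SetOrigin(volume.origin_mm)
    return img


def _from_sitk(img: sitk.Image) -> VolumeGrid:
    values = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return VolumeGrid(values, tuple(img.GetSpacing()), tuple(img.GetOrigin()))


def read_volume(path: str | Path) -> VolumeGrid:
    """Read a NRRD or NIfTI volume; spacing is preserved to 1e-6 mm."""
    path = Path(path)
    fmt = _detect_format(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:  # malformed header
        raise FormatError(f"{path}: cannot be read as {fmt}: {exc}") from exc
    return _from_sitk(img)


def write_volume(volume: VolumeGrid, path: str | Path) -> Path:
    """Write to NRRD or NIfTI (format chosen by extension); round-trips exactly."""
    path = Path(path)
    _detect_format(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sitk.WriteImage(_to_sitk(volume), str(path))
    return path


def resample_isotropic(
    volume: VolumeGrid,
    target_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
    mode: str = "linear",
) -> VolumeGrid:
    """Resample onto an isotropic grid, preserving the physical extent.

    ``mode='nearest'`` is required for masks and guarantees a strictly binary
    result for binary input.  Resampling a grid that already has the target
    spacing is the identity.
    """
    target_mm = tuple(float(t) for t in target_mm)
    if any(t <= 0 for t in target_mm):
        raise GeometryError(f"target spacing must be positive, got {target_mm}")
    if volume.values.size == 0:
        raise GeometryError("cannot resample an empty volume")
    if mode not in ("linear", "nearest"):
        raise ValueError(f"mode must be 'linear' or 'nearest', got {mode!r}")
    if all(abs(s - t) < 1e-12 for s, t in zip(volume.spacing_mm, target_mm)):
        return volume.copy()  # identity grid

    new_size = [
        max(1, int(round(n * s / t)))
        for n, s, t in zip(volume.shape, volume.spacing_mm, target_mm)
    ]
    img = _to_sitk(volume)
    interp = sitk.sitkLinear if mode == "linear" else sitk.sitkNearestNeighbor
    out = sitk.Resample(
        img,
        new_size,
        sitk.Transform(),
        interp,
        img.GetOrigin(),
        target_mm,
        img.GetDirection(),
        0.0,
        img.GetPixelID(),
        True,  # clamp to the nearest edge voxel beyond the input support
    )
    result = _from_sitk(out)
    if mode == "nearest":
        uniq = np.unique(result.values)
        if not np.all(np.isin(uniq, np.unique(volume.values))):
            raise GeometryError("nearest-neighbour resampling produced unseen values")
    return result


def resample_like(
    volume: VolumeGrid,
    reference: VolumeGrid,
    mode: str = "linear",
) -> VolumeGrid:
    """Resample ``volume`` onto the grid of ``reference`` (used to enforce
    dose/CT co-registration before dosiomics)."""
    if volume.same_geometry(reference):
        return volume.copy()
    if mode not in ("linear", "nearest"):
        raise ValueError(f"mode must be 'linear' or 'nearest', got {mode!r}")
    img = _to_sitk(volume)
    ref = _to_sitk(reference)
    interp = sitk.sitkLinear if mode == "linear" else sitk.sitkNearestNeighbor
    out = sitk.Resample(img, ref, sitk.Transform(), interp, 0.0, img.GetPixelID())
    return _from_sitk(out)


def refine_mask_by_hu(
    ct: VolumeGrid,
    mask: VolumeGrid,
    hu_range: tuple[float, float] = (-150.0, 180.0),
) -> VolumeGrid:
    """Keep mask voxels whose HU lies inside the closed window ``hu_range``.

    Removes non-esophagus content such as air cavities (HU far below the soft
    tissue range) from the contoured volume before feature extraction.
    """
    ct.require_same_geometry(mask, "CT and mask")
    lo, hi = hu_range
    if lo > hi:
        raise ValueError(f"hu_range lower bound {lo} exceeds upper bound {hi}")
    keep = (mask.values > 0) & (ct.values >= lo) & (ct.values <= hi)
    if not keep.any():
        raise EmptyMaskError(
            f"HU window [{lo}, {hi}] leaves no voxels for feature extraction"
        )
    return VolumeGrid(keep.astype(np.uint8), mask.spacing_mm, mask.origin_mm)
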