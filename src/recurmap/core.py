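"""Volumetric data model and the low-level image operations shared by the pipeline.

Volumes live on axis-aligned grids: world coordinate = ``origin + index * spacing``
(0-based indices, millimetres).  Oblique NIfTI affines are reoriented to the
nearest canonical axes on read; shears are rejected.  All distances are physical
(mm between voxel centers), so anisotropic grids are handled by weighting each
axis with its spacing.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import nibabel as nib
import numpy as np
from scipy import ndimage

Modality = Literal["CT_HU", "PET_SUV"]
Interpolation = Literal["trilinear", "nearest"]

__all__ = [
    "GridSpec",
    "ImageVolume",
    "Mask",
    "DistanceMap",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "threshold_mask",
    "euclidean_distance_map",
    "resample_isotropic",
    "dilate_metric",
    "dice_score",
]


@dataclass(frozen=True)
class GridSpec:
    """Sampling lattice: voxel counts, physical spacing (mm) and world origin (mm)."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) < 1 for s in self.shape):
            raise ValueError(f"shape must be three integers >= 1, got {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive reals, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(s) for s in self.origin))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def world_coordinates(self, indices: np.ndarray) -> np.ndarray:
        """Map (n, 3) voxel indices to (n, 3) world coordinates in mm."""
        idx = np.asarray(indices, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff

    def is_compatible(self, other: "GridSpec", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )


@dataclass
class ImageVolume:
    """A 3D scalar field (CT in Hounsfield units or PET in SUV) on a grid."""

    grid: GridSpec
    values: np.ndarray
    modality: Modality = "PET_SUV"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("expected 3D volume")
        if tuple(self.values.shape) != self.grid.shape:
            raise ValueError(
                f"value array shape {self.values.shape} does not match grid {self.grid.shape}"
            )
        if self.modality == "PET_SUV" and np.nanmin(self.values) < -1e-9:
            raise ValueError("PET_SUV volumes must be nonnegative")


@dataclass
class Mask:
    """Binary region on a grid (GTV, bone, MTV, failure/responder volumes...)."""

    grid: GridSpec
    membership: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.membership = np.asarray(self.membership, dtype=bool)
        if tuple(self.membership.shape) != self.grid.shape:
            raise ValueError(
                f"mask shape {self.membership.shape} does not match grid {self.grid.shape}"
            )

    @property
    def count(self) -> int:
        return int(self.membership.sum())

    @property
    def volume_ml(self) -> float:
        """Region volume in millilitres (voxel count x voxel volume / 1000)."""
        return self.count * self.grid.voxel_volume_mm3 / 1000.0

    def indices(self) -> np.ndarray:
        """(n, 3) array of member voxel indices in C order."""
        return np.argwhere(self.membership)


@dataclass
class DistanceMap:
    """Per-voxel Euclidean distance (mm) to a source set; zero on the set itself."""

    grid: GridSpec
    distance: np.ndarray

    def __post_init__(self) -> None:
        self.distance = np.asarray(self.distance, dtype=np.float64)
        if tuple(self.distance.shape) != self.grid.shape:
            raise ValueError("distance array shape does not match grid")


# ---------------------------------------------------------------------------
# NIfTI I/O


def _grid_from_affine(affine: np.ndarray, shape: tuple[int, ...]) -> GridSpec:
    lin = affine[:3, :3]
    spacing = np.linalg.norm(lin, axis=0)
    if np.any(spacing <= 0) or not np.isfinite(spacing).all():
        raise ValueError("non-invertible affine: degenerate spacing")
    # Require (near-)axis-aligned direction cosines after canonical reorientation.
    cosines = lin / spacing
    if not np.allclose(np.abs(cosines), np.eye(3), atol=1e-3):
        raise ValueError("oblique affine remains after canonical reorientation")
    return GridSpec(shape=tuple(shape), spacing=tuple(spacing), origin=tuple(affine[:3, 3]))


def read_volume(path: str | Path, modality: Modality = "PET_SUV") -> ImageVolume:
    """Read a 3D NIfTI scalar volume.

    Spacing is taken from the affine's column norms, the origin from its
    translation.  Oblique volumes are reoriented to the closest canonical
    orientation; 4D files are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data)
    if data.ndim != 3:
        raise ValueError(f"expected 3D volume, got {data.ndim}D data in {path}")
    grid = _grid_from_affine(np.asarray(img.affine), data.shape)
    return ImageVolume(grid=grid, values=np.asarray(data, dtype=np.float64), modality=modality)


def write_volume(img: ImageVolume, path: str | Path) -> Path:
    """Write an ImageVolume as NIfTI (float64 data, diagonal affine)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nifti = nib.Nifti1Image(np.asarray(img.values, dtype=np.float64), img.grid.affine())
    nib.save(nifti, str(path))
    return path


def read_mask(path: str | Path, label: str = "") -> Mask:
    vol = read_volume(path, modality="CT_HU")
    return Mask(grid=vol.grid, membership=vol.values > 0.5, label=label or Path(path).stem)


def write_mask(mask: Mask, path: str | Path) -> Path:
    """Masks are serialized as 0/1 integer NIfTI volumes."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nifti = nib.Nifti1Image(mask.membership.astype(np.uint8), mask.grid.affine())
    nib.save(nifti, str(path))
    return path


# ---------------------------------------------------------------------------
# Core operations


def threshold_mask(
    img: ImageVolume, cutoff: float, direction: Literal[">=", ">"] = ">="
) -> Mask:
    """Binary mask of voxels whose value is >= (or >) the cutoff.

    The 200 HU variant of this is how bone is segmented from CT.
    """
    if not np.isfinite(img.values).all():
        raise ValueError("threshold_mask requires finite-valued input")
    if direction == ">=":
        member = img.values >= cutoff
    elif direction == ">":
        member = img.values > cutoff
    else:
        raise ValueError(f"direction must be '>=' or '>', got {direction!r}")
    return Mask(grid=img.grid, membership=member, label=f"value {direction} {cutoff:g}")


def euclidean_distance_map(source: Mask) -> DistanceMap:
    """Exact Euclidean distance (mm, between voxel centers) to the source set."""
    if source.count == 0:
        raise ValueError("distance map undefined for an empty source mask")
    dist = ndimage.distance_transform_edt(~source.membership, sampling=source.grid.spacing)
    return DistanceMap(grid=source.grid, distance=np.asarray(dist, dtype=np.float64))


def _isotropic_grid(grid: GridSpec, target_spacing: float) -> GridSpec:
    extent = np.asarray(grid.shape) * np.asarray(grid.spacing)
    new_shape = np.maximum(1, np.ceil(extent / target_spacing - 1e-9).astype(int))
    return GridSpec(
        shape=tuple(int(s) for s in new_shape),
        spacing=(target_spacing,) * 3,
        origin=grid.origin,
    )


def resample_grid(
    values: np.ndarray,
    grid: GridSpec,
    target: GridSpec,
    interpolation: Interpolation = "trilinear",
) -> np.ndarray:
    """Resample a voxel array from one axis-aligned grid onto another."""
    spacing = np.asarray(grid.spacing)
    # index in source grid for each target voxel center
    scale = np.asarray(target.spacing) / spacing
    offset = (np.asarray(target.origin) - np.asarray(grid.origin)) / spacing
    order = 1 if interpolation == "trilinear" else 0
    # nearest-edge extrapolation: target voxel centers can fall (sub-voxel)
    # outside the source centers while still covering the same physical extent
    out = ndimage.affine_transform(
        np.asarray(values, dtype=np.float64),
        np.diag(scale),
        offset=offset,
        output_shape=target.shape,
        order=order,
        mode="nearest",
    )
    return out


def resample_isotropic(
    img: ImageVolume, target_spacing: float, interpolation: Interpolation = "trilinear"
) -> ImageVolume:
    """Resample onto an isotropic grid covering the same physical extent.

    Texture features are only rotation-comparable on isotropic lattices, so PET
    is resampled before any co-occurrence computation.
    """
    if target_spacing <= 0:
        raise ValueError("target_spacing must be positive")
    target = _isotropic_grid(img.grid, target_spacing)
    out = resample_grid(img.values, img.grid, target, interpolation=interpolation)
    if img.modality == "PET_SUV":
        np.clip(out, 0.0, None, out=out)
    return ImageVolume(grid=target, values=out, modality=img.modality)


def resample_mask_isotropic(mask: Mask, target_spacing: float) -> Mask:
    target = _isotropic_grid(mask.grid, target_spacing)
    out = resample_grid(mask.membership.astype(np.float64), mask.grid, target, "nearest")
    return Mask(grid=target, membership=out > 0.5, label=mask.label)


def resample_mask_to(mask: Mask, target: GridSpec) -> Mask:
    """Nearest-neighbor transfer of a mask onto another grid (e.g. CT -> PET)."""
    out = resample_grid(mask.membership.astype(np.float64), mask.grid, target, "nearest")
    return Mask(grid=target, membership=out > 0.5, label=mask.label)


def dilate_metric(mask: Mask, margin_mm: float) -> Mask:
    """Expand a region by a physical margin: all voxels within margin_mm of it.

    Implemented through the Euclidean distance map so the margin is metric
    (e.g. the 10 mm expansion of a half-maximum metabolic volume), not a voxel
    count, and therefore correct on anisotropic grids.
    """
    if margin_mm < 0:
        raise ValueError("margin must be nonnegative")
    if mask.count == 0:
        return Mask(grid=mask.grid, membership=np.zeros(mask.grid.shape, bool), label=mask.label)
    dist = euclidean_distance_map(mask)
    member = dist.distance <= margin_mm + 1e-9
    return Mask(grid=mask.grid, membership=member, label=f"{mask.label}+{margin_mm:g}mm")


def dice_score(a: Mask, b: Mask) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); undefined when both regions are empty."""
    na, nb = a.count, b.count
    if na == 0 and nb == 0:
        raise ValueError("dice score undefined for two empty masks")
    inter = int(np.logical_and(a.membership, b.membership).sum())
    return 2.0 * inter / (na + nb)


def mask_like(grid: GridSpec, membership: np.ndarray, label: str = "") -> Mask:
    return Mask(grid=grid, membership=membership, label=label)
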