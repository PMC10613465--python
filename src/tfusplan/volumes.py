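"""Hounsfield-unit volumes, skull masks and synthetic skull phantoms.

Grids are axis-aligned and rectilinear.  Voxel indices are 0-based; world
coordinates are millimetres, with ``origin`` the world position of voxel
(0, 0, 0).  Axes follow the anatomical convention used throughout the
package: x = left-right (sagittal-plane normal), y = anterior-posterior
(coronal-plane normal), z = inferior-superior (transverse-plane normal).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "HUVolume",
    "SkullMask",
    "PhantomSpec",
    "resample_isotropic",
    "binarize_skull",
    "generate_phantom",
    "load_nifti",
    "save_nifti",
    "cavity_mask",
]

#: CT threshold separating bone from soft tissue / water, in HU.
DEFAULT_HU_THRESHOLD = 100.0


@dataclass
class _Grid3D:
    """Common geometry of a 3D axis-aligned grid."""

    data: np.ndarray
    spacing: tuple[float, float, float]  # mm per axis
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)  # mm, voxel (0,0,0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D grid, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def voxel_to_world(self, idx) -> np.ndarray:
        """World coordinates (mm) of voxel indices (fractional allowed)."""
        idx = np.asarray(idx, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def world_to_voxel(self, point) -> np.ndarray:
        """Fractional voxel indices of a world point (mm)."""
        point = np.asarray(point, dtype=float)
        return (point - np.asarray(self.origin)) / np.asarray(self.spacing)

    def world_grids(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis world coordinate vectors (mm)."""
        return tuple(
            self.origin[a] + self.spacing[a] * np.arange(self.shape[a])
            for a in range(3)
        )


@dataclass
class HUVolume(_Grid3D):
    """A 3D scalar volume in Hounsfield units."""

    def __post_init__(self) -> None:
        super().__post_init__()
        self.data = self.data.astype(np.float64, copy=False)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("HU values must be finite")


@dataclass
class SkullMask(_Grid3D):
    """Binary mask (True = inside skull bone) on the same grid as its source."""

    threshold: float = DEFAULT_HU_THRESHOLD

    def __post_init__(self) -> None:
        super().__post_init__()
        self.data = self.data.astype(bool, copy=False)


@dataclass
class PhantomSpec:
    """Synthetic closed bony shell standing in for a patient head CT.

    The phantom is a spherical shell of configurable thickness and HU value
    on a water-equivalent (or air) background, with an intracranial target
    point.  ``shell_hu`` may be a constant or a callable ``f(depth_mm)``
    giving a radial HU profile through the shell (depth measured inward
    from the outer surface).
    """

    outer_radius: float  # mm
    thickness: float  # mm
    center: tuple[float, float, float]  # world mm
    target_point: tuple[float, float, float]  # world mm, inside cavity
    shell_hu: float | object = 1500.0
    background_hu: float = 0.0
    domain_extent: tuple[float, float, float] = (128.0, 128.0, 128.0)  # mm
    spacing: float = 1.0  # mm, isotropic
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    binarization_threshold: float = DEFAULT_HU_THRESHOLD

    def validate(self) -> None:
        if not (0 < self.thickness < self.outer_radius):
            raise ValueError("need 0 < thickness < outer_radius")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        inner = self.outer_radius - self.thickness
        d = np.linalg.norm(np.asarray(self.target_point) - np.asarray(self.center))
        if d >= inner:
            raise ValueError(
                f"target_point at {d:.2f} mm from center is not inside the "
                f"cavity (inner radius {inner:.2f} mm)"
            )
        if not callable(self.shell_hu) and self.shell_hu < self.binarization_threshold:
            raise ValueError("shell_hu must be at least the binarization threshold")
        if self.background_hu >= self.binarization_threshold:
            raise ValueError("background_hu must be below the binarization threshold")
        half = np.asarray(self.domain_extent) / 2.0
        cen = np.asarray(self.center) - np.asarray(self.origin)
        if np.any(cen - self.outer_radius < 0) or np.any(cen + self.outer_radius > 2 * half):
            raise ValueError("shell exceeds the domain extent")


def resample_isotropic(vol: HUVolume, spacing: float, order: int = 1) -> HUVolume:
    """Resample a volume to an isotropic voxel size.

    Output dimensions per axis are ``round(extent / spacing)`` where extent
    is the source world extent ``n * spacing_axis``; the world origin is
    preserved.  Default interpolation is trilinear (``order=1``).
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if vol.data.size == 0:
        raise ValueError("cannot resample an empty volume")
    in_sp = np.asarray(vol.spacing)
    if np.allclose(in_sp, spacing):
        return HUVolume(vol.data.copy(), (spacing,) * 3, vol.origin)
    extent = np.asarray(vol.shape) * in_sp
    new_shape = np.maximum(1, np.round(extent / spacing).astype(int))
    # sample at new voxel centres expressed in source voxel coordinates
    coords = np.meshgrid(
        *[(np.arange(n) * spacing) / in_sp[a] for a, n in enumerate(new_shape)],
        indexing="ij",
    )
    out = ndimage.map_coordinates(
        vol.data, np.stack(coords), order=order, mode="nearest"
    )
    return HUVolume(out, (spacing,) * 3, vol.origin)


def binarize_skull(
    vol: HUVolume, threshold: float = DEFAULT_HU_THRESHOLD
) -> SkullMask:
    """Threshold a HU volume into a skull mask (inside iff HU >= threshold)."""
    if vol.data.size == 0:
        raise ValueError("cannot binarize an empty volume")
    return SkullMask(vol.data >= threshold, vol.spacing, vol.origin, threshold=threshold)


def generate_phantom(spec: PhantomSpec) -> HUVolume:
    """Rasterise a spherical-shell phantom into a HU volume.

    A voxel belongs to the shell iff its centre lies at radius
    ``outer_radius - thickness <= r <= outer_radius`` from ``spec.center``.
    Deterministic for a fixed spec.
    """
    spec.validate()
    n = np.maximum(1, np.round(np.asarray(spec.domain_extent) / spec.spacing).astype(int))
    ax = [
        spec.origin[a] + spec.spacing * np.arange(n[a]) - spec.center[a]
        for a in range(3)
    ]
    r = np.sqrt(
        ax[0][:, None, None] ** 2 + ax[1][None, :, None] ** 2 + ax[2][None, None, :] ** 2
    )
    inner = spec.outer_radius - spec.thickness
    shell = (r >= inner) & (r <= spec.outer_radius)
    data = np.full(tuple(n), float(spec.background_hu))
    if callable(spec.shell_hu):
        depth = spec.outer_radius - r[shell]
        data[shell] = np.asarray(spec.shell_hu(depth), dtype=float)
    else:
        data[shell] = float(spec.shell_hu)
    return HUVolume(data, (spec.spacing,) * 3, spec.origin)


def cavity_mask(mask: SkullMask) -> np.ndarray:
    """Boolean mask of the intracranial cavity (holes enclosed by the skull)."""
    filled = ndimage.binary_fill_holes(mask.data)
    return filled & ~mask.data


def load_nifti(path) -> HUVolume:
    """Load a NIfTI-1 volume; spacing/origin are taken from the affine.

    Only axis-aligned affines are supported (the grid must be rectilinear).
    """
    img = nib.load(str(path))
    aff = img.affine
    rot = aff[:3, :3]
    if not np.allclose(rot - np.diag(np.diag(rot)), 0, atol=1e-6):
        raise ValueError("only axis-aligned NIfTI volumes are supported")
    spacing = tuple(np.abs(np.diag(rot)))
    origin = tuple(aff[:3, 3])
    return HUVolume(np.asarray(img.dataobj, dtype=np.float64), spacing, origin)


def save_nifti(vol: _Grid3D, path) -> None:
    """Write a volume as NIfTI-1 with a diagonal affine."""
    aff = np.eye(4)
    aff[:3, :3] = np.diag(vol.spacing)
    aff[:3, 3] = vol.origin
    data = vol.data.astype(np.float32) if vol.data.dtype == bool else vol.data
    nib.save(nib.Nifti1Image(np.asarray(data), aff), str(path))
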