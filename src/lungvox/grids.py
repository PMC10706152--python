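"""Axis-aligned volumetric grids and NIfTI-1 I/O.

All images in this package live on axis-aligned grids described by a voxel
spacing (mm) and a physical origin (mm, coordinate of voxel (0,0,0)).  This
is sufficient for the simulated study data and keeps every physical-space
computation explicit; oblique acquisitions are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

Triple = tuple[float, float, float]


@dataclass(frozen=True)
class Grid:
    """Geometry of an axis-aligned voxel grid in physical (mm) space."""

    shape: tuple[int, int, int]
    spacing: Triple
    origin: Triple = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) < 1 for s in self.shape):
            raise ValueError(f"grid shape must be a positive integer triple, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"voxel spacing must be positive, got {self.spacing}")

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        return aff

    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def extent_mm(self) -> np.ndarray:
        """Physical size of the field of view along each axis."""
        return np.asarray(self.shape, dtype=float) * np.asarray(self.spacing, dtype=float)

    def coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical coordinates (mm) of every voxel centre, as a meshgrid."""
        axes = [
            self.origin[d] + self.spacing[d] * np.arange(self.shape[d], dtype=float)
            for d in range(3)
        ]
        return tuple(np.meshgrid(*axes, indexing="ij"))

    def phys_to_index(self, xyz: np.ndarray) -> np.ndarray:
        """Continuous voxel indices of physical points (..., 3)."""
        xyz = np.asarray(xyz, dtype=float)
        return (xyz - np.asarray(self.origin)) / np.asarray(self.spacing)

    def index_to_phys(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.asarray(ijk, dtype=float)
        return ijk * np.asarray(self.spacing) + np.asarray(self.origin)


@dataclass
class Volume:
    """A scalar volume bound to a :class:`Grid`."""

    data: np.ndarray
    grid: Grid

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.shape[:3] != tuple(self.grid.shape):
            raise ValueError(
                f"data shape {self.data.shape[:3]} does not match grid {self.grid.shape}"
            )

    @property
    def spacing(self) -> Triple:
        return self.grid.spacing

    def copy(self) -> "Volume":
        return Volume(self.data.copy(), self.grid)


def volume_like(vol: Volume, data: np.ndarray) -> Volume:
    return Volume(np.asarray(data), vol.grid)


def save_nifti(vol: Volume, path: str) -> None:
    img = nib.Nifti1Image(np.asarray(vol.data), vol.grid.affine)
    img.header.set_zooms(tuple(vol.grid.spacing) + ((1.0,) if vol.data.ndim == 4 else ()))
    nib.save(img, path)


def load_nifti(path: str) -> Volume:
    img = nib.load(path)
    aff = img.affine
    spacing = tuple(float(np.linalg.norm(aff[:3, d])) for d in range(3))
    origin = tuple(float(v) for v in aff[:3, 3])
    data = np.asarray(img.dataobj)
    grid = Grid(tuple(int(s) for s in data.shape[:3]), spacing, origin)
    return Volume(data, grid)
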