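"""Dense displacement fields, warping, composition and overlap metrics.

A :class:`DeformationField` stores a displacement vector (mm) for every
voxel of a *fixed* grid: a point x (mm) in the fixed frame maps to
x + d(x) in the *moving* image's physical frame.  Warping samples the
moving image at the mapped points, so fields pull intensities from the
moving frame onto the fixed grid.

All transforms operate in physical millimetres; voxel indices are 0-based.
Nearest-neighbour resampling rounds exact half-way points toward the lower
index so results are platform-deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grids import Grid, Volume


@dataclass
class DeformationField:
    """Displacement (mm) on the fixed grid, mapping fixed -> moving space."""

    displacement: np.ndarray  # (X, Y, Z, 3), mm
    fixed_grid: Grid
    moving_grid: Grid

    def __post_init__(self) -> None:
        self.displacement = np.asarray(self.displacement, dtype=float)
        if self.displacement.shape != tuple(self.fixed_grid.shape) + (3,):
            raise ValueError("displacement shape must be fixed grid shape + (3,)")
        if not np.all(np.isfinite(self.displacement)):
            raise ValueError("displacement field contains non-finite values")

    @classmethod
    def identity(cls, fixed_grid: Grid, moving_grid: Grid | None = None) -> "DeformationField":
        disp = np.zeros(tuple(fixed_grid.shape) + (3,))
        return cls(disp, fixed_grid, moving_grid or fixed_grid)

    def mapped_points(self) -> np.ndarray:
        """Physical target points x + d(x) for every fixed voxel, (X,Y,Z,3)."""
        xx, yy, zz = self.fixed_grid.coords()
        pts = np.stack([xx, yy, zz], axis=-1)
        return pts + self.displacement

    def max_displacement(self) -> float:
        return float(np.max(np.linalg.norm(self.displacement, axis=-1)))


def _nearest_indices(idx: np.ndarray) -> np.ndarray:
    # round half-way points toward the lower index
    return np.ceil(idx - 0.5).astype(np.int64)


def _sample(
    volume: Volume, points_phys: np.ndarray, interpolation: str, extend: bool = False
) -> np.ndarray:
    """Sample a volume at physical points (..., 3).

    Out-of-domain points evaluate to 0 (image background) by default; with
    ``extend=True`` the edge value is extended instead, which avoids
    fabricating an artificial boundary when a similarity metric looks at
    the volume border during registration.
    """
    idx = volume.grid.phys_to_index(points_phys)  # (..., 3) continuous indices
    if interpolation == "linear":
        coords = np.moveaxis(idx, -1, 0)
        return ndimage.map_coordinates(
            np.asarray(volume.data, dtype=float), coords, order=1,
            mode="nearest" if extend else "constant", cval=0.0,
        )
    if interpolation == "nearest":
        ii = _nearest_indices(idx)
        shape = np.asarray(volume.data.shape[:3])
        inside = np.all((ii >= 0) & (ii < shape), axis=-1)
        ii_c = np.clip(ii, 0, shape - 1)
        out = volume.data[ii_c[..., 0], ii_c[..., 1], ii_c[..., 2]]
        if extend:
            return out
        background = np.zeros((), dtype=volume.data.dtype)
        return np.where(inside, out, background)
    raise ValueError(f"unknown interpolation {interpolation!r}")


def warp_volume(
    volume: Volume, field: DeformationField, interpolation: str = "linear",
    extend: bool = False,
) -> Volume:
    """Warp ``volume`` (living on the field's moving grid) onto the fixed grid.

    Label maps must use nearest-neighbour interpolation: requesting linear
    interpolation for an integer-typed volume is an error, since averaging
    label codes fabricates classes.  Out-of-domain voxels are set to the
    background value 0 unless ``extend`` requests edge extension.
    """
    if interpolation == "linear" and np.issubdtype(volume.data.dtype, np.integer):
        raise ValueError("linear interpolation is not permitted for integer label maps")
    pts = field.mapped_points()
    data = _sample(volume, pts, interpolation, extend=extend)
    return Volume(data, field.fixed_grid)


def resample_to_grid(volume: Volume, target: Grid, interpolation: str = "linear") -> Volume:
    """Resample onto another grid with no deformation (identity mapping)."""
    field = DeformationField.identity(target, volume.grid)
    return warp_volume(volume, field, interpolation)


def compose_fields(outer: DeformationField, inner: DeformationField) -> DeformationField:
    """Compose so that warp(img, compose(outer, inner)) == warp(warp(img, inner), outer).

    ``outer`` maps grid A -> B and ``inner`` maps B -> C; the result maps
    A -> C: d(x) = d_outer(x) + d_inner(x + d_outer(x)).
    """
    if tuple(outer.moving_grid.shape) != tuple(inner.fixed_grid.shape) or not np.allclose(
        outer.moving_grid.affine, inner.fixed_grid.affine
    ):
        raise ValueError("outer.moving_grid must equal inner.fixed_grid")
    pts = outer.mapped_points()
    # edge-extend the inner displacement: zero-filling outside the domain
    # would fabricate a discontinuity (and negative Jacobians) at the border
    inner_disp = np.stack(
        [
            _sample(Volume(inner.displacement[..., d], inner.fixed_grid), pts, "linear", extend=True)
            for d in range(3)
        ],
        axis=-1,
    )
    return DeformationField(outer.displacement + inner_disp, outer.fixed_grid, inner.moving_grid)


def invert_field(field: DeformationField, n_iter: int = 30) -> DeformationField:
    """Numerical inverse by fixed-point iteration: v(x) = -d(x + v(x))."""
    grid = field.fixed_grid
    v = np.zeros_like(field.displacement)
    xx, yy, zz = grid.coords()
    pts0 = np.stack([xx, yy, zz], axis=-1)
    for _ in range(n_iter):
        pts = pts0 + v
        d_at = np.stack(
            [
                _sample(Volume(field.displacement[..., d], grid), pts, "linear", extend=True)
                for d in range(3)
            ],
            axis=-1,
        )
        v = -d_at
    return DeformationField(v, grid, grid)


def jacobian_determinant(field: DeformationField) -> np.ndarray:
    """Finite-difference Jacobian determinant of the mapping x -> x + d(x)."""
    disp = field.displacement
    spacing = np.asarray(field.fixed_grid.spacing)
    J = np.empty(disp.shape[:3] + (3, 3))
    for comp in range(3):
        for ax in range(3):
            J[..., comp, ax] = np.gradient(disp[..., comp], spacing[ax], axis=ax)
        J[..., comp, comp] += 1.0
    return np.linalg.det(J)


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap 2|A&B| / (|A|+|B|); two empty masks count as 1."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom
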