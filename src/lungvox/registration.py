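"""Multi-resolution, multi-modal image registration.

Each registration runs three sequential stages over an image pyramid
(default downsampling x4 / x2 / x1): a rigid 6-parameter pre-alignment and
a 12-parameter affine refinement driven by mutual information (32-bin joint
histogram) at the coarser levels, followed by a demons-style diffeomorphic
stage at the base level driven by a local normalised cross-correlation
force with Gaussian regularisation of both the update and the accumulated
field.  Updates are composed (not added) so the accumulated field stays
invertible, and every stage only accepts steps that do not increase its
cost, so the per-level cost trace is non-increasing.

The CT <-> DW-MRI alignment is indirect: DW-MRI is registered to the
same-breath ventilation image and CT to the structural image; ventilation
and structural frames are taken as exactly aligned (same breath-hold), so
composing the two legs relates CT and DW-MRI without ever registering the
two modalities to each other directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage, optimize

from .fields import (
    DeformationField,
    Volume,
    compose_fields,
    dice,
    resample_to_grid,
    warp_volume,
    _sample,
)
from .grids import Grid


@dataclass
class RegConfig:
    pyramid: tuple[int, ...] = (4, 2, 1)
    mi_bins: int = 32
    demons_iters: int = 50
    cc_window_sigma_vox: float = 2.0
    sigma_field_vox: float = 1.5
    sigma_update_vox: float = 1.0
    demons_step_mm: float = 1.0
    cc_rel_variance_floor: float = 0.01
    rigid_maxiter: int = 120
    affine_maxiter: int = 120


@dataclass
class RegistrationResult:
    rigid_params: np.ndarray  # tx, ty, tz (mm), rx, ry, rz (deg)
    affine_matrix: np.ndarray  # 3x4, physical space, about the fixed centre
    field: DeformationField  # total fixed -> moving displacement
    dice_before: float
    dice_after: float
    pyramid_log: dict = dc_field(default_factory=dict)


# ---------------------------------------------------------------------------
# parametric transforms (physical mm, rotations about the fixed-image centre)

def _rotation_matrix(deg: np.ndarray) -> np.ndarray:
    rx, ry, rz = np.deg2rad(deg)
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def _rigid_to_affine(params: np.ndarray) -> np.ndarray:
    """(t, angles deg) -> 3x4 matrix [A | t]."""
    A = _rotation_matrix(np.asarray(params[3:6]))
    return np.hstack([A, np.asarray(params[:3], dtype=float)[:, None]])


def _apply_affine(points: np.ndarray, mat34: np.ndarray, centre: np.ndarray) -> np.ndarray:
    rel = points - centre
    return rel @ mat34[:, :3].T + mat34[:, 3] + centre


def _grid_centre(grid: Grid) -> np.ndarray:
    return np.asarray(grid.origin) + (np.asarray(grid.shape) - 1) / 2.0 * np.asarray(grid.spacing)


def _affine_displacement(mat34: np.ndarray, fixed: Grid, moving: Grid) -> DeformationField:
    xx, yy, zz = fixed.coords()
    pts = np.stack([xx, yy, zz], axis=-1)
    mapped = _apply_affine(pts, mat34, _grid_centre(fixed))
    return DeformationField(mapped - pts, fixed, moving)


# ---------------------------------------------------------------------------
# similarity metrics

def mutual_information(a: np.ndarray, b: np.ndarray, bins: int = 32) -> float:
    """Histogram mutual information of two equally-shaped intensity arrays."""
    h, _, _ = np.histogram2d(a.ravel(), b.ravel(), bins=bins)
    p = h / max(h.sum(), 1.0)
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] / (px @ py)[nz])))


def _local_cc_terms(F: np.ndarray, W: np.ndarray, sigma: float):
    """Gaussian-window local cross-correlation terms (Avants-style)."""
    g = lambda x: ndimage.gaussian_filter(x, sigma, mode="nearest")
    Fm = F - g(F)
    Wm = W - g(W)
    A = g(Fm * Wm)
    B = g(Fm * Fm)
    C = g(Wm * Wm)
    return Fm, Wm, A, B, C


def local_cc(
    F: np.ndarray, W: np.ndarray, sigma: float, mask: np.ndarray | None = None,
    rel_floor: float = 0.01,
) -> float:
    """Mean squared local correlation over voxels with real local structure.

    Voxels whose local variance falls below ``rel_floor`` times the global
    variance carry no alignment information (noise-only regions) and are
    excluded from the average."""
    _, _, A, B, C = _local_cc_terms(F, W, sigma)
    eps = rel_floor * (F.std() ** 2 + 1e-30)
    ok = (B > eps) & (C > eps)
    if mask is not None:
        ok &= mask
    if not ok.any():
        return 0.0
    return float(np.mean(A[ok] ** 2 / (B[ok] * C[ok])))


# ---------------------------------------------------------------------------
# pyramid helpers

def _downsample(vol: Volume, factor: int) -> Volume:
    if factor == 1:
        return vol
    data = ndimage.gaussian_filter(np.asarray(vol.data, dtype=float), sigma=0.5 * factor, mode="nearest")
    sl = tuple(slice(None, None, factor) for _ in range(3))
    sub = data[sl]
    g = vol.grid
    grid = Grid(sub.shape, tuple(s * factor for s in g.spacing), g.origin)
    return Volume(sub, grid)


def _resample_moving(moving: Volume, fixed_grid: Grid, mat34: np.ndarray, centre: np.ndarray) -> np.ndarray:
    xx, yy, zz = fixed_grid.coords()
    pts = np.stack([xx, yy, zz], axis=-1)
    mapped = _apply_affine(pts, mat34, centre)
    return _sample(moving, mapped, "linear", extend=True)


# ---------------------------------------------------------------------------
# stages

def _optimise_parametric(
    fixed: Volume,
    moving: Volume,
    x0: np.ndarray,
    mode: str,
    bins: int,
    maxiter: int,
    centre: np.ndarray,
    log: list,
):
    """Powell search of negative MI over rigid or affine parameters."""
    F = np.asarray(fixed.data, dtype=float)
    scales = (
        np.array([1.0, 1.0, 1.0, 1.0, 1.0, 1.0])
        if mode == "rigid"
        else np.concatenate([np.full(9, 0.02), np.ones(3)])
    )
    best = [np.inf]

    def mat_of(x):
        if mode == "rigid":
            return _rigid_to_affine(x * scales)
        p = x * scales
        return np.hstack([p[:9].reshape(3, 3) + np.eye(3) * 0, p[9:][:, None]])

    def cost(x):
        W = _resample_moving(moving, fixed.grid, mat_of(x), centre)
        c = -mutual_information(F, W, bins)
        if not np.isfinite(c):
            raise RuntimeError("non-finite registration cost; aborting")
        if c < best[0]:
            best[0] = c
        log.append(best[0])
        return c

    res = optimize.minimize(
        cost, x0, method="Powell",
        options={"maxiter": maxiter, "xtol": 1e-3, "ftol": 1e-6},
    )
    return res.x, mat_of(res.x)


def _demons(
    fixed: Volume,
    moving: Volume,
    init_field: DeformationField,
    cfg: RegConfig,
    log: list,
) -> DeformationField:
    """Compositive demons with a local-CC force at the base level.

    Images are lightly pre-smoothed so the force follows structure rather
    than voxel noise; only update steps that do not increase the cost are
    accepted (step halving otherwise), so the logged trace is monotone.
    """
    F = ndimage.gaussian_filter(np.asarray(fixed.data, dtype=float), 1.0, mode="nearest")
    Ms = Volume(
        ndimage.gaussian_filter(np.asarray(moving.data, dtype=float), 1.0, mode="nearest"),
        moving.grid,
    )
    grid = fixed.grid
    spacing = np.asarray(grid.spacing)
    sigma = cfg.cc_window_sigma_vox
    floor = cfg.cc_rel_variance_floor
    u = DeformationField.identity(grid, grid)  # incremental diffeomorphic part
    total = compose_fields(u, init_field)
    W = np.asarray(warp_volume(Ms, total, "linear", extend=True).data, dtype=float)
    cost = -local_cc(F, W, sigma, rel_floor=floor)
    log.append(cost)
    step = cfg.demons_step_mm
    eps_var = floor * (F.std() ** 2 + 1e-30)
    for _ in range(cfg.demons_iters):
        Fm, Wm, A, B, C = _local_cc_terms(F, W, sigma)
        ok = (B > eps_var) & (C > eps_var)
        coef = np.where(ok, 2.0 * A / (B * C + 1e-30), 0.0)
        inner = np.where(ok, Fm - np.where(ok, A / (C + 1e-30), 0.0) * Wm, 0.0)
        grads = np.stack(
            [np.gradient(Wm, spacing[d], axis=d) for d in range(3)], axis=-1
        )
        force = coef[..., None] * inner[..., None] * grads
        mag = np.linalg.norm(force, axis=-1)
        peak = float(mag.max())
        if peak <= 0:
            break
        upd = force * (step / peak)
        for d in range(3):
            upd[..., d] = ndimage.gaussian_filter(upd[..., d], cfg.sigma_update_vox, mode="nearest")
        u_try = compose_fields(DeformationField(upd, grid, grid), u)
        disp = u_try.displacement.copy()
        for d in range(3):
            disp[..., d] = ndimage.gaussian_filter(disp[..., d], cfg.sigma_field_vox, mode="nearest")
        u_try = DeformationField(disp, grid, grid)
        total_try = compose_fields(u_try, init_field)
        W_try = np.asarray(warp_volume(Ms, total_try, "linear", extend=True).data, dtype=float)
        cost_try = -local_cc(F, W_try, sigma, rel_floor=floor)
        if not np.isfinite(cost_try):
            raise RuntimeError("non-finite registration cost; aborting")
        if cost_try <= cost:
            u, total, W, cost = u_try, total_try, W_try, cost_try
            step = min(step * 1.1, 4.0 * cfg.demons_step_mm)
        else:
            step *= 0.5  # step halving on cost increase
            if step < 1e-3:
                break
        log.append(cost)
    return total


def register_pair(
    fixed: Volume,
    moving: Volume,
    fixed_mask: np.ndarray | None = None,
    moving_mask: np.ndarray | None = None,
    config: RegConfig | None = None,
) -> RegistrationResult:
    """Rigid -> affine -> diffeomorphic registration of ``moving`` onto ``fixed``."""
    cfg = config or RegConfig()
    for name, vol in (("fixed", fixed), ("moving", moving)):
        if float(np.std(np.asarray(vol.data, dtype=float))) == 0.0:
            raise ValueError(f"{name} image is constant; registration is undefined")
    centre = _grid_centre(fixed.grid)
    levels = sorted(set(cfg.pyramid), reverse=True)
    log: dict[str, list] = {}

    # stage 1: rigid at the coarsest level (mutual information)
    f_lo = _downsample(fixed, levels[0])
    m_lo = _downsample(moving, levels[0])
    log[f"rigid_x{levels[0]}"] = []
    x_r, mat_r = _optimise_parametric(
        f_lo, m_lo, np.zeros(6), "rigid", cfg.mi_bins, cfg.rigid_maxiter, centre,
        log[f"rigid_x{levels[0]}"],
    )
    rigid_params = x_r.copy()

    # stage 2: affine at the middle level (mutual information), seeded by rigid
    mid = levels[1] if len(levels) > 1 else 1
    f_mid = _downsample(fixed, mid)
    m_mid = _downsample(moving, mid)
    A0 = np.concatenate([(mat_r[:, :3] - 0 * np.eye(3)).ravel() / 0.02, mat_r[:, 3]])
    log[f"affine_x{mid}"] = []
    _, mat_a = _optimise_parametric(
        f_mid, m_mid, A0, "affine", cfg.mi_bins, cfg.affine_maxiter, centre,
        log[f"affine_x{mid}"],
    )

    # stage 3: diffeomorphic demons at the base level (local cross-correlation)
    aff_field = _affine_displacement(mat_a, fixed.grid, moving.grid)
    log["demons_x1"] = []
    total = _demons(fixed, moving, aff_field, cfg, log["demons_x1"])

    d_before = d_after = float("nan")
    if fixed_mask is not None and moving_mask is not None:
        mvol = Volume(np.asarray(moving_mask, dtype=np.uint8), moving.grid)
        before = resample_to_grid(mvol, fixed.grid, "nearest")
        after = warp_volume(mvol, total, "nearest")
        d_before = dice(np.asarray(fixed_mask, bool), before.data > 0)
        d_after = dice(np.asarray(fixed_mask, bool), after.data > 0)
    return RegistrationResult(
        rigid_params=rigid_params,
        affine_matrix=mat_a,
        field=total,
        dice_before=d_before,
        dice_after=d_after,
        pyramid_log=log,
    )


DEFAULT_COMMON_SPACING = (1.8, 1.8, 5.0)


def common_grid_for(reference: Grid, spacing=DEFAULT_COMMON_SPACING) -> Grid:
    """A grid with the requested spacing covering the reference field of view."""
    extent = reference.extent_mm()
    shape = tuple(int(np.ceil(extent[d] / spacing[d])) for d in range(3))
    return Grid(shape, tuple(float(s) for s in spacing), reference.origin)


def indirect_coregister(
    images: dict,
    metric_maps: dict | None = None,
    caliper=None,
    common_spacing=DEFAULT_COMMON_SPACING,
    config: RegConfig | None = None,
    extra_dwi_volumes: dict | None = None,
):
    """Indirect CT <-> DW-MRI co-registration via same-breath ventilation/structural MRI.

    ``images`` must contain Volumes 'dwi_b0', 'ventilation', 'structural',
    'ct' and boolean masks 'dwi_mask', 'vent_mask', 'ct_mask' ('struct_mask'
    defaults to the ventilation mask: same breath-hold).  Metric maps
    (:class:`~lungvox.dwi.ParameterMap` on the DW grid) ride the DW leg and
    the CALIPER label map rides the CT leg, both warped nearest-neighbour;
    everything is resampled onto a common grid (default 1.8 x 1.8 x 5 mm).

    ``extra_dwi_volumes`` (name -> 4D/3D Volume on the DW grid) — e.g. a
    follow-up acquisition already registered to the baseline DW frame — are
    carried through the DW leg unchanged.
    """
    required = ("dwi_b0", "ventilation", "structural", "ct", "dwi_mask", "vent_mask", "ct_mask")
    missing = [k for k in required if k not in images]
    if missing:
        raise ValueError(f"indirect co-registration is missing input(s): {missing}")
    cfg = config or RegConfig()
    vent, struct, ct = images["ventilation"], images["structural"], images["ct"]
    struct_mask = np.asarray(images.get("struct_mask", images["vent_mask"]), bool)

    reg_dw = register_pair(vent, images["dwi_b0"], images["vent_mask"], images["dwi_mask"], cfg)
    reg_ct = register_pair(struct, ct, struct_mask, images["ct_mask"], cfg)

    common = common_grid_for(struct.grid, common_spacing)
    to_vent = DeformationField.identity(common, vent.grid)
    to_struct = DeformationField.identity(common, struct.grid)
    dw_total = compose_fields(to_vent, reg_dw.field)  # common -> DW grid
    ct_total = compose_fields(to_struct, reg_ct.field)  # common -> CT grid

    out: dict = {
        "common_grid": common,
        "dw_registration": reg_dw,
        "ct_registration": reg_ct,
        "dw_field_common": dw_total,
        "ct_field_common": ct_total,
    }
    dw_mask_c = warp_volume(
        Volume(np.asarray(images["dwi_mask"], np.uint8), images["dwi_b0"].grid), dw_total, "nearest"
    ).data > 0
    ct_mask_c = warp_volume(
        Volume(np.asarray(images["ct_mask"], np.uint8), ct.grid), ct_total, "nearest"
    ).data > 0
    out["dwi_mask_common"] = dw_mask_c
    out["ct_mask_common"] = ct_mask_c
    out["ct_common"] = warp_volume(ct, ct_total, "linear")
    out["dice"] = {
        "dw_to_ventilation": reg_dw.dice_after,
        "ct_to_structural": reg_ct.dice_after,
        "ct_dw_overall": dice(dw_mask_c, ct_mask_c),
        "dw_to_ventilation_before": reg_dw.dice_before,
        "ct_to_structural_before": reg_ct.dice_before,
    }
    if metric_maps:
        warped = {}
        for name, pmap in metric_maps.items():
            vals = warp_volume(Volume(np.nan_to_num(pmap.values, nan=0.0), pmap.grid), dw_total, "nearest")
            vmask = warp_volume(Volume(pmap.validity_mask.astype(np.uint8), pmap.grid), dw_total, "nearest")
            from .dwi import ParameterMap

            warped[name] = ParameterMap(
                pmap.kind, np.where(vmask.data > 0, vals.data, np.nan), vmask.data > 0, common
            )
        out["metric_maps_common"] = warped
    if caliper is not None:
        from .patterns import CaliperLabelMap

        lab = warp_volume(Volume(caliper.labels, caliper.grid), ct_total, "nearest")
        out["caliper_common"] = CaliperLabelMap(lab.data, common, scheme=caliper.scheme)
    if extra_dwi_volumes:
        carried = {}
        for name, vol in extra_dwi_volumes.items():
            data = np.asarray(vol.data)
            if data.ndim == 4:
                chans = [
                    warp_volume(Volume(data[..., i], vol.grid), dw_total, "nearest").data
                    for i in range(data.shape[3])
                ]
                carried[name] = Volume(np.stack(chans, axis=-1), common)
            else:
                carried[name] = warp_volume(Volume(data, vol.grid), dw_total, "nearest")
        out["extra_dwi_common"] = carried
    return out
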