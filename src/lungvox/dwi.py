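"""Per-voxel diffusion model fitting for hyperpolarised-gas DW-MRI.

Two models are fitted voxel-by-voxel to multi-b-value magnitude data:

* a two-b-value mono-exponential apparent diffusion coefficient,
  ADC = ln(S(0)/S(b1)) / b1  (cm^2/s), from b = 0 and the first nonzero
  b-value only;
* the stretched exponential model (SEM)
  S(b) = S0 * exp(-(b * DDC)^alpha), fitted over all b-values, yielding the
  distributed diffusion coefficient DDC (cm^2/s) and heterogeneity index
  alpha in (0, 1].

From the SEM parameters the mean diffusive length scale (mean acinar
dimension) Lm_D is derived by averaging l(D) = sqrt(2 n D Delta) over the
distribution of diffusivities P(D; DDC, alpha) implied by the stretched
exponential — the inverse Laplace transform of the signal decay, a
one-sided alpha-stable density truncated at the gas free-diffusion ceiling
D0.  At alpha = 1 the distribution collapses to a point mass and Lm_D
reduces exactly to sqrt(2 n Delta DDC).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import Grid, Volume
from .protocols import GasProtocol
from .stable import positive_stable_pdf, sqrt_moment_table

__all__ = [
    "SemFit",
    "ParameterMap",
    "fit_adc_two_point",
    "sem_signal",
    "fit_sem",
    "lmd_from_sem",
    "fit_maps",
]

CM_TO_UM = 1.0e4
MS_TO_S = 1.0e-3


@dataclass
class SemFit:
    S0: float
    DDC: float
    alpha: float
    rss: float
    valid: bool


@dataclass
class ParameterMap:
    """A fitted parameter volume plus its per-voxel validity mask."""

    kind: str  # one of ADC, DDC, alpha, LmD
    values: np.ndarray
    validity_mask: np.ndarray
    grid: Grid

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.validity_mask = np.asarray(self.validity_mask, dtype=bool)
        if self.values.shape != self.validity_mask.shape:
            raise ValueError("values/validity shape mismatch")

    def as_volume(self) -> Volume:
        return Volume(self.values, self.grid)


def sem_signal(b, S0, DDC, alpha):
    """Noiseless stretched-exponential signal S(b) = S0 exp(-(b DDC)^alpha)."""
    b = np.asarray(b, dtype=float)
    bd = b * np.asarray(DDC, dtype=float)
    return np.asarray(S0) * np.exp(-np.power(bd, alpha, where=bd > 0, out=np.zeros_like(bd)))


def fit_adc_two_point(S0_obs, Sb_obs, b: float, D0: float = np.inf):
    """Two-point mono-exponential ADC, vectorised.

    Returns (adc, valid).  Voxels where the b-weighted signal is
    non-positive or exceeds S(0) are noise-dominated and flagged invalid
    rather than raising; the ADC is clamped to [0, D0].
    """
    if b <= 0:
        raise ValueError("b must be positive")
    S0_obs = np.asarray(S0_obs, dtype=float)
    Sb_obs = np.asarray(Sb_obs, dtype=float)
    valid = (S0_obs > 0) & (Sb_obs > 0) & (Sb_obs <= S0_obs)
    with np.errstate(divide="ignore", invalid="ignore"):
        adc = np.log(S0_obs / Sb_obs) / b
    adc = np.where(valid, adc, np.nan)
    over = valid & (adc > D0)
    valid = valid & ~over
    adc = np.where(over, np.nan, adc)
    adc = np.clip(adc, 0.0, D0)
    if np.ndim(valid) == 0:
        return float(adc) if valid else float("nan"), bool(valid)
    return adc, valid


# ---------------------------------------------------------------------------
# Stretched-exponential fitting: batched projected Levenberg-Marquardt.
# The (DDC, alpha) objective has a shallow ridge, so three alpha starts are
# used and the best residual kept.

_ALPHA_STARTS = (0.6, 0.8, 1.0)
_ALPHA_LO = 0.01
_DDC_LO_FRAC = 1e-4  # lower DDC bound as a fraction of D0


def _batched_lm(y, b, S0_init, DDC_init, alpha_init, D0, n_iter=60):
    """Levenberg-Marquardt on (S0, DDC, alpha) for many voxels at once.

    y: (N, nb) signals; returns (S0, DDC, alpha, rss) arrays of length N.
    Bounds are enforced by projection after each accepted step.
    """
    N, nb = y.shape
    S0 = np.asarray(S0_init, dtype=float).copy()
    D = np.asarray(DDC_init, dtype=float).copy()
    A = np.full(N, alpha_init, dtype=float)
    lam = np.full(N, 1e-3)
    lo_D = _DDC_LO_FRAC * D0

    def residual(S0, D, A):
        bd = b[None, :] * D[:, None]
        with np.errstate(divide="ignore"):
            u = np.power(bd, A[:, None], where=bd > 0, out=np.zeros_like(bd))
        model = S0[:, None] * np.exp(-u)
        return model - y, model, u, bd

    r, model, u, bd = residual(S0, D, A)
    rss = np.sum(r * r, axis=1)
    for _ in range(n_iter):
        # analytic Jacobian of the model wrt (S0, D, alpha)
        with np.errstate(divide="ignore", invalid="ignore"):
            logbd = np.where(bd > 0, np.log(bd), 0.0)
        dS0 = model / np.maximum(S0[:, None], 1e-300)
        dD = -model * u * A[:, None] / np.maximum(D[:, None], 1e-300)
        dA = -model * u * logbd
        J = np.stack([dS0, dD, dA], axis=2)  # (N, nb, 3)
        g = np.einsum("nbk,nb->nk", J, r)  # gradient
        H = np.einsum("nbk,nbl->nkl", J, J)  # Gauss-Newton Hessian
        Hd = H + lam[:, None, None] * np.eye(3)[None]
        try:
            step = -np.linalg.solve(Hd, g[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:  # pragma: no cover - defensive
            Hd = Hd + 1e-8 * np.eye(3)[None]
            step = -np.linalg.solve(Hd, g[:, :, None])[:, :, 0]
        S0_new = np.maximum(S0 + step[:, 0], 1e-12)
        D_new = np.clip(D + step[:, 1], lo_D, D0)
        A_new = np.clip(A + step[:, 2], _ALPHA_LO, 1.0)
        r_new, model_new, u_new, bd_new = residual(S0_new, D_new, A_new)
        rss_new = np.sum(r_new * r_new, axis=1)
        improved = rss_new < rss
        lam = np.where(improved, np.maximum(lam * 0.3, 1e-10), np.minimum(lam * 5.0, 1e6))
        S0 = np.where(improved, S0_new, S0)
        D = np.where(improved, D_new, D)
        A = np.where(improved, A_new, A)
        upd = improved[:, None]
        r = np.where(upd, r_new, r)
        model = np.where(upd, model_new, model)
        u = np.where(upd, u_new, u)
        bd = np.where(upd, bd_new, bd)
        rss = np.where(improved, rss_new, rss)
    return S0, D, A, rss


def fit_sem_batch(signals: np.ndarray, protocol: GasProtocol):
    """Fit the SEM to many voxels.

    signals: (N, n_b) array, one row per voxel in protocol b-value order.
    Returns (S0, DDC, alpha, rss, valid) arrays.
    """
    y = np.asarray(signals, dtype=float)
    if y.ndim != 2 or y.shape[1] != protocol.n_b:
        raise ValueError("signals must be (N, n_b) matching the protocol")
    b = np.asarray(protocol.b_values)
    D0 = protocol.free_diffusion_D0
    N = y.shape[0]
    # initial DDC from the two-point ADC of each voxel
    adc0, _ = fit_adc_two_point(np.maximum(y[:, 0], 1e-12), np.maximum(y[:, 1], 1e-12), b[1], D0)
    adc0 = np.clip(np.nan_to_num(adc0, nan=0.1 * D0), 2 * _DDC_LO_FRAC * D0, D0)
    best = None
    for a0 in _ALPHA_STARTS:
        S0, D, A, rss = _batched_lm(y, b, y[:, 0].clip(min=1e-12), adc0, a0, D0)
        if best is None:
            best = [S0, D, A, rss]
        else:
            better = rss < best[3]
            for i, arr in enumerate((S0, D, A, rss)):
                best[i] = np.where(better, arr, best[i])
    S0, D, A, rss = best
    lo_D = _DDC_LO_FRAC * D0
    valid = (
        np.isfinite(rss)
        & (y[:, 0] > 0)
        & (D > lo_D * 1.001)  # pinned at the lower bound: no measurable decay
        & (A > _ALPHA_LO * 1.001)
    )
    return S0, D, A, rss, valid


def fit_sem(signal_vector, protocol: GasProtocol) -> SemFit:
    """Fit the stretched exponential model to a single voxel's decay."""
    y = np.asarray(signal_vector, dtype=float)
    if y.shape != (protocol.n_b,):
        raise ValueError(f"expected {protocol.n_b} signal values, got {y.shape}")
    if y[0] <= 0:
        return SemFit(0.0, 0.0, 1.0, np.inf, False)
    S0, D, A, rss, valid = fit_sem_batch(y[None, :], protocol)
    return SemFit(float(S0[0]), float(D[0]), float(A[0]), float(rss[0]), bool(valid[0]))


# ---------------------------------------------------------------------------
# Mean acinar dimension

_TABLE_ALPHAS = np.linspace(0.30, 0.995, 140)
_TABLE_LOG10R = np.linspace(0.02, 6.0, 100)
_ALPHA_EXACT_ONE = 0.995  # above this, blend linearly into the alpha=1 limit
_table_cache: dict[str, np.ndarray] = {}


def _moment_interpolator():
    if "c" not in _table_cache:
        _table_cache["c"] = sqrt_moment_table(_TABLE_ALPHAS, _TABLE_LOG10R)
    return _table_cache["c"]


def _sqrt_moment(alpha: np.ndarray, rmax: np.ndarray) -> np.ndarray:
    """c(alpha, rmax) = E[sqrt(D/DDC)] under the truncated stable weight,
    by bilinear interpolation of a precomputed table; c -> 1 as alpha -> 1."""
    from scipy.interpolate import RegularGridInterpolator

    tab = _moment_interpolator()
    interp = RegularGridInterpolator(
        (_TABLE_ALPHAS, _TABLE_LOG10R), tab, bounds_error=False, fill_value=None
    )
    alpha = np.asarray(alpha, dtype=float)
    logr = np.clip(np.log10(np.asarray(rmax, dtype=float)), _TABLE_LOG10R[0], _TABLE_LOG10R[-1])
    a_clip = np.clip(alpha, _TABLE_ALPHAS[0], _ALPHA_EXACT_ONE)
    c = interp(np.stack([a_clip, logr], axis=-1))
    # alpha in (0.995, 1]: the stable weight collapses to a point mass at
    # D = DDC; blend linearly to the exact limit c = 1
    near1 = alpha > _ALPHA_EXACT_ONE
    if np.any(near1):
        c_at = interp(np.stack([np.full_like(alpha, _ALPHA_EXACT_ONE), logr], axis=-1))
        t = (alpha - _ALPHA_EXACT_ONE) / (1.0 - _ALPHA_EXACT_ONE)
        c = np.where(near1, c_at * (1.0 - t) + 1.0 * t, c)
    return c


def lmd_from_sem(DDC, alpha, protocol: GasProtocol, method: str = "table"):
    """Mean acinar dimension Lm_D (um) from SEM parameters.

    Lm_D is the mean of l(D) = sqrt(2 n D Delta) over the diffusivity
    distribution implied by the stretched exponential, truncated at the
    free-diffusion ceiling D0.  By the scaling D = DDC * u this equals
    sqrt(2 n Delta DDC) * E[sqrt(u)], with u distributed as the standard
    positive stable law of index alpha truncated at D0/DDC.

    At alpha = 1 the result is exactly sqrt(2 n Delta DDC).

    method="table" (default) interpolates a precomputed moment table and is
    vectorised; method="quadrature" evaluates the spectral integral on a
    2000-point log-spaced diffusivity grid per call (scalar only).
    """
    DDC_arr = np.atleast_1d(np.asarray(DDC, dtype=float))
    alpha_arr = np.broadcast_to(np.atleast_1d(np.asarray(alpha, dtype=float)), DDC_arr.shape).copy()
    if np.any((alpha_arr <= 0) | (alpha_arr > 1)):
        raise ValueError("alpha must lie in (0, 1]")
    if np.any(DDC_arr <= 0):
        raise ValueError("DDC must be positive")
    n = protocol.length_dimensionality_n
    delta_s = protocol.diffusion_time_ms * MS_TO_S
    base_cm = np.sqrt(2.0 * n * delta_s * DDC_arr)  # alpha=1 closed form, cm
    rmax = protocol.free_diffusion_D0 / DDC_arr
    if method == "table":
        c = np.where(alpha_arr >= 1.0, 1.0, np.nan)
        sub = alpha_arr < 1.0
        if np.any(sub):
            c[sub] = _sqrt_moment(alpha_arr[sub], rmax[sub])
    elif method == "quadrature":
        c = np.empty_like(DDC_arr)
        for i, (a, r) in enumerate(zip(alpha_arr.ravel(), rmax.ravel())):
            if a >= 1.0:
                c.ravel()[i] = 1.0
            else:
                u = np.geomspace(1e-4, r, 2000)
                p = positive_stable_pdf(u, float(a))
                w = p * u  # log-spacing measure
                c.ravel()[i] = np.sum(w * np.sqrt(u)) / np.sum(w)
    else:
        raise ValueError(f"unknown method {method!r}")
    lmd = base_cm * c * CM_TO_UM
    if np.ndim(DDC) == 0 and np.ndim(alpha) == 0:
        return float(lmd[0])
    return lmd.reshape(np.shape(DDC))


def fit_maps(
    dwi: np.ndarray,
    mask: np.ndarray,
    protocol: GasProtocol,
    grid: Grid | None = None,
    noise_sigma: float | None = None,
) -> dict[str, ParameterMap]:
    """Voxel-wise ADC / SEM / Lm_D maps over a lung mask.

    dwi: 4D array (x, y, z, b) with one volume per protocol b-value.
    The ADC uses b = 0 and the first nonzero b-value only; the SEM and Lm_D
    use all b-values.  Voxels whose b = 0 signal falls below twice the
    background noise estimate are excluded as unventilated; the estimate is
    taken from outside-mask voxels unless supplied.
    """
    dwi = np.asarray(dwi, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if dwi.ndim != 4:
        raise ValueError("dwi must be 4D (x, y, z, b)")
    if dwi.shape[3] != protocol.n_b:
        raise ValueError(
            f"dwi carries {dwi.shape[3]} b-volumes but protocol has {protocol.n_b}"
        )
    if mask.shape != dwi.shape[:3]:
        raise ValueError("mask shape mismatch")
    if grid is None:
        grid = Grid(dwi.shape[:3], (1.0, 1.0, 1.0))
    shape = dwi.shape[:3]
    b = np.asarray(protocol.b_values)
    D0 = protocol.free_diffusion_D0

    empty = lambda: np.full(shape, np.nan)
    out_valid = np.zeros(shape, dtype=bool)
    maps = {
        "ADC": empty(), "DDC": empty(), "alpha": empty(), "LmD": empty(),
    }
    if mask.any():
        if noise_sigma is None:
            bg = dwi[..., 0][~mask]
            # Rayleigh background: sigma = mean / sqrt(pi/2)
            noise_sigma = float(np.mean(np.abs(bg)) / np.sqrt(np.pi / 2)) if bg.size else 0.0
        sig = dwi[mask]  # (N, nb)
        ventilated = sig[:, 0] > 2.0 * noise_sigma
        adc, adc_valid = fit_adc_two_point(sig[:, 0], sig[:, 1], b[1], D0)
        S0, D, A, rss, sem_valid = fit_sem_batch(sig, protocol)
        sem_valid = sem_valid & ventilated
        adc_valid = adc_valid & ventilated
        lmd = np.full(sig.shape[0], np.nan)
        if sem_valid.any():
            lmd[sem_valid] = lmd_from_sem(D[sem_valid], A[sem_valid], protocol)
        idx = np.where(mask)
        maps["ADC"][idx] = np.where(adc_valid, adc, np.nan)
        maps["DDC"][idx] = np.where(sem_valid, D, np.nan)
        maps["alpha"][idx] = np.where(sem_valid, A, np.nan)
        maps["LmD"][idx] = lmd
        adc_mask = np.zeros(shape, dtype=bool)
        adc_mask[idx] = adc_valid
        sem_mask = np.zeros(shape, dtype=bool)
        sem_mask[idx] = sem_valid
    else:
        adc_mask = np.zeros(shape, dtype=bool)
        sem_mask = np.zeros(shape, dtype=bool)
    return {
        "ADC": ParameterMap("ADC", maps["ADC"], adc_mask, grid),
        "DDC": ParameterMap("DDC", maps["DDC"], sem_mask, grid),
        "alpha": ParameterMap("alpha", maps["alpha"], sem_mask, grid),
        "LmD": ParameterMap("LmD", maps["LmD"], sem_mask, grid),
    }
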