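"""One-sided (positive) alpha-stable density, Kanter's integral form.

The stretched-exponential diffusion signal exp(-(b*DDC)^alpha) is, for
0 < alpha < 1, the Laplace transform of a one-sided alpha-stable density
p(u; alpha) over a dimensionless diffusivity ratio u = D/DDC:

    exp(-s^alpha) = int_0^inf p(u; alpha) exp(-s u) du.

Its explicit integral representation (Kanter, 1975) is

    p(u) = alpha/(1-alpha) * u^(-1/(1-alpha))
           * (1/pi) int_0^pi A(phi) exp(-A(phi) u^(-alpha/(1-alpha))) dphi,

    A(phi) = sin(alpha*phi)^(alpha/(1-alpha)) * sin((1-alpha)*phi)
             / sin(phi)^(1/(1-alpha)),

which is numerically benign for all u > 0 once evaluated in log space.
This density is the spectral weight used to average the diffusive length
scale over the per-voxel diffusivity distribution.
"""

from __future__ import annotations

import numpy as np

_N_PHI = 256  # midpoint rule on (0, pi); integrand is smooth and periodic-free


def _log_A(phi: np.ndarray, alpha: float) -> np.ndarray:
    r = alpha / (1.0 - alpha)
    return (
        r * np.log(np.sin(alpha * phi))
        + np.log(np.sin((1.0 - alpha) * phi))
        - (1.0 + r) * np.log(np.sin(phi))
    )


def positive_stable_pdf(u: np.ndarray, alpha: float) -> np.ndarray:
    """Density p(u; alpha) of the standard positive stable law, vectorised in u.

    Valid for 0 < alpha < 1.  Returns 0 for u <= 0.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie strictly between 0 and 1")
    u = np.atleast_1d(np.asarray(u, dtype=float))
    out = np.zeros_like(u)
    pos = u > 0
    if not pos.any():
        return out
    up = u[pos]
    r = alpha / (1.0 - alpha)
    phi = (np.arange(_N_PHI) + 0.5) * (np.pi / _N_PHI)
    logA = _log_A(phi, alpha)  # (n_phi,)
    # everything in log space: log integrand = logA - A * u^{-r}
    log_y = logA[None, :] - r * np.log(up)[:, None]
    expo = np.exp(np.minimum(log_y, 700.0))  # A * u^{-r}, saturates harmlessly
    log_integrand = logA[None, :] - expo
    # log-sum-exp over phi (midpoint rule => mean over samples)
    m = np.max(log_integrand, axis=1, keepdims=True)
    m = np.where(np.isfinite(m), m, 0.0)
    log_integral = np.squeeze(m, 1) + np.log(
        np.mean(np.exp(log_integrand - m), axis=1)
    )
    log_p = np.log(r) - (1.0 + r) * np.log(up) + log_integral
    with np.errstate(over="ignore"):
        out[pos] = np.where(np.isfinite(log_p), np.exp(np.minimum(log_p, 700.0)), 0.0)
    return out


def sqrt_moment_table(
    alphas: np.ndarray,
    log10_rmax: np.ndarray,
    u_lo: float = 1e-4,
    n_u: int = 2000,
):
    """Tabulate c(alpha, rmax) = E[sqrt(u)] over p(u; alpha) truncated to
    [u_lo, rmax], for interpolation.

    rmax plays the role of D0/DDC, the free-diffusion ceiling expressed in
    units of the distributed diffusion coefficient.  Returns an array of
    shape (len(alphas), len(log10_rmax)).
    """
    rmax_max = 10.0 ** float(np.max(log10_rmax))
    # master log-spaced grid; extends to the largest ceiling requested
    u = np.geomspace(u_lo, rmax_max, n_u)
    table = np.empty((len(alphas), len(log10_rmax)))
    for i, a in enumerate(alphas):
        p = positive_stable_pdf(u, float(a))
        w = p * u  # du = u dlog(u); absorb u into the weight
        num = np.cumsum(w * np.sqrt(u))
        den = np.cumsum(w)
        # cumulative trapezoid is overkill: the grid is dense; cumsum of the
        # log-midpoint weights is accurate to << 0.1% here
        idx = np.searchsorted(u, 10.0 ** np.asarray(log10_rmax, dtype=float))
        idx = np.clip(idx, 1, n_u - 1)
        table[i] = num[idx] / den[idx]
    return table
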