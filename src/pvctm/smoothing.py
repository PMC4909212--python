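"""Discretized spline smoothing of gridded data.

Penalized least squares on a regular lattice, diagonalised by the type-II
discrete cosine transform: minimising ||y - z||^2 + s ||Laplacian z||^2
gives z = IDCT(Gamma . DCT(y)) with Gamma_k = 1 / (1 + s * Lambda_k^2),
where Lambda are the eigenvalues of the discrete Laplacian under
reflective boundaries.  The smoothing parameter s is chosen by
generalized cross-validation (GCV); missing nodes enter with zero weight
and are imputed by the smoother, and a robust mode iteratively
down-weights outliers with a bisquare function of the studentized
residuals.
"""

from __future__ import annotations

import numpy as np
from scipy.fft import dctn, idctn

__all__ = ["smoothn"]

_BISQUARE_C = 4.685


def _laplacian_eigenvalues(shape) -> np.ndarray:
    lam = np.zeros(shape)
    for ax, n in enumerate(shape):
        k = np.arange(n).reshape([-1 if a == ax else 1 for a in range(len(shape))])
        lam = lam + (-2.0 + 2.0 * np.cos(np.pi * k / n))
    return lam


def _solve(y_filled: np.ndarray, gamma: np.ndarray) -> np.ndarray:
    return idctn(gamma * dctn(y_filled, norm="ortho"), norm="ortho")


def _gcv_grid(y, z, w, lam2, s_grid):
    """GCV score for each candidate s, with missing data folded in via z."""
    y_filled = w * (y - z) + z
    dcty = dctn(y_filled, norm="ortho")
    n = y.size
    n_eff = max(int(np.count_nonzero(w > 0)), 1)
    scores = np.empty(len(s_grid))
    for i, s in enumerate(s_grid):
        gamma = 1.0 / (1.0 + s * lam2)
        zs = idctn(gamma * dcty, norm="ortho")
        rss = float(np.sum(w * (y - zs) ** 2))
        trh = float(gamma.sum())
        denom = max(1.0 - trh / n, 1e-12)
        scores[i] = rss / n_eff / denom ** 2
    return scores


def smoothn(
    y: np.ndarray,
    weights: np.ndarray | None = None,
    robust: bool = False,
    s: float | None = None,
    tol: float = 1e-5,
    max_iter: int = 100,
):
    """Smooth (and impute) gridded data; returns ``(z, s)``.

    Parameters
    ----------
    y : ndarray
        Data on a regular lattice, any dimensionality.  NaNs are treated
        as missing.
    weights : ndarray, optional
        Non-negative weights; zero marks missing nodes.
    robust : bool
        Iteratively re-weight outliers (bisquare) so isolated spikes do not
        drag the fit.
    s : float, optional
        Fixed smoothing parameter; by default chosen by GCV on a log grid.
    """
    y = np.asarray(y, dtype=np.float64)
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=np.float64).copy()
    if w.shape != y.shape or np.any(w < 0):
        raise ValueError("weights must be non-negative and match y's shape")
    nan = ~np.isfinite(y)
    w[nan] = 0.0
    if not np.any(w > 0):
        raise ValueError("no valid nodes to smooth")
    wmax = w.max()
    if wmax > 0:
        w = w / wmax
    y = np.where(nan, 0.0, y)

    lam2 = _laplacian_eigenvalues(y.shape) ** 2
    s_grid = np.logspace(-9, 9, 91)

    z = np.full_like(y, y[w > 0].mean())
    w_total = w
    n_robust = 3 if robust else 1
    s_used = s
    for _ in range(n_robust):
        for _ in range(max_iter):
            if s is None:
                scores = _gcv_grid(y, z, w_total, lam2, s_grid)
                s_used = float(s_grid[int(np.argmin(scores))])
            gamma = 1.0 / (1.0 + s_used * lam2)
            z_new = _solve(w_total * (y - z) + z, gamma)
            dz = np.linalg.norm(z_new - z) / (np.linalg.norm(z_new) + 1e-30)
            z = z_new
            if dz < tol:
                break
        if robust:
            r = y - z
            rv = r[w > 0]
            mad = np.median(np.abs(rv - np.median(rv)))
            scale = 1.4826 * mad if mad > 0 else (rv.std() + 1e-30)
            u = np.abs(r) / (scale + 1e-30)
            bis = np.where(u < _BISQUARE_C, (1.0 - (u / _BISQUARE_C) ** 2) ** 2, 0.0)
            w_total = w * bis
            if not np.any(w_total > 0):
                w_total = w
    return z, float(s_used)
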