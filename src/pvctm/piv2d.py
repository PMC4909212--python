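"""Stage 1: per-slice 2D sub-window cross-correlation (PIV).

Each z-slice of the "before" stack is compared with the slice at the same
height in the "after" stack through a grid of interrogation sub-windows.
For every sub-window the zero-mean normalized cross-correlation surface is
computed over a bounded range of integer lags; the correlation at each lag
is the Pearson coefficient of the two windows restricted to their overlap,
so a pure integer shift of identical content scores exactly 1 at the true
lag.  A three-point Gaussian interpolation of the peak then yields
sub-pixel lateral displacements (Dx, Dy).

The FFT and direct (DCC) paths evaluate the same quantity and agree to
numerical precision; FFT is the default and is batched over all windows of
a slice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stack_io import ImageStack, RunConfig

__all__ = [
    "SliceField",
    "correlate_2d",
    "subpixel_peak_2d",
    "normalized_median_test",
    "piv_slice",
    "piv_stack",
]

#: Windows whose intensity standard deviation falls below this fraction of
#: the slice-wide standard deviation are considered featureless (empty
#: pores) and masked invalid.
VARIANCE_FLOOR = 0.01

_EPS = 1e-12


@dataclass
class SliceField:
    """Lateral displacement field of one z-slice on the sub-window grid."""

    Dx: np.ndarray            # (gx, gy), pixels
    Dy: np.ndarray
    peak_quality: np.ndarray  # correlation peak height
    valid: np.ndarray         # bool
    origin: tuple[float, float]  # center of the first window, pixels
    step: int
    z_index: int


# ---------------------------------------------------------------------------
# Correlation surfaces


def _rect_sums(cs, a_x, b_x, a_y, b_y):
    """Rectangle sums from padded cumulative sums, batched over windows.

    cs has shape (G, wx+1, wy+1); a_x/b_x (Lx,) and a_y/b_y (Ly,) are the
    per-lag rectangle bounds.  Returns (G, Lx, Ly).
    """
    return (
        cs[:, b_x[:, None], b_y[None, :]]
        - cs[:, a_x[:, None], b_y[None, :]]
        - cs[:, b_x[:, None], a_y[None, :]]
        + cs[:, a_x[:, None], a_y[None, :]]
    )


def _overlap_bounds(lags, w):
    """Overlap rectangle bounds in window-1 and window-2 coordinates."""
    a1 = np.maximum(0, -lags)
    b1 = w - np.maximum(0, lags)
    return a1, b1, a1 + lags, b1 + lags


def _surfaces(wins1: np.ndarray, wins2: np.ndarray, search: int, method: str) -> np.ndarray:
    """Per-lag overlap Pearson correlation, batched.

    wins1, wins2: (G, wx, wy) float arrays; returns (G, L, L) with
    L = 2*search + 1, lag axis ordered -search..search.
    """
    G, wx, wy = wins1.shape
    s = int(search)
    if s >= min(wx, wy):
        raise ValueError("search range must be smaller than the window")
    lags = np.arange(-s, s + 1)
    n = ((wx - np.abs(lags))[:, None] * (wy - np.abs(lags))[None, :]).astype(np.float64)

    # Pre-centering leaves the per-lag Pearson value unchanged but avoids
    # catastrophic cancellation in the overlap sums for high-offset data.
    w1 = wins1.astype(np.float64)
    w2 = wins2.astype(np.float64)
    w1 = w1 - w1.mean(axis=(1, 2), keepdims=True)
    w2 = w2 - w2.mean(axis=(1, 2), keepdims=True)

    if method == "fft":
        N1, N2 = wx + 2 * s, wy + 2 * s
        F1 = np.fft.rfft2(w1, s=(N1, N2))
        F2 = np.fft.rfft2(w2, s=(N1, N2))
        full = np.fft.irfft2(np.conj(F1) * F2, s=(N1, N2))
        cross = full[:, lags % N1][:, :, lags % N2]
    elif method == "dcc":
        cross = np.empty((G, lags.size, lags.size))
        for i, dx in enumerate(lags):
            a1x, b1x, a2x, b2x = (int(v[0]) for v in _overlap_bounds(np.array([dx]), wx))
            for j, dy in enumerate(lags):
                a1y, b1y, a2y, b2y = (int(v[0]) for v in _overlap_bounds(np.array([dy]), wy))
                cross[:, i, j] = np.einsum(
                    "gxy,gxy->g",
                    w1[:, a1x:b1x, a1y:b1y],
                    w2[:, a2x:b2x, a2y:b2y],
                )
    else:
        raise ValueError(f"unknown method {method!r}")

    # Overlap sums / sums of squares via integral images.
    pad = ((0, 0), (1, 0), (1, 0))
    cs1 = np.pad(w1.cumsum(1).cumsum(2), pad)
    cq1 = np.pad((w1 ** 2).cumsum(1).cumsum(2), pad)
    cs2 = np.pad(w2.cumsum(1).cumsum(2), pad)
    cq2 = np.pad((w2 ** 2).cumsum(1).cumsum(2), pad)

    a1x, b1x, a2x, b2x = _overlap_bounds(lags, wx)
    a1y, b1y, a2y, b2y = _overlap_bounds(lags, wy)
    S1 = _rect_sums(cs1, a1x, b1x, a1y, b1y)
    Q1 = _rect_sums(cq1, a1x, b1x, a1y, b1y)
    S2 = _rect_sums(cs2, a2x, b2x, a2y, b2y)
    Q2 = _rect_sums(cq2, a2x, b2x, a2y, b2y)

    cov = cross - S1 * S2 / n
    v1 = np.maximum(Q1 - S1 ** 2 / n, 0.0)
    v2 = np.maximum(Q2 - S2 ** 2 / n, 0.0)
    # an overlap is degenerate when its variance is negligible relative to
    # the window's own variance (guards against cancellation round-off)
    floor1 = 1e-9 * (w1 ** 2).mean(axis=(1, 2))[:, None, None] * n + _EPS
    floor2 = 1e-9 * (w2 ** 2).mean(axis=(1, 2))[:, None, None] * n + _EPS
    ok = (v1 > floor1) & (v2 > floor2)
    denom = np.sqrt(v1 * v2)
    out = np.where(ok, cov / np.where(ok, denom, 1.0), 0.0)
    return np.clip(out, -1.0, 1.0)


def correlate_2d(win1, win2, method: str = "fft", search: int = 8):
    """Correlation surface of two equal-shape 2D windows over integer lags.

    Returns ``(surface, lags)`` where ``surface[i, j]`` is the zero-mean
    normalized (overlap-Pearson) correlation at lag
    ``(lags[i], lags[j])`` and ``lags = -search..search``.  A window with
    zero variance yields an all-zero surface (flagged invalid upstream).
    """
    win1 = np.asarray(win1, dtype=np.float64)
    win2 = np.asarray(win2, dtype=np.float64)
    if win1.shape != win2.shape or win1.ndim != 2:
        raise ValueError("windows must be 2D and of equal shape")
    surf = _surfaces(win1[None], win2[None], search, method)[0]
    return surf, np.arange(-search, search + 1)


# ---------------------------------------------------------------------------
# Sub-pixel peak


def _axis_refine(cm, c0, cp):
    """Three-point Gaussian (log-parabola) refinement along one axis."""
    if cm > 0 and c0 > 0 and cp > 0:
        lm, l0, lp = np.log(cm), np.log(c0), np.log(cp)
    else:  # fall back to a parabolic fit when logs are unavailable
        lm, l0, lp = cm, c0, cp
    denom = lm - 2.0 * l0 + lp
    if denom >= 0 or abs(denom) < _EPS:
        return 0.0
    delta = 0.5 * (lm - lp) / denom
    return float(np.clip(delta, -0.999, 0.999))


def subpixel_peak_2d(surface: np.ndarray, lags: np.ndarray | None = None):
    """Locate the correlation peak with per-axis 3-point Gaussian fits.

    Returns ``(dx, dy, ok)``.  A peak on the surface border cannot be
    refined; the integer lag is returned with ``ok = False``.
    """
    surface = np.asarray(surface, dtype=np.float64)
    if lags is None:
        s = (surface.shape[0] - 1) // 2
        lags = np.arange(-s, s + 1)
    i, j = np.unravel_index(np.argmax(surface), surface.shape)
    dx, dy = float(lags[i]), float(lags[j])
    if i == 0 or i == surface.shape[0] - 1 or j == 0 or j == surface.shape[1] - 1:
        return dx, dy, False
    dx += _axis_refine(surface[i - 1, j], surface[i, j], surface[i + 1, j])
    dy += _axis_refine(surface[i, j - 1], surface[i, j], surface[i, j + 1])
    return dx, dy, True


# ---------------------------------------------------------------------------
# Vector validation


def normalized_median_test(
    Dx: np.ndarray,
    Dy: np.ndarray,
    valid: np.ndarray,
    threshold: float = 2.0,
    noise: float = 0.1,
) -> np.ndarray:
    """Universal outlier detection for PIV vector fields.

    Each vector is compared against the median of its (up to 8) valid grid
    neighbors; the residual is normalized by the median residual of those
    neighbors plus a noise floor (px).  Vectors whose normalized residual
    exceeds ``threshold`` in either component are marked invalid.  Windows
    compared against decorrelated content (e.g. slices separated by a large
    axial displacement) occasionally lock onto a spurious correlation peak;
    this test removes such isolated outliers.
    """
    gx, gy = Dx.shape
    out = valid.copy()
    shifts = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)]
    for comp in (Dx, Dy):
        nb = np.full((len(shifts), gx, gy), np.nan)
        for s, (di, dj) in enumerate(shifts):
            src_i = slice(max(0, -di), gx - max(0, di))
            dst_i = slice(max(0, di), gx - max(0, -di))
            src_j = slice(max(0, -dj), gy - max(0, dj))
            dst_j = slice(max(0, dj), gy - max(0, -dj))
            vals = np.where(valid[src_i, src_j], comp[src_i, src_j], np.nan)
            nb[s, dst_i, dst_j] = vals
        with np.errstate(invalid="ignore"):
            med = np.nanmedian(nb, axis=0)
            resid = np.nanmedian(np.abs(nb - med), axis=0)
            r = np.abs(comp - med) / (resid + noise)
        has_nb = np.isfinite(med)
        out &= ~(has_nb & (r > threshold))
    return out


# ---------------------------------------------------------------------------
# Slice / stack drivers


def _window_grid(n: int, w: int, step: int) -> np.ndarray:
    """Start indices of sub-windows of width w stepped by step along n px."""
    if w > n:
        raise ValueError("window larger than slice")
    return np.arange(0, n - w + 1, step)


def piv_slice(slice1: np.ndarray, slice2: np.ndarray, cfg: RunConfig, z_index: int = 0) -> SliceField:
    """2D displacement field of one slice pair on the sub-window grid."""
    slice1 = np.asarray(slice1, dtype=np.float64)
    slice2 = np.asarray(slice2, dtype=np.float64)
    if slice1.shape != slice2.shape:
        raise ValueError("slices must have equal shape")
    wx, wy = cfg.window
    xs = _window_grid(slice1.shape[0], wx, cfg.step_xy)
    ys = _window_grid(slice1.shape[1], wy, cfg.step_xy)
    gx, gy = xs.size, ys.size

    sw1 = np.lib.stride_tricks.sliding_window_view(slice1, (wx, wy))[::cfg.step_xy, ::cfg.step_xy]
    sw2 = np.lib.stride_tricks.sliding_window_view(slice2, (wx, wy))[::cfg.step_xy, ::cfg.step_xy]
    wins1 = sw1.reshape(gx * gy, wx, wy)
    wins2 = sw2.reshape(gx * gy, wx, wy)

    floor1 = VARIANCE_FLOOR * slice1.std()
    floor2 = VARIANCE_FLOOR * slice2.std()
    ok_var = (wins1.std(axis=(1, 2)) > floor1) & (wins2.std(axis=(1, 2)) > floor2)

    surfs = _surfaces(wins1, wins2, cfg.search_xy, cfg.piv_method)
    lags = np.arange(-cfg.search_xy, cfg.search_xy + 1)

    Dx = np.zeros(gx * gy)
    Dy = np.zeros(gx * gy)
    peak = np.zeros(gx * gy)
    valid = np.zeros(gx * gy, dtype=bool)
    for g in range(gx * gy):
        if not ok_var[g]:
            continue
        dx, dy, ok = subpixel_peak_2d(surfs[g], lags)
        Dx[g], Dy[g] = dx, dy
        peak[g] = surfs[g].max()
        valid[g] = ok
    Dx = Dx.reshape(gx, gy)
    Dy = Dy.reshape(gx, gy)
    valid = normalized_median_test(Dx, Dy, valid.reshape(gx, gy))
    return SliceField(
        Dx, Dy, peak.reshape(gx, gy), valid,
        origin=(xs[0] + (wx - 1) / 2.0, ys[0] + (wy - 1) / 2.0),
        step=cfg.step_xy, z_index=z_index,
    )


def piv_stack(stack1: ImageStack, stack2: ImageStack, cfg: RunConfig) -> list[SliceField]:
    """Apply :func:`piv_slice` independently at every height of the stacks."""
    if stack1.shape != stack2.shape:
        raise ValueError("stacks must have equal shape")
    return [
        piv_slice(stack1.intensity[:, :, k], stack2.intensity[:, :, k], cfg, z_index=k)
        for k in range(stack1.shape[2])
    ]


def stack_surfaces(stack1: ImageStack, stack2: ImageStack, cfg: RunConfig):
    """Correlation surfaces of every sub-window of every slice pair.

    Returns ``(surfaces, usable, lags, (xs, ys))`` where ``surfaces`` has
    shape (nz, gx, gy, L, L) in float32, ``usable`` marks windows passing
    the variance floor and ``xs, ys`` are the window start indices.  This
    is the shared stage-1 product: per-slice vector fields are one
    reduction of it (:func:`piv_slice`), the slice-ensemble average used
    by the volume stage is another.
    """
    if stack1.shape != stack2.shape:
        raise ValueError("stacks must have equal shape")
    wx, wy = cfg.window
    nx, ny, nz = stack1.shape
    xs = _window_grid(nx, wx, cfg.step_xy)
    ys = _window_grid(ny, wy, cfg.step_xy)
    gx, gy = xs.size, ys.size
    L = 2 * cfg.search_xy + 1
    surfaces = np.empty((nz, gx, gy, L, L), dtype=np.float32)
    usable = np.zeros((nz, gx, gy), dtype=bool)
    for k in range(nz):
        s1 = np.asarray(stack1.intensity[:, :, k], dtype=np.float64)
        s2 = np.asarray(stack2.intensity[:, :, k], dtype=np.float64)
        sw1 = np.lib.stride_tricks.sliding_window_view(s1, (wx, wy))[::cfg.step_xy, ::cfg.step_xy]
        sw2 = np.lib.stride_tricks.sliding_window_view(s2, (wx, wy))[::cfg.step_xy, ::cfg.step_xy]
        w1 = sw1.reshape(gx * gy, wx, wy)
        w2 = sw2.reshape(gx * gy, wx, wy)
        ok = (
            (w1.std(axis=(1, 2)) > VARIANCE_FLOOR * s1.std())
            & (w2.std(axis=(1, 2)) > VARIANCE_FLOOR * s2.std())
        )
        surfaces[k] = _surfaces(w1, w2, cfg.search_xy, cfg.piv_method).reshape(gx, gy, L, L)
        usable[k] = ok.reshape(gx, gy)
    return surfaces, usable, np.arange(-cfg.search_xy, cfg.search_xy + 1), (xs, ys)
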