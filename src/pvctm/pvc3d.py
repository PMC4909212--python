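"""Stage 2: axial scan of normalized volume correlation (PVC core).

With the lateral displacement (Dx, Dy) of each sub-volume known from the
per-slice PIV stage, the axial component is recovered by a one-dimensional
scan: the sub-volume V1 of the "before" stack is compared against
sub-volumes V2 of the "after" stack centred at the laterally offset
position and shifted by integer dz in [-Mz, Mz].  The similarity measure
is the normalized volume correlation

    C = (V1 - <V1>) * (V2 - <V2>) /
        sqrt[(V1 - <V1>) * (V1 - <V1>)  (V2 - <V2>) * (V2 - <V2>)]

where ``*`` is the element-wise product summed over all voxels.  A
Gaussian fitted to the 5 samples around the peak of C(dz) gives Dz at
sub-pixel resolution.  Assembling (Dx, Dy, Dz) over a regular lattice of
sub-volumes yields the coarse-grained 3D deformation field.

An exhaustive direct-volume-correlation (DVC) search over all integer
3D lags is provided as the expensive cross-validation baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import warnings

import numpy as np
from scipy.optimize import OptimizeWarning, curve_fit
from skimage.feature import match_template

from . import piv2d
from .smoothing import smoothn
from .stack_io import DeformationGrid, ImageStack, RunConfig

__all__ = [
    "CorrelationProfile",
    "volume_correlation",
    "z_scan",
    "subpixel_peak_z",
    "validate_grid",
    "pvc_field",
    "smooth_field",
    "dvc_field",
]

_EPS = 1e-12


@dataclass
class CorrelationProfile:
    """Sampled C(dz) curve for one sub-volume; NaN marks out-of-bounds."""

    dz_values: np.ndarray
    C: np.ndarray

    def __post_init__(self):
        self.dz_values = np.asarray(self.dz_values, dtype=np.int64)
        self.C = np.asarray(self.C, dtype=np.float64)
        if self.dz_values.shape != self.C.shape:
            raise ValueError("dz_values and C must have equal length")

    @property
    def argmax(self) -> int:
        """Index of the maximum; ties broken toward the smaller |dz|."""
        finite = np.isfinite(self.C)
        if not finite.any():
            raise ValueError("profile has no valid samples")
        cmax = np.nanmax(self.C)
        cand = np.flatnonzero(finite & (self.C >= cmax - 1e-15))
        return int(cand[np.argmin(np.abs(self.dz_values[cand]))])


def volume_correlation(V1: np.ndarray, V2: np.ndarray) -> float:
    """Normalized volume correlation of two equal-shape sub-volumes.

    Returns NaN when either sub-volume has zero variance (undefined).
    """
    V1 = np.asarray(V1, dtype=np.float64)
    V2 = np.asarray(V2, dtype=np.float64)
    if V1.shape != V2.shape:
        raise ValueError("sub-volumes must have equal shape")
    a = V1 - V1.mean()
    b = V2 - V2.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom < _EPS:
        return float("nan")
    return float(np.clip((a * b).sum() / denom, -1.0, 1.0))


# ---------------------------------------------------------------------------
# z-scan


def _subvolume_start(center, window, depth):
    cx, cy, cz = center
    wx, wy = window
    return (
        int(round(cx - (wx - 1) / 2.0)),
        int(round(cy - (wy - 1) / 2.0)),
        int(round(cz - (depth - 1) / 2.0)),
    )


def z_scan(
    stack1: ImageStack,
    stack2: ImageStack,
    center,
    Dxy,
    cfg: RunConfig,
) -> CorrelationProfile:
    """Scan C(dz) for the sub-volume centred at ``center`` (voxel coords).

    ``Dxy`` is the stage-1 lateral displacement averaged over the
    sub-volume; V2 is extracted at the lateral offset rounded to the
    nearest pixel.  Out-of-bounds offsets are NaN-masked.
    """
    wx, wy = cfg.window
    lz = cfg.subvolume_depth
    Mz = cfg.z_scan_limit
    nx, ny, nz = stack1.shape
    x0, y0, z0 = _subvolume_start(center, cfg.window, lz)
    if x0 < 0 or y0 < 0 or z0 < 0 or x0 + wx > nx or y0 + wy > ny or z0 + lz > nz:
        raise ValueError("V1 out of bounds")
    x2 = x0 + int(round(Dxy[0]))
    y2 = y0 + int(round(Dxy[1]))
    dz_values = np.arange(-Mz, Mz + 1)
    C = np.full(dz_values.size, np.nan)
    if x2 < 0 or y2 < 0 or x2 + wx > nx or y2 + wy > ny:
        raise ValueError("all offsets out of bounds (lateral offset escapes the stack)")
    zlo = max(0, z0 - Mz)
    zhi = min(nz, z0 + Mz + lz)
    if zhi - zlo < lz:
        raise ValueError("all offsets out of bounds (axial)")

    V1 = stack1.intensity[x0:x0 + wx, y0:y0 + wy, z0:z0 + lz].astype(np.float64)
    a = V1 - V1.mean()
    va = (a * a).sum()
    block = stack2.intensity[x2:x2 + wx, y2:y2 + wy, zlo:zhi].astype(np.float64)
    sw = np.lib.stride_tricks.sliding_window_view(block, lz, axis=2)  # (wx, wy, K, lz)
    K = sw.shape[2]
    nvox = wx * wy * lz
    sums = sw.sum(axis=(0, 1, 3))
    sq = np.einsum("xykz,xykz->k", sw, sw)
    vb = sq - sums ** 2 / nvox
    cross = np.einsum("xyz,xykz->k", a, sw)
    denom = np.sqrt(np.maximum(va * vb, 0.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(denom > _EPS, cross / np.maximum(denom, _EPS), np.nan)
    offsets = zlo - z0 + np.arange(K)
    sel = (offsets >= -Mz) & (offsets <= Mz)
    C[offsets[sel] + Mz] = np.clip(c[sel], -1.0, 1.0)
    return CorrelationProfile(dz_values, C)


def _gauss(x, a, mu, sig):
    return a * np.exp(-((x - mu) ** 2) / (2.0 * sig ** 2))


def _parabolic(x, y):
    denom = y[0] - 2.0 * y[1] + y[2]
    if denom >= 0 or abs(denom) < _EPS:
        return None
    return float(x[1] + 0.5 * (y[0] - y[2]) / denom)


def subpixel_peak_z(profile: CorrelationProfile):
    """Sub-pixel Dz from a Gaussian fit to 5 samples around the peak.

    Returns ``(dz, ok)``.  Degenerate profiles (flat), edge peaks and
    non-convergent fits fall back with ``ok = False`` (to the integer peak
    or a 3-point parabola).
    """
    C = profile.C
    dz = profile.dz_values.astype(np.float64)
    finite = np.isfinite(C)
    if not finite.any():
        return float("nan"), False
    if np.nanmax(C) - np.nanmin(C) < 1e-12:
        return float("nan"), False
    p = profile.argmax
    d0 = float(dz[p])

    def _window_ok(half):
        lo, hi = p - half, p + half
        return lo >= 0 and hi < C.size and finite[lo:hi + 1].all()

    if _window_ok(2):
        x = dz[p - 2:p + 3]
        y = C[p - 2:p + 3]
        par = _parabolic(x[1:4], y[1:4])
        mu0 = par if par is not None and abs(par - d0) < 1.0 else d0
        sig0 = max(np.sqrt(max((x[-1] - x[0]) ** 2 / 8.0, 1.0)), 0.5)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", OptimizeWarning)
                popt, _ = curve_fit(
                    _gauss, x, y, p0=[max(y[2], 1e-3), mu0, sig0],
                    maxfev=400,
                )
            mu = float(popt[1])
            if abs(mu - d0) < 1.0:
                return mu, True
        except (RuntimeError, ValueError):
            pass
        if par is not None and abs(par - d0) < 1.0:
            return par, False
        return d0, False
    if _window_ok(1):
        par = _parabolic(dz[p - 1:p + 2], C[p - 1:p + 2])
        if par is not None and abs(par - d0) < 1.0:
            return par, False
    return d0, False


# ---------------------------------------------------------------------------
# Full-field drivers


def _lattice(shape, cfg: RunConfig):
    wx, wy = cfg.window
    lz = cfg.subvolume_depth
    if shape[0] < wx or shape[1] < wy or shape[2] < lz:
        raise ValueError("stacks too small for one sub-volume")
    xs = np.arange(0, shape[0] - wx + 1, cfg.step_xy)
    ys = np.arange(0, shape[1] - wy + 1, cfg.step_xy)
    zs = np.arange(0, shape[2] - lz + 1, cfg.step_z)
    return xs, ys, zs


def _grid_meta(xs, ys, zs, cfg):
    wx, wy = cfg.window
    lz = cfg.subvolume_depth
    origin = (xs[0] + (wx - 1) / 2.0, ys[0] + (wy - 1) / 2.0, zs[0] + (lz - 1) / 2.0)
    spacing = (float(cfg.step_xy), float(cfg.step_xy), float(cfg.step_z))
    return origin, spacing


def pvc_field(
    stack1: ImageStack,
    stack2: ImageStack,
    cfg: RunConfig,
) -> DeformationGrid:
    """Full two-stage PVC: slice-wise 2D correlation, sub-volume-averaged
    (Dx, Dy), then the axial z-scan.

    The lateral displacement of each sub-volume is taken from the ensemble
    average of the stage-1 correlation surfaces over the sub-volume's
    slice range (the correlation-plane analogue of averaging the 2D field
    over V1; far more robust when large axial motion decorrelates
    individual slice pairs).  Returns the displacement field in pixels on
    the sub-volume lattice.  Nodes where either stage degenerates
    (featureless windows, border peaks, flat or clipped profiles) or that
    fail the universal outlier test are masked invalid.  Smoothing is
    applied afterwards when ``cfg.smoothing`` is set.
    """
    if stack1.shape != stack2.shape:
        raise ValueError("stacks must have equal shape")
    xs, ys, zs = _lattice(stack1.shape, cfg)
    lz = cfg.subvolume_depth
    surfaces, usable, lags, _ = piv2d.stack_surfaces(stack1, stack2, cfg)

    shape = (xs.size, ys.size, zs.size)
    Dx = np.zeros(shape)
    Dy = np.zeros(shape)
    Dz = np.zeros(shape)
    mask = np.zeros(shape, dtype=bool)
    wx, wy = cfg.window
    for k, z0 in enumerate(zs):
        zr = slice(z0, z0 + lz)
        nok = usable[zr].sum(axis=0)                   # (gx, gy)
        num = np.einsum(
            "zxyab,zxy->xyab", surfaces[zr].astype(np.float64), usable[zr].astype(np.float64)
        )
        ens = num / np.maximum(nok, 1)[:, :, None, None]
        for i, x0 in enumerate(xs):
            for j, y0 in enumerate(ys):
                if nok[i, j] == 0:
                    continue
                dxy = piv2d.subpixel_peak_2d(ens[i, j], lags)
                if not dxy[2]:
                    continue
                center = (x0 + (wx - 1) / 2.0, y0 + (wy - 1) / 2.0, z0 + (lz - 1) / 2.0)
                try:
                    prof = z_scan(stack1, stack2, center, (dxy[0], dxy[1]), cfg)
                    dz, ok = subpixel_peak_z(prof)
                except ValueError:
                    continue
                if not np.isfinite(dz):
                    continue
                Dx[i, j, k] = dxy[0]
                Dy[i, j, k] = dxy[1]
                Dz[i, j, k] = dz
                mask[i, j, k] = True
    origin, spacing = _grid_meta(xs, ys, zs, cfg)
    grid = DeformationGrid(Dx, Dy, Dz, origin=origin, spacing=spacing, mask=mask,
                           unit="px", voxel_size=stack1.voxel_size)
    grid = validate_grid(grid)
    if cfg.smoothing:
        grid = smooth_field(grid)
    return grid


def validate_grid(field: DeformationGrid, threshold: float = 2.0,
                  noise: float = 0.1) -> DeformationGrid:
    """Universal outlier detection on the assembled 3D vector field.

    Each component of every node is compared against the median over its
    (up to 26) valid lattice neighbors, normalized by the neighbors' median
    residual plus a noise floor (px).  Nodes exceeding ``threshold`` are
    masked invalid; values are left untouched.  This is the lattice
    analogue of the per-slice test in stage 1 and removes nodes where the
    slice-averaged lateral displacement locked onto a spurious peak.
    """
    shape = field.shape
    shifts = [
        (di, dj, dk)
        for di in (-1, 0, 1) for dj in (-1, 0, 1) for dk in (-1, 0, 1)
        if (di, dj, dk) != (0, 0, 0)
    ]
    mask = field.mask.copy()
    for comp in (field.Dx, field.Dy, field.Dz):
        nb = np.full((len(shifts),) + shape, np.nan)
        for s, sh in enumerate(shifts):
            src = tuple(slice(max(0, -d), n - max(0, d)) for d, n in zip(sh, shape))
            dst = tuple(slice(max(0, d), n - max(0, -d)) for d, n in zip(sh, shape))
            nb[(s,) + dst] = np.where(field.mask[src], comp[src], np.nan)
        with np.errstate(invalid="ignore"):
            med = np.nanmedian(nb, axis=0)
            resid = np.nanmedian(np.abs(nb - med), axis=0)
            r = np.abs(comp - med) / (resid + noise)
        mask &= ~(np.isfinite(med) & (r > threshold))
    return DeformationGrid(
        field.Dx, field.Dy, field.Dz, origin=field.origin, spacing=field.spacing,
        mask=mask, unit=field.unit, voxel_size=field.voxel_size,
    )


def smooth_field(field: DeformationGrid, robust: bool = False) -> DeformationGrid:
    """Component-wise penalized spline smoothing with GCV-chosen parameter.

    Invalid nodes are treated as missing and imputed; the validity mask is
    preserved on the output so callers can still distinguish measured from
    imputed nodes.
    """
    if int(field.mask.sum()) < 10:
        raise ValueError("need at least 10 valid nodes to smooth")
    w = field.mask.astype(np.float64)
    comps = []
    for comp in (field.Dx, field.Dy, field.Dz):
        z, _ = smoothn(comp, weights=w, robust=robust)
        comps.append(z)
    return DeformationGrid(
        comps[0], comps[1], comps[2],
        origin=field.origin, spacing=field.spacing, mask=field.mask.copy(),
        unit=field.unit, voxel_size=field.voxel_size,
    )


def dvc_field(stack1: ImageStack, stack2: ImageStack, cfg: RunConfig) -> DeformationGrid:
    """Exhaustive integer 3D correlation search with sub-pixel refinement.

    For every node of the same lattice as :func:`pvc_field`, the sub-volume
    V1 is swept over all integer lags within (+-search_xy, +-search_xy,
    +-Mz) of the "after" stack by normalized correlation, followed by a
    per-axis 3-point refinement of the peak.  Intended as the (slow)
    cross-validation baseline on small stacks.
    """
    if stack1.shape != stack2.shape:
        raise ValueError("stacks must have equal shape")
    nx, ny, nz = stack1.shape
    wx, wy = cfg.window
    lz = cfg.subvolume_depth
    S, Mz = cfg.search_xy, cfg.z_scan_limit
    if 2 * S + wx > nx or 2 * S + wy > ny or 2 * Mz + lz > nz:
        raise ValueError("search range exceeds stack extent")
    xs, ys, zs = _lattice(stack1.shape, cfg)
    shape = (xs.size, ys.size, zs.size)
    Dx = np.zeros(shape)
    Dy = np.zeros(shape)
    Dz = np.zeros(shape)
    mask = np.zeros(shape, dtype=bool)
    vol2 = stack2.intensity.astype(np.float64)
    vol1 = stack1.intensity.astype(np.float64)
    for i, x0 in enumerate(xs):
        for j, y0 in enumerate(ys):
            for k, z0 in enumerate(zs):
                tmpl = vol1[x0:x0 + wx, y0:y0 + wy, z0:z0 + lz]
                if tmpl.std() < _EPS:
                    continue
                rx0, ry0, rz0 = max(0, x0 - S), max(0, y0 - S), max(0, z0 - Mz)
                rx1 = min(nx, x0 + wx + S)
                ry1 = min(ny, y0 + wy + S)
                rz1 = min(nz, z0 + lz + Mz)
                region = vol2[rx0:rx1, ry0:ry1, rz0:rz1]
                if any(r < t for r, t in zip(region.shape, tmpl.shape)):
                    continue
                corr = match_template(region, tmpl, pad_input=False)
                lag0 = np.array([rx0 - x0, ry0 - y0, rz0 - z0])
                cmax = corr.max()
                cand = np.argwhere(corr >= cmax - 1e-15)
                lag_cand = cand + lag0
                best = cand[np.argmin(np.abs(lag_cand).sum(axis=1))]
                lag = best + lag0
                disp = lag.astype(np.float64)
                refined = True
                for ax in range(3):
                    u = best[ax]
                    if u == 0 or u == corr.shape[ax] - 1:
                        refined = False
                        continue
                    sl = list(best)
                    tri = []
                    for off in (-1, 0, 1):
                        sl[ax] = u + off
                        tri.append(corr[tuple(sl)])
                    disp[ax] += piv2d._axis_refine(*tri)
                Dx[i, j, k], Dy[i, j, k], Dz[i, j, k] = disp
                mask[i, j, k] = refined
    origin, spacing = _grid_meta(xs, ys, zs, cfg)
    return DeformationGrid(Dx, Dy, Dz, origin=origin, spacing=spacing, mask=mask,
                           unit="px", voxel_size=stack1.voxel_size)
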