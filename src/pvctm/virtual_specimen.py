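"""Virtual specimens: synthetic speckle stacks with known ground truth.

The simulator emulates what a confocal reflection stack of a fibrous gel
looks like to a correlation algorithm: a dense random field of point
scatterers, each rendered as a 3D Gaussian point spread function and summed
into a volume.  Deforming the scatterer positions with a prescribed field
and re-rendering yields an image pair whose true displacement field is
known everywhere, which is the basis of every validation experiment in
this package.  Local matrix remodeling (densification/degradation) is
emulated by overwriting randomly placed cubes with a bright or dark
intensity quantile of the original volume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .stack_io import ImageStack

__all__ = [
    "ParticleSet",
    "PrescribedField",
    "RemodelingSpec",
    "sample_particles",
    "render_stack",
    "deform_particles",
    "translate_stack",
    "common_region",
    "apply_remodeling",
    "synthetic_cell_mask",
    "radial_intensity_correlation",
    "compression_shear_field",
]


@dataclass
class ParticleSet:
    """Point scatterers: continuous-valued centers (pixels) and amplitudes."""

    centers: np.ndarray  # (n, 3)
    amplitude: np.ndarray  # (n,)

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=np.float64))
        if self.centers.shape[1] != 3:
            raise ValueError("centers must be (n, 3)")
        if not np.all(np.isfinite(self.centers)):
            raise ValueError("particle centers must be finite")
        self.amplitude = np.broadcast_to(
            np.asarray(self.amplitude, dtype=np.float64), (len(self.centers),)
        ).copy()

    def __len__(self) -> int:
        return len(self.centers)


@dataclass
class PrescribedField:
    """A ground-truth displacement field u(r), evaluable anywhere.

    ``kind`` is one of ``translation`` (u = t), ``affine``
    (u(r) = A r + b - r) or ``custom`` (u given by a callable).
    """

    kind: str
    t: np.ndarray | None = None
    A: np.ndarray | None = None
    b: np.ndarray | None = None
    func: Callable[[np.ndarray], np.ndarray] | None = None

    @classmethod
    def translation(cls, t) -> "PrescribedField":
        return cls("translation", t=np.asarray(t, dtype=np.float64))

    @classmethod
    def affine(cls, A, b=(0.0, 0.0, 0.0)) -> "PrescribedField":
        return cls("affine", A=np.asarray(A, dtype=np.float64),
                   b=np.asarray(b, dtype=np.float64))

    @classmethod
    def custom(cls, func) -> "PrescribedField":
        return cls("custom", func=func)

    def displacement(self, r: np.ndarray) -> np.ndarray:
        """Evaluate u at positions r of shape (..., 3)."""
        r = np.asarray(r, dtype=np.float64)
        if self.kind == "translation":
            return np.broadcast_to(self.t, r.shape).copy()
        if self.kind == "affine":
            return r @ self.A.T + self.b - r
        if self.kind == "custom":
            return np.asarray(self.func(r), dtype=np.float64)
        raise ValueError(f"unknown field kind {self.kind!r}")


def compression_shear_field(nz: int, peak: float = 4.0) -> PrescribedField:
    """Uniform z-compression plus x-shear, linear in z about the mid-plane.

    u_x = s (z - nz/2) and u_z = -g (z - nz/2), with s and g chosen so the
    peak displacement of each component is ``peak`` pixels at the top and
    bottom faces.  With the standard axial scan limit (12 px) and peak 4 px
    this keeps the whole field inside the valid scan range while exercising
    sub-pixel recovery over the full window.
    """
    rate = peak / (nz / 2.0)
    A = np.eye(3)
    A[0, 2] = rate     # shear: ux grows with z
    A[2, 2] = 1 - rate  # compression along z
    b = np.array([-rate * nz / 2.0, 0.0, rate * nz / 2.0])
    return PrescribedField.affine(A, b)


@dataclass
class RemodelingSpec:
    """Bright/dark cube insertion emulating local ECM remodeling."""

    n_cubes: int = 110
    cube_edge: int = 8
    mode: str = "densify"
    fill_quantile: float = 0.02

    def __post_init__(self) -> None:
        if self.n_cubes < 0 or self.cube_edge < 1:
            raise ValueError("n_cubes must be >= 0 and cube_edge >= 1")
        if self.mode not in ("densify", "degrade"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not (0 < self.fill_quantile < 0.5):
            raise ValueError("fill_quantile must lie in (0, 0.5)")


# ---------------------------------------------------------------------------


def sample_particles(n: int, extent, seed: int, amplitude: float = 1.0) -> ParticleSet:
    """Sample n particle centers i.i.d. uniform over [0, extent) per axis."""
    extent = tuple(int(e) for e in extent)
    if n < 1 or any(e < 1 for e in extent):
        raise ValueError("n and extents must be positive")
    rng = np.random.default_rng(seed)
    centers = rng.uniform(0.0, 1.0, size=(n, 3)) * np.asarray(extent, dtype=np.float64)
    return ParticleSet(centers, np.full(n, float(amplitude)))


def render_stack(
    particles: ParticleSet,
    extent,
    psf_width: float = 2.0,
    voxel_size=(0.358, 0.358, 0.5),
    truncate: float = 4.0,
    batch: int = 1024,
    dtype=np.float32,
) -> ImageStack:
    """Render particles into a volume by direct summation of Gaussian PSFs.

    intensity(r) = sum_i a_i exp(-|r - c_i|^2 / (2 sigma^2)) with
    sigma = ``psf_width`` (isotropic), evaluated at voxel centers and
    truncated beyond ``truncate`` sigma from each particle.
    """
    if len(particles) == 0:
        raise ValueError("empty particle set")
    if psf_width <= 0:
        raise ValueError("psf_width must be positive")
    nx, ny, nz = (int(e) for e in extent)
    sigma = float(psf_width)
    R = int(np.ceil(truncate * sigma))
    offsets = np.arange(-R, R + 1)  # (L,)
    L = offsets.size
    out = np.zeros(nx * ny * nz, dtype=np.float64)
    centers = particles.centers
    amps = particles.amplitude
    for lo in range(0, len(centers), batch):
        c = centers[lo:lo + batch]          # (B, 3)
        a = amps[lo:lo + batch]
        base = np.floor(c).astype(np.int64)  # (B, 3)
        idx = base[:, :, None] + offsets[None, None, :]       # (B, 3, L)
        d = idx.astype(np.float64) - c[:, :, None]            # voxel - center
        g = np.exp(-0.5 * (d / sigma) ** 2)                   # (B, 3, L)
        inb = (idx >= 0) & (idx < np.array([nx, ny, nz])[None, :, None])
        g = np.where(inb, g, 0.0)
        idx = np.clip(idx, 0, np.array([nx, ny, nz])[None, :, None] - 1)
        w = np.einsum("bi,bj,bk,b->bijk", g[:, 0], g[:, 1], g[:, 2], a)
        flat = (
            (idx[:, 0, :, None, None] * ny + idx[:, 1, None, :, None]) * nz
            + idx[:, 2, None, None, :]
        )
        out += np.bincount(flat.ravel(), weights=w.ravel(), minlength=out.size)
    return ImageStack(out.reshape(nx, ny, nz).astype(dtype), voxel_size)


def deform_particles(particles: ParticleSet, prescribed: PrescribedField) -> ParticleSet:
    """Move each center c -> c + u(c); amplitudes unchanged."""
    u = prescribed.displacement(particles.centers)
    return ParticleSet(particles.centers + u, particles.amplitude.copy())


def translate_stack(stack: ImageStack, shift) -> ImageStack:
    """Shift a stack by integer pixels without wrap-around.

    The vacated margin is filled with zeros; use :func:`common_region` to
    obtain the slices of the region valid in both the original and shifted
    frames before any quantitative comparison.
    """
    shift = tuple(int(s) for s in shift)
    shape = stack.shape
    if any(abs(s) >= n for s, n in zip(shift, shape)):
        raise ValueError(f"shift {shift} exceeds extents {shape}")
    out = np.zeros_like(stack.intensity)
    src = tuple(slice(max(0, -s), n - max(0, s)) for s, n in zip(shift, shape))
    dst = tuple(slice(max(0, s), n - max(0, -s)) for s, n in zip(shift, shape))
    out[dst] = stack.intensity[src]
    return ImageStack(out, stack.voxel_size)


def common_region(extent, shift) -> tuple[slice, slice, slice]:
    """Slices of the region populated in both frames after translate_stack."""
    shift = tuple(int(s) for s in shift)
    if any(abs(s) >= n for s, n in zip(shift, extent)):
        raise ValueError(f"shift {shift} exceeds extents {tuple(extent)}")
    return tuple(slice(max(0, s), n - max(0, -s)) for s, n in zip(shift, extent))


def apply_remodeling(
    stack: ImageStack, spec: RemodelingSpec, seed: int, return_info: bool = False
):
    """Overwrite randomly placed cubes with a bright or dark quantile value.

    ``densify`` fills each cube with the (1 - fill_quantile) intensity
    quantile of the input, ``degrade`` with the fill_quantile quantile.
    Cubes may overlap; only voxels inside the cubes change.
    """
    nx, ny, nz = stack.shape
    e = spec.cube_edge
    if e > min(nx, ny, nz):
        raise ValueError("cube_edge exceeds volume extent")
    data = stack.intensity.copy()
    if spec.n_cubes == 0:
        out = ImageStack(data, stack.voxel_size)
        return (out, {"replaced_fraction": 0.0}) if return_info else out
    q = 1.0 - spec.fill_quantile if spec.mode == "densify" else spec.fill_quantile
    fill = float(np.quantile(stack.intensity.astype(np.float64), q))
    rng = np.random.default_rng(seed)
    corners = np.stack([
        rng.integers(0, nx - e + 1, spec.n_cubes),
        rng.integers(0, ny - e + 1, spec.n_cubes),
        rng.integers(0, nz - e + 1, spec.n_cubes),
    ], axis=1)
    touched = np.zeros(stack.shape, dtype=bool)
    for cx, cy, cz in corners:
        touched[cx:cx + e, cy:cy + e, cz:cz + e] = True
    data[touched] = fill
    out = ImageStack(data, stack.voxel_size)
    if return_info:
        return out, {
            "replaced_fraction": float(touched.sum()) / touched.size,
            "fill_value": fill,
            "corners": corners,
        }
    return out


def synthetic_cell_mask(extent, semi_axes, center=None) -> np.ndarray:
    """Binary ellipsoid mask (1 inside) on the voxel lattice.

    A fixture for surface-relative analyses; warns when the ellipsoid is so
    small that the mask degenerates to at most one voxel.
    """
    nx, ny, nz = (int(e) for e in extent)
    a = np.asarray(semi_axes, dtype=np.float64)
    if a.shape != (3,) or np.any(a <= 0):
        raise ValueError("semi_axes must be three positive numbers")
    c = (np.array([nx, ny, nz]) - 1) / 2.0 if center is None else np.asarray(center, float)
    x, y, z = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    mask = (
        ((x - c[0]) / a[0]) ** 2 + ((y - c[1]) / a[1]) ** 2 + ((z - c[2]) / a[2]) ** 2
    ) <= 1.0
    if mask.sum() <= 1:
        warnings.warn("degenerate cell mask (<= 1 voxel)", stacklevel=2)
    return mask


def radial_intensity_correlation(stack: ImageStack, max_r: float):
    """Two-point intensity correlation g(r) at lateral separation r.

    g(r) is the normalized autocovariance of the intensity at in-plane
    separation r, averaged over directions and z-slices, with g(0) = 1 and
    r sampled at the lateral pixel pitch.  Returns (r_um, g).
    """
    vol = stack.intensity.astype(np.float64)
    if float(vol.std()) == 0.0:
        raise ValueError("constant stack has no intensity fluctuations")
    sx = stack.voxel_size[0]
    nx, ny, nz = vol.shape
    acc = np.zeros((nx, ny))
    n_used = 0
    for k in range(nz):
        sl = vol[:, :, k]
        sl = sl - sl.mean()
        var = (sl ** 2).mean()
        if var == 0:
            continue
        f = np.fft.fft2(sl)
        ac = np.fft.ifft2(f * np.conj(f)).real / (sl.size * var)
        acc += ac
        n_used += 1
    if n_used == 0:
        raise ValueError("no slice with positive variance")
    acc /= n_used
    lag_x = np.minimum(np.arange(nx), nx - np.arange(nx))
    lag_y = np.minimum(np.arange(ny), ny - np.arange(ny))
    r_px = np.sqrt(lag_x[:, None] ** 2 + lag_y[None, :] ** 2)
    r_um = r_px * sx
    nbins = int(np.floor(max_r / sx)) + 1
    bins = np.clip(np.round(r_px).astype(int), 0, None)
    keep = (bins < nbins) & (r_um <= max_r + 0.5 * sx)
    sums = np.bincount(bins[keep], weights=acc[keep], minlength=nbins)
    counts = np.bincount(bins[keep], minlength=nbins)
    g = np.divide(sums, counts, out=np.full(nbins, np.nan), where=counts > 0)
    r = np.arange(nbins) * sx
    return r, g
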