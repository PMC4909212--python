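"""Image-stack and deformation-field containers and their file formats.

Conventions used throughout the package:

* Volumes are indexed ``(x, y, z)``, 0-based, with ``z`` the optical axis.
  The physical position of voxel ``(i, j, k)`` is ``(i*sx, j*sy, k*sz)`` in
  micrometres, where ``(sx, sy, sz)`` is the voxel size.
* Multi-page TIFF files store one ``z``-slice per page (bottom to top); a
  page is a 2D ``(y, x)`` raster, transposed on read to the ``(x, y)``
  convention above.
* Deformation fields live on a regular coarse lattice; they are serialised
  to HDF5 with named datasets ``Dx``, ``Dy``, ``Dz``, ``mask``, ``origin``,
  ``spacing``.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import tifffile

__all__ = [
    "ImageStack",
    "RunConfig",
    "DeformationGrid",
    "read_stack",
    "write_stack",
    "read_field",
    "write_field",
    "load_config",
    "save_config",
]

#: Default voxel size (μm) for 1024-px confocal frames of a 366.6 μm field
#: of view recorded in 0.5 μm axial increments.
DEFAULT_VOXEL_SIZE = (0.358, 0.358, 0.5)


@dataclass
class ImageStack:
    """A 3D scalar intensity volume with per-axis voxel size.

    Parameters
    ----------
    intensity : ndarray, shape (nx, ny, nz)
        Non-negative scalar intensities indexed (x, y, z).
    voxel_size : tuple of float
        Physical size of one voxel along (x, y, z), in μm.
    """

    intensity: np.ndarray
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity)
        if self.intensity.ndim != 3:
            raise ValueError(f"intensity must be 3D, got ndim={self.intensity.ndim}")
        if min(self.intensity.shape) < 1:
            raise ValueError("zero-size volume")
        vs = tuple(float(v) for v in self.voxel_size)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"voxel sizes must be three positive numbers, got {self.voxel_size}")
        self.voxel_size = vs
        if not np.all(np.isfinite(np.asarray(self.intensity, dtype=np.float64))):
            raise ValueError("intensity contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensity.shape

    def astype(self, dtype) -> "ImageStack":
        return ImageStack(self.intensity.astype(dtype), self.voxel_size)


@dataclass
class RunConfig:
    """Parameters of a partial-volume-correlation run.

    Defaults follow the standard confocal protocol: 32x32 px sub-windows
    stepped by 16 px laterally, 32x32x20 px sub-volumes, axial scan limit
    Mz = 12 px, axial lattice step 10 px (half the sub-volume depth).
    """

    window: tuple[int, int] = (32, 32)
    step_xy: int = 16
    subvolume_depth: int = 20
    z_scan_limit: int = 12
    step_z: int = 10
    search_xy: int = 8
    piv_method: str = "fft"
    smoothing: bool = False
    shear_modulus: float = 50.0  # Pa
    poisson_ratio: float = 0.2

    def __post_init__(self) -> None:
        wx, wy = self.window
        if wx < 4 or wy < 4 or self.subvolume_depth < 4:
            raise ValueError("window sides and sub-volume depth must be >= 4 px")
        if not (0 < self.step_xy <= wx):
            raise ValueError("step_xy must satisfy 0 < step_xy <= window width")
        if self.z_scan_limit < 1:
            raise ValueError("z_scan_limit must be >= 1")
        if self.step_z < 1:
            raise ValueError("step_z must be >= 1")
        if self.search_xy < 1:
            raise ValueError("search_xy must be >= 1")
        if self.piv_method not in ("fft", "dcc"):
            raise ValueError(f"unknown piv_method {self.piv_method!r}")
        if self.shear_modulus <= 0:
            raise ValueError("shear modulus must be positive")
        if not (0 < self.poisson_ratio < 0.5):
            raise ValueError("Poisson ratio must lie in (0, 0.5)")

    def replace(self, **kw) -> "RunConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class DeformationGrid:
    """Three-component displacement field on a regular coarse lattice.

    ``Dx``, ``Dy``, ``Dz`` share a common 3D shape (lattice nodes).  The
    lattice node (i, j, k) sits at ``origin + (i, j, k) * spacing`` in the
    voxel coordinates of the parent stacks.  ``unit`` records whether the
    components are in pixels ("px") or micrometres ("um").
    """

    Dx: np.ndarray
    Dy: np.ndarray
    Dz: np.ndarray
    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    mask: np.ndarray = None
    unit: str = "px"
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE

    def __post_init__(self) -> None:
        self.Dx = np.asarray(self.Dx, dtype=np.float64)
        self.Dy = np.asarray(self.Dy, dtype=np.float64)
        self.Dz = np.asarray(self.Dz, dtype=np.float64)
        if not (self.Dx.shape == self.Dy.shape == self.Dz.shape):
            raise ValueError("Dx, Dy, Dz must share a shape")
        if self.mask is None:
            self.mask = np.ones(self.Dx.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.Dx.shape:
                raise ValueError("mask shape must match component shape")
        self.origin = tuple(float(v) for v in self.origin)
        self.spacing = tuple(float(v) for v in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("lattice spacing must be positive")
        if self.unit not in ("px", "um"):
            raise ValueError(f"unknown unit {self.unit!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.Dx.shape

    def components(self) -> np.ndarray:
        """Stack (Dx, Dy, Dz) into shape (3, nx, ny, nz)."""
        return np.stack([self.Dx, self.Dy, self.Dz])

    def node_positions(self, unit: str = "px") -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis 1D node coordinate arrays in pixels or μm."""
        axes = []
        for a in range(3):
            x = self.origin[a] + np.arange(self.shape[a]) * self.spacing[a]
            if unit == "um":
                x = x * self.voxel_size[a]
            axes.append(x)
        return tuple(axes)

    def to_um(self) -> "DeformationGrid":
        """Convert displacement components from pixels to micrometres."""
        if self.unit == "um":
            return self
        sx, sy, sz = self.voxel_size
        return DeformationGrid(
            self.Dx * sx, self.Dy * sy, self.Dz * sz,
            origin=self.origin, spacing=self.spacing, mask=self.mask.copy(),
            unit="um", voxel_size=self.voxel_size,
        )

    def magnitude(self) -> np.ndarray:
        return np.sqrt(self.Dx ** 2 + self.Dy ** 2 + self.Dz ** 2)


# ---------------------------------------------------------------------------
# Stack I/O


def read_stack(path, voxel_size: tuple[float, float, float] | None = None) -> ImageStack:
    """Read an image stack from multi-page TIFF or HDF5.

    TIFF pages are z-slices in (y, x) raster order; HDF5 files must hold an
    ``intensity`` dataset in (x, y, z) order with an optional ``voxel_size``
    attribute.  An explicit ``voxel_size`` argument overrides metadata; when
    both are absent the confocal default applies.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            data = f["intensity"][()]
            meta_vs = f["intensity"].attrs.get("voxel_size")
        vs = voxel_size or (tuple(meta_vs) if meta_vs is not None else DEFAULT_VOXEL_SIZE)
        return ImageStack(data, vs)
    with tifffile.TiffFile(str(path)) as tf:
        shapes = {p.shape for p in tf.pages}
        if len(shapes) > 1:
            raise ValueError(f"inconsistent page shapes in {path.name}: {sorted(shapes)}")
        pages = tf.asarray()
    if pages.ndim == 2:
        pages = pages[None]
    if pages.ndim != 3:
        raise ValueError(f"expected a single-channel z-stack, got shape {pages.shape}")
    # pages: (z, y, x) -> (x, y, z)
    volume = np.transpose(pages, (2, 1, 0))
    vs = voxel_size or _tiff_voxel_size(path) or DEFAULT_VOXEL_SIZE
    return ImageStack(volume, vs)


def _tiff_voxel_size(path: Path):
    """Pull (sx, sy, sz) from ImageJ-style TIFF metadata if present."""
    try:
        with tifffile.TiffFile(str(path)) as tf:
            meta = tf.imagej_metadata or {}
            sz = meta.get("spacing")
            page = tf.pages[0]
            xres = page.tags.get("XResolution")
            yres = page.tags.get("YResolution")
            if sz and xres and yres:
                sx = xres.value[1] / xres.value[0]
                sy = yres.value[1] / yres.value[0]
                return (float(sx), float(sy), float(sz))
    except Exception:
        pass
    return None


def write_stack(stack: ImageStack, path, dtype=None) -> None:
    """Write a stack as a multi-page TIFF (one page per z-slice).

    Lossless for 8/16-bit integer and 32-bit float intensities.  Requesting
    an integer dtype for a volume with negative intensities is an error.
    """
    path = Path(path)
    data = stack.intensity
    if dtype is not None:
        dtype = np.dtype(dtype)
        if np.issubdtype(dtype, np.integer) and np.any(data < 0):
            raise ValueError("negative intensities cannot be stored in an integer dtype")
        data = data.astype(dtype)
    pages = np.transpose(data, (2, 1, 0))  # (z, y, x)
    sx, sy, sz = stack.voxel_size
    tifffile.imwrite(
        str(path), pages,
        imagej=pages.dtype in (np.dtype(np.uint8), np.dtype(np.uint16), np.dtype(np.float32)),
        resolution=(1.0 / sx, 1.0 / sy),
        metadata={"spacing": sz, "unit": "um", "axes": "ZYX"},
    )


# ---------------------------------------------------------------------------
# Deformation-field I/O


def write_field(fld: DeformationGrid, path) -> None:
    """Serialise a deformation lattice to HDF5 (datasets Dx, Dy, Dz, mask,
    origin, spacing; attributes unit and voxel_size)."""
    with h5py.File(Path(path), "w") as f:
        for name in ("Dx", "Dy", "Dz"):
            f.create_dataset(name, data=getattr(fld, name))
        f.create_dataset("mask", data=fld.mask.astype(np.uint8))
        f.create_dataset("origin", data=np.asarray(fld.origin, dtype=np.float64))
        f.create_dataset("spacing", data=np.asarray(fld.spacing, dtype=np.float64))
        f.attrs["unit"] = fld.unit
        f.attrs["voxel_size"] = np.asarray(fld.voxel_size, dtype=np.float64)


def read_field(path) -> DeformationGrid:
    with h5py.File(Path(path), "r") as f:
        return DeformationGrid(
            f["Dx"][()], f["Dy"][()], f["Dz"][()],
            origin=tuple(f["origin"][()]),
            spacing=tuple(f["spacing"][()]),
            mask=f["mask"][()].astype(bool),
            unit=str(f.attrs.get("unit", "px")),
            voxel_size=tuple(f.attrs.get("voxel_size", DEFAULT_VOXEL_SIZE)),
        )


# ---------------------------------------------------------------------------
# Config I/O (TOML)

_CONFIG_KEYS = [f.name for f in dataclasses.fields(RunConfig)]


def load_config(path) -> RunConfig:
    """Read a RunConfig from a TOML file (top-level or under [pvc])."""
    with open(Path(path), "rb") as fh:
        doc = tomllib.load(fh)
    section = doc.get("pvc", doc)
    unknown = set(section) - set(_CONFIG_KEYS)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "window" in section:
        section["window"] = tuple(section["window"])
    return RunConfig(**section)


def save_config(cfg: RunConfig, path) -> None:
    lines = ["[pvc]"]
    for f in dataclasses.fields(cfg):
        v = getattr(cfg, f.name)
        if isinstance(v, str):
            lines.append(f'{f.name} = "{v}"')
        elif isinstance(v, bool):
            lines.append(f"{f.name} = {str(v).lower()}")
        elif isinstance(v, tuple):
            lines.append(f"{f.name} = [{', '.join(str(x) for x in v)}]")
        else:
            lines.append(f"{f.name} = {v}")
    Path(path).write_text("\n".join(lines) + "\n")
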