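"""Model/Results interface to the reflectance traction microscopy chain.

``PartialVolumeCorrelation`` is constructed from a before/after stack pair
(plus a run configuration); ``fit()`` runs the two-stage correlation and
returns a ``PVCResults`` object holding the deformation lattice with its
validity mask and diagnostics.  Downstream mechanics — strain, the
normal/tangential decomposition around a cell mask, traction and
contractility — hang off the results object, as does ``summary()``.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import mechanics, pvc3d, surface as surf_mod
from .stack_io import DeformationGrid, ImageStack, RunConfig, read_stack

__all__ = ["PartialVolumeCorrelation", "PVCResults"]


class PartialVolumeCorrelation:
    """Two-stage deformation estimator for a confocal stack pair.

    Parameters
    ----------
    before, after : ImageStack
        The traction-stressed and relaxed stacks, equal shape.
    config : RunConfig, optional
        Window/scan parameters; the confocal defaults apply otherwise.
    """

    def __init__(self, before: ImageStack, after: ImageStack,
                 config: RunConfig | None = None):
        if before.shape != after.shape:
            raise ValueError("before/after stacks must have equal shape")
        self.before = before
        self.after = after
        self.config = config or RunConfig()

    @classmethod
    def from_files(cls, before_path, after_path, config: RunConfig | None = None):
        return cls(read_stack(before_path), read_stack(after_path), config)

    def fit(self, smoothing: bool | None = None) -> "PVCResults":
        """Run PIV + z-scan; optionally override the smoothing switch."""
        cfg = self.config if smoothing is None else self.config.replace(smoothing=smoothing)
        t0 = time.perf_counter()
        grid = pvc3d.pvc_field(self.before, self.after, cfg)
        elapsed = time.perf_counter() - t0
        return PVCResults(self, grid, cfg, elapsed)


@dataclass
class PVCResults:
    """Fitted deformation field plus diagnostics and downstream mechanics."""

    model: PartialVolumeCorrelation
    field: DeformationGrid         # displacement lattice, pixels
    config: RunConfig
    elapsed_s: float

    @property
    def field_um(self) -> DeformationGrid:
        return self.field.to_um()

    @property
    def invalid_fraction(self) -> float:
        return float(1.0 - self.field.mask.mean())

    def strain(self) -> mechanics.StrainGrid:
        return mechanics.strain_tensor(self.field)

    def membrane_distances(self, cell_mask: np.ndarray) -> surf_mod.MembraneDistanceField:
        return surf_mod.membrane_distance(cell_mask, self.field,
                                          voxel_size=self.field.voxel_size)

    def decompose(self, cell_mask: np.ndarray) -> pd.DataFrame:
        """Normal/tangential decomposition of D around the cell mask (μm)."""
        return mechanics.decompose_deformation(self.field, self.membrane_distances(cell_mask))

    def profile(self, cell_mask: np.ndarray, bin_width: float = 10.0) -> pd.DataFrame:
        return mechanics.profile_by_distance(self.decompose(cell_mask), bin_width)

    def traction(self, cell_mask: np.ndarray,
                 params: mechanics.ElasticParams | None = None):
        """Cell surface, per-face traction and contractility (linear elastic)."""
        params = params or mechanics.ElasticParams(
            G=self.config.shear_modulus, nu=self.config.poisson_ratio
        )
        cell = surf_mod.isosurface(cell_mask, voxel_size=self.field.voxel_size)
        stress = mechanics.cauchy_stress(self.strain(), params)
        result = mechanics.surface_traction(stress, cell, params)
        return cell, result

    # -- presentation -----------------------------------------------------

    def summary(self) -> str:
        g = self.field_um
        ok = self.field.mask
        lines = [
            "Partial Volume Correlation Results",
            "=" * 50,
            f"stack shape (voxels):    {self.model.before.shape}",
            f"voxel size (um):         {self.field.voxel_size}",
            f"lattice nodes:           {self.field.shape}"
            f"  spacing (px): {tuple(int(s) for s in self.field.spacing)}",
            f"window / depth / Mz:     {self.config.window} / "
            f"{self.config.subvolume_depth} / {self.config.z_scan_limit}",
            f"valid nodes:             {int(ok.sum())}/{ok.size} "
            f"({100 * ok.mean():.1f}%)",
            f"fit time:                {self.elapsed_s:.1f} s",
            "-" * 50,
            "displacement (um)        mean      std      min      max",
        ]
        for name, comp in (("Dx", g.Dx), ("Dy", g.Dy), ("Dz", g.Dz),
                           ("|D|", g.magnitude())):
            v = comp[ok]
            if v.size == 0:
                lines.append(f"  {name:<6}  (no valid nodes)")
            else:
                lines.append(
                    f"  {name:<6} {v.mean():>12.3f} {v.std():>8.3f} "
                    f"{v.min():>8.3f} {v.max():>8.3f}"
                )
        return "\n".join(lines)

    def plot_field(self, z_index: int | None = None, ax=None):
        """Quiver plot of (Dx, Dy) on one lattice plane, colored by |D|."""
        import matplotlib.pyplot as plt

        g = self.field_um
        k = g.shape[2] // 2 if z_index is None else z_index
        xs, ys, _ = g.node_positions(unit="um")
        X, Y = np.meshgrid(xs, ys, indexing="ij")
        mag = np.sqrt(g.Dx[:, :, k] ** 2 + g.Dy[:, :, k] ** 2)
        if ax is None:
            _, ax = plt.subplots()
        q = ax.quiver(X, Y, g.Dx[:, :, k], g.Dy[:, :, k], mag)
        ax.set_xlabel("x (um)")
        ax.set_ylabel("y (um)")
        ax.set_aspect("equal")
        plt.colorbar(q, ax=ax, label="|D| lateral (um)")
        return ax

    def plot_profile(self, cell_mask: np.ndarray, bin_width: float = 10.0, ax=None):
        """Distance-binned |D|, |Dn|, |Dt| with standard-deviation bars."""
        import matplotlib.pyplot as plt

        prof = self.profile(cell_mask, bin_width)
        if ax is None:
            _, ax = plt.subplots()
        for mean, std, label in (("mean_D", "std_D", "D"),
                                 ("mean_absDn", "std_absDn", "Dn"),
                                 ("mean_Dt", "std_Dt", "Dt")):
            ax.errorbar(prof["R_bin_center"], prof[mean], yerr=prof[std],
                        marker="o", capsize=3, label=label)
        ax.set_xlabel("distance to membrane R (um)")
        ax.set_ylabel("deformation (um)")
        ax.legend()
        return ax
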