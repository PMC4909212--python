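"""Mechanics downstream of the deformation field.

Small-strain tensor by finite differences on the coarse lattice,
normal/tangential decomposition of the deformation around the cell
surface, distance-binned profiles, and the linear-elastic chain: Cauchy
stress sigma = 2 G eps + lambda tr(eps) I, surface traction T = sigma . n
and the scalar contractility C = sum_f A_f T_f . R_hat_cm.

All mechanical quantities assume displacement components and lattice
spacing in micrometres; strains are dimensionless, stresses in Pa and
contractility is reported in nN (1 Pa um^2 = 1e-6 nN).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .stack_io import DeformationGrid
from .surface import CellSurface, MembraneDistanceField

__all__ = [
    "StrainGrid",
    "ElasticParams",
    "TractionResult",
    "strain_tensor",
    "strain_magnitude",
    "decompose_deformation",
    "profile_by_distance",
    "normal_strain_projection",
    "cauchy_stress",
    "surface_traction",
    "contractility",
]

PA_UM2_TO_NN = 1e-3  # 1 Pa·μm² = 1e-12 N = 1e-3 nN


@dataclass
class StrainGrid:
    """Symmetric small-strain tensor per lattice node (dimensionless)."""

    tensor: np.ndarray  # (nx, ny, nz, 3, 3)
    origin: tuple[float, float, float]   # lattice origin, μm
    spacing: tuple[float, float, float]  # lattice spacing, μm
    mask: np.ndarray

    @property
    def magnitude(self) -> np.ndarray:
        return strain_magnitude(self)


@dataclass
class ElasticParams:
    """Linear isotropic elasticity: shear modulus G (Pa), Poisson ratio ν."""

    G: float = 50.0
    nu: float = 0.2

    def __post_init__(self):
        if self.G <= 0:
            raise ValueError("shear modulus must be positive")
        if not (0 < self.nu < 0.5):
            raise ValueError("Poisson ratio must lie in (0, 0.5)")

    @property
    def lam(self) -> float:
        """First Lamé parameter λ = 2Gν/(1−2ν), in Pa."""
        return 2.0 * self.G * self.nu / (1.0 - 2.0 * self.nu)


@dataclass
class TractionResult:
    """Per-face surface traction (Pa) and the scalar contractility (nN)."""

    T: np.ndarray           # (nf, 3) traction vectors, Pa
    Tn: np.ndarray          # (nf,) normal traction, Pa
    contractility_nN: float
    linear_elastic: bool = True  # caveat flag: linear, isotropic constitutive law


# ---------------------------------------------------------------------------
# Strain


def strain_tensor(field: DeformationGrid) -> StrainGrid:
    """ε_ij = (∂D_i/∂x_j + ∂D_j/∂x_i)/2 by central differences.

    The field is converted to μm (components and lattice spacing) before
    differentiation; one-sided second-order differences are used at the
    lattice boundary.  Nodes touching an invalid node propagate invalidity.
    """
    if any(n < 3 for n in field.shape):
        raise ValueError("need at least 3 lattice nodes per axis for strain")
    f = field.to_um()
    spacing_um = tuple(s * v for s, v in zip(f.spacing, f.voxel_size))
    origin_um = tuple(o * v for o, v in zip(f.origin, f.voxel_size))
    comps = [f.Dx, f.Dy, f.Dz]
    grads = [np.gradient(c, *spacing_um, edge_order=2) for c in comps]
    eps = np.empty(f.shape + (3, 3))
    for i in range(3):
        for j in range(3):
            eps[..., i, j] = 0.5 * (grads[i][j] + grads[j][i])
    # a node is valid only if the stencil it used saw no invalid neighbor
    bad = ~f.mask
    grown = bad.copy()
    for ax in range(3):
        grown |= np.roll(bad, 1, axis=ax) | np.roll(bad, -1, axis=ax)
    mask = ~grown & f.mask
    return StrainGrid(eps, origin=origin_um, spacing=spacing_um, mask=mask)


def strain_magnitude(strain: StrainGrid) -> np.ndarray:
    """Frobenius norm sqrt(ε:ε) per node."""
    return np.sqrt(np.einsum("...ij,...ij->...", strain.tensor, strain.tensor))


# ---------------------------------------------------------------------------
# Normal / tangential decomposition


def decompose_deformation(
    field: DeformationGrid, distances: MembraneDistanceField
) -> pd.DataFrame:
    """Split D at each node into membrane-normal and tangential parts.

    For a node at r_A with nearest membrane point r_B, Δr = r_B − r_A and
    Dn = D·Δr/|Δr| (signed: motion toward the cell is positive).  Returns a
    tidy frame with columns R, D, Dn, Dt over valid nodes outside the cell;
    nodes on the membrane (R = 0) are excluded since the direction is
    undefined.
    """
    f = field.to_um()
    if distances.R.shape != f.shape:
        raise ValueError("distance field and deformation lattice differ in shape")
    xs, ys, zs = f.node_positions(unit="um")
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    rA = np.stack([X, Y, Z], axis=-1)
    dr = distances.nearest_point - rA
    R = np.linalg.norm(dr, axis=-1)
    D = np.stack([f.Dx, f.Dy, f.Dz], axis=-1)
    ok = f.mask & ~distances.inside & (R > 1e-9)
    with np.errstate(invalid="ignore", divide="ignore"):
        nhat = dr / np.maximum(R[..., None], 1e-30)
    Dn = np.einsum("...i,...i->...", D, nhat)
    Dt_vec = D - Dn[..., None] * nhat
    Dt = np.linalg.norm(Dt_vec, axis=-1)
    Dmag = np.linalg.norm(D, axis=-1)
    return pd.DataFrame({
        "R": R[ok],
        "D": Dmag[ok],
        "Dn": Dn[ok],
        "Dt": Dt[ok],
    })


def profile_by_distance(decomposed: pd.DataFrame, bin_width: float = 10.0) -> pd.DataFrame:
    """Bin the decomposition by membrane distance (default 10 μm bins).

    Returns per-bin mean and standard deviation of |D|, Dn (signed and
    absolute) and |Dt|, plus counts; empty bins are reported with n = 0.
    """
    if len(decomposed) == 0:
        return pd.DataFrame(columns=[
            "R_bin_center", "n", "mean_D", "std_D", "mean_Dn", "std_Dn",
            "mean_absDn", "std_absDn", "mean_Dt", "std_Dt",
        ])
    nbins = int(np.floor(decomposed["R"].max() / bin_width)) + 1
    idx = np.clip((decomposed["R"] // bin_width).astype(int), 0, nbins - 1)
    rows = []
    for b in range(nbins):
        sel = decomposed[idx == b]
        row = {"R_bin_center": (b + 0.5) * bin_width, "n": len(sel)}
        for col, name in (("D", "D"), ("Dn", "Dn"), ("Dt", "Dt")):
            row[f"mean_{name}"] = sel[col].mean() if len(sel) else np.nan
            row[f"std_{name}"] = sel[col].std(ddof=0) if len(sel) else np.nan
        row["mean_absDn"] = sel["Dn"].abs().mean() if len(sel) else np.nan
        row["std_absDn"] = sel["Dn"].abs().std(ddof=0) if len(sel) else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Stress, traction, contractility


def _interp_tensor(grid_tensor, origin, spacing, points):
    """Trilinear interpolation of a per-node 3x3 tensor at physical points."""
    axes = [origin[a] + np.arange(grid_tensor.shape[a]) * spacing[a] for a in range(3)]
    out = np.empty((len(points), 3, 3))
    outside = np.zeros(len(points), dtype=bool)
    for a in range(3):
        outside |= (points[:, a] < axes[a][0]) | (points[:, a] > axes[a][-1])
    for i in range(3):
        for j in range(3):
            itp = RegularGridInterpolator(
                axes, grid_tensor[..., i, j], bounds_error=False, fill_value=None
            )
            out[:, i, j] = itp(points)
    return out, outside


def normal_strain_projection(strain: StrainGrid, surf: CellSurface):
    """ε_nn = n·ε·n per face (pulling < 0, pushing > 0).

    Returns ``(eps_nn, inside_lattice)``; faces outside the strain lattice
    are extrapolated and flagged False.
    """
    eps, outside = _interp_tensor(strain.tensor, strain.origin, strain.spacing,
                                  surf.face_centers)
    n = surf.face_normals
    eps_nn = np.einsum("fi,fij,fj->f", n, eps, n)
    return eps_nn, ~outside


def cauchy_stress(strain: StrainGrid, params: ElasticParams) -> StrainGrid:
    """σ = 2Gε + λ tr(ε) I per node (Pa); warns when strain exceeds 5%."""
    mag = strain_magnitude(strain)
    if np.any(mag[strain.mask] > 0.05):
        warnings.warn(
            "strain magnitudes exceed 5%; the linear elastic approximation "
            "becomes questionable", stacklevel=2,
        )
    tr = np.einsum("...ii->...", strain.tensor)
    sigma = 2.0 * params.G * strain.tensor + params.lam * tr[..., None, None] * np.eye(3)
    return StrainGrid(sigma, origin=strain.origin, spacing=strain.spacing,
                      mask=strain.mask)


def surface_traction(
    stress: StrainGrid, surf: CellSurface, params: ElasticParams | None = None
) -> TractionResult:
    """T = σ·n per face (Pa), with Tn = T·n; pulling gives Tn < 0.

    The stress tensor is trilinearly interpolated to the face centers.  On
    an open mesh the contractility sum is still evaluated but a warning is
    raised.
    """
    if not surf.closed:
        warnings.warn("open mesh: traction and contractility are approximate",
                      stacklevel=2)
    sigma, _ = _interp_tensor(stress.tensor, stress.origin, stress.spacing,
                              surf.face_centers)
    n = surf.face_normals
    T = np.einsum("fij,fj->fi", sigma, n)
    Tn = np.einsum("fi,fi->f", T, n)
    C = contractility_from_vectors(T, surf)
    return TractionResult(T=T, Tn=Tn, contractility_nN=C)


def contractility_from_vectors(T: np.ndarray, surf: CellSurface) -> float:
    """C = Σ_f A_f (T_f · R̂_cm,f) in nN.

    R̂_cm points from each face center toward the surface's center of mass,
    so a uniformly inward (pulling) traction gives positive contractility.
    Zero-area faces are excluded by construction.
    """
    rvec = surf.center_of_mass[None, :] - surf.face_centers
    norm = np.linalg.norm(rvec, axis=1)
    ok = norm > 1e-12
    rhat = np.zeros_like(rvec)
    rhat[ok] = rvec[ok] / norm[ok, None]
    c_pa_um2 = float(np.sum(surf.face_areas * np.einsum("fi,fi->f", T, rhat)))
    return c_pa_um2 * PA_UM2_TO_NN


def contractility(traction: TractionResult, surf: CellSurface) -> float:
    """Scalar contractility (nN) of an existing traction result."""
    if not surf.closed:
        warnings.warn("open mesh: contractility is approximate", stacklevel=2)
    return contractility_from_vectors(traction.T, surf)
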