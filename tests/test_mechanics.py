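import numpy as np
import pandas as pd
import pytest

from pvctm import mechanics as mech, surface as surf_mod, virtual_specimen as vs
from pvctm.stack_io import DeformationGrid
from pvctm.surface import MembraneDistanceField


def affine_grid(A, shape=(6, 6, 5), spacing=4.0):
    """Displacement u(r) = (A - I) r on a lattice with unit voxels."""
    idx = [np.arange(s) * spacing for s in shape]
    X, Y, Z = np.meshgrid(*idx, indexing="ij")
    r = np.stack([X, Y, Z], axis=-1)
    u = r @ (A - np.eye(3)).T
    return DeformationGrid(u[..., 0], u[..., 1], u[..., 2], origin=(0, 0, 0),
                           spacing=(spacing,) * 3, voxel_size=(1, 1, 1))


class TestStrainTensor:
    def test_rigid_translation_zero_strain(self):
        c = np.full((5, 5, 4), 3.7)
        g = DeformationGrid(c, -c, 2 * c, origin=(0, 0, 0), spacing=(4, 4, 4),
                            voxel_size=(1, 1, 1))
        eps = mech.strain_tensor(g)
        np.testing.assert_allclose(eps.tensor, 0.0, atol=1e-12)

    def test_pure_z_compression(self):
        gamma = 0.02
        A = np.diag([1.0, 1.0, 1.0 - gamma])
        eps = mech.strain_tensor(affine_grid(A))
        np.testing.assert_allclose(eps.tensor[..., 2, 2], -gamma, atol=1e-10)
        eps_others = eps.tensor.copy()
        eps_others[..., 2, 2] = 0.0
        np.testing.assert_allclose(eps_others, 0.0, atol=1e-10)

    def test_simple_shear(self):
        s = 0.04
        A = np.eye(3)
        A[0, 2] = s  # Dx = s * z
        eps = mech.strain_tensor(affine_grid(A))
        np.testing.assert_allclose(eps.tensor[..., 0, 2], s / 2, atol=1e-10)
        np.testing.assert_allclose(eps.tensor[..., 2, 0], s / 2, atol=1e-10)
        np.testing.assert_allclose(eps.tensor[..., 0, 0], 0.0, atol=1e-10)

    def test_affine_field_gives_symmetrized_matrix(self):
        rng = np.random.default_rng(0)
        A = np.eye(3) + 0.02 * rng.normal(size=(3, 3))
        eps = mech.strain_tensor(affine_grid(A))
        expected = 0.5 * ((A - np.eye(3)) + (A - np.eye(3)).T)
        np.testing.assert_allclose(eps.tensor[2, 2, 2], expected, atol=1e-10)
        sym_err = np.abs(eps.tensor - np.swapaxes(eps.tensor, -1, -2)).max()
        assert sym_err < 1e-12

    def test_anisotropic_voxels_enter_derivatives(self):
        # Dz (px) constant gradient in z-index; physical strain uses um
        shape = (4, 4, 4)
        Z = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")[2]
        g = DeformationGrid(np.zeros(shape), np.zeros(shape), -0.1 * Z,
                            origin=(0, 0, 0), spacing=(16, 16, 10),
                            voxel_size=(0.358, 0.358, 0.5))
        eps = mech.strain_tensor(g)
        # dDz/dz = (-0.1 px per node * 0.5 um/px) / (10 px * 0.5 um/px)
        np.testing.assert_allclose(eps.tensor[..., 2, 2], -0.1 / 10, atol=1e-12)

    def test_too_small_lattice_rejected(self):
        z = np.zeros((2, 4, 4))
        g = DeformationGrid(z, z, z, origin=(0, 0, 0), spacing=(4, 4, 4))
        with pytest.raises(ValueError):
            mech.strain_tensor(g)


class TestStrainMagnitude:
    def test_zero(self):
        eps = mech.StrainGrid(np.zeros((3, 3, 3, 3, 3)), (0, 0, 0), (1, 1, 1),
                              np.ones((3, 3, 3), dtype=bool))
        assert np.all(mech.strain_magnitude(eps) == 0)

    def test_single_component(self):
        t = np.zeros((2, 2, 2, 3, 3))
        t[..., 2, 2] = -0.03
        eps = mech.StrainGrid(t, (0, 0, 0), (1, 1, 1), np.ones((2, 2, 2), bool))
        np.testing.assert_allclose(mech.strain_magnitude(eps), 0.03)

    def test_simple_shear_contraction(self):
        s = 0.04
        t = np.zeros((2, 2, 2, 3, 3))
        t[..., 0, 2] = t[..., 2, 0] = s / 2
        eps = mech.StrainGrid(t, (0, 0, 0), (1, 1, 1), np.ones((2, 2, 2), bool))
        np.testing.assert_allclose(mech.strain_magnitude(eps), s / np.sqrt(2))


def radial_setup(direction="radial"):
    """Deformation lattice around a spherical cell with a prescribed field."""
    shape = (48, 48, 48)
    mask = vs.synthetic_cell_mask(shape, (8, 8, 8))
    step = 4
    n = tuple((s - 1) // step + 1 for s in shape)
    xs = np.arange(0, 48, step)
    X, Y, Z = np.meshgrid(xs, xs, xs, indexing="ij")
    center = np.array([23.5, 23.5, 23.5])
    rvec = np.stack([X - center[0], Y - center[1], Z - center[2]], axis=-1)
    rmag = np.maximum(np.linalg.norm(rvec, axis=-1), 1e-9)
    rhat = rvec / rmag[..., None]
    if direction == "radial":
        D = -0.5 * rhat          # contraction toward the cell
    else:
        tang = np.cross(rhat, [0.0, 0.0, 1.0])
        tn = np.linalg.norm(tang, axis=-1, keepdims=True)
        D = 0.5 * tang / np.maximum(tn, 1e-9)
    grid = DeformationGrid(D[..., 0], D[..., 1], D[..., 2], origin=(0, 0, 0),
                           spacing=(step,) * 3, voxel_size=(1, 1, 1))
    dist = surf_mod.membrane_distance(mask, grid, voxel_size=(1, 1, 1))
    return grid, dist


class TestDecomposition:
    def test_pythagorean_identity(self):
        grid, dist = radial_setup()
        rng = np.random.default_rng(1)
        grid.Dx += rng.normal(0, 0.2, grid.shape)
        grid.Dy += rng.normal(0, 0.2, grid.shape)
        dec = mech.decompose_deformation(grid, dist)
        np.testing.assert_allclose(dec["D"] ** 2, dec["Dn"] ** 2 + dec["Dt"] ** 2,
                                   atol=1e-10)

    def test_parallel_displacement_is_all_normal(self):
        # flat membrane: the nearest-point direction is exact, so a
        # displacement along it has no tangential part at all
        mask = np.zeros((33, 33, 33), dtype=bool)
        mask[:, :, :9] = True  # membrane plane z = 8
        n = (9, 9, 9)
        zeros = np.zeros(n)
        g = DeformationGrid(zeros, zeros, np.full(n, -0.7), origin=(0, 0, 0),
                            spacing=(4, 4, 4), voxel_size=(1, 1, 1))
        dist = surf_mod.membrane_distance(mask, g, voxel_size=(1, 1, 1))
        dec = mech.decompose_deformation(g, dist)
        np.testing.assert_allclose(dec["Dt"], 0.0, atol=1e-10)
        np.testing.assert_allclose(dec["Dn"], 0.7, atol=1e-10)

    def test_perpendicular_displacement_is_all_tangential(self):
        mask = np.zeros((33, 33, 33), dtype=bool)
        mask[:, :, :9] = True
        n = (9, 9, 9)
        zeros = np.zeros(n)
        g = DeformationGrid(np.full(n, 0.7), zeros, zeros, origin=(0, 0, 0),
                            spacing=(4, 4, 4), voxel_size=(1, 1, 1))
        dist = surf_mod.membrane_distance(mask, g, voxel_size=(1, 1, 1))
        dec = mech.decompose_deformation(g, dist)
        np.testing.assert_allclose(dec["Dn"], 0.0, atol=1e-10)
        np.testing.assert_allclose(dec["Dt"], 0.7, atol=1e-10)

    def test_radial_contraction_is_normal_dominant(self):
        grid, dist = radial_setup("radial")
        dec = mech.decompose_deformation(grid, dist)
        far = dec[dec["R"] > 6]  # away from the surface, r_B direction ~ radial
        ratio = far["Dt"] / far["D"]
        # the nearest point is a boundary *voxel*, so the direction wobbles
        # by up to ~half a voxel over |dr|
        assert ratio.quantile(0.95) < 0.15
        assert ratio.max() < 0.3
        assert (far["Dn"] > 0).all()  # motion toward the cell is positive

    def test_tangential_field_has_no_normal_part(self):
        grid, dist = radial_setup("tangential")
        dec = mech.decompose_deformation(grid, dist)
        far = dec[dec["R"] > 6]
        assert (far["Dn"].abs() / far["D"]).quantile(0.95) < 0.2

    def test_inside_nodes_excluded(self):
        grid, dist = radial_setup()
        dec = mech.decompose_deformation(grid, dist)
        assert len(dec) == int((~dist.inside & (dist.R > 0)).sum())


class TestProfileByDistance:
    def test_single_bin(self):
        dec = pd.DataFrame({"R": [1.0, 5.0, 9.0], "D": [1, 1, 1],
                            "Dn": [1, 1, 1], "Dt": [0, 0, 0]})
        prof = mech.profile_by_distance(dec)
        assert len(prof) == 1 and prof["n"][0] == 3

    def test_constant_field_stats(self):
        dec = pd.DataFrame({"R": np.linspace(0, 35, 50), "D": np.ones(50),
                            "Dn": np.ones(50), "Dt": np.zeros(50)})
        prof = mech.profile_by_distance(dec)
        occupied = prof[prof["n"] > 0]
        np.testing.assert_allclose(occupied["mean_D"], 1.0)
        np.testing.assert_allclose(occupied["std_D"], 0.0)

    def test_decaying_field_monotone_bins(self):
        R = np.linspace(2, 60, 200)
        dec = pd.DataFrame({"R": R, "D": 1.0 / R, "Dn": 1.0 / R, "Dt": 0.0 * R})
        prof = mech.profile_by_distance(dec)
        means = prof[prof["n"] > 0]["mean_D"].to_numpy()
        assert np.all(np.diff(means) < 0)

    def test_bin_width_is_10um(self):
        dec = pd.DataFrame({"R": [3.0, 17.0], "D": [1, 2], "Dn": [1, 2],
                            "Dt": [0, 0]})
        prof = mech.profile_by_distance(dec)
        np.testing.assert_allclose(prof["R_bin_center"], [5.0, 15.0])


def constant_strain_grid(t):
    tensor = np.tile(t, (8, 8, 8, 1, 1)).astype(float)
    return mech.StrainGrid(tensor, origin=(0, 0, 0), spacing=(6, 6, 6),
                           mask=np.ones((8, 8, 8), bool))


@pytest.fixture(scope="module")
def sphere_mesh():
    mask = vs.synthetic_cell_mask((40, 40, 40), (10, 10, 10))
    return surf_mod.isosurface(mask, voxel_size=(1, 1, 1))


class TestNormalStrainProjection:
    def test_isotropic(self, sphere_mesh):
        eps = constant_strain_grid(0.02 * np.eye(3))
        enn, ok = mech.normal_strain_projection(eps, sphere_mesh)
        np.testing.assert_allclose(enn, 0.02, atol=1e-9)

    def test_uniaxial_z(self, sphere_mesh):
        t = np.zeros((3, 3))
        t[2, 2] = -0.03
        eps = constant_strain_grid(t)
        enn, _ = mech.normal_strain_projection(eps, sphere_mesh)
        expected = -0.03 * sphere_mesh.face_normals[:, 2] ** 2
        np.testing.assert_allclose(enn, expected, atol=1e-9)

    def test_normal_in_xy_plane_gives_zero(self):
        t = np.zeros((3, 3))
        t[2, 2] = -0.03
        eps = constant_strain_grid(t)
        fake = surf_mod.CellSurface(
            vertices=np.zeros((3, 3)), faces=np.array([[0, 1, 2]]),
            face_normals=np.array([[1.0, 0.0, 0.0]]), face_areas=np.ones(1),
            face_centers=np.array([[10.0, 10.0, 10.0]]),
            center_of_mass=np.zeros(3))
        enn, _ = mech.normal_strain_projection(eps, fake)
        assert enn[0] == pytest.approx(0.0, abs=1e-12)


class TestCauchyStress:
    def test_zero_strain_zero_stress(self):
        eps = constant_strain_grid(np.zeros((3, 3)))
        sig = mech.cauchy_stress(eps, mech.ElasticParams())
        np.testing.assert_allclose(sig.tensor, 0.0)

    def test_lame_parameter(self):
        p = mech.ElasticParams(G=50.0, nu=0.2)
        assert p.lam == pytest.approx(2 * 50 * 0.2 / (1 - 0.4))
        assert p.lam == pytest.approx(33.33, abs=0.01)

    def test_pure_shear_traceless(self):
        s = 0.04
        t = np.zeros((3, 3))
        t[0, 2] = t[2, 0] = s / 2
        sig = mech.cauchy_stress(constant_strain_grid(t), mech.ElasticParams(G=50))
        np.testing.assert_allclose(sig.tensor[..., 0, 2], 50 * s)
        np.testing.assert_allclose(np.einsum("...ii->...", sig.tensor), 0.0,
                                   atol=1e-12)

    def test_trace_identity(self):
        rng = np.random.default_rng(0)
        t = 0.01 * rng.normal(size=(3, 3))
        t = (t + t.T) / 2
        p = mech.ElasticParams(G=50, nu=0.2)
        sig = mech.cauchy_stress(constant_strain_grid(t), p)
        np.testing.assert_allclose(
            np.einsum("...ii->...", sig.tensor),
            (2 * p.G + 3 * p.lam) * np.trace(t), rtol=1e-10,
        )

    def test_large_strain_warns(self):
        t = np.zeros((3, 3))
        t[0, 0] = 0.2
        with pytest.warns(UserWarning, match="5%"):
            mech.cauchy_stress(constant_strain_grid(t), mech.ElasticParams())


class TestTractionAndContractility:
    def test_hydrostatic(self, sphere_mesh):
        p = 7.0
        sig = constant_strain_grid(np.eye(3) * p)
        sig = mech.StrainGrid(sig.tensor, sig.origin, sig.spacing, sig.mask)
        tr = mech.surface_traction(sig, sphere_mesh)
        np.testing.assert_allclose(tr.T, p * sphere_mesh.face_normals, atol=1e-9)
        np.testing.assert_allclose(tr.Tn, p, atol=1e-9)

    def test_zero_stress(self, sphere_mesh):
        sig = constant_strain_grid(np.zeros((3, 3)))
        tr = mech.surface_traction(sig, sphere_mesh)
        np.testing.assert_allclose(tr.T, 0.0)
        assert tr.contractility_nN == pytest.approx(0.0)

    def test_uniaxial_on_sphere_polar_pattern(self, sphere_mesh):
        t = np.zeros((3, 3))
        t[2, 2] = 5.0
        sig = constant_strain_grid(t)
        tr = mech.surface_traction(sig, sphere_mesh)
        np.testing.assert_allclose(tr.Tn, 5.0 * sphere_mesh.face_normals[:, 2] ** 2,
                                   atol=1e-9)

    def test_inward_traction_closed_form(self, sphere_mesh):
        p = 5.0
        T = -p * sphere_mesh.face_normals
        C = mech.contractility_from_vectors(T, sphere_mesh)
        assert C == pytest.approx(p * 4 * np.pi * 100 * 1e-3, rel=0.02)

    def test_uniform_vector_traction_cancels(self, sphere_mesh):
        T = np.tile([0.0, 0.0, 3.0], (len(sphere_mesh.faces), 1))
        C = mech.contractility_from_vectors(T, sphere_mesh)
        assert abs(C) < 0.02 * 3.0 * sphere_mesh.total_area * 1e-3
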