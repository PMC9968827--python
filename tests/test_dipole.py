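import math

import numpy as np
import pytest
import trimesh

from laminareeg.csd import CSDProfile
from laminareeg.dipole import dipole_from_csd, dipole_from_stc, orient_from_mesh
from laminareeg.metrics import rdm
from laminareeg.synthetic import CompartmentCurrentSet


def _profile(z, csd, dt=1.0):
    return CSDProfile(
        z_mm=np.asarray(z, float),
        csd_ua_mm3=np.atleast_2d(np.asarray(csd, float).T).T,
        dt_ms=dt,
        method="standard",
    )


class TestDipoleFromCSD:
    def test_source_at_reference_depth_contributes_nothing(self):
        z = np.linspace(-1, 1, 21)
        csd = np.zeros((21, 1))
        csd[10, 0] = 5.0  # exactly at z_m = 0
        assert dipole_from_csd(_profile(z, csd), z_m_mm=0.0)[0] == 0.0

    def test_even_symmetric_csd_cancels(self):
        z = np.linspace(-1, 1, 41)
        csd = np.exp(-0.5 * (z / 0.3) ** 2)[:, None]
        assert dipole_from_csd(_profile(z, csd), z_m_mm=0.0)[0] == pytest.approx(
            0.0, abs=1e-15
        )

    def test_hand_computed_two_point_example(self):
        # +-1 uA/mm^3 at z_m +- 0.5 mm on a 0.1 mm grid, r_c = 1.5 mm
        z = np.arange(-0.8, 0.8001, 0.1)
        csd = np.zeros((len(z), 1))
        csd[np.argmin(np.abs(z - 0.5)), 0] = 1.0
        csd[np.argmin(np.abs(z + 0.5)), 0] = -1.0
        d = dipole_from_csd(_profile(z, csd), r_c_mm=1.5, z_m_mm=0.0)[0]
        assert d * 1e-9 == pytest.approx(7.069e-10, rel=5e-4)  # A*m, 4 sig figs

    def test_trapezoid_matches_dense_grid_integration(self):
        # smooth synthetic CSD: same analytic profile on the working grid and
        # on a 100x denser grid; trapezoid results must agree within 1%
        f = lambda z: np.sin(2 * np.pi * z / 1.6) * np.exp(-((z - 0.3) ** 2))
        z = np.arange(-0.8, 0.8001, 0.1)
        zf = np.linspace(-0.8, 0.8, 16001)
        d = dipole_from_csd(_profile(z, f(z)[:, None]), r_c_mm=1.5, z_m_mm=0.0)[0]
        df = dipole_from_csd(_profile(zf, f(zf)[:, None]), r_c_mm=1.5, z_m_mm=0.0)[0]
        assert d == pytest.approx(df, rel=0.01)

    def test_linear_in_csd(self, rng):
        z = np.linspace(-0.8, 0.8, 17)
        a = rng.standard_normal((17, 3))
        b = rng.standard_normal((17, 3))
        da = dipole_from_csd(_profile(z, a))
        db = dipole_from_csd(_profile(z, b))
        dab = dipole_from_csd(_profile(z, 2 * a - b))
        np.testing.assert_allclose(dab, 2 * da - db, rtol=1e-10, atol=1e-15)

    def test_short_grid_rejected(self):
        with pytest.raises(ValueError):
            dipole_from_csd(_profile([0.0], [[1.0]]))


def _two_monopole_set():
    return CompartmentCurrentSet(
        coords_mm=np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 1.0]]),
        currents_na=np.array([[1.0], [-1.0]]),
        dt_ms=0.1,
        neuron_index=np.zeros(2, int),
        labels=["L3"],
    )


class TestDipoleFromSTC:
    def test_two_monopole_hand_value(self):
        # +1 nA at origin, -1 nA at (0,0,1) mm -> d = (0,0,-1) nA*mm
        d = dipole_from_stc(_two_monopole_set(), r_m_mm=np.zeros(3))
        np.testing.assert_allclose(d[:, 0], [0.0, 0.0, -1e-3], atol=1e-15)

    def test_invariant_to_expansion_point(self):
        a = dipole_from_stc(_two_monopole_set(), r_m_mm=np.zeros(3))
        b = dipole_from_stc(_two_monopole_set(), r_m_mm=np.array([5.0, 5.0, 5.0]))
        np.testing.assert_allclose(a, b, rtol=0, atol=1e-18)

    def test_population_invariance_with_conserved_currents(self, small_column_currents):
        a = dipole_from_stc(small_column_currents, r_m_mm=np.zeros(3))
        b = dipole_from_stc(small_column_currents, r_m_mm=np.array([10.0, -3.0, 7.0]))
        scale = np.abs(a).max()
        assert np.abs(a - b).max() <= 1e-9 * scale

    def test_zero_currents_zero_moment(self):
        cur = _two_monopole_set()
        cur.currents_na[:] = 0.0
        assert np.all(dipole_from_stc(cur) == 0.0)

    def test_warns_when_not_conserved(self):
        cur = CompartmentCurrentSet(
            coords_mm=np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 1.0]]),
            currents_na=np.array([[1.0], [-0.5]]),
            dt_ms=0.1,
            neuron_index=np.zeros(2, int),
            labels=["L3"],
        )
        with pytest.warns(UserWarning, match="sum to zero"):
            dipole_from_stc(cur)

    def test_on_axis_population_matches_exact_csd_dipole(self, rng):
        # compartments on the column axis; bin their currents into a fine
        # depth grid to form the exact volumetric CSD, then compare Eq-style
        # moment estimates: RDM of the two amplitude traces < 0.1
        n_t = 200
        z_comp = np.array([-1.5, -1.2, -0.9, -0.6, -0.3, 0.0])
        base = np.vstack([
            np.sin(2 * np.pi * np.arange(n_t) / 50 + k) for k in range(5)
        ])
        weights = rng.standard_normal((len(z_comp) - 1, 5))
        I = np.vstack([weights @ base, np.zeros((1, n_t))])
        I[-1] = -I[:-1].sum(axis=0)  # enforce conservation
        coords = np.column_stack([np.zeros_like(z_comp), np.zeros_like(z_comp), z_comp])
        cur = CompartmentCurrentSet(coords, I, 0.1, np.zeros(len(z_comp), int), ["L5"])
        d_stc = dipole_from_stc(cur, r_m_mm=np.zeros(3))[2]

        r_c = 1.5
        grid = np.linspace(-1.6, 0.1, 1701)
        dz = grid[1] - grid[0]
        csd = np.zeros((len(grid), n_t))
        for zc, row in zip(z_comp, I):
            k = np.argmin(np.abs(grid - zc))
            csd[k] += row / (math.pi * r_c**2 * dz)  # nA -> uA/mm^3 * mm^3
        csd *= 1e-3  # nA to uA
        prof = CSDProfile(grid, csd, 0.1, "exact")
        d_csd = dipole_from_csd(prof, r_c_mm=r_c, z_m_mm=-0.75)
        assert rdm(d_stc, d_csd) < 0.1


class TestOrientFromMesh:
    def test_planar_mesh_normal(self):
        verts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], float)
        faces = np.array([[0, 1, 2], [1, 3, 2]])
        mesh = trimesh.Trimesh(verts, faces, process=False)
        n = orient_from_mesh(mesh, np.array([0.5, 0.5, 0.0]))
        np.testing.assert_allclose(n, [0, 0, 1.0], atol=1e-12)

    def test_icosphere_vertex_radial_within_2_degrees(self):
        mesh = trimesh.creation.icosphere(subdivisions=2, radius=10.0)
        v = np.asarray(mesh.vertices[37], float)
        n = orient_from_mesh(mesh, v)
        angle = math.degrees(math.acos(np.clip(n @ (v / np.linalg.norm(v)), -1, 1)))
        assert angle < 2.0

    def test_far_position_rejected(self):
        mesh = trimesh.creation.icosphere(subdivisions=1, radius=1.0)
        with pytest.raises(ValueError):
            orient_from_mesh(mesh, np.array([50.0, 0.0, 0.0]))
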