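"""Incremental-strain kinematics and the element library, verified against
closed-form elasticity and finite-difference tangents."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cytomech import elements as el
from cytomech.geometry import build_icosahedron_tensegrity
from cytomech.materials import MaterialSpec
from cytomech.solver import relax_free_tensegrity

rng = np.random.default_rng(20240811)


class TestStrainIncrement:
    def test_zero_gradient_gives_zero_strain(self):
        inc = el.compute_strain_increment(np.zeros((3, 3)))
        assert np.allclose(inc.dE, 0) and np.allclose(inc.de, 0) and np.allclose(inc.deta, 0)

    def test_uniaxial_stretch_linear_and_quadratic_parts(self):
        eps = 1e-3
        G = np.zeros((3, 3))
        G[0, 0] = eps
        inc = el.compute_strain_increment(G)
        assert inc.de[0, 0] == pytest.approx(eps)
        assert inc.deta[0, 0] == pytest.approx(eps**2 / 2)
        assert inc.dE[0, 0] == pytest.approx(eps + eps**2 / 2)

    def test_rigid_rotation_gives_zero_green_strain_exactly(self):
        # E = (F^T F - I)/2 vanishes for F a rotation; symbolic identity,
        # so the numerical result is zero to machine precision.
        for theta in (1e-3, 0.1, 0.7):
            c, s = np.cos(theta), np.sin(theta)
            R = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
            inc = el.compute_strain_increment(R - np.eye(3))
            assert np.allclose(inc.dE, 0.0, atol=1e-15)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_split_is_exact_and_symmetric(self, seed):
        G = np.random.default_rng(seed).normal(size=(3, 3))
        inc = el.compute_strain_increment(G)
        assert np.allclose(inc.de + inc.deta, inc.dE)
        for M in (inc.de, inc.deta, inc.dE):
            assert np.allclose(M, M.T)

    def test_nonfinite_rejected(self):
        G = np.full((3, 3), np.nan)
        with pytest.raises(el.ElementError):
            el.compute_strain_increment(G)


TET_NODES = np.array(
    [[0.0, 0, 0], [1e-6, 0, 0], [0, 1e-6, 0], [0, 0, 1e-6]]
)
TET_CONN = np.array([[0, 1, 2, 3]])


class TestTetElement:
    def test_zero_displacement_zero_force_and_stress(self):
        gradN, vol = el.tet_precompute(TET_NODES, TET_CONN)
        K, f, sig, J = el.tet_batch(gradN, vol, np.zeros((1, 4, 3)), 1.0, 1.0)
        assert np.allclose(f, 0) and np.allclose(sig, 0) and J[0] == pytest.approx(1.0)

    def test_rigid_translation_zero_force(self):
        gradN, vol = el.tet_precompute(TET_NODES, TET_CONN)
        ue = np.broadcast_to(np.array([3e-6, -1e-6, 2e-6]), (1, 4, 3)).copy()
        _, f, sig, _ = el.tet_batch(gradN, vol, ue, 2.0, 1.5)
        assert np.allclose(f, 0, atol=1e-20) and np.allclose(sig, 0, atol=1e-12)

    def test_uniaxial_small_strain_matches_hooke(self):
        E_mod, nu = 400.0, 0.37
        lam = E_mod * nu / ((1 + nu) * (1 - 2 * nu))
        mu = E_mod / (2 * (1 + nu))
        eps = 1e-8  # small enough that the quadratic term is negligible
        gradN, vol = el.tet_precompute(TET_NODES, TET_CONN)
        ue = np.zeros((1, 4, 3))
        ue[0, :, 0] = eps * TET_NODES[:, 0] / 1e-6 * 1e-6  # u_x = eps * x
        ue[0, :, 0] = eps * TET_NODES[:, 0]
        _, _, sig, _ = el.tet_batch(gradN, vol, ue, lam, mu)
        # uniform strain eps_xx with lateral constraint: sigma from 3-D Hooke
        assert sig[0, 0, 0] == pytest.approx((lam + 2 * mu) * eps, rel=1e-6)
        assert sig[0, 1, 1] == pytest.approx(lam * eps, rel=1e-6)
        assert sig[0, 2, 2] == pytest.approx(lam * eps, rel=1e-6)

    def test_tangent_matches_finite_differences(self):
        gradN, vol = el.tet_precompute(TET_NODES, TET_CONN)
        ue = 1e-7 * rng.normal(size=(1, 4, 3))
        lam, mu = 80.0, 37.0
        K, f0, _, _ = el.tet_batch(gradN, vol, ue, lam, mu)
        h = 1e-12
        K_fd = np.zeros((12, 12))
        for j in range(12):
            du = np.zeros((1, 4, 3))
            du.reshape(-1)[j] = h
            _, f1, _, _ = el.tet_batch(gradN, vol, ue + du, lam, mu, stiffness=False)
            K_fd[:, j] = (f1 - f0).reshape(-1) / h
        assert np.allclose(K[0], K_fd, rtol=1e-4, atol=1e-10 * np.abs(K[0]).max())


TRI_NODES = np.array([[0.0, 0, 0], [2e-6, 0, 0], [0, 1.5e-6, 0]])
TRI_CONN = np.array([[0, 1, 2]])


class TestMembraneElement:
    def setup_method(self):
        self.E, self.nu, self.t = 1000.0, 0.3, 6e-9
        self.lam_bar = self.E * self.nu / (1 - self.nu**2)
        self.mu = self.E / (2 * (1 + self.nu))
        self.pre = el.tri_precompute(TRI_NODES, TRI_CONN)

    def test_equibiaxial_stretch_closed_form(self):
        eps = 1e-8
        ue = (eps * TRI_NODES).reshape(1, 3, 3)
        _, f, sig = el.tri_batch(*self.pre, ue, self.lam_bar, self.mu, self.t)
        expect = self.E * eps / (1 - self.nu)
        assert sig[0, 0, 0] == pytest.approx(expect, rel=1e-6)
        assert sig[0, 1, 1] == pytest.approx(expect, rel=1e-6)
        assert abs(sig[0, 0, 1]) < 1e-12 * expect + 1e-20

    def test_uniaxial_stretch_transverse_ratio_is_nu(self):
        eps = 1e-8
        ue = np.zeros((1, 3, 3))
        ue[0, :, 0] = eps * TRI_NODES[:, 0]  # stretch along x only
        _, _, sig = el.tri_batch(*self.pre, ue, self.lam_bar, self.mu, self.t)
        assert sig[0, 1, 1] / sig[0, 0, 0] == pytest.approx(self.nu, rel=1e-6)

    def test_rigid_rotation_zero_force(self):
        theta = 0.3
        c, s = np.cos(theta), np.sin(theta)
        R = np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])
        ue = (TRI_NODES @ R.T - TRI_NODES).reshape(1, 3, 3)
        _, f, sig = el.tri_batch(*self.pre, ue, self.lam_bar, self.mu, self.t)
        assert np.allclose(f, 0, atol=1e-25)
        assert np.allclose(sig, 0, atol=1e-10)

    def test_zero_area_triangle_rejected(self):
        bad = np.array([[0.0, 0, 0], [1e-6, 0, 0], [2e-6, 0, 0]])
        with pytest.raises(el.ElementError):
            el.tri_precompute(bad, TRI_CONN)

    def test_tangent_matches_finite_differences(self):
        ue = 1e-8 * rng.normal(size=(1, 3, 3))
        K, f0, _ = el.tri_batch(*self.pre, ue, self.lam_bar, self.mu, self.t)
        h = 1e-13
        K_fd = np.zeros((9, 9))
        for j in range(9):
            du = np.zeros((1, 3, 3))
            du.reshape(-1)[j] = h
            _, f1, _ = el.tri_batch(
                *self.pre, ue + du, self.lam_bar, self.mu, self.t, stiffness=False
            )
            K_fd[:, j] = (f1 - f0).reshape(-1) / h
        assert np.allclose(K[0], K_fd, rtol=1e-3, atol=1e-8 * np.abs(K[0]).max())


class TestTrussElement:
    NODES = np.array([[0.0, 0, 0], [10e-6, 0, 0]])
    CONN = np.array([[0, 1]])

    def test_unloaded_bar_zero_force(self):
        L0, dir0 = el.truss_precompute(self.NODES, self.CONN)
        d = (self.NODES[1] - self.NODES[0]).reshape(1, 3)
        _, f, s11 = el.truss_batch(L0, dir0, d, np.array([1e-8]), np.array([1e-16]), 0.0)
        assert np.allclose(f, 0) and s11[0] == 0

    def test_held_fixed_tendon_stress_is_prestress_over_area(self):
        P, A, E = 2e-12, 18e-18, 2.6e9
        L0, dir0 = el.truss_precompute(self.NODES, self.CONN)
        d = (self.NODES[1] - self.NODES[0]).reshape(1, 3)
        _, f, s11 = el.truss_batch(
            L0, dir0, d, np.array([E * A]), np.array([A]), P / (E * A)
        )
        assert s11[0] == pytest.approx(P / A, rel=1e-12)
        # end force magnitude equals the prestress force, along the axis
        assert np.linalg.norm(f[0, 1]) == pytest.approx(P, rel=1e-12)

    def test_zero_length_member_rejected(self):
        with pytest.raises(el.ElementError):
            el.truss_precompute(np.zeros((2, 3)), self.CONN)

    def test_tangent_matches_finite_differences(self):
        L0, dir0 = el.truss_precompute(self.NODES, self.CONN)
        EA, A = np.array([1e-8]), np.array([1e-16])
        u = 1e-7 * rng.normal(size=(2, 3))
        d = (self.NODES[1] + u[1] - self.NODES[0] - u[0]).reshape(1, 3)
        K, f0, _ = el.truss_batch(L0, dir0, d, EA, A, 1e-4)
        h = 1e-12
        K_fd = np.zeros((6, 6))
        for j in range(6):
            du = np.zeros((2, 3))
            du.reshape(-1)[j] = h
            d1 = (self.NODES[1] + u[1] + du[1] - self.NODES[0] - u[0] - du[0]).reshape(1, 3)
            _, f1, _ = el.truss_batch(L0, dir0, d1, EA, A, 1e-4, stiffness=False)
            K_fd[:, j] = (f1 - f0).reshape(-1) / h
        assert np.allclose(K[0], K_fd, rtol=1e-3, atol=1e-7 * np.abs(K[0]).max())


class TestFreeTensegrityEquilibrium:
    def test_self_stress_signs_and_nodal_balance(self):
        """A free prestressed tensegrity relaxes to tendons tensile, bars
        compressive; the nodal force balance is verified independently from
        the relaxed geometry and member forces."""
        graph = build_icosahedron_tensegrity(10e-6)
        mats = MaterialSpec.defaults("stiff")
        X, bar_s11, tendon_s11, residual = relax_free_tensegrity(graph, mats)
        assert np.all(tendon_s11 > 0), "tendons must be tensile"
        assert np.all(bar_s11 < 0), "bars must be compressive"
        P_norm = mats.actin_tendon.prestress_force * np.sqrt(48.0)
        assert residual < 1e-8 * P_norm

        # independent check: sum member forces at every node from scratch
        forces = np.zeros((12, 3))
        members = [
            (graph.bars, bar_s11, mats.microtubule_bar.cross_section_area),
            (graph.tendons, tendon_s11, mats.actin_tendon.cross_section_area),
        ]
        for conn, s11, area in members:
            for (i, j), s in zip(conn, s11):
                axis = X[j] - X[i]
                axis /= np.linalg.norm(axis)
                forces[i] += s * area * axis  # tension pulls i toward j
                forces[j] -= s * area * axis
        assert np.abs(forces).max() < 1e-8 * P_norm

    def test_bar_to_tendon_force_ratio(self):
        """Equal tendon tensions t balance strut compressions of sqrt(6) t in
        the 6-strut tensegrity's equilibrium configuration."""
        graph = build_icosahedron_tensegrity(10e-6)
        mats = MaterialSpec.defaults("stiff")
        _, bar_s11, tendon_s11, _ = relax_free_tensegrity(graph, mats)
        fb = bar_s11.mean() * mats.microtubule_bar.cross_section_area
        ft = tendon_s11.mean() * mats.actin_tendon.cross_section_area
        assert fb / ft == pytest.approx(-np.sqrt(6.0), rel=1e-6)
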