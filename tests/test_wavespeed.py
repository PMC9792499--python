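"""Tests for acoustic-tensor wave speeds, direction maximization and the
critical time step."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from discfem import constitutive as cm
from discfem import wavespeed as ws
from discfem.errors import MaterialInstabilityError

from conftest import random_deformations

RHO = 1000.0


def bundle_at(F, mat, fibers=None):
    st = cm.decompose_kinematics(F)
    return st, cm.elasticity_tensors(st, mat, fibers)


class TestPwaveSpeed:
    def test_isotropic_reference_closed_form(self, np_mat_kpa):
        st, b = bundle_at(np.eye(3), np_mat_kpa)
        expected = np.sqrt((np_mat_kpa.k + 4 * np_mat_kpa.mu0 / 3) / RHO)
        assert expected == pytest.approx(5.5045, abs=1e-3)
        rng = np.random.default_rng(0)
        n = rng.normal(size=(100, 3))
        n /= np.linalg.norm(n, axis=1, keepdims=True)
        v = np.array([ws.pwave_speed(st, b, ni, RHO) for ni in n])
        assert np.allclose(v, expected, rtol=1e-10)

    def test_fiber_stiffened_direction_is_faster(self, af_mat_kpa, fibers30):
        lam = 1.15
        M = fibers30.M1
        U = np.eye(3) + (lam - 1) * np.outer(M, M)
        st, b = bundle_at(U / np.linalg.det(U) ** (1 / 3), af_mat_kpa, fibers30)
        v_fiber = ws.pwave_speed(st, b, M, RHO)
        v_perp = ws.pwave_speed(st, b, np.array([0.0, 0.0, 1.0]), RHO)
        assert v_fiber > v_perp

    def test_nonunit_direction_rejected(self, np_mat_kpa):
        st, b = bundle_at(np.eye(3), np_mat_kpa)
        with pytest.raises(ValueError):
            ws.pwave_speed(st, b, np.array([1.0, 1.0, 0.0]), RHO)


class TestTheoreticalMax:
    def test_isotropic_reference(self, np_mat_kpa):
        st, b = bundle_at(np.eye(3), np_mat_kpa)
        res = ws.max_wave_speed_theoretical(st, b, RHO)
        assert res.method == "theoretical"
        assert res.v_max == pytest.approx(
            np.sqrt((np_mat_kpa.k + 4 * np_mat_kpa.mu0 / 3) / RHO), rel=1e-10)
        assert 0 <= res.phi_star < np.pi and 0 <= res.theta_star < np.pi

    def test_matches_brute_force_grid(self, af_mat_kpa, fibers30):
        """721x721 angular-grid oracle on random annulus states, 0.1% speed."""
        F = random_deformations(5, amplitude=0.25, seed=21)
        st = cm.decompose_kinematics(F)
        fibs = cm.FiberPair(M1=np.broadcast_to(fibers30.M1, (5, 3)),
                            M2=np.broadcast_to(fibers30.M2, (5, 3)))
        b = cm.elasticity_tensors(st, af_mat_kpa, fibs)
        v, _, _, _ = ws.max_speed_theoretical_batch(b.c_spat, b.sigma, st.J, RHO)
        phi = np.linspace(0, np.pi, 721, endpoint=False)
        theta = np.linspace(0, np.pi, 721, endpoint=False)
        P, T = np.meshgrid(phi, theta, indexing="ij")
        dirs = ws._angles_to_dirs(P.ravel(), T.ravel())
        v2 = ws._v2_grid(b.c_spat, b.sigma, st.J, RHO, dirs)
        v_brute = np.sqrt(v2.max(axis=1))
        assert np.all(v >= v_brute * (1 - 1e-12))
        assert np.max(np.abs(v - v_brute) / v_brute) < 1e-3

    def test_bounds_random_directions(self, af_mat_kpa, fibers30):
        F = random_deformations(20, seed=2)
        st = cm.decompose_kinematics(F)
        fibs = cm.FiberPair(M1=np.broadcast_to(fibers30.M1, (20, 3)),
                            M2=np.broadcast_to(fibers30.M2, (20, 3)))
        b = cm.elasticity_tensors(st, af_mat_kpa, fibs)
        v, _, _, _ = ws.max_speed_theoretical_batch(b.c_spat, b.sigma, st.J, RHO)
        rng = np.random.default_rng(4)
        n = rng.normal(size=(10_000, 3))
        n /= np.linalg.norm(n, axis=1, keepdims=True)
        v2 = ws._v2_grid(b.c_spat, b.sigma, st.J, RHO, n)
        assert np.all(v[:, None] ** 2 >= v2 - 1e-9 * v2.max())

    def test_frame_indifference(self, af_mat_kpa, fibers30):
        F = random_deformations(10, seed=6)
        rng = np.random.default_rng(8)
        Q = Rotation.random(10, rng=rng).as_matrix()
        fibs = cm.FiberPair(M1=np.broadcast_to(fibers30.M1, (10, 3)),
                            M2=np.broadcast_to(fibers30.M2, (10, 3)))
        st0 = cm.decompose_kinematics(F)
        b0 = cm.elasticity_tensors(st0, af_mat_kpa, fibs)
        v0, _, _, _ = ws.max_speed_theoretical_batch(b0.c_spat, b0.sigma, st0.J, RHO)
        st1 = cm.decompose_kinematics(Q @ F)
        b1 = cm.elasticity_tensors(st1, af_mat_kpa, fibs)
        v1, _, _, _ = ws.max_speed_theoretical_batch(b1.c_spat, b1.sigma, st1.J, RHO)
        assert np.allclose(v0, v1, rtol=1e-8)


class TestApproxMax:
    def test_direction_set_members(self, fibers30):
        ds = ws.direction_set(fibers30)
        assert ds.directions.shape == (5, 3)
        assert np.allclose(np.linalg.norm(ds.directions, axis=1), 1.0)
        # pairwise distinct
        dots = np.abs(ds.directions @ ds.directions.T - np.eye(5))
        assert np.all(dots[~np.eye(5, dtype=bool)] < 1 - 1e-6)

    def test_degenerate_pair_drops_members(self):
        fp = cm.FiberPair(M1=np.array([1.0, 0, 0]), M2=np.array([1.0, 0, 0]))
        ds = ws.direction_set(fp)
        # M1 - M2 and M1 x M2 vanish
        assert ds.directions.shape[0] == 3

    def test_equals_plain_maximum_over_probes(self, af_mat_kpa, fibers30):
        st, b = bundle_at(np.diag([1.1, 1 / np.sqrt(1.1), 1 / np.sqrt(1.1)]),
                          af_mat_kpa, fibers30)
        res = ws.max_wave_speed_approx(st, b, fibers30, RHO)
        speeds = [ws.pwave_speed(st, b, d, RHO)
                  for d in ws.direction_set(fibers30).directions]
        assert res.v_max == pytest.approx(max(speeds))
        assert res.method == "approx"

    def test_subset_bound_on_random_states(self, af_mat_kpa, fibers30):
        """approx <= theoretical on 10^4 random states; mean ratio < 1.10."""
        F = random_deformations(10_000, amplitude=0.25, seed=13)
        n = len(F)
        st = cm.decompose_kinematics(F)
        fibs = cm.FiberPair(M1=np.broadcast_to(fibers30.M1, (n, 3)),
                            M2=np.broadcast_to(fibers30.M2, (n, 3)))
        b = cm.elasticity_tensors(st, af_mat_kpa, fibs)
        dirs5 = ws.five_direction_matrix(fibs.M1, fibs.M2)
        v_a, _ = ws.max_speed_approx_batch(b.c_spat, b.sigma, st.J, RHO, dirs5)
        v_t, _, _, _ = ws.max_speed_theoretical_batch(
            b.c_spat, b.sigma, st.J, RHO, n_grid=61, refine=2,
            extra_dirs=dirs5)
        ratio = v_t / v_a
        assert np.all(ratio >= 1 - 1e-9)
        assert ratio.mean() < 1.10


class TestIsotropicMax:
    def test_reference_and_dilation_are_direction_independent(self, np_mat_kpa):
        for F in (np.eye(3), 1.2 * np.eye(3)):
            st, b = bundle_at(F, np_mat_kpa)
            res = ws.wave_speed_isotropic_max(st, b, RHO)
            rng = np.random.default_rng(1)
            n = rng.normal(size=(50, 3))
            n /= np.linalg.norm(n, axis=1, keepdims=True)
            v = np.array([ws.pwave_speed(st, b, ni, RHO) for ni in n])
            assert np.allclose(v, res.v_max, rtol=1e-10)

    def test_matches_grid_oracle_on_compressed_states(self, np_mat_kpa):
        """Principal-direction probe within 1% of the dense grid max."""
        F = random_deformations(500, amplitude=0.2, seed=17)
        st = cm.decompose_kinematics(F)
        b = cm.elasticity_tensors(st, np_mat_kpa)
        v_iso = ws.isotropic_max_batch(b.c_spat, b.sigma, st.J, st.C, RHO)
        v_grid, _, _, _ = ws.max_speed_theoretical_batch(
            b.c_spat, b.sigma, st.J, RHO, n_grid=91, refine=2)
        assert np.all(v_grid >= v_iso * (1 - 1e-9))
        assert np.max((v_grid - v_iso) / v_grid) < 0.01


class TestCriticalTimestep:
    def test_arithmetic_examples(self):
        est = ws.critical_timestep(1.0e-3, 5.0, factor=0.9)
        assert est.dt_crit == pytest.approx(1.8e-4)
        assert ws.critical_timestep(2.0, 2.0, factor=1.0).dt_crit == 1.0
        a = ws.critical_timestep(1.0e-3, 5.0)
        assert ws.critical_timestep(0.5e-3, 5.0).dt_crit == pytest.approx(
            a.dt_crit / 2)

    def test_invalid_inputs(self):
        for bad in ((0.0, 1.0, 0.9), (1.0, -1.0, 0.9), (1.0, 1.0, 1.5)):
            with pytest.raises(ValueError):
                ws.critical_timestep(*bad)

    def test_timestep_scales_inversely_with_sqrt_stiffness(self, af_mat_kpa,
                                                           fibers30):
        st = cm.decompose_kinematics(
            np.diag([1.05, 1 / np.sqrt(1.05), 1 / np.sqrt(1.05)]))
        stiff = cm.AFMaterial(c10=4 * af_mat_kpa.c10, c01=4 * af_mat_kpa.c01,
                              a1=4 * af_mat_kpa.a1, a2=af_mat_kpa.a2,
                              k=4 * af_mat_kpa.k)
        b0 = cm.elasticity_tensors(st, af_mat_kpa, fibers30)
        b1 = cm.elasticity_tensors(st, stiff, fibers30)
        v0 = ws.max_wave_speed_approx(st, b0, fibers30, RHO).v_max
        v1 = ws.max_wave_speed_approx(st, b1, fibers30, RHO).v_max
        assert v1 == pytest.approx(2 * v0, rel=1e-10)
        dt0 = ws.critical_timestep(1e-3, v0).dt_crit
        dt1 = ws.critical_timestep(1e-3, v1).dt_crit
        assert dt1 == pytest.approx(dt0 / 2, rel=1e-10)

    def test_rank_one_convexity_loss_raises(self, np_mat_kpa):
        # an artificial state with strongly negative stress triggers a
        # negative acoustic contraction along some direction
        st = cm.decompose_kinematics(np.eye(3))
        b = cm.elasticity_tensors(st, np_mat_kpa)
        b.sigma = -10 * (np_mat_kpa.k + np_mat_kpa.mu0) * np.eye(3)
        with pytest.raises(MaterialInstabilityError):
            ws.pwave_speed(st, b, np.array([1.0, 0, 0]), RHO)
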