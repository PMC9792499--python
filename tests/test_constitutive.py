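"""Unit and property tests for the hyperelastic constitutive models.

Analytic stresses and elasticity tensors are checked against central
finite differences of the strain energy; invariance properties
(objectivity, fiber-swap symmetry, tension-only response) are checked on
random admissible deformations.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_
from scipy.spatial.transform import Rotation

from discfem import constitutive as cm
from discfem.errors import IncompressibilityError, InvalidDeformationError

from conftest import random_deformations

KPA = 1.0e3


# --------------------------------------------------------------------------
# independent oracles
# --------------------------------------------------------------------------

def energy_of_C(C, mat, fibers=None):
    """Strain energy as a plain function of C (independent of the library's
    kinematics path): J = sqrt(det C), distortional invariants from C_bar."""
    J = np.sqrt(np.linalg.det(C))
    Cb = J ** (-2.0 / 3.0) * C
    I1b = np.trace(Cb)
    I2b = 0.5 * (I1b**2 - np.trace(Cb @ Cb))
    if isinstance(mat, cm.NPMaterial):
        return mat.b10 * (I1b - 3) + mat.b01 * (I2b - 3) + mat.k / 2 * (J - 1) ** 2
    psi = mat.c10 * (I1b - 3) + mat.c01 * (I2b - 3) + mat.k / 2 * (J - 1) ** 2
    for M in (fibers.M1, fibers.M2):
        e = max(float(M @ Cb @ M) - 1.0, 0.0)
        psi += mat.a1 / mat.a2 * np.expm1(mat.a2 * e * e)
    return psi


def pk2_fd(C, mat, fibers=None, h=1e-7):
    """Central-difference S = 2 dPsi/dC (symmetric perturbations)."""
    S = np.zeros((3, 3))
    for i in range(3):
        for j in range(i, 3):
            dC = np.zeros((3, 3))
            dC[i, j] += h
            dC[j, i] += h
            d = (energy_of_C(C + dC, mat, fibers)
                 - energy_of_C(C - dC, mat, fibers)) / (2 * h)
            # d = (dPsi/dC_ij + dPsi/dC_ji) = S_ij for i != j, = S_ii
            S[i, j] = S[j, i] = d if i != j else 2 * d / 2
    for i in range(3):
        dC = np.zeros((3, 3))
        dC[i, i] = h
        S[i, i] = 2 * (energy_of_C(C + dC, mat, fibers)
                       - energy_of_C(C - dC, mat, fibers)) / (2 * h)
    return S


def cmat_fd(state, mat, fibers=None, h=1e-7):
    """Central-difference C = 2 dS/dC of the analytic stress."""
    def S_of_C(C):
        w, V = np.linalg.eigh(C)
        F = V @ np.diag(np.sqrt(w)) @ V.T
        return cm.pk2_stress(cm.decompose_kinematics(F), mat, fibers)

    C = state.C
    out = np.zeros((3, 3, 3, 3))
    for k in range(3):
        for l in range(k, 3):
            dC = np.zeros((3, 3))
            dC[k, l] += h
            dC[l, k] += h
            dS = (S_of_C(C + dC) - S_of_C(C - dC)) / (2 * h)
            out[:, :, k, l] = out[:, :, l, k] = dS if k != l else dS
    for k in range(3):
        dC = np.zeros((3, 3))
        dC[k, k] = h
        out[:, :, k, k] = 2 * (S_of_C(C + dC) - S_of_C(C - dC)) / (2 * h)
    return out


# --------------------------------------------------------------------------
# kinematics
# --------------------------------------------------------------------------

class TestKinematics:
    @pytest.mark.parametrize("F,J,C_bar_diag,I1b", [
        (np.eye(3), 1.0, (1, 1, 1), 3.0),
        (2.0 * np.eye(3), 8.0, (1, 1, 1), 3.0),
        (np.diag([2.0, 1.0, 1.0]), 2.0,
         (2 ** (-2 / 3) * 4, 2 ** (-2 / 3), 2 ** (-2 / 3)), 6 * 2 ** (-2 / 3)),
    ])
    def test_examples(self, F, J, C_bar_diag, I1b):
        st = cm.decompose_kinematics(F)
        assert st.J == pytest.approx(J)
        assert np.allclose(np.diag(st.C_bar), C_bar_diag)
        assert st.I1_bar == pytest.approx(I1b)

    def test_distortional_determinant_and_invariant_bounds(self):
        F = random_deformations(200, seed=7)
        st = cm.decompose_kinematics(F)
        assert np.allclose(np.linalg.det(st.C_bar), 1.0, atol=1e-12)
        # AM-GM on the unimodular C_bar
        assert np.all(st.I1_bar >= 3.0 - 1e-12)
        assert np.all(st.I2_bar >= 3.0 - 1e-12)

    def test_negative_determinant_rejected(self):
        with pytest.raises(InvalidDeformationError, match="det"):
            cm.decompose_kinematics(np.diag([-1.0, 1.0, 1.0]))

    def test_macaulay(self):
        assert cm.macaulay(-1.0) == 0.0
        assert cm.macaulay(2.0) == 2.0
        assert cm.macaulay(0.0) == 0.0

    @settings(max_examples=60, derandomize=True)
    @given(st_.floats(min_value=-1e6, max_value=1e6, allow_nan=False))
    def test_macaulay_properties(self, x):
        y = cm.macaulay(x)
        assert y >= 0.0
        assert y == (abs(x) + x) / 2

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st_.lists(st_.floats(min_value=-0.35, max_value=0.35),
                     min_size=9, max_size=9))
    def test_distortional_split_invariants_hypothesis(self, entries):
        """For any admissible F: det(C_bar) = 1 and the distortional
        invariants satisfy the AM-GM lower bound of 3."""
        F = np.eye(3) + np.asarray(entries).reshape(3, 3)
        if np.linalg.det(F) <= 0.05:
            return
        st = cm.decompose_kinematics(F)
        assert np.linalg.det(st.C_bar) == pytest.approx(1.0, abs=1e-12)
        assert st.I1_bar >= 3.0 - 1e-12
        assert st.I2_bar >= 3.0 - 1e-12


# --------------------------------------------------------------------------
# energies
# --------------------------------------------------------------------------

class TestEnergies:
    def test_np_reference_state_is_energy_free(self, np_mat_kpa):
        st = cm.decompose_kinematics(np.eye(3))
        e = cm.energy_np(st, np_mat_kpa)
        assert e.psi_iso == 0 and e.psi_vol == 0 and e.psi_aniso == 0

    def test_np_uniaxial_example(self, np_mat_kpa):
        st = cm.decompose_kinematics(np.diag([2.0, 1.0, 1.0]))
        e = cm.energy_np(st, np_mat_kpa)
        assert e.psi_iso / KPA == pytest.approx(0.1107, abs=2e-4)
        assert e.psi_vol / KPA == pytest.approx(14.95)

    def test_np_simple_shear_example(self, np_mat_kpa):
        F = np.eye(3)
        F[0, 1] = 0.5
        st = cm.decompose_kinematics(F)
        e = cm.energy_np(st, np_mat_kpa)
        assert st.I1_bar == pytest.approx(3.25)
        assert st.I2_bar == pytest.approx(3.25)
        assert e.psi_iso == pytest.approx((0.12 + 0.03) * KPA * 0.25)
        assert e.psi_vol == 0.0

    def test_af_reference_state(self, af_mat_kpa, fibers30):
        st = cm.decompose_kinematics(np.eye(3))
        e = cm.energy_af(st, af_mat_kpa, fibers30)
        assert e.psi_iso == pytest.approx(0.0, abs=1e-12)
        assert e.psi_aniso == 0.0
        assert e.IM1_bar == pytest.approx(1.0)
        assert e.IM2_bar == pytest.approx(1.0)

    def test_af_fiber_stretch_example(self, af_mat_kpa, fibers30):
        lam = 1.2
        F = np.diag([lam, lam ** -0.5, lam ** -0.5])
        st = cm.decompose_kinematics(F)
        e = cm.energy_af(st, af_mat_kpa, fibers30)
        I4 = lam**2 * 0.75 + (1 / lam) * 0.25
        assert e.IM1_bar == pytest.approx(I4)
        assert e.IM2_bar == pytest.approx(I4)
        a1, a2 = af_mat_kpa.a1, af_mat_kpa.a2
        expected = 2 * (a1 / a2) * np.expm1(a2 * (I4 - 1) ** 2)
        assert e.psi_aniso == pytest.approx(expected, rel=1e-12)

    def test_af_contraction_clamps_fiber_energy(self, af_mat_kpa, fibers30):
        lam = 0.9
        st = cm.decompose_kinematics(np.diag([lam, lam ** -0.5, lam ** -0.5]))
        e = cm.energy_af(st, af_mat_kpa, fibers30)
        assert e.IM1_bar < 1 and e.IM2_bar < 1
        assert e.psi_aniso == 0.0

    def test_energy_terms_nonnegative(self, af_mat_kpa, np_mat_kpa, fibers30):
        F = random_deformations(10_000, seed=11)
        st = cm.decompose_kinematics(F)
        for e in (cm.energy_af(st, af_mat_kpa, fibers30),
                  cm.energy_np(st, np_mat_kpa)):
            assert np.all(e.psi_iso >= -1e-9)
            assert np.all(e.psi_vol >= 0)
            assert np.all(e.psi_aniso >= 0)


# --------------------------------------------------------------------------
# stresses and tangents
# --------------------------------------------------------------------------

class TestStress:
    def test_reference_state_stress_free(self, np_mat_kpa, af_mat_kpa, fibers30):
        st = cm.decompose_kinematics(np.eye(3))
        assert np.linalg.norm(cm.pk2_stress(st, np_mat_kpa)) == 0.0
        assert np.linalg.norm(cm.pk2_stress(st, af_mat_kpa, fibers30)) == 0.0

    def test_pure_dilation_closed_form(self, np_mat_kpa):
        st = cm.decompose_kinematics(1.1 * np.eye(3))
        S = cm.pk2_stress(st, np_mat_kpa)
        J = 1.331
        expected = np_mat_kpa.k * (J - 1) * J / 1.21
        assert np.allclose(S, expected * np.eye(3), rtol=1e-12)
        assert expected / KPA == pytest.approx(10.887, abs=1e-3)
        sigma = cm.cauchy_stress(S, st.F)
        assert np.allclose(sigma, np_mat_kpa.k * (J - 1) * np.eye(3))
        assert sigma[0, 0] / KPA == pytest.approx(9.8969, abs=1e-4)
        assert cm.pressure(sigma) / KPA == pytest.approx(-9.8969, abs=1e-4)

    def test_rotation_pushforward(self):
        rng = np.random.default_rng(5)
        Q = Rotation.random(1, rng=rng).as_matrix()[0]
        S = rng.normal(size=(3, 3))
        S = S + S.T
        assert np.allclose(cm.cauchy_stress(S, Q), Q @ S @ Q.T)

    def test_pk2_matches_fd_oracle(self, np_mat_kpa, af_mat_kpa, fibers30,
                                   random_states):
        st = cm.decompose_kinematics(random_states)
        for mat, fb in ((np_mat_kpa, None), (af_mat_kpa, fibers30)):
            S = cm.pk2_stress(st, mat, fb)
            scale = np.abs(S).max()
            for i in range(len(random_states)):
                Sf = pk2_fd(st.C[i], mat, fb)
                assert np.abs(S[i] - Sf).max() / scale < 1e-6

    def test_elasticity_matches_fd_oracle(self, np_mat_kpa, af_mat_kpa,
                                          fibers30, random_states):
        F = random_states[:25]
        st = cm.decompose_kinematics(F)
        for mat, fb in ((np_mat_kpa, None), (af_mat_kpa, fibers30)):
            bundle = cm.elasticity_tensors(st, mat, fb)
            scale = np.abs(bundle.C_mat).max()
            for i in range(len(F)):
                sti = cm.decompose_kinematics(F[i])
                Cf = cmat_fd(sti, mat, fb)
                assert np.abs(bundle.C_mat[i] - Cf).max() / scale < 1e-5

    def test_elasticity_symmetries(self, af_mat_kpa, fibers30, random_states):
        st = cm.decompose_kinematics(random_states[:20])
        b = cm.elasticity_tensors(st, af_mat_kpa, fibers30)
        scale = np.abs(b.C_mat).max()
        for perm in ("...jikl", "...ijlk", "...klij"):
            assert np.abs(b.C_mat - np.einsum(f"...ijkl->{perm}", b.C_mat)
                          ).max() / scale < 1e-8
        assert np.allclose(b.S, np.swapaxes(b.S, -1, -2))
        assert np.allclose(b.sigma, np.swapaxes(b.sigma, -1, -2))

    def test_spatial_tensor_at_identity_equals_material(self, af_mat_kpa, fibers30):
        st = cm.decompose_kinematics(np.eye(3))
        b = cm.elasticity_tensors(st, af_mat_kpa, fibers30)
        assert np.allclose(b.c_spat, b.C_mat)

    def test_np_linearization_is_isotropic_elasticity(self, np_mat_kpa):
        st = cm.decompose_kinematics(np.eye(3))
        b = cm.elasticity_tensors(st, np_mat_kpa)
        mu = np_mat_kpa.mu0
        lam = np_mat_kpa.k - 2 * mu / 3
        eye = np.eye(3)
        iso = (lam * np.einsum("ij,kl->ijkl", eye, eye)
               + mu * (np.einsum("ik,jl->ijkl", eye, eye)
                       + np.einsum("il,jk->ijkl", eye, eye)))
        assert np.allclose(b.c_spat, iso, atol=1e-8 * np_mat_kpa.k)

    def test_np_rejects_fibers_and_af_requires_them(self, np_mat_kpa,
                                                    af_mat_kpa, fibers30):
        st = cm.decompose_kinematics(np.eye(3))
        with pytest.raises(ValueError):
            cm.pk2_stress(st, np_mat_kpa, fibers30)
        with pytest.raises(ValueError):
            cm.pk2_stress(st, af_mat_kpa, None)


# --------------------------------------------------------------------------
# invariance properties
# --------------------------------------------------------------------------

class TestInvariance:
    def test_objectivity_of_energies(self, af_mat_kpa, fibers30):
        rng = np.random.default_rng(3)
        F = random_deformations(1000, seed=3)
        Q = Rotation.random(1000, rng=rng).as_matrix()
        e0 = cm.energy_af(cm.decompose_kinematics(F), af_mat_kpa, fibers30)
        e1 = cm.energy_af(cm.decompose_kinematics(Q @ F), af_mat_kpa, fibers30)
        for name in ("psi_iso", "psi_vol", "psi_aniso"):
            a, b = getattr(e0, name), getattr(e1, name)
            assert np.allclose(a, b, rtol=1e-10, atol=1e-10 * np.abs(a).max())

    def test_fiber_swap_and_reflection_symmetry(self, af_mat_kpa, fibers30):
        F = random_deformations(50, seed=9)
        st = cm.decompose_kinematics(F)
        swapped = cm.FiberPair(M1=fibers30.M2, M2=fibers30.M1)
        e0 = cm.energy_af(st, af_mat_kpa, fibers30)
        e1 = cm.energy_af(st, af_mat_kpa, swapped)
        assert np.allclose(e0.psi_aniso, e1.psi_aniso)
        # reflection about the M1+M2 plane maps the deformation to one with
        # identical energy: reflect F about the e1 (bisector) axis
        R = np.diag([1.0, -1.0, 1.0])
        e2 = cm.energy_af(cm.decompose_kinematics(R @ F @ R), af_mat_kpa, fibers30)
        assert np.allclose(e0.psi_aniso, e2.psi_aniso)
        assert np.allclose(e0.psi_iso, e2.psi_iso)

    def test_tension_only_stress_contribution(self, af_mat_kpa, fibers30):
        # fiber-compressed state: perturbations keep psi_aniso = 0 and the
        # AF stress equals the fiber-free matrix stress
        lam = 0.92
        base = np.diag([lam, lam ** -0.5, lam ** -0.5])
        rng = np.random.default_rng(1)
        for _ in range(20):
            F = base + 0.01 * rng.uniform(-1, 1, (3, 3))
            st = cm.decompose_kinematics(F)
            e = cm.energy_af(st, af_mat_kpa, fibers30)
            if e.IM1_bar >= 1 or e.IM2_bar >= 1:
                continue
            assert e.psi_aniso == 0.0
            S_af = cm.pk2_stress(st, af_mat_kpa, fibers30)
            matrix_only = cm.NPMaterial(b10=af_mat_kpa.c10, b01=af_mat_kpa.c01,
                                        k=af_mat_kpa.k)
            S_matrix = cm.pk2_stress(st, matrix_only)
            assert np.allclose(S_af, S_matrix)


# --------------------------------------------------------------------------
# parameter plumbing
# --------------------------------------------------------------------------

class TestParameters:
    def test_bulk_from_poisson_reproduces_table_values(self):
        assert cm.bulk_from_poisson(0.12, 0.03, 0.495) == pytest.approx(29.9, abs=5e-3)
        assert cm.bulk_from_poisson(0.18, 0.045, 0.45) == pytest.approx(4.35, abs=5e-3)

    def test_bulk_from_poisson_limit_and_error(self):
        mu0 = 2 * (0.2 + 0.1)
        assert cm.bulk_from_poisson(0.2, 0.1, 0.0) == pytest.approx(2 * mu0 / 3)
        with pytest.raises(IncompressibilityError):
            cm.bulk_from_poisson(0.1, 0.1, 0.5)

    def test_presets_load_with_consistent_bulk(self, np_mat, af_mat):
        # the shipped bulk moduli match the Poisson-ratio reconstruction
        assert np_mat.k == pytest.approx(
            cm.bulk_from_poisson(np_mat.b10, np_mat.b01, 0.495), rel=1e-3)
        assert af_mat.k == pytest.approx(
            cm.bulk_from_poisson(af_mat.c10, af_mat.c01, 0.45), rel=1e-3)
        af3 = cm.load_material("af_table3")
        assert af3.a2 == 151.0

    def test_material_validation(self):
        with pytest.raises(ValueError):
            cm.NPMaterial(b10=-1.0, b01=0.0, k=1.0)
        with pytest.raises(ValueError):
            cm.AFMaterial(c10=1.0, c01=0.0, a1=1.0, a2=1.0, k=1.0, phi_deg=95.0)

    def test_fiber_pair_construction(self):
        fp = cm.FiberPair.from_angle(30.0)
        assert fp.M1 @ fp.M2 == pytest.approx(0.5)
        assert not fp.degenerate
        assert cm.FiberPair.from_angle(0.0).degenerate
        with pytest.raises(ValueError):
            cm.FiberPair(M1=np.array([2.0, 0, 0]), M2=np.array([0, 1.0, 0]))
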