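"""Hyperelastic constitutive models for intervertebral disc tissue.

The nucleus pulposus (NP) is a compressible Mooney-Rivlin solid,

    Psi_NP = b10 (I1_bar - 3) + b01 (I2_bar - 3) + k_NP/2 (J - 1)^2,

and the annulus fibrosus (AF) adds two exponential, tension-only collagen
fiber families M1, M2 at +/-phi about the local transverse plane,

    Psi_AF = c10 (I1_bar - 3) + c01 (I2_bar - 3) + k_AF/2 (J - 1)^2
             + sum_i (a1/a2) [exp(a2 <I_Mi_bar - 1>^2) - 1],

with <x> = (|x| + x)/2 the Macaulay bracket and I_Mi_bar = tr(C_bar Mi x Mi)
the distortional squared fiber stretch.  All formulations use the standard
multiplicative distortional/dilatational split F_bar = J^(-1/3) F.

Stresses (second Piola-Kirchhoff S = 2 dPsi/dC, Cauchy sigma = J^-1 F S F^T)
and the material/spatial elasticity tensors are evaluated analytically; a
finite-difference oracle exists only in the test suite.  Every function
broadcasts over leading batch dimensions so that whole meshes can be
evaluated in one call.

Internal unit system is SI (Pa, m, kg, s).  Shipped parameter presets carry
a unit suffix (MPa here; see docs/methods.md) and are converted on load.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Union

import numpy as np

from .errors import IncompressibilityError, InvalidDeformationError

__all__ = [
    "DeformationState",
    "NPMaterial",
    "AFMaterial",
    "FiberPair",
    "EnergyBreakdown",
    "ElasticityBundle",
    "decompose_kinematics",
    "macaulay",
    "energy_np",
    "energy_af",
    "pk2_stress",
    "cauchy_stress",
    "elasticity_tensors",
    "pressure",
    "bulk_from_poisson",
    "load_material",
]

KPA = 1.0e3  # kPa -> Pa
MPA = 1.0e6  # MPa -> Pa


# --------------------------------------------------------------------------
# materials
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class NPMaterial:
    """Nucleus pulposus parameters (SI units: Pa, kg/m^3).

    b10, b01 : Mooney-Rivlin distortional constants.
    k        : bulk modulus.
    rho0     : reference mass density.
    """

    b10: float
    b01: float
    k: float
    rho0: float = 1000.0

    def __post_init__(self):
        if not (self.b10 > 0 and self.b01 >= 0 and self.k > 0 and self.rho0 > 0):
            raise ValueError(
                "NPMaterial requires b10 > 0, b01 >= 0, k > 0, rho0 > 0; got "
                f"b10={self.b10}, b01={self.b01}, k={self.k}, rho0={self.rho0}"
            )

    @property
    def mu0(self) -> float:
        """Reference shear modulus of the linearized model, 2 (b10 + b01)."""
        return 2.0 * (self.b10 + self.b01)


@dataclass(frozen=True)
class AFMaterial:
    """Annulus fibrosus parameters (SI units: Pa, kg/m^3, degrees).

    c10, c01 : Mooney-Rivlin matrix constants.
    a1       : fiber stress scale.
    a2       : dimensionless fiber exponent.
    k        : bulk modulus.
    rho0     : reference mass density.
    phi_deg  : fiber angle about the local transverse plane.
    """

    c10: float
    c01: float
    a1: float
    a2: float
    k: float
    rho0: float = 1000.0
    phi_deg: float = 30.0

    def __post_init__(self):
        ok = (
            self.c10 > 0
            and self.c01 >= 0
            and self.a1 >= 0
            and self.a2 > 0
            and self.k > 0
            and self.rho0 > 0
            and 0.0 < self.phi_deg < 90.0
        )
        if not ok:
            raise ValueError(f"invalid AFMaterial parameters: {self}")

    @property
    def mu0(self) -> float:
        """Reference shear modulus of the fiber-free matrix, 2 (c10 + c01)."""
        return 2.0 * (self.c10 + self.c01)


Material = Union[NPMaterial, AFMaterial]


def load_material(name_or_path: Union[str, Path]) -> Material:
    """Load a material from a TOML preset name or a file path.

    Shipped presets: ``np_table1``, ``af_table1``, ``af_table3``.  Files store
    stress-like constants with a unit suffix (``_mpa`` or ``_kpa``); they are
    converted to Pa here.
    """
    path = Path(name_or_path)
    if path.suffix == ".toml" and path.exists():
        data = tomllib.loads(path.read_text())
    else:
        ref = resources.files("discfem.presets").joinpath(f"{name_or_path}.toml")
        if not ref.is_file():
            raise FileNotFoundError(f"unknown material preset {name_or_path!r}")
        data = tomllib.loads(ref.read_text())
    m = data["material"]
    rho0 = float(m.get("rho0_kg_m3", 1000.0))

    def stress(name):
        if f"{name}_mpa" in m:
            return m[f"{name}_mpa"] * MPA
        if f"{name}_kpa" in m:
            return m[f"{name}_kpa"] * KPA
        raise KeyError(f"material file lacks {name}_mpa / {name}_kpa")

    if m["kind"] == "NP":
        return NPMaterial(b10=stress("b10"), b01=stress("b01"),
                          k=stress("k"), rho0=rho0)
    if m["kind"] == "AF":
        return AFMaterial(c10=stress("c10"), c01=stress("c01"),
                          a1=stress("a1"), a2=m["a2"], k=stress("k"),
                          rho0=rho0, phi_deg=m.get("phi_deg", 30.0))
    raise ValueError(f"unknown material kind {m['kind']!r}")


# --------------------------------------------------------------------------
# kinematics
# --------------------------------------------------------------------------

@dataclass
class DeformationState:
    """Pointwise kinematic quantities derived from a deformation gradient.

    All arrays broadcast over leading batch dimensions: F has shape
    (..., 3, 3) and the scalar invariants shape (...,).
    """

    F: np.ndarray
    J: np.ndarray
    C: np.ndarray
    C_bar: np.ndarray
    F_bar: np.ndarray
    I1_bar: np.ndarray
    I2_bar: np.ndarray


def decompose_kinematics(F: np.ndarray) -> DeformationState:
    """Split a deformation gradient into dilatational and distortional parts.

    Raises :class:`InvalidDeformationError` if det(F) <= 0 anywhere.
    """
    F = np.asarray(F, dtype=float)
    if F.shape[-2:] != (3, 3):
        raise ValueError(f"F must have shape (..., 3, 3), got {F.shape}")
    J = np.linalg.det(F)
    if np.any(J <= 0.0) or not np.all(np.isfinite(J)):
        bad = np.min(J)
        raise InvalidDeformationError(
            f"deformation gradient with non-positive determinant: det(F) = {bad}"
        )
    C = np.swapaxes(F, -1, -2) @ F
    Jm13 = J ** (-1.0 / 3.0)
    F_bar = Jm13[..., None, None] * F
    C_bar = (Jm13**2)[..., None, None] * C
    I1_bar = np.trace(C_bar, axis1=-2, axis2=-1)
    # tr(C_bar^-1) for unimodular C_bar equals the second invariant of C_bar
    I2_bar = 0.5 * (I1_bar**2 - np.trace(C_bar @ C_bar, axis1=-2, axis2=-1))
    return DeformationState(F=F, J=J, C=C, C_bar=C_bar, F_bar=F_bar,
                            I1_bar=I1_bar, I2_bar=I2_bar)


def macaulay(x):
    """Macaulay bracket <x> = (|x| + x)/2 = max(x, 0)."""
    return np.maximum(x, 0.0)


@dataclass(frozen=True)
class FiberPair:
    """Two unit reference fiber directions M1, M2 (broadcastable, (..., 3))."""

    M1: np.ndarray
    M2: np.ndarray

    def __post_init__(self):
        M1 = np.asarray(self.M1, dtype=float)
        M2 = np.asarray(self.M2, dtype=float)
        object.__setattr__(self, "M1", M1)
        object.__setattr__(self, "M2", M2)
        n1 = np.linalg.norm(M1, axis=-1)
        n2 = np.linalg.norm(M2, axis=-1)
        if not (np.allclose(n1, 1.0, atol=1e-8) and np.allclose(n2, 1.0, atol=1e-8)):
            raise ValueError("fiber directions must be unit vectors")

    @classmethod
    def from_angle(cls, phi_deg: float, e1=None, e2=None) -> "FiberPair":
        """Fiber pair at +/-phi in the (e1, e2) plane: Mi = cos(phi) e1 +/- sin(phi) e2."""
        e1 = np.array([1.0, 0.0, 0.0]) if e1 is None else np.asarray(e1, float)
        e2 = np.array([0.0, 1.0, 0.0]) if e2 is None else np.asarray(e2, float)
        phi = np.deg2rad(phi_deg)
        return cls(M1=np.cos(phi) * e1 + np.sin(phi) * e2,
                   M2=np.cos(phi) * e1 - np.sin(phi) * e2)

    @property
    def degenerate(self) -> np.ndarray:
        """True where M1 is (anti)parallel to M2 (e.g. phi = 0)."""
        cross = np.cross(self.M1, self.M2)
        return np.linalg.norm(cross, axis=-1) < 1e-8


# --------------------------------------------------------------------------
# energies
# --------------------------------------------------------------------------

@dataclass
class EnergyBreakdown:
    """Strain energy density split (Pa) plus the fiber invariants."""

    psi_iso: np.ndarray
    psi_vol: np.ndarray
    psi_aniso: np.ndarray
    IM1_bar: np.ndarray
    IM2_bar: np.ndarray

    @property
    def total(self) -> np.ndarray:
        return self.psi_iso + self.psi_vol + self.psi_aniso


def _fiber_invariant(C_bar: np.ndarray, M: np.ndarray) -> np.ndarray:
    return np.einsum("...ij,...i,...j->...", C_bar, M, M)


def _fiber_energy(I4b: np.ndarray, a1: float, a2: float) -> np.ndarray:
    e = macaulay(I4b - 1.0)
    return (a1 / a2) * np.expm1(a2 * e * e)


def energy_np(state: DeformationState, mat: NPMaterial) -> EnergyBreakdown:
    """Strain energy split for the isotropic nucleus pulposus."""
    zeros = np.zeros_like(state.J)
    return EnergyBreakdown(
        psi_iso=mat.b10 * (state.I1_bar - 3.0) + mat.b01 * (state.I2_bar - 3.0),
        psi_vol=0.5 * mat.k * (state.J - 1.0) ** 2,
        psi_aniso=zeros,
        IM1_bar=np.ones_like(state.J),
        IM2_bar=np.ones_like(state.J),
    )


def energy_af(state: DeformationState, mat: AFMaterial,
              fibers: FiberPair) -> EnergyBreakdown:
    """Strain energy split for the fiber-reinforced annulus fibrosus.

    The anisotropic term is tension-only: fiber families with distortional
    invariant I_Mi_bar <= 1 store no energy (Macaulay clamp).
    """
    I41 = _fiber_invariant(state.C_bar, fibers.M1)
    I42 = _fiber_invariant(state.C_bar, fibers.M2)
    return EnergyBreakdown(
        psi_iso=mat.c10 * (state.I1_bar - 3.0) + mat.c01 * (state.I2_bar - 3.0),
        psi_vol=0.5 * mat.k * (state.J - 1.0) ** 2,
        psi_aniso=_fiber_energy(I41, mat.a1, mat.a2)
        + _fiber_energy(I42, mat.a1, mat.a2),
        IM1_bar=I41,
        IM2_bar=I42,
    )


# --------------------------------------------------------------------------
# stress and elasticity tensors (analytic)
# --------------------------------------------------------------------------

def _unpack(mat: Material, fibers):
    """Common (matrix constants, fiber list) view of either material."""
    if isinstance(mat, NPMaterial):
        if fibers is not None:
            raise ValueError("NPMaterial takes no fiber pair")
        return mat.b10, mat.b01, mat.k, []
    if fibers is None:
        raise ValueError("AFMaterial requires a FiberPair")
    return mat.c10, mat.c01, mat.k, [(fibers.M1, mat.a1, mat.a2),
                                     (fibers.M2, mat.a1, mat.a2)]


def _invariant_gradients(state: DeformationState):
    """First derivatives of (J, I1_bar, I2_bar) with respect to C, plus the
    raw ingredients shared with the second derivatives."""
    C, J = state.C, state.J
    Ci = np.linalg.inv(C)
    I1 = np.trace(C, axis1=-2, axis2=-1)
    I2 = 0.5 * (I1**2 - np.trace(C @ C, axis1=-2, axis2=-1))
    Jm23 = J ** (-2.0 / 3.0)
    Jm43 = Jm23**2
    eye = np.broadcast_to(np.eye(3), C.shape)
    s = (..., None, None)
    G1 = Jm23[s] * (eye - (I1 / 3.0)[s] * Ci)
    G2 = Jm43[s] * (I1[s] * eye - C - (2.0 * I2 / 3.0)[s] * Ci)
    return Ci, I1, I2, Jm23, Jm43, eye, G1, G2


def _fiber_response(I4b, a1, a2, tension_at_one: bool = True):
    """psi' and psi'' of the exponential fiber energy w.r.t. I4_bar.

    The stiffness is one-sided at I4_bar = 1; the tension branch (value
    2 a1 per family) is used for I4_bar >= 1, zero below, which upper-bounds
    the wave speed and is conservative for explicit time stepping.
    """
    e = macaulay(I4b - 1.0)
    g = np.exp(a2 * e * e)
    psi1 = 2.0 * a1 * e * g
    branch = I4b >= 1.0 if tension_at_one else I4b > 1.0
    psi2 = np.where(branch, 2.0 * a1 * g * (1.0 + 2.0 * a2 * e * e), 0.0)
    return psi1, psi2


def pk2_stress(state: DeformationState, mat: Material,
               fibers: FiberPair | None = None) -> np.ndarray:
    """Second Piola-Kirchhoff stress S = 2 dPsi/dC (Pa), shape (..., 3, 3)."""
    c10, c01, k, fiber_terms = _unpack(mat, fibers)
    Ci, I1, I2, Jm23, Jm43, eye, G1, G2 = _invariant_gradients(state)
    s = (..., None, None)
    S = 2.0 * (c10 * G1 + c01 * G2)
    for M, a1, a2 in fiber_terms:
        MM = np.einsum("...i,...j->...ij", M, M)
        I4 = np.einsum("...ij,...ij->...", state.C, MM)
        I4b = Jm23 * I4
        psi1, _ = _fiber_response(I4b, a1, a2)
        G4 = Jm23[s] * (MM - (I4 / 3.0)[s] * Ci)
        S = S + 2.0 * psi1[s] * G4
    S = S + (k * (state.J - 1.0) * state.J)[s] * Ci
    return S


def cauchy_stress(S: np.ndarray, F: np.ndarray) -> np.ndarray:
    """Push-forward sigma = J^-1 F S F^T."""
    F = np.asarray(F, float)
    S = np.asarray(S, float)
    J = np.linalg.det(F)
    if np.any(J <= 0):
        raise InvalidDeformationError(f"det(F) = {np.min(J)} must be positive")
    return (F @ S @ np.swapaxes(F, -1, -2)) / J[..., None, None]


@dataclass
class ElasticityBundle:
    """Stress and tangent-stiffness package at one (batch of) material point(s).

    S      : second Piola-Kirchhoff stress, (..., 3, 3), Pa.
    sigma  : Cauchy stress, (..., 3, 3), Pa.
    C_mat  : material elasticity tensor 2 dS/dC, (..., 3, 3, 3, 3), Pa.
    c_spat : spatial elasticity tensor (push-forward of C_mat), Pa.
    """

    S: np.ndarray
    sigma: np.ndarray
    C_mat: np.ndarray
    c_spat: np.ndarray


def _sym_outer(A, B):
    """(A x B)_ijkl = A_ij B_kl."""
    return np.einsum("...ij,...kl->...ijkl", A, B)


def _odot(A):
    """(A . A)_ijkl = (A_ik A_jl + A_il A_jk)/2, i.e. -d(A^-1)/dC for A=C^-1."""
    t1 = np.einsum("...ik,...jl->...ijkl", A, A)
    t2 = np.einsum("...il,...jk->...ijkl", A, A)
    return 0.5 * (t1 + t2)


def elasticity_tensors(state: DeformationState, mat: Material,
                       fibers: FiberPair | None = None) -> ElasticityBundle:
    """Analytic stress plus material and spatial elasticity tensors.

    C_mat = 2 dS/dC is assembled from closed-form second derivatives of the
    distortional invariants; c_spat follows by the push-forward
    c_ijkl = J^-1 F_iP F_jQ F_kR F_lS C_PQRS.
    """
    c10, c01, k, fiber_terms = _unpack(mat, fibers)
    C, J, F = state.C, state.J, state.F
    Ci, I1, I2, Jm23, Jm43, eye, G1, G2 = _invariant_gradients(state)
    s = (..., None, None)
    s4 = (..., None, None, None, None)

    S = 2.0 * (c10 * G1 + c01 * G2)

    CixCi = _sym_outer(Ci, Ci)
    CioCi = _odot(Ci)
    IxCi = _sym_outer(eye, Ci)
    CixI = _sym_outer(Ci, eye)
    Is = _odot(eye)

    H1 = Jm23[s4] * (
        -(IxCi + CixI) / 3.0
        + (I1 / 9.0)[s4] * CixCi
        + (I1 / 3.0)[s4] * CioCi
    )
    Bt = I1[s] * eye - C  # d I2 / dC
    H2 = Jm43[s4] * (
        _sym_outer(eye, eye) - Is
        + (2.0 * I2 / 3.0)[s4] * CioCi
        + (4.0 * I2 / 9.0)[s4] * CixCi
        - (2.0 / 3.0) * (_sym_outer(Bt, Ci) + _sym_outer(Ci, Bt))
    )
    C_mat = 4.0 * (c10 * H1 + c01 * H2)

    for M, a1, a2 in fiber_terms:
        MM = np.einsum("...i,...j->...ij", M, M)
        I4 = np.einsum("...ij,...ij->...", C, MM)
        I4b = Jm23 * I4
        psi1, psi2 = _fiber_response(I4b, a1, a2)
        G4 = Jm23[s] * (MM - (I4 / 3.0)[s] * Ci)
        H4 = Jm23[s4] * (
            -(_sym_outer(MM, Ci) + _sym_outer(Ci, MM)) / 3.0
            + (I4 / 9.0)[s4] * CixCi
            + (I4 / 3.0)[s4] * CioCi
        )
        S = S + 2.0 * psi1[s] * G4
        C_mat = C_mat + 4.0 * (psi2[s4] * _sym_outer(G4, G4) + psi1[s4] * H4)

    p = k * (J - 1.0)
    S = S + (p * J)[s] * Ci
    C_mat = C_mat + (J * (p + J * k))[s4] * CixCi - (2.0 * J * p)[s4] * CioCi

    sigma = cauchy_stress(S, F)
    t = np.einsum("...iP,...PQRS->...iQRS", F, C_mat)
    t = np.einsum("...jQ,...iQRS->...ijRS", F, t)
    t = np.einsum("...kR,...ijRS->...ijkS", F, t)
    c_spat = np.einsum("...lS,...ijkS->...ijkl", F, t) / J[s4]
    return ElasticityBundle(S=S, sigma=sigma, C_mat=C_mat, c_spat=c_spat)


def acoustic_contraction(state: DeformationState, mat: Material,
                         fibers: FiberPair | None, dirs: np.ndarray,
                         S: np.ndarray | None = None) -> np.ndarray:
    """Spatial acoustic contraction (c_ijkl + sigma_ik d_jl) n_i n_j n_k n_l.

    Closed-form fast path for the per-element-per-step wave-speed estimate:
    with the pulled-back direction w = F^T n every term of the material
    elasticity tensor contracts to products of the scalars w.w, w C^-1 w,
    w C w and (M.w)^2, so no rank-four tensor is ever assembled.  Returns
    shape (..., d) in Pa for dirs of shape (..., d, 3); agrees with the
    contraction of :func:`elasticity_tensors` to rounding error.
    """
    c10, c01, k, fiber_terms = _unpack(mat, fibers)
    C, J, F = state.C, state.J, state.F
    if S is None:
        S = pk2_stress(state, mat, fibers)
    Ci = np.linalg.inv(C)
    I1 = np.trace(C, axis1=-2, axis2=-1)
    I2 = 0.5 * (I1**2 - np.trace(C @ C, axis1=-2, axis2=-1))
    Jm23 = J ** (-2.0 / 3.0)
    Jm43 = Jm23**2

    w = np.einsum("...ip,...di->...dp", F, np.asarray(dirs, float))
    wIw = np.einsum("...dp,...dp->...d", w, w)
    wCiw = np.einsum("...pq,...dp,...dq->...d", Ci, w, w)
    wCw = np.einsum("...pq,...dp,...dq->...d", C, w, w)
    wSw = np.einsum("...pq,...dp,...dq->...d", S, w, w)

    e = (..., None)  # broadcast per-element scalars over directions
    # isochoric Mooney-Rivlin matrix terms (second invariant-derivatives of
    # I1_bar and I2_bar contracted with w x w x w x w)
    h1 = Jm23[e] * (-(2.0 / 3.0) * wIw * wCiw
                    + (4.0 * I1 / 9.0)[e] * wCiw**2)
    wBtw = I1[e] * wIw - wCw
    h2 = Jm43[e] * ((10.0 * I2 / 9.0)[e] * wCiw**2
                    - (4.0 / 3.0) * wBtw * wCiw)
    q = 4.0 * (c10 * h1 + c01 * h2)

    for M, a1, a2 in fiber_terms:
        Mw = np.einsum("...p,...dp->...d", M, w)
        wMw = Mw * Mw
        I4 = np.einsum("...ij,...i,...j->...", C, M, M)
        I4b = Jm23 * I4
        psi1, psi2 = _fiber_response(I4b, a1, a2)
        g4 = Jm23[e] * (wMw - (I4 / 3.0)[e] * wCiw)
        h4 = Jm23[e] * (-(2.0 / 3.0) * wMw * wCiw
                        + (4.0 * I4 / 9.0)[e] * wCiw**2)
        q = q + 4.0 * (psi2[e] * g4**2 + psi1[e] * h4)

    p = k * (J - 1.0)
    q = q + (J * (p + J * k))[e] * wCiw**2 - (2.0 * J * p)[e] * wCiw**2
    return (q + wSw) / J[e]


def pressure(sigma: np.ndarray) -> np.ndarray:
    """Mechanical pressure p = -tr(sigma)/3 (compression positive)."""
    return -np.trace(np.asarray(sigma, float), axis1=-2, axis2=-1) / 3.0


def bulk_from_poisson(c10_like: float, c01_like: float, nu: float) -> float:
    """Bulk modulus from Mooney-Rivlin constants and a Poisson ratio.

    Uses the reference shear modulus mu0 = 2 (c10 + c01) and the isotropic
    small-strain relation k = 2 mu0 (1 + nu) / (3 (1 - 2 nu)).
    """
    if not 0.0 <= nu < 0.5:
        raise IncompressibilityError(
            f"Poisson ratio must lie in [0, 0.5), got nu = {nu}"
        )
    mu0 = 2.0 * (c10_like + c01_like)
    return 2.0 * mu0 * (1.0 + nu) / (3.0 * (1.0 - 2.0 * nu))
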