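"""Acoustic-tensor longitudinal wave speeds and the explicit critical time step.

For a plane wave with propagation direction n and polarization m the acoustic
tensor is Q_jl = A_ijkl n_i n_k with A_ijkl = c_ijkl + sigma_ik delta_jl.
Only longitudinal (P-) waves, m = n, are considered here, for which

    v(n) = sqrt( (J / rho0) * (c_ijkl + sigma_ik delta_jl) n_i n_j n_k n_l ).

The maximum over all directions governs the stable time step of explicit
central-difference integration, dt_crit = factor * l_c / v_max.  Two
estimators are provided:

* a theoretical maximizer over the half-sphere (dense angular grid plus a
  derivative-free grid-refinement polish), and
* a cheap five-direction approximation probing the fiber-symmetry axes
  {M1, M2, M1+M2, M1-M2, M1xM2} of the annulus, which exploits that the
  stiff collagen fibers dominate the directional stiffness.

Isotropic (nucleus) elements have no fiber set; for those the maximum is
taken over the three principal directions of C, along which the extreme
longitudinal speeds of an isotropic solid occur.

A non-positive acoustic contraction signals loss of rank-one convexity and
raises :class:`MaterialInstabilityError` instead of returning an imaginary
speed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constitutive import DeformationState, ElasticityBundle, FiberPair
from .errors import MaterialInstabilityError

__all__ = [
    "WaveResult",
    "DirectionSet",
    "TimestepEstimate",
    "pwave_speed",
    "max_wave_speed_theoretical",
    "max_wave_speed_approx",
    "wave_speed_isotropic_max",
    "critical_timestep",
    "direction_set",
]


@dataclass
class WaveResult:
    """Maximum longitudinal wave speed and the direction achieving it."""

    v_max: float
    n_star: np.ndarray
    method: str  # "theoretical" | "approx" | "isotropic"
    phi_star: float | None = None
    theta_star: float | None = None


@dataclass
class DirectionSet:
    """Normalized probe directions built from a fiber pair (Eq.-11-style set)."""

    directions: np.ndarray  # (d, 3), unit rows


@dataclass
class TimestepEstimate:
    """Critical explicit time step dt_crit = factor * l_c / v_max."""

    dt_crit: float
    l_c: float
    v_max: float
    factor: float


# --------------------------------------------------------------------------
# core contraction
# --------------------------------------------------------------------------

def _contraction_batch(c_spat, sigma, dirs):
    """(c_ijkl + sigma_ik d_jl) n_i n_j n_k n_l for dirs (..., d, 3).

    c_spat: (..., 3, 3, 3, 3), sigma: (..., 3, 3).  Returns (..., d).
    """
    nn = np.einsum("...di,...dj->...dij", dirs, dirs)
    q = np.einsum("...ijkl,...dij,...dkl->...d", c_spat, nn, nn)
    q = q + np.einsum("...ik,...dik->...d", sigma, nn)
    return q


def _v2_grid(c_spat, sigma, J, rho0, dirs):
    """Squared speeds over a large shared direction grid via one GEMM.

    c_spat (E, 3,3,3,3) or (3,3,3,3); dirs (D, 3).  Returns (E, D) or (D,).
    """
    D = dirs.shape[0]
    N4 = np.einsum("di,dj,dk,dl->dijkl", dirs, dirs, dirs, dirs).reshape(D, 81)
    c81 = np.asarray(c_spat).reshape(-1, 81)
    q = c81 @ N4.T  # (E, D)
    nn = np.einsum("di,dk->dik", dirs, dirs).reshape(D, 9)
    q = q + np.asarray(sigma).reshape(-1, 9) @ nn.T
    v2 = (np.asarray(J).reshape(-1, 1) / rho0) * q
    if np.ndim(c_spat) == 4:
        return v2[0]
    return v2


def pwave_speed(state: DeformationState, bundle: ElasticityBundle,
                n: np.ndarray, rho0: float) -> np.ndarray:
    """Longitudinal wave speed along unit direction(s) n, in m/s.

    n may be a single (3,) vector or a stack (..., 3) matching the batch
    shape of the state.
    """
    n = np.asarray(n, dtype=float)
    norms = np.linalg.norm(n, axis=-1)
    if not np.allclose(norms, 1.0, atol=1e-8):
        raise ValueError("propagation direction must be a unit vector")
    q = np.einsum("...ijkl,...i,...j,...k,...l->...", bundle.c_spat, n, n, n, n)
    q = q + np.einsum("...ik,...i,...k->...", bundle.sigma, n, n)
    v2 = state.J / rho0 * q
    if np.any(v2 <= 0.0):
        raise MaterialInstabilityError(
            f"loss of rank-one convexity along n = {n}: rho v^2 = {np.min(v2)}",
            direction=n,
        )
    return np.sqrt(v2)


# --------------------------------------------------------------------------
# direction search
# --------------------------------------------------------------------------

def _angles_to_dirs(phi, theta):
    """Spherical parametrization n = (cos phi sin theta, sin phi sin theta, cos theta)."""
    phi = np.asarray(phi, float)
    theta = np.asarray(theta, float)
    st = np.sin(theta)
    return np.stack([np.cos(phi) * st, np.sin(phi) * st, np.cos(theta)], axis=-1)


def _angle_grid(n_grid):
    phi = np.linspace(0.0, np.pi, n_grid, endpoint=False)
    theta = np.linspace(0.0, np.pi, n_grid, endpoint=False)
    P, T = np.meshgrid(phi, theta, indexing="ij")
    return P.ravel(), T.ravel()


def _fold_to_half_sphere(n):
    """Angles (phi, theta) in [0, pi)^2 of directions n, folding antipodes."""
    n = np.asarray(n, float)
    flip = np.arctan2(n[..., 1], n[..., 0]) < 0
    n = np.where(flip[..., None], -n, n)
    theta = np.arccos(np.clip(n[..., 2], -1.0, 1.0))
    phi = np.mod(np.arctan2(n[..., 1], n[..., 0]), np.pi)
    return phi, theta


def max_speed_theoretical_batch(c_spat, sigma, J, rho0, n_grid: int = 181,
                                refine: int = 3, chunk: int = 256,
                                extra_dirs=None):
    """Directionally maximized P-wave speed for a batch of element states.

    Dense (n_grid x n_grid) angular scan over the half-sphere followed by
    `refine` vectorized local grid-refinement passes (window shrinks 8x per
    pass).  `extra_dirs` (E, d, 3) adds per-element candidate directions to
    the scan (e.g. the fiber probe set), which guarantees the result
    dominates any maximum taken over those directions.  Returns
    (v_max (E,), n_star (E, 3), phi (E,), theta (E,)).
    """
    c_spat = np.asarray(c_spat, float).reshape(-1, 3, 3, 3, 3)
    sigma = np.asarray(sigma, float).reshape(-1, 3, 3)
    J = np.asarray(J, float).reshape(-1)
    E = c_spat.shape[0]
    phi_g, theta_g = _angle_grid(n_grid)
    dirs = _angles_to_dirs(phi_g, theta_g)

    best_phi = np.empty(E)
    best_theta = np.empty(E)
    best_v2 = np.empty(E)
    for lo in range(0, E, chunk):
        hi = min(lo + chunk, E)
        v2 = _v2_grid(c_spat[lo:hi], sigma[lo:hi], J[lo:hi], rho0, dirs)
        idx = np.argmax(v2, axis=1)
        best_phi[lo:hi] = phi_g[idx]
        best_theta[lo:hi] = theta_g[idx]
        best_v2[lo:hi] = v2[np.arange(hi - lo), idx]

    if extra_dirs is not None:
        extra_dirs = np.asarray(extra_dirs, float).reshape(E, -1, 3)
        q = _contraction_batch(c_spat, sigma, extra_dirs)
        v2x = (J[:, None] / rho0) * q
        k = np.argmax(v2x, axis=1)
        tk = np.arange(E)
        phi_x, theta_x = _fold_to_half_sphere(extra_dirs[tk, k])
        sel = v2x[tk, k] >= best_v2
        best_phi = np.where(sel, phi_x, best_phi)
        best_theta = np.where(sel, theta_x, best_theta)
        best_v2 = np.maximum(v2x[tk, k], best_v2)

    # local polish: 9x9 windows shrinking around the incumbent
    half = np.pi / n_grid
    n_loc = 9
    off = np.linspace(-1.0, 1.0, n_loc)
    OP, OT = np.meshgrid(off, off, indexing="ij")
    OP, OT = OP.ravel(), OT.ravel()
    for _ in range(refine):
        for lo in range(0, E, chunk):
            hi = min(lo + chunk, E)
            ph = best_phi[lo:hi, None] + half * OP[None, :]
            th = best_theta[lo:hi, None] + half * OT[None, :]
            d = _angles_to_dirs(ph, th)  # (e, m, 3)
            q = _contraction_batch(c_spat[lo:hi], sigma[lo:hi], d)
            v2 = (J[lo:hi, None] / rho0) * q
            idx = np.argmax(v2, axis=1)
            tk = np.arange(hi - lo)
            sel = v2[tk, idx] > best_v2[lo:hi]
            best_phi[lo:hi] = np.where(sel, ph[tk, idx], best_phi[lo:hi])
            best_theta[lo:hi] = np.where(sel, th[tk, idx], best_theta[lo:hi])
            best_v2[lo:hi] = np.maximum(v2[tk, idx], best_v2[lo:hi])
        half /= 8.0

    if np.any(best_v2 <= 0.0):
        raise MaterialInstabilityError(
            "loss of rank-one convexity at the directional maximum"
        )
    n_star = _angles_to_dirs(best_phi, best_theta)
    # fold angles back to the canonical [0, pi) half-sphere
    best_phi = np.mod(best_phi, np.pi)
    best_theta = np.mod(best_theta, np.pi)
    return np.sqrt(best_v2), n_star, best_phi, best_theta


def max_wave_speed_theoretical(state: DeformationState, bundle: ElasticityBundle,
                               rho0: float, n_grid: int = 181,
                               refine: int = 3) -> WaveResult:
    """Global maximum of the longitudinal wave speed over all directions."""
    v, n_star, phi, theta = max_speed_theoretical_batch(
        bundle.c_spat, bundle.sigma, state.J, rho0, n_grid=n_grid, refine=refine
    )
    return WaveResult(v_max=float(v[0]), n_star=n_star[0], method="theoretical",
                      phi_star=float(phi[0]), theta_star=float(theta[0]))


def direction_set(fibers: FiberPair) -> DirectionSet:
    """Probe directions {M1, M2, M1+M2, M1-M2, M1xM2}, normalized to unit
    length; degenerate members (parallel fibers) are dropped."""
    M1 = np.asarray(fibers.M1, float)
    M2 = np.asarray(fibers.M2, float)
    cands = np.stack([M1, M2, M1 + M2, M1 - M2, np.cross(M1, M2)])
    norms = np.linalg.norm(cands, axis=-1)
    keep = norms > 1e-8
    if not np.any(keep):
        raise ValueError("degenerate fiber pair: empty direction set")
    return DirectionSet(directions=cands[keep] / norms[keep, None])


def five_direction_matrix(M1: np.ndarray, M2: np.ndarray) -> np.ndarray:
    """Batched (E, 5, 3) unit probe set for per-element fiber pairs."""
    d = np.stack([M1, M2, M1 + M2, M1 - M2, np.cross(M1, M2)], axis=-2)
    n = np.linalg.norm(d, axis=-1, keepdims=True)
    if np.any(n < 1e-12):
        raise ValueError("degenerate fiber pair in batched direction set")
    return d / n


def max_speed_approx_batch(c_spat, sigma, J, rho0, dirs5):
    """Five-direction wave-speed maximum for a batch; dirs5 (E, 5, 3)."""
    q = _contraction_batch(c_spat, sigma, dirs5)
    v2 = (np.asarray(J)[..., None] / rho0) * q
    if np.any(v2.max(axis=-1) <= 0.0):
        raise MaterialInstabilityError(
            "loss of rank-one convexity along all probe directions"
        )
    idx = np.argmax(v2, axis=-1)
    take = np.take_along_axis(v2, idx[..., None], axis=-1)[..., 0]
    n_star = np.take_along_axis(dirs5, idx[..., None, None], axis=-2)[..., 0, :]
    return np.sqrt(take), n_star


def max_wave_speed_approx(state: DeformationState, bundle: ElasticityBundle,
                          fibers: FiberPair, rho0: float) -> WaveResult:
    """Maximum wave speed over the five fiber-derived probe directions."""
    ds = direction_set(fibers)
    q = _contraction_batch(bundle.c_spat, bundle.sigma, ds.directions)
    v2 = (state.J / rho0) * q
    if np.max(v2) <= 0.0:
        raise MaterialInstabilityError(
            "loss of rank-one convexity along all probe directions"
        )
    i = int(np.argmax(v2))
    return WaveResult(v_max=float(np.sqrt(v2[i])), n_star=ds.directions[i],
                      method="approx")


def wave_speed_isotropic_max(state: DeformationState, bundle: ElasticityBundle,
                             rho0: float) -> WaveResult:
    """Maximum P-wave speed of an isotropic element: probe the principal
    directions of C, where the extrema of the isotropic acoustic tensor lie."""
    _, vecs = np.linalg.eigh(state.C)
    dirs = np.swapaxes(vecs, -1, -2)  # rows are principal directions
    q = _contraction_batch(bundle.c_spat, bundle.sigma, dirs)
    v2 = (state.J / rho0) * q
    if np.max(v2) <= 0.0:
        raise MaterialInstabilityError("loss of rank-one convexity (isotropic)")
    i = int(np.argmax(v2))
    return WaveResult(v_max=float(np.sqrt(v2[i])), n_star=dirs[i],
                      method="isotropic")


def isotropic_max_batch(c_spat, sigma, J, C, rho0):
    """Batched principal-direction maximum for isotropic elements."""
    _, vecs = np.linalg.eigh(C)
    dirs = np.swapaxes(vecs, -1, -2)
    q = _contraction_batch(c_spat, sigma, dirs)
    v2 = (np.asarray(J)[..., None] / rho0) * q
    vmax2 = v2.max(axis=-1)
    if np.any(vmax2 <= 0.0):
        raise MaterialInstabilityError("loss of rank-one convexity (isotropic batch)")
    return np.sqrt(vmax2)


def critical_timestep(l_c, v_max, factor: float = 0.9) -> TimestepEstimate:
    """Critical explicit time step dt_crit = factor * l_c / v_max.

    The default factor 0.9 trades a small efficiency loss for a stability
    buffer below the estimated limit.
    """
    l_c = float(l_c)
    v_max = float(v_max)
    if l_c <= 0 or v_max <= 0 or not 0.0 < factor <= 1.0:
        raise ValueError(
            f"need l_c > 0, v_max > 0, 0 < factor <= 1; got {l_c}, {v_max}, {factor}"
        )
    return TimestepEstimate(dt_crit=factor * l_c / v_max, l_c=l_c,
                            v_max=v_max, factor=factor)
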