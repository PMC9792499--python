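"""Total-Lagrangian explicit quasi-static solver on linear tetrahedra.

Load protocol: a pure moment (default 5 N*m) about an axis through the disc
centroid is ramped with a C2 smoothstep onto the cranial vertebra, both
vertebrae being rigid bodies tied kinematically to the disc's interface node
sets.  The caudal vertebra may only translate in the moment plane (all
rotations locked); the cranial vertebra is free and carries the torque.
Quasi-static response is reached through light mass-proportional damping;
a run is accepted once the moment target is reached and the kinetic energy
falls below a set fraction (default 1%) of the internal energy.

Time integration is central difference with an adaptive, state-dependent
step: every step each element's longitudinal wave speed is estimated (the
five-direction fiber probe for annulus elements, the principal-direction
probe for nucleus elements), and dt = factor * min_e(l_c / v_max) with l_c
the current minimum tet altitude.

An energy ledger (external work vs internal + kinetic + damping-dissipated
energy) is maintained; runs whose ledger residual exceeds 2% are flagged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.spatial.transform import Rotation

from . import constitutive as cm
from .constitutive import AFMaterial, FiberPair, NPMaterial
from .errors import (
    ElementInversionError,
    MaterialInstabilityError,
    QuasiStaticError,
    SimulationInstabilityError,
)
from .geometry import AF, TetMesh, tet_min_altitude
from .wavespeed import five_direction_matrix, max_speed_theoretical_batch

log = logging.getLogger(__name__)

__all__ = [
    "LoadCase",
    "RigidBody",
    "DiscMaterials",
    "SolverControls",
    "SimulationResult",
    "lumped_mass",
    "internal_forces",
    "run_explicit",
    "rom_angle",
]

_AXES = {
    "flexion": np.array([1.0, 0.0, 0.0]),
    "extension": np.array([-1.0, 0.0, 0.0]),
    "lateral_bending": np.array([0.0, 1.0, 0.0]),
    "axial_rotation": np.array([0.0, 0.0, 1.0]),
}


@dataclass(frozen=True)
class LoadCase:
    """A moment load about an axis through the disc centroid.

    The four standard cases rotate about the lateral axis (flexion forward,
    extension backward), the anterior-posterior axis (lateral bending) and
    the cranial-caudal axis (axial rotation).
    """

    name: str
    moment_nm: float = 5.0
    axis: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    ramp_s: float = 0.012
    damping: float = 1000.0  # mass-proportional damping coefficient, 1/s

    def __post_init__(self):
        axis = np.asarray(self.axis, dtype=float)
        n = np.linalg.norm(axis)
        if n == 0 or self.moment_nm <= 0 or self.ramp_s <= 0:
            raise ValueError("load case needs a nonzero axis, moment > 0, ramp > 0")
        object.__setattr__(self, "axis", axis / n)

    @classmethod
    def standard(cls, name: str, moment_nm: float = 5.0, ramp_s: float = 0.012,
                 damping: float = 1000.0) -> "LoadCase":
        if name not in _AXES:
            raise ValueError(f"unknown load case {name!r}; choose from {sorted(_AXES)}")
        return cls(name=name, moment_nm=moment_nm, axis=_AXES[name],
                   ramp_s=ramp_s, damping=damping)


@dataclass(frozen=True)
class DiscMaterials:
    """Material pair for the two disc regions."""

    af: AFMaterial
    nucleus: NPMaterial

    @classmethod
    def table1(cls) -> "DiscMaterials":
        return cls(af=cm.load_material("af_table1"),
                   nucleus=cm.load_material("np_table1"))


@dataclass
class SolverControls:
    """Numerical knobs of the explicit integrator."""

    dt_factor: float = 0.9
    wavespeed_mode: str = "approx"  # "approx" (five-direction) or "theoretical"
    theoretical_grid: int = 61      # angular grid when mode == "theoretical"
    max_steps: int = 2_000_000
    settle_s: float | None = None   # extra time allowed after the ramp (default = ramp)
    ke_tol: float = 0.01            # kinetic/internal energy acceptance ratio
    sample_every: int = 20          # steps between ROM-curve samples
    check_every: int = 10           # steps between stability/termination checks
    blowup_ratio: float = 50.0      # kinetic/internal ratio treated as blow-up


@dataclass
class RigidBody:
    """6-DOF rigid vertebra with kinematically tied interface nodes."""

    ref_point: np.ndarray
    node_idx: np.ndarray
    mass: float
    inertia: np.ndarray  # 3x3, about ref_point, reference orientation
    mode: str = "free"   # "free" | "in_plane"
    plane_normal: np.ndarray | None = None

    u: np.ndarray = field(default_factory=lambda: np.zeros(3))
    R: np.ndarray = field(default_factory=lambda: np.eye(3))
    v: np.ndarray = field(default_factory=lambda: np.zeros(3))
    omega: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def positions(self, X_nodes: np.ndarray) -> np.ndarray:
        return self.ref_point + self.u + (X_nodes - self.ref_point) @ self.R.T

    @property
    def rotation_vector(self) -> np.ndarray:
        return Rotation.from_matrix(self.R).as_rotvec()


# --------------------------------------------------------------------------
# assembly
# --------------------------------------------------------------------------

def lumped_mass(mesh: TetMesh, rho0) -> np.ndarray:
    """Row-sum lumped nodal masses: each node receives V_e/4 of its elements.

    rho0 may be a scalar or a {"AF": ..., "NP": ...} mapping of densities.
    """
    vol = mesh.volumes()
    if np.any(vol <= 0) or rho0 is None:
        raise ValueError("mesh must have positive volumes and a density")
    if isinstance(rho0, dict):
        rho = np.where(mesh.region == AF, rho0["AF"], rho0["NP"])
    else:
        rho = float(rho0)
    me = rho * vol / 4.0
    masses = np.zeros(mesh.n_nodes)
    np.add.at(masses, mesh.tets, me[:, None] if np.ndim(me) else me)
    return masses


class _Assembler:
    """Precomputed reference quantities for fast internal-force assembly."""

    def __init__(self, mesh: TetMesh, materials: DiscMaterials):
        self.mesh = mesh
        self.materials = materials
        X = mesh.nodes[mesh.tets]
        Dm = np.swapaxes(X[:, 1:] - X[:, :1], 1, 2)  # columns are edges
        self.V0 = np.linalg.det(Dm) / 6.0
        if np.any(self.V0 <= 0):
            raise ValueError("mesh contains non-positively oriented tets")
        self.Bm = np.linalg.inv(Dm)
        m = mesh.n_elements
        rows = mesh.tets.ravel()
        cols = np.arange(4 * m)
        self.scatter = sparse.csr_matrix(
            (np.ones(4 * m), (rows, cols)), shape=(mesh.n_nodes, 4 * m)
        )
        self.af = np.flatnonzero(mesh.af_mask)
        self.np_ = np.flatnonzero(mesh.np_mask)
        self.fibers_af = FiberPair(M1=mesh.M1[self.af], M2=mesh.M2[self.af])
        self.dirs5 = five_direction_matrix(mesh.M1[self.af], mesh.M2[self.af])

    def deformation(self, x: np.ndarray, step: int | None = None):
        """Per-element deformation gradients from current positions."""
        xe = x[self.mesh.tets]
        dm = np.swapaxes(xe[:, 1:] - xe[:, :1], 1, 2)
        F = dm @ self.Bm
        J = np.linalg.det(F)
        if np.any(J <= 0.0) or not np.all(np.isfinite(J)):
            with np.errstate(invalid="ignore"):
                bad = int(np.nanargmin(J))
            raise ElementInversionError(
                f"element {bad} inverted (J = {J[bad]:.3e})"
                + (f" at step {step}" if step is not None else ""),
                element=bad,
                step=step,
            )
        return F

    def stresses(self, F: np.ndarray):
        """Per-element second Piola-Kirchhoff stress, ordered like the mesh."""
        S = np.empty_like(F)
        st_af = cm.decompose_kinematics(F[self.af])
        st_np = cm.decompose_kinematics(F[self.np_])
        S[self.af] = cm.pk2_stress(st_af, self.materials.af, self.fibers_af)
        S[self.np_] = cm.pk2_stress(st_np, self.materials.nucleus)
        return S, st_af, st_np

    def nodal_forces(self, S: np.ndarray, F: np.ndarray) -> np.ndarray:
        """Restoring nodal forces (-dE/dx) assembled from element stresses."""
        P = F @ S
        H = -self.V0[:, None, None] * (P @ np.swapaxes(self.Bm, 1, 2))
        ef = np.empty((self.mesh.n_elements, 4, 3))
        ef[:, 1:, :] = np.swapaxes(H, 1, 2)
        ef[:, 0, :] = -ef[:, 1:, :].sum(axis=1)
        return self.scatter @ ef.reshape(-1, 3)

    def strain_energy(self, st_af, st_np) -> float:
        e_af = cm.energy_af(st_af, self.materials.af, self.fibers_af)
        e_np = cm.energy_np(st_np, self.materials.nucleus)
        return float(np.sum(self.V0[self.af] * e_af.total)
                     + np.sum(self.V0[self.np_] * e_np.total))


def internal_forces(mesh: TetMesh, displacements: np.ndarray,
                    materials: DiscMaterials) -> np.ndarray:
    """Nodal internal (restoring) forces for a displacement field, in N."""
    asm = _Assembler(mesh, materials)
    F = asm.deformation(mesh.nodes + np.asarray(displacements, float))
    S, _, _ = asm.stresses(F)
    return asm.nodal_forces(S, F)


def rom_angle(rotation, axis) -> float:
    """Rotation angle (degrees) of a rigid state about the load axis.

    `rotation` may be a rotation vector, a 3x3 matrix, a RigidBody or a
    SimulationResult (cranial body).  The angle is the component of the
    rotation vector along the axis, so rotations about perpendicular axes
    contribute zero.
    """
    if isinstance(rotation, SimulationResult):
        rv = rotation.cranial_rotation_vector
    elif isinstance(rotation, RigidBody):
        rv = rotation.rotation_vector
    else:
        arr = np.asarray(rotation, dtype=float)
        rv = (Rotation.from_matrix(arr).as_rotvec() if arr.shape == (3, 3) else arr)
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    return float(np.degrees(rv @ axis))


# --------------------------------------------------------------------------
# simulation result
# --------------------------------------------------------------------------

@dataclass
class SimulationResult:
    """Outputs of one explicit quasi-static run."""

    load_name: str
    times: np.ndarray
    moments_nm: np.ndarray
    rom_deg: np.ndarray
    dt_history: np.ndarray
    final_positions: np.ndarray
    cranial_rotation_vector: np.ndarray
    F: np.ndarray            # per-element deformation gradient at peak load
    sigma: np.ndarray        # per-element Cauchy stress at peak load (Pa)
    pressure: np.ndarray     # per-element mechanical pressure (Pa)
    psi_iso: np.ndarray      # distortional isotropic energy density (Pa)
    psi_aniso: np.ndarray    # distortional anisotropic energy density (Pa)
    psi_vol: np.ndarray      # dilatational energy density (Pa)
    energy: dict
    n_steps: int
    mesh: TetMesh | None = None
    config: dict = field(default_factory=dict)  # run provenance (load, controls)

    @property
    def rom_curve(self):
        """(moments_nm, rom_deg) time series."""
        return self.moments_nm, self.rom_deg

    @property
    def peak_rom_deg(self) -> float:
        return float(self.rom_deg[-1])

    def rom_at(self, moment_grid) -> np.ndarray:
        """ROM interpolated onto a moment grid (loading branch).

        Uses the strictly increasing ramp samples; the value at the peak
        moment is the settled (post-ramp) rotation, not the instant the ramp
        ends."""
        m, r = self.moments_nm, self.rom_deg
        peak = m.max()
        ramp = m < peak
        xp = np.append(m[ramp], peak)
        fp = np.append(r[ramp], r[-1])
        keep = np.concatenate([[True], np.diff(xp) > 0])
        return np.interp(moment_grid, xp[keep], fp[keep])

    def save(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.attrs["load_name"] = self.load_name
            f.attrs["n_steps"] = self.n_steps
            for k, v in self.energy.items():
                f.attrs[f"energy_{k}"] = v
            for k, v in self.config.items():
                f.attrs[f"config_{k}"] = v
            for name in ("times", "moments_nm", "rom_deg", "dt_history",
                         "final_positions", "cranial_rotation_vector", "F",
                         "sigma", "pressure", "psi_iso", "psi_aniso", "psi_vol"):
                f.create_dataset(name, data=getattr(self, name))
            if self.mesh is not None:
                g = f.create_group("mesh")
                for name in ("nodes", "tets", "region", "cranial_nodes",
                             "caudal_nodes", "M1", "M2", "lc"):
                    arr = getattr(self.mesh, name)
                    if arr is not None:
                        g.create_dataset(name, data=arr)

    @classmethod
    def load(cls, path) -> "SimulationResult":
        import h5py

        with h5py.File(path, "r") as f:
            kwargs = {name: f[name][...] for name in
                      ("times", "moments_nm", "rom_deg", "dt_history",
                       "final_positions", "cranial_rotation_vector", "F",
                       "sigma", "pressure", "psi_iso", "psi_aniso", "psi_vol")}
            energy = {k[len("energy_"):]: float(v) for k, v in f.attrs.items()
                      if k.startswith("energy_")}
            config = {k[len("config_"):]: (v.item() if hasattr(v, "item") else v)
                      for k, v in f.attrs.items() if k.startswith("config_")}
            mesh = None
            if "mesh" in f:
                g = f["mesh"]
                mesh = TetMesh(
                    nodes=g["nodes"][...], tets=g["tets"][...],
                    region=g["region"][...],
                    cranial_nodes=g["cranial_nodes"][...],
                    caudal_nodes=g["caudal_nodes"][...],
                    M1=g["M1"][...] if "M1" in g else None,
                    M2=g["M2"][...] if "M2" in g else None,
                    lc=g["lc"][...] if "lc" in g else None,
                )
            return cls(load_name=str(f.attrs["load_name"]),
                       n_steps=int(f.attrs["n_steps"]), energy=energy,
                       config=config, mesh=mesh, **kwargs)


# --------------------------------------------------------------------------
# the explicit integrator
# --------------------------------------------------------------------------

def _smoothstep(tau):
    """C2 quintic smoothstep on [0, 1]."""
    t = np.clip(tau, 0.0, 1.0)
    return t * t * t * (10.0 + t * (-15.0 + 6.0 * t))


def _make_rigid_body(mesh: TetMesh, node_idx: np.ndarray, nodal_mass: np.ndarray,
                     mode: str, plane_normal, rho0: float) -> RigidBody:
    """Rigid vertebra: tied tissue mass plus a 5 mm bony slab over the disc
    footprint approximates the vertebral inertia without meshing bone."""
    X = mesh.nodes[node_idx]
    ref = X.mean(axis=0)
    height = np.ptp(mesh.nodes[:, 2])
    footprint = np.sum(mesh.volumes()) / max(height, 1e-9)
    slab_mass = rho0 * footprint * 0.005
    m_nodes = nodal_mass[node_idx] + slab_mass / len(node_idx)
    mass = float(np.sum(m_nodes))
    r = X - ref
    r2 = np.einsum("ni,ni->n", r, r)
    inertia = np.einsum("n,nij->ij",
                        m_nodes,
                        r2[:, None, None] * np.eye(3)
                        - np.einsum("ni,nj->nij", r, r))
    inertia += 1e-12 * np.eye(3) * max(mass, 1.0)  # thin-set regularization
    return RigidBody(ref_point=ref, node_idx=node_idx, mass=mass,
                     inertia=inertia, mode=mode, plane_normal=plane_normal)


def run_explicit(mesh: TetMesh, materials: DiscMaterials, load: LoadCase,
                 controls: SolverControls | None = None) -> SimulationResult:
    """Run one quasi-static moment-ramp simulation.

    Raises :class:`SimulationInstabilityError` on energy blow-up or NaN,
    :class:`ElementInversionError` if an element reaches J <= 0, and
    :class:`QuasiStaticError` if the kinetic/internal ratio criterion is not
    met within the allowed settle time.
    """
    controls = controls or SolverControls()
    if mesh.M1 is None or mesh.lc is None:
        raise ValueError("mesh must carry fiber frames and characteristic lengths")
    if len(mesh.cranial_nodes) == 0 or len(mesh.caudal_nodes) == 0:
        raise ValueError("mesh must define cranial and caudal interface node sets")

    asm = _Assembler(mesh, materials)
    rho = {"AF": materials.af.rho0, "NP": materials.nucleus.rho0}
    masses = lumped_mass(mesh, rho)
    rho_af, rho_np = materials.af.rho0, materials.nucleus.rho0

    cranial = _make_rigid_body(mesh, mesh.cranial_nodes, masses, "free",
                               None, rho_af)
    caudal = _make_rigid_body(mesh, mesh.caudal_nodes, masses, "in_plane",
                              load.axis, rho_af)
    tied = np.zeros(mesh.n_nodes, dtype=bool)
    tied[mesh.cranial_nodes] = True
    tied[mesh.caudal_nodes] = True
    free = ~tied
    m_free = masses[free][:, None]
    if np.any(masses[free] <= 0):
        raise ValueError("free node with zero mass")

    x = mesh.nodes.copy()
    v = np.zeros_like(x)
    X_cran = mesh.nodes[mesh.cranial_nodes]
    X_caud = mesh.nodes[mesh.caudal_nodes]
    alpha = load.damping
    settle = controls.settle_s if controls.settle_s is not None else load.ramp_s
    t_end = load.ramp_s + settle
    axis = load.axis

    times, moments, roms, dts = [], [], [], []
    W_ext = 0.0
    E_damp = 0.0
    E_int = 0.0
    E_kin = 0.0
    t = 0.0
    step = 0
    done = False

    def record(mom):
        times.append(t)
        moments.append(mom)
        roms.append(rom_angle(cranial, axis))

    record(0.0)

    def timestep(S, st_af, st_np):
        with np.errstate(over="raise", invalid="raise"):
            if controls.wavespeed_mode == "theoretical":
                b_af = cm.elasticity_tensors(st_af, materials.af, asm.fibers_af)
                v_af, _, _, _ = max_speed_theoretical_batch(
                    b_af.c_spat, b_af.sigma, st_af.J, rho_af,
                    n_grid=controls.theoretical_grid, refine=2,
                    extra_dirs=asm.dirs5)
            else:
                q_af = cm.acoustic_contraction(
                    st_af, materials.af, asm.fibers_af, asm.dirs5,
                    S=S[asm.af])
                v2_af = (st_af.J[:, None] / rho_af) * q_af
                v2_af = v2_af.max(axis=1)
                if np.any(v2_af <= 0):
                    raise MaterialInstabilityError(
                        "loss of rank-one convexity in an AF element")
                v_af = np.sqrt(v2_af)
            # nucleus: principal directions of C carry the isotropic extrema
            _, vecs = np.linalg.eigh(st_np.C)
            q_np = cm.acoustic_contraction(
                st_np, materials.nucleus, None, np.swapaxes(vecs, -1, -2),
                S=S[asm.np_])
            v2_np = (st_np.J[:, None] / rho_np) * q_np
            v2_np = v2_np.max(axis=1)
            if np.any(v2_np <= 0):
                raise MaterialInstabilityError(
                    "loss of rank-one convexity in an NP element")
            v_np = np.sqrt(v2_np)
        lc = tet_min_altitude(x, mesh.tets)
        ratios = np.concatenate([lc[asm.af] / v_af, lc[asm.np_] / v_np])
        return controls.dt_factor * float(np.min(ratios))

    while True:
        if step >= controls.max_steps:
            raise QuasiStaticError(
                f"quasi-static criterion unmet within {controls.max_steps} steps"
            )
        try:
            F = asm.deformation(x, step=step)
            S, st_af, st_np = asm.stresses(F)
            dt = timestep(S, st_af, st_np)
        except (FloatingPointError, OverflowError) as exc:
            raise SimulationInstabilityError(
                f"numerical overflow at step {step}, t = {t:.6f} s "
                f"(energy blow-up): {exc}"
            ) from exc
        f = np.asarray(asm.nodal_forces(S, F))

        tau_mag = load.moment_nm * _smoothstep(t / load.ramp_s)
        torque = tau_mag * axis

        c = 0.5 * alpha * dt
        a_free = f[free] / m_free
        v[free] = ((1.0 - c) * v[free] + dt * a_free) / (1.0 + c)
        E_damp += float(alpha * np.sum(masses[free] * np.einsum(
            "ni,ni->n", v[free], v[free]))) * dt
        x[free] += dt * v[free]

        for body, ext_torque in ((cranial, torque), (caudal, None)):
            idx = body.node_idx
            F_net = f[idx].sum(axis=0)
            r = x[idx] - (body.ref_point + body.u)
            T_net = np.cross(r, f[idx]).sum(axis=0)
            if ext_torque is not None:
                T_net = T_net + ext_torque
            if body.mode == "in_plane":
                nrm = body.plane_normal
                F_net = F_net - (F_net @ nrm) * nrm
                body.v = ((1.0 - c) * body.v + dt * F_net / body.mass) / (1.0 + c)
                body.v = body.v - (body.v @ nrm) * nrm
                body.omega[:] = 0.0
            else:
                body.v = ((1.0 - c) * body.v + dt * F_net / body.mass) / (1.0 + c)
                Iw = body.R @ body.inertia @ body.R.T
                gyro = np.cross(body.omega, Iw @ body.omega)
                dom = np.linalg.solve(Iw, T_net - gyro)
                body.omega = ((1.0 - c) * body.omega + dt * dom) / (1.0 + c)
            E_damp += alpha * (body.mass * body.v @ body.v
                               + body.omega @ (body.R @ body.inertia @ body.R.T)
                               @ body.omega) * dt
            body.u = body.u + dt * body.v
            if body.mode != "in_plane":
                dR = Rotation.from_rotvec(body.omega * dt).as_matrix()
                body.R = dR @ body.R

        W_ext += float(torque @ cranial.omega) * dt
        x[mesh.cranial_nodes] = cranial.positions(X_cran)
        x[mesh.caudal_nodes] = caudal.positions(X_caud)

        t += dt
        step += 1

        if step % controls.sample_every == 0:
            record(tau_mag)
            dts.append(dt)

        if step % controls.check_every == 0 or t >= t_end:
            if not np.all(np.isfinite(x)):
                raise SimulationInstabilityError(
                    f"NaN/Inf positions at step {step}, t = {t:.6f} s"
                )
            E_int = asm.strain_energy(st_af, st_np)
            E_kin = 0.5 * float(np.sum(masses[free] * np.einsum(
                "ni,ni->n", v[free], v[free])))
            for body in (cranial, caudal):
                Iw = body.R @ body.inertia @ body.R.T
                E_kin += 0.5 * (body.mass * body.v @ body.v
                                + body.omega @ Iw @ body.omega)
            scale = max(E_int, 1e-12)
            if E_kin > controls.blowup_ratio * scale and E_kin > 1e-6:
                raise SimulationInstabilityError(
                    f"kinetic energy blow-up at step {step}: "
                    f"E_kin = {E_kin:.3e} J vs E_int = {E_int:.3e} J"
                )
            log.debug("step %d t=%.4fs dt=%.3es M=%.3f ROM=%.3f "
                      "E_int=%.3e E_kin=%.3e", step, t, dt, tau_mag,
                      roms[-1], E_int, E_kin)
            if t >= load.ramp_s and E_kin < controls.ke_tol * scale:
                done = True
            if t >= t_end and not done:
                raise QuasiStaticError(
                    f"kinetic/internal ratio {E_kin / scale:.3f} still above "
                    f"{controls.ke_tol} at t = {t:.4f} s"
                )
        if done:
            break

    record(load.moment_nm * _smoothstep(t / load.ramp_s))
    dts.append(dt)
    log.info("%s: %d steps, ROM %.3f deg, KE/E_int %.2e",
             load.name, step, roms[-1], E_kin / max(E_int, 1e-12))

    # peak-load element fields
    F = asm.deformation(x)
    S, st_af, st_np = asm.stresses(F)
    sigma = cm.cauchy_stress(S, F)
    m = mesh.n_elements
    psi_iso = np.empty(m)
    psi_aniso = np.empty(m)
    psi_vol = np.empty(m)
    e_af = cm.energy_af(st_af, materials.af, asm.fibers_af)
    e_np = cm.energy_np(st_np, materials.nucleus)
    psi_iso[asm.af], psi_iso[asm.np_] = e_af.psi_iso, e_np.psi_iso
    psi_aniso[asm.af], psi_aniso[asm.np_] = e_af.psi_aniso, e_np.psi_aniso
    psi_vol[asm.af], psi_vol[asm.np_] = e_af.psi_vol, e_np.psi_vol

    residual = abs(W_ext - (E_int + E_kin + E_damp)) / max(W_ext, 1e-12)
    energy = dict(W_ext=W_ext, E_int=E_int, E_kin=E_kin, E_damp=E_damp,
                  residual_fraction=residual)
    if residual > 0.02:
        log.warning("energy ledger residual %.1f%% exceeds 2%%", 100 * residual)

    return SimulationResult(
        load_name=load.name,
        times=np.asarray(times),
        moments_nm=np.asarray(moments),
        rom_deg=np.asarray(roms),
        dt_history=np.asarray(dts),
        final_positions=x,
        cranial_rotation_vector=cranial.rotation_vector,
        F=F,
        sigma=sigma,
        pressure=cm.pressure(sigma),
        psi_iso=psi_iso,
        psi_aniso=psi_aniso,
        psi_vol=psi_vol,
        energy=energy,
        n_steps=step,
        mesh=mesh,
        config=dict(load=load.name, moment_nm=load.moment_nm,
                    ramp_s=load.ramp_s, damping=load.damping,
                    dt_factor=controls.dt_factor,
                    wavespeed_mode=controls.wavespeed_mode,
                    ke_tol=controls.ke_tol),
    )
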