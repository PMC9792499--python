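"""Inverse-FEM estimation of annulus parameters from moment-rotation curves.

The mismatch between an experimental range-of-motion curve Theta_exp and the
simulated curve Theta_sim(p) is scored per load case by

    O(p) = (1/n) * sum_i [ (Theta_exp_i - Theta_sim_i(p)) / Theta_exp_n ]^2,

with n load increments and Theta_exp_n the experimental rotation at the
final (largest) increment; multiple load cases are aggregated by an
unweighted mean.  The objective is invariant under a uniform rescaling of
both curves, so discs of different absolute compliance are scored alike.

Minimization is bound-constrained gradient-based (SLSQP with forward-
difference gradients) over a scaled parameter space; the stiff exponent a2
is optimized in log-space.  A forward simulation that fails at a trial point
contributes a large penalty instead of aborting the search.

Because the cadaveric reference dataset is external, the module ships a
synthetic-experiment generator: forward-simulated curves at known parameters
(optionally noised) that support parameter-recovery studies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize

from .constitutive import AFMaterial, NPMaterial
from .errors import CalibrationError, DiscfemError
from .geometry import TetMesh
from .solver import DiscMaterials, LoadCase, SolverControls, run_explicit

log = logging.getLogger(__name__)

__all__ = [
    "CalibrationProblem",
    "CalibrationResult",
    "objective",
    "objective_from_curves",
    "calibrate",
    "synthesize_experiment",
    "simulate_rom_curves",
]

_FREE_CHOICES = ("c10", "c01", "a1", "a2", "k")
_LOG_SCALE = {"a2"}  # stiff exponential sensitivity


@dataclass
class CalibrationProblem:
    """Specification of one inverse-FEM run.

    curves        : {case name: (moments_nm, rom_deg)} experimental data;
                    each curve needs n >= 2 increments and a nonzero final
                    rotation (it normalizes the objective).
    mesh          : disc mesh used for the forward simulations.
    nucleus       : fixed NP material.
    base_af       : AF material supplying the fixed parameters.
    free          : names of the AF parameters being optimized.
    bounds        : {name: (lo, hi)}; defaults to (0.2x, 5x) of the base
                    value, (0.5x, 2x) for a2.
    load_kwargs   : forwarded to LoadCase.standard (ramp, damping, moment).
    controls      : solver controls for the forward runs.
    """

    curves: dict
    mesh: TetMesh
    nucleus: NPMaterial
    base_af: AFMaterial
    free: tuple = ("c10", "a1", "a2")
    bounds: dict = field(default_factory=dict)
    load_kwargs: dict = field(default_factory=dict)
    controls: SolverControls = field(default_factory=SolverControls)

    def __post_init__(self):
        if not self.curves:
            raise CalibrationError("no experimental curves given")
        for case, (mom, rom) in self.curves.items():
            mom = np.asarray(mom, float)
            if mom.size < 2:
                raise CalibrationError(f"{case}: need at least 2 load increments")
            if rom is not None:
                # rom = None leaves a grid-only placeholder, to be filled by
                # synthesize_experiment before calibration
                rom = np.asarray(rom, float)
                if rom[-1] == 0.0:
                    raise CalibrationError(
                        f"{case}: final experimental rotation is zero (objective "
                        "normalizer Theta_exp_n would vanish)")
            self.curves[case] = (mom, rom)
        for name in self.free:
            if name not in _FREE_CHOICES:
                raise CalibrationError(f"unknown free parameter {name!r}")
        for name in self.free:
            if name not in self.bounds:
                base = getattr(self.base_af, name)
                lohi = (0.5 * base, 2.0 * base) if name in _LOG_SCALE \
                    else (0.2 * base, 5.0 * base)
                self.bounds[name] = lohi
        for name, (lo, hi) in self.bounds.items():
            if not 0 < lo < hi:
                raise CalibrationError(f"bounds for {name} must be 0 < lo < hi")

    def af_material(self, p: dict) -> AFMaterial:
        return replace(self.base_af, **p)


@dataclass
class CalibrationResult:
    """Optimal parameters and convergence diagnostics."""

    p_opt: dict
    objective_value: float
    history: list            # (iteration, objective) pairs, accepted iterates
    curves_sim: dict         # {case: (moments_nm, rom_deg)} at p_opt
    converged: bool
    message: str
    n_evaluations: int


def objective_from_curves(theta_exp: np.ndarray, theta_sim: np.ndarray) -> float:
    """Single-case objective: mean squared rotation mismatch normalized by the
    experimental rotation at the final increment."""
    theta_exp = np.asarray(theta_exp, float)
    theta_sim = np.asarray(theta_sim, float)
    norm = theta_exp[-1]
    if norm == 0.0:
        raise CalibrationError("zero objective normalizer Theta_exp_n")
    return float(np.mean(((theta_exp - theta_sim) / norm) ** 2))


def simulate_rom_curves(mesh: TetMesh, af: AFMaterial, nucleus: NPMaterial,
                        cases, moment_grids: dict, load_kwargs=None,
                        controls=None) -> dict:
    """Forward-simulate ROM at the given moment grids for each load case."""
    load_kwargs = dict(load_kwargs or {})
    controls = controls or SolverControls()
    mats = DiscMaterials(af=af, nucleus=nucleus)
    out = {}
    for case in cases:
        grid = np.asarray(moment_grids[case], float)
        load = LoadCase.standard(case, moment_nm=float(grid[-1]), **load_kwargs)
        res = run_explicit(mesh, mats, load, controls)
        out[case] = (grid, res.rom_at(grid))
    return out


def objective(p: dict, problem: CalibrationProblem) -> float:
    """Multi-case objective at a parameter dict (runs forward simulations)."""
    af = problem.af_material(p)
    sims = simulate_rom_curves(
        problem.mesh, af, problem.nucleus, problem.curves.keys(),
        {c: m for c, (m, _) in problem.curves.items()},
        load_kwargs=problem.load_kwargs, controls=problem.controls)
    vals = [objective_from_curves(rom_exp, sims[case][1])
            for case, (_, rom_exp) in problem.curves.items()]
    return float(np.mean(vals))


def _encode(p: dict, problem) -> np.ndarray:
    return np.array([np.log(p[n]) if n in _LOG_SCALE else p[n]
                     for n in problem.free])


def _decode(x: np.ndarray, problem) -> dict:
    return {n: float(np.exp(v)) if n in _LOG_SCALE else float(v)
            for n, v in zip(problem.free, x)}


def calibrate(problem: CalibrationProblem, p0: dict | None = None,
              maxiter: int = 40, fd_step: float = 0.005,
              penalty: float = 1.0e3, method: str = "L-BFGS-B",
              max_evaluations: int | None = None) -> CalibrationResult:
    """Bound-constrained gradient-based fit of the free AF parameters.

    p0 defaults to the base material's values.  Gradients are forward
    differences with relative step fd_step; the forward model is made
    deterministic and smooth by the solver's dense ROM sampling, so modest
    steps work.  method is any bound-constrained scipy minimizer
    ("L-BFGS-B" default — it traverses the correlated (a1, a2) valley in
    far fewer function evaluations than SLSQP, which is also available).
    Deterministic for a fixed problem and controls.
    """
    p0 = dict(p0 or {n: getattr(problem.base_af, n) for n in problem.free})
    for n in problem.free:
        lo, hi = problem.bounds[n]
        if not lo <= p0[n] <= hi:
            raise CalibrationError(f"initial {n} = {p0[n]} outside bounds {lo, hi}")

    x0 = _encode(p0, problem)
    bounds = []
    for n in problem.free:
        lo, hi = problem.bounds[n]
        bounds.append((np.log(lo), np.log(hi)) if n in _LOG_SCALE else (lo, hi))
    # scale linear parameters to O(1) so one FD step suits all coordinates
    scale = np.array([1.0 if n in _LOG_SCALE else max(abs(x), 1e-12)
                      for n, x in zip(problem.free, x0)])
    n_eval = 0
    best = {"x": x0.copy(), "f": np.inf}
    history = []

    def fun(z):
        nonlocal n_eval
        n_eval += 1
        p = _decode(z * scale, problem)
        try:
            val = objective(p, problem)
        except DiscfemError as exc:
            log.warning("penalized failed forward run at %s: %s", p, exc)
            return penalty
        if val < best["f"]:
            best["f"], best["x"] = val, (z * scale).copy()
            history.append((n_eval, val))
        return val

    options = {"maxiter": maxiter, "eps": fd_step, "ftol": 1e-10}
    if method == "L-BFGS-B":
        options["gtol"] = 1e-10
        if max_evaluations is not None:
            options["maxfun"] = max_evaluations
    res = minimize(
        fun, x0 / scale, method=method,
        bounds=[(lo / s, hi / s) for (lo, hi), s in zip(bounds, scale)],
        options=options,
    )
    x_best = best["x"] if best["f"] <= res.fun else res.x * scale
    p_opt = _decode(x_best, problem)
    f_best = min(best["f"], float(res.fun))

    af = problem.af_material(p_opt)
    curves_sim = simulate_rom_curves(
        problem.mesh, af, problem.nucleus, problem.curves.keys(),
        {c: m for c, (m, _) in problem.curves.items()},
        load_kwargs=problem.load_kwargs, controls=problem.controls)
    return CalibrationResult(
        p_opt=p_opt, objective_value=f_best, history=history,
        curves_sim=curves_sim, converged=bool(res.success),
        message=str(res.message), n_evaluations=n_eval)


def synthesize_experiment(p_true: dict, problem: CalibrationProblem,
                          noise_sd: float = 0.0, seed: int = 0) -> dict:
    """Forward-simulated ROM curves at known parameters, optionally noised.

    A synthetic stand-in for cadaveric range-of-motion measurements: returns
    {case: (moments_nm, rom_deg)} on the problem's moment grids, with
    additive Gaussian noise of standard deviation `noise_sd` degrees drawn
    from a seeded generator.
    """
    af = problem.af_material(p_true)
    curves = simulate_rom_curves(
        problem.mesh, af, problem.nucleus, problem.curves.keys(),
        {c: m for c, (m, _) in problem.curves.items()},
        load_kwargs=problem.load_kwargs, controls=problem.controls)
    if noise_sd > 0.0:
        rng = np.random.default_rng(seed)
        curves = {c: (m, r + rng.normal(0.0, noise_sd, size=r.shape))
                  for c, (m, r) in curves.items()}
    return curves
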