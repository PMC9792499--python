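"""Field statistics and wave-speed audits of simulation results.

Per-element peak-load fields (pressure, isotropic and anisotropic energy
densities) are summarized as normalized histograms and exact empirical
cumulative distribution functions (ECDF); two runs are compared by the
maximum vertical ECDF distance (the two-sample Kolmogorov-Smirnov statistic,
reported in percent).

The wave-speed audit recomputes, for every annulus element at peak load, the
direction-maximized longitudinal wave speed (dense angular search) and the
five-direction approximation, reporting the elementwise ratio and the
angular separation between the two propagation directions (directions are
axes: antipodes are identified via |dot|).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import constitutive as cm
from .errors import DiscfemError
from .solver import DiscMaterials, SimulationResult
from .wavespeed import five_direction_matrix, max_speed_approx_batch, max_speed_theoretical_batch

__all__ = [
    "FieldSummary",
    "WaveAudit",
    "summarize_field",
    "ecdf_max_difference",
    "wavespeed_audit",
    "rom_report",
]

_FIELDS = {"pressure", "psi_iso", "psi_aniso"}


@dataclass
class FieldSummary:
    """Sample, normalized histogram and ECDF of one per-element field."""

    variable: str
    values: np.ndarray
    bin_edges: np.ndarray
    probabilities: np.ndarray  # sums to 1

    def ecdf(self, x) -> np.ndarray:
        """Exact right-continuous ECDF evaluated at x."""
        xs = np.sort(self.values)
        return np.searchsorted(xs, np.asarray(x), side="right") / xs.size


def summarize_field(result: SimulationResult, variable: str,
                    bins="fd", region: str | None = None,
                    bin_edges=None) -> FieldSummary:
    """Histogram + ECDF summary of a peak-load field.

    `bins` follows numpy's histogram conventions (default Freedman-Diaconis);
    pass explicit `bin_edges` to share bins between two runs.  `region`
    optionally restricts to "AF" or "NP" elements.
    """
    if variable not in _FIELDS:
        raise ValueError(f"variable must be one of {sorted(_FIELDS)}")
    values = np.asarray(getattr(result, variable), dtype=float)
    if region is not None:
        if result.mesh is None:
            raise ValueError("region selection requires the mesh in the result")
        mask = result.mesh.af_mask if region == "AF" else result.mesh.np_mask
        values = values[mask]
    if values.size == 0:
        raise DiscfemError("empty element selection")
    if bin_edges is not None:
        counts, edges = np.histogram(values, bins=bin_edges)
    else:
        if np.ptp(values) == 0:
            edges = np.array([values[0] - 0.5, values[0] + 0.5])
            counts = np.array([values.size])
        else:
            counts, edges = np.histogram(values, bins=bins)
    return FieldSummary(variable=variable, values=values, bin_edges=edges,
                        probabilities=counts / values.size)


def ecdf_max_difference(a: FieldSummary, b: FieldSummary) -> float:
    """Maximum vertical ECDF distance between two summaries, in percent."""
    if a.variable != b.variable:
        raise ValueError(f"cannot compare {a.variable} with {b.variable}")
    grid = np.concatenate([a.values, b.values])
    return float(np.max(np.abs(a.ecdf(grid) - b.ecdf(grid)))) * 100.0


@dataclass
class WaveAudit:
    """Elementwise theoretical-vs-approximated wave-speed comparison."""

    ratio: np.ndarray        # v_theoretical / v_approx per AF element
    angle_deg: np.ndarray    # angular separation of the two directions
    v_theoretical: np.ndarray
    v_approx: np.ndarray
    mean_ratio: float
    sd_ratio: float
    mean_angle_deg: float
    sd_angle_deg: float

    @property
    def n(self) -> int:
        return self.ratio.size

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "ratio": self.ratio,
            "angle_deg": self.angle_deg,
            "v_theoretical": self.v_theoretical,
            "v_approx": self.v_approx,
        })


def wavespeed_audit(result: SimulationResult, materials: DiscMaterials,
                    n_grid: int = 181, refine: int = 3) -> WaveAudit:
    """Audit the five-direction wave-speed approximation at peak load.

    For every annulus element the longitudinal speed is maximized over a
    dense angular grid (with local refinement) and compared against the
    maximum over the fiber probe set; the per-element speed ratio and the
    angle between the two maximizing directions are pooled into mean/SD
    summaries.
    """
    mesh = result.mesh
    if mesh is None:
        raise ValueError("wavespeed_audit requires the mesh in the result")
    af = np.flatnonzero(mesh.af_mask)
    F = result.F[af]
    state = cm.decompose_kinematics(F)
    fibers = cm.FiberPair(M1=mesh.M1[af], M2=mesh.M2[af])
    bundle = cm.elasticity_tensors(state, materials.af, fibers)
    rho0 = materials.af.rho0

    dirs5 = five_direction_matrix(mesh.M1[af], mesh.M2[af])
    # the probe set seeds the dense search so that the theoretical maximum
    # dominates the approximation exactly, not just to grid accuracy
    v_theo, n_theo, _, _ = max_speed_theoretical_batch(
        bundle.c_spat, bundle.sigma, state.J, rho0, n_grid=n_grid,
        refine=refine, extra_dirs=dirs5)
    v_appr, n_appr = max_speed_approx_batch(
        bundle.c_spat, bundle.sigma, state.J, rho0, dirs5)

    ratio = v_theo / v_appr
    cosang = np.clip(np.abs(np.einsum("ei,ei->e", n_theo, n_appr)), 0.0, 1.0)
    angle = np.degrees(np.arccos(cosang))
    return WaveAudit(
        ratio=ratio,
        angle_deg=angle,
        v_theoretical=v_theo,
        v_approx=v_appr,
        mean_ratio=float(ratio.mean()),
        sd_ratio=float(ratio.std(ddof=1)) if ratio.size > 1 else 0.0,
        mean_angle_deg=float(angle.mean()),
        sd_angle_deg=float(angle.std(ddof=1)) if angle.size > 1 else 0.0,
    )


def rom_report(results, reference: dict | None = None,
               moment_grid=None) -> pd.DataFrame:
    """Tabulate moment-rotation outcomes for a set of runs.

    `reference` optionally maps load-case name -> (moments_nm, rom_deg)
    curves; simulated curves are linearly interpolated onto the reference
    moment grid (endpoints preserved) and the peak relative difference is
    reported.
    """
    rows = []
    for res in results:
        row = {"case": res.load_name,
               "peak_moment_nm": float(res.moments_nm[-1]),
               "peak_rom_deg": res.peak_rom_deg}
        if reference is not None:
            if res.load_name not in reference:
                raise ValueError(f"no reference curve for load case {res.load_name!r}")
            mom_ref, rom_ref = (np.asarray(a, float) for a in reference[res.load_name])
            grid = np.asarray(moment_grid, float) if moment_grid is not None else mom_ref
            sim = res.rom_at(grid)
            ref = np.interp(grid, mom_ref, rom_ref)
            row["peak_rom_ref_deg"] = float(ref[-1])
            row["peak_rel_diff"] = float((sim[-1] - ref[-1]) / ref[-1])
        rows.append(row)
    return pd.DataFrame(rows)
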