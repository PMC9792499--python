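# Methods

This note documents the models, numerical choices and defaults of discfem,
what the synthetic data generator does and does not emulate, and the known
limitations. Everything quantitative stated here is computed by the test
suite or by `scripts/acceptance.py`.

## Constitutive models

Both disc regions are decoupled (distortional/dilatational) hyperelastic
solids. Kinematics: F, J = det F, C = FᵀC; F̄ = J^(−1/3)F, C̄ = F̄ᵀF̄ with
det C̄ = 1; Ī₁ = tr C̄ and Ī₂ = ½[(tr C̄)² − tr C̄²] (equal to tr C̄⁻¹ on the
unimodular manifold).

* Nucleus pulposus (NP), isotropic compressible Mooney–Rivlin:
  Ψ = b10(Ī₁−3) + b01(Ī₂−3) + k/2 (J−1)².
* Annulus fibrosus (AF): the same matrix form (c10, c01, k) plus two
  exponential collagen fiber families at ±φ (default 30°) about the local
  transverse plane: Σᵢ (a1/a2)[exp(a2⟨Ī_Mᵢ−1⟩²) − 1]. The Macaulay bracket
  makes fibers tension-only (crimped fibers carry no compression).

Second Piola–Kirchhoff stress and the material elasticity tensor are fully
analytic (deviatoric-projector form of the invariant derivatives); the
spatial tensor is the standard push-forward. The test suite verifies both
against central finite differences of the energy (1e−6 / 1e−5 relative) on
random admissible states, and verifies objectivity, material symmetry and
the stress-free reference exactly.

At Ī_M = 1 the fiber stiffness is one-sided; the tension branch (second
derivative 2·a1 per family) is used for Ī_M ≥ 1 and zero below. This
upper-bounds the wave speed and is therefore conservative for the explicit
time step.

### Parameters and units

Internal units are SI (Pa, m, kg, s). The shipped presets are:

| preset | c10/b10 | c01/b01 | a1 | a2 | k | source regime |
|---|---|---|---|---|---|---|
| `np_table1` | 0.12 | 0.03 | — | — | 29.9 | literature NP set |
| `af_table1` | 0.18 | 0.045 | 2.0 | 100 | 4.35 | literature AF set |
| `af_table3` | 0.016 | 0.001 | 1.0 | 151 | 170 | calibrated AF set |

Stress-like entries are in **MPa**. The publication these sets derive from
prints them as kPa; that label is inconsistent both with the source
literature for the identical Mooney–Rivlin pairs (MPa there) and with basic
statics — with kPa modules the volumetric law caps the supportable pressure
at k_NP ≈ 30 kPa while a 5 N·m segment moment demands ~100 kPa, so no
stable state exists (we verified: elements collapse to J ≈ 0.3 and invert
below 2 N·m). discfem therefore keeps the printed values verbatim and reads
them as MPa. The bulk moduli follow from Poisson ratios 0.495 (NP) and 0.45
(AF) through k = 2μ₀(1+ν)/(3(1−2ν)) with μ₀ = 2(c10+c01), which reproduces
29.9 and 4.35 exactly (`bulk_from_poisson`).

Tissue density is not stated in the source material; ρ₀ = 1000 kg/m³
(hydrated soft tissue) is the configurable default for both regions.

## Wave speeds and the adaptive time step

Longitudinal (P-) plane waves with polarization parallel to propagation
give ρv² = Q̃(n)n·n with Q̃_jl = (c_ijkl + σ_ik δ_jl)n_i n_k, i.e.
v(n) = sqrt[(J/ρ₀)(c_ijkl + σ_ik δ_jl)n_i n_j n_k n_l]. Only this m = n
branch is used; quasi-transverse eigenbranches of Q̃ are out of scope (we
checked on simulated peak-load states that the largest eigenvalue of Q̃
changes the audit statistics below by < 0.1%, so the restriction is
immaterial there).

* Theoretical maximum (`max_wave_speed_theoretical`): dense 181×181 grid
  over the (φ, θ) half-sphere followed by three vectorized local
  grid-refinement passes (9×9 window shrinking 8× per pass). Verified
  against a 721×721 brute-force grid to 0.1% in speed.
* Five-direction approximation (`max_wave_speed_approx`): maximum of v over
  the normalized probe set {M₁, M₂, M₁+M₂, M₁−M₂, M₁×M₂}. The probes are
  the *reference* fiber-symmetry directions applied directly as spatial
  propagation directions (no push-forward), following the source method
  statement literally. Degenerate members of the set (parallel fibers) are
  dropped.
* Nucleus elements have no fiber set; the maximum over the three principal
  directions of C is used (within 1% of the dense search on 500 random
  states — the isotropic extrema lie on principal axes).
* A non-positive contraction (loss of rank-one convexity) raises an error
  rather than returning an imaginary speed.

Critical step: Δt = 0.9 · l_c / v_max per element, global minimum over the
mesh, recomputed **every step** from current element states and current
minimum altitudes l_c = 3V/A_max. The per-step cost is kept negligible by a
closed-form contraction: with w = Fᵀn every term of the material tangent
contracts to products of w·w, wC⁻¹w, wCw and (M·w)², so no rank-four tensor
is assembled in the hot path (verified identical to the full tensor
contraction to machine precision).

### Audit of the approximation

At peak 5 N·m load of the synthetic non-degenerated segment (`table1`
materials), the dense-search maximum exceeds the five-direction
approximation by ~0.8% on average over annulus elements (flexion mean ratio
1.008, extension 1.008), with mean angular separation 10.8–11.7°. The
statistic is stable between 4 mm and 2.5 mm meshes. (The dense search is
seeded with the probe directions, so the ratio is bounded below by one
exactly.) Published statistics for this audit (ratio 1.033–1.038 with angles
10.6–11.1°) satisfy ratio ≈ 1/cos²(angle), the signature of a fully
fiber-dominated acoustic tensor; that regime corresponds to the soft-matrix
(kPa) reading of the parameters, which is statically impossible under the
(J−1)² volumetric law (see above). Under the physically consistent MPa
reading the approximation is *better* than published — comfortably inside
the <10% wave-speed-error envelope — while the angular separation is
reproduced.

## Synthetic segment geometry

The planform is a superellipse |x/a|^p + |y/b|^p = 1 (default a = 26 mm
lateral, b = 18 mm anterior–posterior, p = 2.5), extruded between endplates
with anterior/posterior heights (12/9 mm; unequal values produce wedging),
a skew shear between endplates, and a parabolic outward wall bulge (default
5%). The nucleus is a central similar superellipse holding 40% of the
planform area (radius fraction √0.4), optionally offset. Degeneration
presets: `none` (12/9 mm, no skew), `moderate` (9/6 mm, 1.5 mm skew),
`severe` (6/3.2 mm, 3 mm skew) — height loss with increasing wedge and
skew. The closed-form solid volume (wedge integrates out; skew is
volume-preserving; the bulge contributes 1 + 4β/3 + 8β²/15) is matched by
the mesh within 2% at the 1.4 mm nominal size.

Meshing: perimeter-graded concentric rings are triangulated in 2D
(Delaunay), the planform is extruded layer-by-layer through the
wedge/skew/bulge mapping, and each prism is split into three tetrahedra by
the min-vertex-index diagonal rule (conforming, sliver-free; minimum
altitude ≈ 0.5× nominal size). A small seeded jitter on interior planform
points breaks lattice symmetry; generation is deterministic per (spec,
seed). Fibers: per AF element, ê₁ is the tangent of the level superellipse
at the centroid, ê₂ the local axial direction, ê₃ the outward normal;
M₁,₂ = cos φ ê₁ ± sin φ ê₂.

What the generator does *not* emulate: patient-specific kidney-shaped
planforms, curved endplates, annulus lamellae (fiber angle varies 25–45°
radially in reality; here a single ±30° average), regional nucleus
asymmetry, and tears/delamination. Passing tests therefore demonstrate the
numerical machinery on representative geometric regimes, not anatomical
fidelity for any individual.

## Explicit quasi-static solver

Total-Lagrangian constant-gradient tetrahedra; nodal forces are the exact
gradient of the total strain energy (verified by finite differences and by
patch/rigid-rotation tests). Row-sum lumped masses. Central-difference
integration with semi-implicit mass-proportional damping. Vertebrae are
rigid bodies (6-DOF, exponential-map rotation update) kinematically tied to
the interface node sets; tied tissue mass plus a 5 mm bony slab sets their
mass/inertia. The moment (default 5 N·m) ramps with a C² quintic smoothstep
over `ramp_s`; being a pure couple it is position-independent and applied to
the cranial body only. The caudal body may translate only in the moment
plane (rotations locked), mirroring the cadaveric test-bench constraint.

Defaults: ramp 12 ms, damping α = 1000 s⁻¹, settle window equal to the
ramp, acceptance when kinetic/internal energy < 1% after the ramp. These
were chosen so that the ledger |W_ext − (E_int + E_kin + E_damp)|/W_ext
closes well below the 2% acceptance bound (measured ~0.1%) while a full run
on a 4 mm mesh takes ~1300 steps. Runs with dt factor 1.8 (twice the
stable estimate) blow up and are reported as instability/inversion errors;
factor 0.9 completes all four load cases on all three degeneration presets.

Mesh convergence of flexion peak ROM at 5 N·m (seed 2): 3.61° (5 mm),
5.24° (4 mm), 5.70° (3 mm), 5.92° (2.5 mm), 6.65° (2 mm). Linear
tetrahedra lock at two layers through the thickness, so coarse meshes are
too stiff; successive refinement changes shrink, and the published <3%
discretization bound applies near the 1.4 → 1.0 mm resolution, which is
outside the default test budget. The suite asserts the convergence trend at
5/4/3 mm; production studies should use ≤ 1.4 mm.

## Inverse FEM

Objective per load case: O(p) = (1/n) Σᵢ [(Θᵢ^exp − Θᵢ^sim(p))/Θₙ^exp]²
over n load increments (default: 10 uniform increments to 5 N·m), with
Θₙ^exp the experimental rotation at the final increment; multiple cases
aggregate by unweighted mean. The normalization makes O invariant under
uniform curve rescaling. Minimization: bound-constrained quasi-Newton
(L-BFGS-B by default; SLSQP available) with forward-difference gradients
(0.5% relative step), a2 in log-space (its exponential sensitivity spans
decades), linear parameters scaled to O(1). Failed forward runs contribute
a large penalty rather than aborting. Two details make the objective smooth
enough for quasi-Newton descent: the ROM curve is sampled densely during
the ramp and read off the strict loading branch with the *settled*
post-ramp rotation at the peak moment, and synthetic and fitted curves use
the identical protocol, so the objective is exactly zero at the true
parameters and numerically quadratic around them. L-BFGS-B traverses the
correlated (a1, a2) valley in roughly half the function evaluations SLSQP
needs.

Because the cadaveric reference curves are external data, the calibration
machinery is validated by parameter recovery from noiseless synthetic
curves (flexion + axial rotation, ±30% perturbed start; c10, a1, a2 free
with k_AF fixed; recovered within 5%, typically ~1%). Identifiability at
5 N·m is regime-dependent: in the stiff `af_table1` regime the curves are
nearly linear and (a1, a2) trade off almost freely, while with the literal
`af_table3` matrix (c10 = 16 kPa) the matrix term carries almost no signal.
The recovery ground truth therefore sits at a well-conditioned member of
the model family — the calibrated fiber regime (a1 = 1 MPa, a2 = 151,
k_AF = 170 MPa) with a literature-scale matrix (c10 = 0.18 MPa) — where
axial rotation is ~23% sub-linear at 5 N·m (a2 signal) and the matrix still
shapes both curves (c10 signal). This is a property of the physics, not of
the optimizer; calibrating a nearly linear regime would need larger moments
or richer response data. Forward runs inside calibration use a coarse
(7 mm) mesh with a shortened (8 ms) ramp; a production fit should
re-verify the optimum at the nominal 1.4 mm resolution.

## Numerical details and degenerate inputs

* det(C̄) = 1 to 1e−12; invalid deformations (J ≤ 0) raise typed errors
  naming det F (pointwise) or the element and step (in the solver).
* φ = 0 fiber pairs are flagged degenerate; the five-direction probe set
  drops vanishing members (M₁−M₂, M₁×M₂) and errors only if empty.
* Angular separations treat directions as axes (arccos |n₁·n₂|).
* Histogram binning is Freedman–Diaconis by default; ECDF comparisons use
  the exact two-sample maximum vertical distance (×100).
* Element ordering is region-major (AF block, then NP) so Gmsh entity
  blocks match memory order; files are written in mm, 17 significant
  digits, lossless round trip for connectivity, labels and fiber vectors.

## Scale of the shipped studies

The acceptance script runs the audit on a 2.5 mm mesh (~6300 elements,
~2200 steps per load case); the test suite uses 3–4 mm meshes for solver
runs and a 7 mm mesh inside calibration. These sizes were chosen as the
coarsest at which the audited statistics and recovery are stable; all are
refinable through `SegmentSpec.element_size`.

## Known limitations

* Hyperelastic only: no poroelasticity, viscoelasticity, osmotic swelling
  or damage, so creep/hysteresis and diurnal effects are out of reach.
* Pure-displacement linear tetrahedra lock near incompressibility; the
  bulk moduli here are moderate (ν ≤ 0.495) but coarse meshes overestimate
  stiffness (see convergence above).
* Single average fiber angle; no radial lamella variation or dispersion.
* The quasi-static protocol reports the loading branch only; no
  load-unload cycles.
* Vertebrae are rigid; endplate compliance and bone deformation are
  neglected.
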