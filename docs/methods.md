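# Methods

## Flow model and assumptions

CSF is modelled as an incompressible Newtonian fluid (ρ = 1000 kg/m³,
μ = 7.0·10⁻⁴ Pa·s, hence ν = 0.7 mm²/s) in a rigid domain. Rigid walls plus
incompressibility mean the instantaneous boundary fluxes must balance
exactly; the package enforces this algebraically at every step rather than
approximately. Flow is laminar; no turbulence model is used. Domains are
two-dimensional idealizations — planar (with an out-of-plane depth used
for fluxes and areas) or axisymmetric (r, z) — of the craniospinal axis;
the axisymmetric annulus is the default solver geometry (the spinal SAS is
annular), the plane channel the verification geometry (its closed forms
are simplest), and the branched planar domain exercises the two-inlet
mass-conservation split (cervical SAS ↔ constriction ↔ cistern ← aqueduct).

Internal units are mm–g–s. This system is SI-consistent and makes
1 g/(mm·s²) = 1 Pa exactly, so pressures are pascal, velocities mm/s and
fluxes mm³/s with no conversion constants anywhere in the solver; it also
makes the resistance unit g/(mm⁴·s) numerically identical to
Pa/(mm³/s).

## Discretization

Staggered (MAC) finite differences: axial velocity u on z-normal faces,
transverse velocity v on y-normal faces, pressure at cell centres. The
axisymmetric operators carry the 1/r metric terms (r = 0 never occurs).
Time stepping is the standard incremental pressure-correction scheme:

1. **Tentative velocity** — viscous terms implicit (backward Euler),
   convection explicit second-order central advanced with Adams–Bashforth 2
   (forward Euler on the first step). Plain forward-Euler central
   convection is weakly unstable for advection over the ~5·10³ steps of a
   three-cycle run; AB2's growth on the imaginary axis is O(CFL⁴) and
   negligible at the enforced CFL ≤ 0.5.
2. **Pressure increment** — a finite-volume Poisson solve with homogeneous
   Neumann conditions on all boundaries; the nullspace is pinned by fixing
   one cell during the solve and removing the volume-weighted mean from the
   updated pressure. All reported measures are pressure differences and a
   test asserts their invariance to a constant offset.
3. **Projection** — divergence is removed to solver tolerance (direct
   sparse factorization; the measured residual is ~10⁻¹⁰ s⁻¹ against a
   10⁻⁶ s⁻¹ tolerance).

Operators are assembled once per run and LU-factorized (SuperLU), so a
step costs three triangular solves.

Walls: the normal velocity lives on wall faces and is set exactly to zero.
Tangential no-slip uses a quadratic ghost value u_ghost = −2u₀ + u₁/3
(wall on the face), which is second-order accurate and exact for parabolic
profiles; where a cell has walls on both sides the linear reflection
u_ghost = −u₀ is used. The stenosis bump is rendered as stair-step solid
cells (a cell is solid when its centre lies inside the wall); the shipped
mesh pairs place the throat wall exactly on a cell face at the transect
used for the velocity comparison, so the between-mesh metrics compare
discretizations of the same geometry rather than two different staircase
renderings of the throat.

### Boundary conditions

Velocity is prescribed on the entire boundary. At each opening the flux is
distributed by the wall-distance weight τ (zero at the opening's wall
junctions, increasing linearly with distance — a tent over the opening),
normalized by the *discrete* integral Στ·a over the opening's faces so the
discrete flux equals Q(t) to round-off (tested at 10⁻¹⁰ relative).
Outflow openings use the same profile with the waveform's sign. Openings
without a measured waveform receive the conservation remainder
Q_CS − ΣQ_measured split over their areas. The advective CFL number is
checked every step and a violation raises with advice to reduce Δt.

## Waveforms

Flux samples (default 32 per cycle, matching a typical PC-MRI acquisition)
are interpolated with a **periodic** cubic spline — the cardiac cycle
wraps, and a natural/clamped spline would have a C² defect at the seam
that pollutes the solver's time derivative. Negative flux is caudal
(systolic). The cycle origin is shifted to the systolic flow reversal
(Q(0) = 0 entering the negative phase); alignment is idempotent and a pure
time shift. Cycle statistics (caudal fraction, peak times, zero crossings)
are measured on a ≥4096-point dense grid of the spline and refined by
bounded root/extremum searches to 10⁻⁶ of the period; with multiple
systolic peaks the global minimum wins, ties broken by earliest time.

### Synthetic presets

The study subjects' waveforms exist only as plots; the printed summary
statistics are the only quantitative anchors. Each preset therefore
targets exactly those: heart rate, caudal-flow fraction, systolic-peak
time, amplitude. The generator builds a smooth two-lobe template (an
asymmetric sine-power caudal lobe and a compensating diastolic lobe),
projects it onto a truncated Fourier series (zero mean enforced through
the constant term; 8 harmonics by default), and corrects the template's
lobe width and peak position by a damped deterministic fixed-point
iteration until the statistics — measured through the same
sample → periodic-spline → align → analyse pipeline used downstream —
match the targets to 0.2 % (well inside the 1 % guarantee). Infeasible
target sets (e.g. caudal fraction 0.99 with two harmonics) fail the
iteration and raise an error naming the violated target. Optional Gaussian
noise is seeded; noise-free presets are seed-independent.

Cervical peak-flux amplitudes are recovered from the published measures
themselves (Q_CSmax = Δp_(PC−CS)max / R_sys → 4200, 2450, 3650 mm³/s),
which lands idealized-geometry velocities in the physiological
10–100 mm/s range. Aqueduct waveforms are delayed, amplitude-scaled copies
of the cervical spline (default ratio 0.10 — only ~10 % of the flow below
the foramen magnum originates in the ventricular system).

What the generator does **not** emulate: the true curve shapes (only their
summary statistics), beat-to-beat variability, PC-MRI noise structure and
velocity-aliasing artefacts, and any anatomical specificity. Passing tests
therefore demonstrate that the pipeline reproduces its own study
conditions and the printed worked examples, not that it predicts a
particular patient's absolute values.

## Hydrodynamic measures

Δp_PC−CS = p_PC − p_CS and Δp_Aq−PC = p_Aq − p_PC from slice-averaged
pressures (stations default to 35, 110 and 128 mm). Resistances divide the
respective Δp extremum magnitude by the peak systolic (or diastolic) flux
magnitude. θ = (t_umax − t_Δp(PC−CS)max)/T uses, per its stated
definition, the **caudal-flow duration** as T, not the full period; the
published θ values cannot be re-derived without the raw data, so this
quantity is reported but not used as an external check. The "FM" region
for peak velocity is the stenosis throat ± one gap width — the idealized
geometry has no anatomical landmark. Report tables round velocities to
integers, pressures to 0.1 Pa and resistances to 3 decimals.

The aqueduct pressure drop is implemented as Δp_Aq−PC = p_Aq − p_PC, the
form consistent with the published tables and figures (the prose
definition circulating for this quantity duplicates the cistern-to-cervical
one and is treated as a misprint).

## Mesh-independence metrics

e_|u| is the maximum over transect points of the relative |u| difference
between the coarse run and the fine run interpolated to the coarse
positions, at peak systole, along the mid-stenosis and mid-cervical
transects. Points where the fine speed is below 1 % of the line's peak are
masked (formalizing the near-wall caveat: relative differences there are
meaningless), as are points adjacent to a sign change of the axial
velocity (vortex regions). e_Δp is the signed percentage difference of the
peak Δp_PC−CS over the final cycle. Both metrics are scale-invariant.

The shipped pair: coarse 90×20 (1.5 mm axial, 0.125 mm radial), fine
144×25 — cell-count ratio exactly 2, mirroring a coarse/fine doubling.
With the Con1-like waveform in test mode the measured values are
e_Δp ≈ 0.5 % and e_|u| ≈ 6.5 %.

## Problem sizes and run settings

Defaults follow the study conditions: Δt = 10⁻⁴ s, three cardiac cycles,
zero-flow initialization ("reference mode"). The test-mode default
Δt = 5·10⁻⁴ s with the 20–25-cell-per-gap grids keeps a full three-cycle
annulus run at a few seconds while leaving the oscillatory-benchmark error
at 0.1 % and the cycle-periodicity residual (relative L2 difference of the
final two cycles' probe traces) near 10⁻⁴, far inside the ≤1 % criterion.
Only the final cycle feeds the measures. Convergence studies use 8–32
cells across the gap (steady) and Δt ∈ {4, 2, 1}·10⁻³ s
(temporal self-convergence).

## Numerical choices and degenerate inputs

* Pressure-solve and divergence tolerance: 10⁻⁶ s⁻¹ (direct solves leave
  ~10⁻¹⁰); CFL limit 0.5; periodicity tolerance 1 % (a warning in the run
  log, not fatal, since the criterion is diagnostic).
* The IPCS variant is the standard incremental form; the rotational
  variant is deliberately not implemented (a config field records the
  scheme name for forward compatibility).
* Degenerate inputs raise informative errors: fewer than 8 samples,
  non-monotone times, single-signed waveforms (no flow reversal),
  degenerate openings (∫τ = 0), zero peak flux in a resistance, zero
  station separation in a gradient, stenosis narrower than two cells,
  refinement factor ≤ 1, mass-unconservable flux assignments.
* The stenosis profile is a C¹ cosine bump; slope discontinuities would
  produce spurious pressure spikes.

## Known limitations

* Two-dimensional idealized geometries cannot reproduce the published
  patient-specific absolute velocities, pressure drops, resistances or θ;
  those require the (undeposited) patient meshes and raw PC-MRI data. The
  package's claims are therefore structural: analytic-benchmark agreement,
  conservation properties, convergence orders, and reproduction of the
  printed summary statistics and worked examples.
* Rigid walls and exact mass conservation neglect tissue compliance and
  the axial variation of volume flow seen in vivo.
* Stair-step stenosis walls limit geometric fidelity off the aligned
  transects; the cosine bump is a stand-in for tonsillar anatomy.
* Explicit central convection restricts the cell Péclet regime; the CFL
  guard rejects configurations it cannot integrate stably.
* Fine anatomical structures (trabeculae, nerve roots, denticulate
  ligaments), non-Newtonian effects and transitional flow are out of
  scope.
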