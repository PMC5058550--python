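# csfflow

Pulsatile cerebrospinal-fluid (CSF) flow on idealized craniospinal
geometries: an incompressible Navier–Stokes pipeline for the kind of
hydrodynamic comparison used to characterize Chiari I malformation —
pressure drop across the foramen magnum, flow resistance, and the phase
difference between pressure and flow — driven by phase-contrast-MRI-style
volumetric flux waveforms.

## The problem

CSF oscillates between the cranial and spinal compartments with every heart
beat. In Chiari I malformation the cerebellar tonsils partially obstruct
the subarachnoid space (SAS) at the foramen magnum, and the resulting
changes in velocity, pressure drop and resistance are candidates for
quantifying obstruction severity. Patient-specific CFD studies measure the
flux waveform at the cervical SAS and in the aqueduct with PC-MRI, impose
it on a segmented geometry, and compare subjects by a small set of
hydrodynamic measures. `csfflow` implements that whole chain at desk scale:
patient images are replaced by idealized geometries (plane channel, stenosed
axisymmetric annulus, branched two-inlet domain) and the measured waveforms
by synthetic presets calibrated to the published per-subject cycle
statistics (heart rates 71/86/77 bpm; caudal-flow fractions 26/47/37 % of
the cycle; systolic peaks at 8/17.5/14 % of the cycle; aqueduct flux ≈10 %
of cervical flux, delayed 28/15/16 % of the cycle).

## Model and measures

The solver integrates the incompressible Navier–Stokes equations

    ∂u/∂t + (u·∇)u = −(1/ρ)∇p + ν∇²u,     ∇·u = 0

with ρ = 1000 kg/m³ and μ = 7.0·10⁻⁴ Pa·s (CSF is water-like at body
temperature), using a semi-implicit incremental pressure-correction (IPCS)
fractional-step scheme on a staggered (MAC) grid in planar or axisymmetric
coordinates. Velocity is prescribed on the whole boundary: no-slip at
walls, and at each opening Γᵢ the flux Qᵢ(t) is distributed by a
wall-distance weight τ(x),

    u_Γᵢ = Qᵢ(t) · τ(x) / ∫_Γᵢ τ dΓ · n ,

so the discrete boundary integral of u·n equals Qᵢ exactly. Flux not
measured at an opening is assigned by mass conservation, split over the
unmeasured openings proportionally to their areas. Pressure gets
homogeneous Neumann conditions; all reported quantities are differences.

From slice-averaged pressures at the cervical SAS (CS), pontine cistern
(PC) and aqueduct (Aq) stations the package computes

* Δp_PC−CS = p_PC − p_CS and Δp_Aq−PC = p_Aq − p_PC (extrema, value at
  peak systolic flux, gradient in Pa/cm),
* resistances R = Δp_max / Q_max in g/(mm⁴·s) (numerically equal to
  Pa/(mm³/s)),
* the phase difference θ = (t_umax − t_Δpmax)/T with T the caudal-flow
  duration,
* peak regional speeds, the synchronous-bidirectional-flow fraction, and
  across-subject max/min ratio tables,

plus the mesh-independence metrics e_|u| (maximum relative |u| discrepancy
along sampling transects, outside near-wall and vortex masks) and e_Δp
(signed percentage difference of the peak Δp_PC−CS) between a coarse and a
~2×-refined mesh.

## Worked example

Simulate the control-like subject (Con1 waveform, stenosed annulus,
test-mode resolution) and print its summary row:

```sh
csfflow simulate --outdir runs/demo --seed 1
```

```
{"subject": "Con1", "|u|max_CS [mm/s]": 50, "|u|max_Aq [mm/s]": 73,
 "|u|max_FM [mm/s]": 85, "dp(PC-CS)max [Pa]": 80.8, "dp(PC-CS)min [Pa]": -33.7,
 "dp(Aq-PC)max [Pa]": 17.7, "dp(Aq-PC)min [Pa]": -7.7,
 "dp(PC-CS)tQmax [Pa]": 12.0, "grad(PC-CS) [Pa/cm]": 10.8,
 "R(PC-CS)sys [g/(mm4 s)]": 0.019, "R(PC-CS)dia [g/(mm4 s)]": 0.028,
 "R(Aq-PC)sys [g/(mm4 s)]": 0.004, "R(Aq-PC)dia [g/(mm4 s)]": 0.006,
 "theta [-]": 0.2}
```

Reading the row: the cervical peak speed (50 mm/s) and the foramen-magnum
jet peak (85 mm/s) are in the physiological tens-of-mm/s range; the peak
pressure drop from the pontine cistern to the cervical SAS is 80.8 Pa
(10.8 Pa/cm over the 75 mm between stations) but only 12.0 Pa at the
instant of peak systolic flux — the drop is dominated by inertia, not
friction, which is also why θ is small. The systolic resistance
R(PC−CS) = 80.8 Pa / 4200 mm³/s ≈ 0.019 g/(mm⁴·s). The run directory
contains the waveform and probe-trace CSVs, summary CSV/JSON, a legacy-VTK
snapshot at peak systole, and a log with the CFL margin, divergence
maximum and cycle-periodicity residual.

Other verbs: `csfflow synth-waveform` (preset → CSV), `csfflow measure`
(recompute a summary from traces), `csfflow converge` (two-mesh
sensitivity report), `csfflow report` (across-subject ratio table).

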