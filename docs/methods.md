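# Methods

## Physical model

Blood is treated as an incompressible Newtonian fluid with dynamic
viscosity η = 0.004 Pa·s and density ρ = 1235 kg/m³; vessel walls are
rigid with no-slip.  With a typical murine aortic-root peak velocity
V = 1 m/s and hydraulic diameter D = 1.58 mm the peak Reynolds number is
ρVD/η ≈ 488, well inside the laminar regime, so the unsteady Navier–Stokes
equations are solved without any turbulence model.  The cardiac cycle time
defaults to T = 0.1 s (≈ 600 bpm, murine); at this frequency the Womersley
number of the default geometry is α = (h/2)·√(2πρ/(Tη)) ≈ 3.48.

The vessel is idealized as a plane 2-D channel of height h = D = 1.58 mm
and length 12 h, with 12 small outflow openings ("ostia", width 0.18 h) in
6 axial pairs on opposite walls.  This is a deliberate desk-scale stand-in
for a subject-specific 3-D aorta: it preserves the model class (laminar,
Newtonian, rigid), the boundary-condition protocol and the metric
definitions, but no absolute 3-D WSS level.  Ostia are boundary openings;
the branch lumens are not meshed (`branch_length` is retained as metadata
only).

## Boundary conditions

* **Inlet** (x = 0): Dirichlet velocity profile whose instantaneous mean
  follows a periodic waveform.  The default profile is parabolic scaled to
  the waveform value; a plug profile and the exact pulsatile
  (Womersley-channel) profile are available, the latter used for
  validation runs so the analytic solution satisfies the boundary data
  exactly.
* **Outlets**: every exit carries a fixed fraction of the instantaneous
  inflow, enforced strongly by prescribing the outflow velocity each step.
  The raw split values are 69.8% for the main (descending) outlet and
  0.14% per ostium; because the full protocol's percentages do not sum to
  100 and the arch branches are absent from the single-channel
  idealization, fractions are renormalized among the exits present so mass
  is conserved exactly.  Ostium openings use plug outflow.  The main
  outlet defaults to a "scaled" profile — the zero-gradient extrapolation
  of the neighboring interior profile rescaled to the split flux — which
  enforces the flow division exactly without imposing an artificial
  profile shape; a plug main outlet is available but generates a strong
  local profile adjustment (and transverse velocities) at peak systole.
* **Walls**: no-slip, rigid.

The inlet waveform is a periodic composite cubic Bezier spline fitted by
linear least squares to sampled data.  Within each segment the control
times sit at the uniform thirds of the segment, making the spline an
explicit function of time; C0 continuity at the joins and periodic closure
v(0) = v(T) are built into the parameterization and therefore hold
exactly.  C1 continuity is deliberately not imposed.  Interior knots are
uniform in time.  The default murine waveform is a raised-cosine systolic
pulse spanning about a third of the cycle on a 5%-of-peak diastolic
plateau, sampled at 128 points with the peak on a sample.

Mapping the 1 m/s aortic-root peak onto the 2-D channel is a modeling
choice; the branched-channel studies scale the waveform to a peak mean
velocity of 0.4 m/s, which keeps the advective CFL number of the protocol
time step (T/1000) near 0.4 on the default 128×32 grid.

## Numerics

The solver is a staggered-grid (MAC) finite-volume projection method:

* QUICK (quadratic upwind) interpolation for advective fluxes, advanced
  explicitly with Adams–Bashforth 2 (forward Euler on the first step);
  faces lacking a far-upwind node fall back to central averaging.
* Crank–Nicolson viscous terms; the constant implicit operators are
  factorized once per run (sparse LU) and reused every step.
* Incremental pressure correction: the pressure Poisson equation (pure
  Neumann, one pinned cell, direct sparse LU) projects the predictor onto
  the divergence-free space; the discrete divergence after projection is
  at solver roundoff (≲ 1e-8 of the velocity-gradient scale V/h on all
  grids used).
* No-slip wall values lie half a cell outside the first velocity node;
  they enter the viscous operator through a quadratic ghost
  (∂²u/∂y² ≈ (4/3 u₁ − 4 u₀)/Δy²), which is exact for parabolic profiles.
  A mirror ghost was measurably first-order in the wall shear (relative
  error 2/(3 n_y) for fully developed flow); with the quadratic ghost the
  discrete steady solution reproduces 6ηU/h to machine precision.
* Wall shear is extracted with a one-sided second-order difference through
  the wall value, τ = η (9u₀ − u₁)/(3Δy), exact for quadratics.
* The advective CFL number is checked each step and a violation raises
  rather than silently destabilizing.
* The solver is deterministic; no randomness enters any flow run.

**Protocol.**  Production runs use the cardiac-cycle protocol: time step
T/1000, three cycles from rest so that periodicity is fully developed, and
the last cycle evaluated.  The recorded final-cycle wall-shear series at
phase k·Δt (k = 0…999) is compared cycle-over-cycle; the RMS change
between the last two cycles is ~1e-6 relative in the default runs.

**Validation.**  Three analytic checks (see `analysis/02_validate_solver.py`):

1. *Steady plane Poiseuille*: wall shear within 2% of 6ηU/h at 64
   transverse cells (measured: machine precision, because the discrete
   fully developed solution is the exact sampled parabola).  Wall shear is
   measured on the central band of an 8h channel, away from inlet/outlet
   adjustment regions.
2. *Pulsatile Womersley channel* at α = 3.48: final-cycle wall shear
   within 3% RMS of the closed-form series (measured: 0.015% at 64 cells
   with the protocol step count).
3. *Grid convergence* across 32/64/128 transverse cells with the time step
   refined proportionally (both the spatial and temporal discretizations
   are second order, so a fixed time step would impose a splitting-error
   floor at the finest grid): least-squares observed order ≈ 1.97.

## WSS metrics

For a record of WSS vectors on a uniform time grid spanning one period
(endpoint-exclusive), integrals are evaluated by the periodic trapezoidal
rule, which reduces to the arithmetic mean of the samples and is
spectrally accurate for smooth periodic signals.  Conventions:

* **TAWSS** is the time average of the shear *magnitude* (1/T)∫|τ⃗|dt.
  (With the time-averaged *vector* instead, OSI would be identically
  zero; the magnitude form is the standard definition and the one
  consistent with the OSI formula.)
* **OSI** = ½(1 − |τ⃗_mean|/TAWSS), clamped to [0, ½] against rounding;
  defined as 0 when TAWSS < 1e-12 Pa.
* **transWSS** takes the absolute value of the projection onto
  n⃗ × τ⃗_mean/|τ⃗_mean| inside the integral, so it is non-negative and
  bounded by TAWSS.  When the cycle-mean vector vanishes the transverse
  direction is undefined; the value is reported as 0 with a
  direction-degeneracy flag.  transWSS requires 3-D vectors and the wall
  normal; for 2-component records it raises, since the in-plane cross
  product leaves no tangential transverse direction.  The 2-D solver
  embeds its records in 3-D (τ_z = 0), for which transWSS is exactly 0 —
  planar flow has no transverse shear component.

Region summaries report mean, SEM = sd/√n (ddof = 1, not available at
n = 1) and n per region, plus pooled "all_ostial" and "all" rows, covering
both interpretations of a single per-group summary number (ostial points
only vs the whole wall).

**Ostium regions.**  A wall point belongs to an ostium's region when it
lies within 1.5 ostium-widths of the ostium mouth center on the same wall.
The 12 ostia map onto 4 quadrants of 3: the lower wall is the "left" pair
column, the upper wall "right"; the proximal half of the channel is
"upper", the distal half "lower".

## Synthetic data

The generator emulates the statistical structure of surface WSS vector
time series without any 3-D geometry.  Per surface point, in a random
orthonormal tangent frame (e₁, e₂) of a random unit normal:

τ(t) = e₁·(m + f_osc·m·sin ωt) + e₂·(f_trans·m·sin(ωt + φ)) + noise,

with the point magnitude m drawn around its regional mean (default CV
10%), a single global frequency ω = 2π/T (higher harmonics are available
through the spec), transverse phase φ = π/2, and tangential Gaussian noise
(default sd 0.05 Pa).  Defaults: 12 ostium regions (4 quadrants × 3) at
20 Pa mean shear plus a non-ostial region at 10 Pa, 5 points per ostium
region, 64 time samples, f_osc = 0.25, f_trans = 0.10.  All randomness
derives from one seed through `numpy` SeedSequence spawning, so fields and
cohorts are exactly reproducible.

**Cohorts.**  Two groups; the treated ("dha") group scales the mean shear
magnitude and the oscillatory and transverse fractions by 0.8, emulating
the direction and approximate ratio of the reference contrast (treated ≈
0.78–0.80 of control TAWSS) rather than absolute Pa levels, which depend
on unavailable subject-specific 3-D geometry.  Between-subject variability
is a multiplicative Gaussian factor on each subject's shear level (default
CV 5%); per-subject seeds are spawned deterministically from the base
seed.

What passing tests on these fields do **not** show: fidelity of absolute
WSS magnitudes, spatial correlation along the wall, inter-metric
correlations of real aortic flow, or measurement error of a real CFD/
imaging chain.  They do show that the metric implementations, the summary
statistics and the inference pipeline recover known structure and known
contrasts exactly and with calibrated error rates.

## Statistics

The unit of analysis is the subject (region-mean per simulated subject),
not the wall point, avoiding pseudo-replication.  Group comparisons use
Welch's two-sample t test per metric × region, two-sided, with Holm
correction across regions within each metric; comparisons with fewer than
2 subjects per group are flagged not-available.  Simulation studies (sizes
chosen as the package's standard configurations):

* *Power*: 200 replicate cohorts at n = 12/12 with the 0.8× treated
  group; the fraction of replicates in which all three metrics are
  significantly lower (p < 0.05) in the treated group exceeds 95%.
* *Calibration*: 1000 replicate cohorts with identical groups at
  n = 10/10; the rejection rate at α = 0.05 sits within 0.05 ± 0.02.
  Calibration replicates use a reduced per-subject field (2 points per
  region, 32 time samples): under the null the p-value distribution does
  not depend on the field resolution, and the smaller field keeps the
  1000-replicate study fast.

## Known limitations

* The 2-D channel cannot produce transverse WSS (transWSS ≡ 0 on solver
  output); multidirectionality is exercised through the synthetic 3-D
  fields.  Absolute WSS magnitudes of the 3-D reference system are out of
  scope by design.
* Outflow splits are enforced strongly (prescribed outflow velocities);
  weak gradient-based outlet conditions are not implemented.
* The Bezier fit uses uniform knots and C0 continuity only; waveforms
  with very sharp features may need more segments rather than adaptive
  knots.
* The Womersley oracles reject Womersley numbers above ~500, where the
  complex Bessel/cosh evaluations overflow.
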