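# Methods

Numerical methods, conventions, frozen benchmark settings and known
limitations of the `embryoflow` pipeline.

## Synthetic heart generator

The heart is a looped serial tube (inlet → RA → LA → AV junction → LV → RV →
OFT → outlet) built from per-station cross-sections with chamber-specific
radial bumps. Per-chamber volume waveforms are the construction target: the
enclosed volume of the discrete mesh is an exactly quadratic function of each
chamber's radial bump scale, so the generator solves one quadratic per chamber
per frame and the realised mesh volumes match the target waveforms to machine
precision. Atrial and ventricular activation waveforms are smooth, periodic
and normalised to [0, 1]; the LAL condition is modelled by `la_narrowing_factor`,
which scales the left-atrial EDV and SV jointly. At HH28 the AV cross-section
is pinched into two lumen lobes (`n_av_junctions = 2` metadata).

Cohort parameters are fitted (`fit_cohort_params`) so that the generated
cohort reproduces the packaged target statistics — mean ± SD of atrial SV,
ventricular SV and the per-embryo atrial/ventricular SV ratio — exactly (or
to ≤0.2 % relative where the joint system is overdetermined). The packaged
cohort table (`data/cohort_targets.csv`) defines the study conditions:
control/LAL at HH25 (n = 5/4) and HH28 (n = 4/4). These defaults were frozen
during calibration and are not tuned against downstream outcomes.

## Volumetry (kinematics)

Chamber volumes use the divergence theorem over each region's faces plus caps
built from the region's oriented boundary edge loops. The cap construction is
independent of the generator's internal bookkeeping, so mesh volumetry is a
genuine oracle for the generator and vice versa. Stroke metrics: EDV = max V,
ESV = min V, SV = EDV − ESV, EF = SV/EDV, CO = SV/period. Through-flow is the
fraction of ventricular filling that occurs outside the atrial-emptying
window. Area stretch is the per-face first-frame-relative area ratio.

## Imaging

`phase_align` scores candidate periods by frame-pair similarity and selects
the **shortest** lag whose score is within 0.02 of the maximum: integer
multiples of the true period score equally up to noise, so the tolerance
prefers the fundamental. Ensemble averaging supports `mean` and `rms` modes
(RMS preserves oscillating-speckle contrast that coherent averaging cancels).
`sync_slices` recovers inter-slice phase offsets by maximising cyclic
cross-correlation between adjacent averaged slices; offsets are relative to
the first slice.

## Flow solver (hemosolver)

2D incompressible Navier–Stokes on a moving channel-fitted grid
(x × η, where η spans the local gap between the moving walls):
incremental pressure-correction (projection) with semi-Lagrangian advection
and implicit viscosity on a staggered (MAC-type) layout; `u` lives on
x-faces × η-centres, `v` on x-centres × η-faces. Wall motion enters through
the grid velocity. Fluid defaults: ρ = 1060 kg/m³, μ = 4·10⁻³ Pa·s. Solves
are scaled-down (2D) analogues of the full 3D problem; Reynolds numbers are
reported per region as peak ρU D/μ with D the local hydraulic diameter.

Domains built from a heart mesh (`build_domain`) append an outlet extrusion
about two outlet diameters long whose wall motion is decayed by a sigmoid to
< 5 % of the peak heart-wall motion at the domain end; an axisymmetric
static-pipe mode supplies the Poiseuille tube benchmark.

Boundary conditions: Dirichlet inlet pressure (reference 0 Pa for heart
solves), outlet either pressure (0 Pa) or Dirichlet velocity
`outlet_scale · outlet_shape(t)`. Cyclic convergence: the solver repeats
cycles until the cycle-to-cycle change of the velocity field metric falls
below `tol` (default 0.5 %), recorded in `convergence_history`; converged
solves reach this within 10 cycles.

### Frozen benchmarks

* **Poiseuille pipe** (R = 0.15 mm, U = 0.05 m/s): WSS within 2 % of
  4μQ/(πR³); centreline profile within 2 % of 2U(1 − (r/R)²).
* **Steady channel** (half-width a = 0.15 mm, Δp = 0.5 Pa over 2 mm):
  parabola and WSS = G·a within 2 %.
* **Oscillatory channel** (a = 0.15 mm, L = 2 mm, T = 0.45 s, Δp₀ = 1 Pa
  sinusoid, nx = 48, ny = 16, 240 steps/cycle; Womersley number α = 0.289):
  compared against the **exact** analytic solution
  û(y) = C(1 − cosh(ky)/cosh(ka)), k = √(iωρ/μ), C = −Δp₀/(ωρL),
  u = Re[û e^{iωt}]. Measured max relative error 1.65 % (tolerance 3 %).
  The temporal error is second-order in dt (≈ 2(ω dt)²/α²: 6.6 % → 1.65 %
  → 0.41 % over 120/240/480 steps per cycle); note the exact solution itself
  deviates ≈ 0.34·α² from the naive quasi-steady parabola, so refinement
  moves *away* from quasi-steady toward the true solution. Halving dt changes
  the solution by ≤ 3 % (measured 2.55 %).

## Boundary-condition tuning (bc_tuner)

The outlet velocity scale is tuned against a Doppler peak by multiplicative
ratio updates: scale_{k+1} = scale_k · target/measured. For a linear plant
this converges exactly after one update (two trials); on a surrogate with
20–25 % saturating nonlinearity it reaches 5 % within 3–4 trials with
monotone error contraction. Heart-solve protocol: velocity outlet with the
Doppler-normalised waveform shape, target = Doppler peak; `solver_plant`
caches its last converged solution/scale so callers can reuse the final solve.

## Wall forces (wallforces)

* **OSI** = ½(1 − |∫τ dt| / ∫|τ| dt), computed per wall face over the cycle;
  where ∫|τ| dt = 0 the OSI is defined as 0 (no shear ⇒ no oscillation).
  OSI ∈ [0, 0.5]: 0 for unidirectional shear, 0.5 for a zero-mean reversal.
* **Systole** is the window where ventricular volume decreases
  (`systole_window`); metrics can also be evaluated on explicit intervals.
* **Ejection work** = ∫ P dV over the ejection window (trapezoidal), per
  metre of depth (2D); rigid walls give exactly 0.
* `regional_summary` reports per-region time-mean, time-peak and facewise-peak
  WSS, area-weighted.

## Particles

`seed` places particles uniformly in the lumen with a wall clearance
(default 10⁻⁶ m); positions are advected through the periodically-extended
solved flow with bilinear-in-space, linear-in-time velocity interpolation and
RK2 stepping. Retention per region is *continuous residence*: the fraction of
particles seeded in a region that have remained inside it for every store
point up to cycle k (monotonically non-increasing). Particles leaving the
outlet are flagged and conservation is checked.

## Cohort statistics

Shapiro–Wilk W and one-tailed two-sample t-tests (pooled or Welch) with
directional hypotheses declared per metric; significance stars follow the
declared direction (wrong-direction differences are never starred). Results
are deterministic and serialisable to JSON/text.

## Known limitation: LV particle retention direction

End-to-end cohort comparisons on the default study conditions reproduce the
expected directional findings for wall shear (LAL LV WSS < control,
LAL LA WSS > control), oscillatory shear (LAL LV and RV OSI > control) and
atrial through-flow (LAL > control), and the synthetic Doppler peaks fall in
the LAL group as expected. The **particle-retention direction does not
reproduce**: left-ventricular retention at cycle 5 is *lower* in the LAL
cohort than in controls (cohort means 0.084 vs 0.102 whole-LV; 0.141 vs 0.187
in an LV-free-wall band; 0.183 vs 0.251 for particles seeded in the apical
wall depression), the opposite of the expected sheltered-apex accumulation.

The underlying mechanism *is* present: the time-mean flow speed in the LAL
apical pocket is about half the control value (0.0006 vs 0.0012 m/s), and LV
speeds are lower overall in LAL. The discrepancy is geometric: the
generator's apical wall depression has a fixed amplitude, so the sharper
(higher-concentration) LAL depression produces a *narrower* sheltered pocket
than the broad control depression — fewer particles start in, or wander into,
the low-speed zone even though that zone is slower. A generator whose
depression amplitude grows with its sharpness would likely reverse this, but
the generator defaults are study conditions frozen at calibration time and
are deliberately not adjusted to change downstream comparison outcomes. The
corresponding acceptance test reports this direction as a genuine failure
rather than masking it.
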