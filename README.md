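# embryoflow

Synthetic 4D embryonic-heart generation, chamber volumetry, scaled-down
intracardiac hemodynamics and cohort statistics for the left-atrial-ligation
(LAL) chick-embryo model of hypoplastic left heart syndrome (HLHS).

## Scientific problem

In the LAL model, a suture placed across the left atrium of a chick embryo at
an early developmental stage (HH21) restricts flow into the left heart.
Downstream of that single mechanical insult, the left ventricle grows far less
than in control embryos while the right ventricle over-grows — a
flow-dependent growth cascade that mirrors human HLHS. Quantifying that
cascade requires a pipeline from 4D imaging of the beating heart through
chamber volumetry to computational hemodynamics: wall shear stress (WSS),
oscillatory shear index (OSI), ejection work, intracardiac particle transport,
and group statistics across control and LAL cohorts at stages HH25 and HH28.

`embryoflow` implements that pipeline end-to-end over *synthetic* hearts. A
deterministic generator produces watertight, chamber-labelled 4D surface
meshes whose per-chamber volume waveforms exactly realise calibrated cohort
statistics (stroke volumes, atrial/ventricular SV ratios, stage-to-stage EDV
growth), so every downstream stage can be validated against known ground
truth.

## Modules

| Module | Purpose |
|---|---|
| `params`, `cohort`, `geometry` | Cohort calibration and the 4D synthetic heart generator (looped tube: inlet → RA → LA → AV junction → LV → RV → OFT) |
| `meshseq`, `doppler`, `cine` | Mesh-sequence container with VTP/CSV I/O, synthetic Doppler traces, cine-microscopy renderer |
| `imaging` | Cine phase alignment (period detection), ensemble averaging, inter-slice synchronisation |
| `kinematics` | Divergence-theorem chamber volumetry, stroke metrics, atrial→ventricular through-flow, area stretch, section profiles |
| `hemosolver` | 2D moving-boundary incompressible Navier–Stokes solver (projection method on a channel-fitted grid), domain builder with sigmoid-decayed outlet extrusion, Reynolds-number reporting |
| `bc_tuner` | Ratio-update tuning of the outlet velocity scale against a Doppler peak |
| `wallforces` | WSS/OSI fields, regional summaries, ejection work |
| `particles` | Passive particle seeding, advection through the solved flow, residence/retention curves |
| `cohortstats` | Shapiro–Wilk normality checks and one-tailed two-sample t-tests over cohort tables |

## Worked example

Generate a control HH25 cohort, measure one embryo, tune and solve its flow,
then compute wall forces and particle retention:

```python
import numpy as np
from dataclasses import replace
from embryoflow import (
    generate_cohort, build_kinematics_report, synth_doppler,
    BoundaryConditions, build_domain, solve_cycle, tune_outlet,
    build_wall_report, seed, advect, retention)
from embryoflow.bc_tuner import solver_plant, _doppler_shape

# 1. Cohort of 5 synthetic control HH25 embryos (deterministic per seed)
cohort = generate_cohort("control", "HH25", seed=42)
params, seq, labels, waveforms = cohort[0]

# 2. Volumetry: EDV/SV/EF per chamber, AV SV ratio, through-flow
rep = build_kinematics_report(seq, labels)
print(rep.atrial_sv, rep.ventricular_sv, rep.av_sv_ratio)

# 3. Doppler-tuned scaled-down flow solve
dop = synth_doppler(params, rep.oft_systolic_area)
bc = BoundaryConditions(inlet_pressure=lambda t: 0.0, outlet_bc="velocity")
dom = build_domain(seq, labels, bc, nx=120)
plant = solver_plant(dom, bc, dop, cycles_max=10, tol=0.005,
                     ny=16, steps_per_cycle=240)
res = tune_outlet(plant, dop.peak / 1000.0, tol=0.05,
                  scale0=dop.peak / 1000.0)
sol = plant.last_solution          # converged cycle at the tuned scale

# 4. Wall forces and particle transport
wall = build_wall_report(sol)
print(wall.region_wss["LV"]["mean"], wall.region_osi["LV"])
ens = seed(sol, n=500, clearance=1e-6, seed=42)
ens = advect(sol, ens, n_cycles=5, store_every=8)
print(retention(ens, sol)["LV"])   # fraction retained per cycle
```

The same pipeline is scriptable from the CLI:

```sh
embryoflow generate --group control --stage HH25 --seed 42 --out data/
embryoflow kinematics --mesh data/control_HH25_00/mesh.series \
    --labels data/control_HH25_00/labels.csv --out kin/
embryoflow tune --mesh data/control_HH25_00/mesh.series \
    --labels data/control_HH25_00/labels.csv \
    --doppler data/control_HH25_00/doppler.csv --out tune.json
embryoflow stats --table cohort_table.csv --direction "lv_wss=control>LAL"
```

## Reproduction

All headline quantities are recomputed from scratch (no cached numbers) by

```sh
python scripts/acceptance.py --seed 42 --out targets.json
```

which regenerates the four cohorts, runs the volumetry pipeline on every
embryo, performs one Doppler-tuned flow solve, and writes the cohort-mean
stroke volumes, SV ratios, EDV growth percentages and the peak AV/OFT
Reynolds number as JSON. The full validation suite is

```sh
python -m pytest tests
```

Solver benchmarks (Poiseuille pipe, steady and oscillatory channel against
closed-form solutions), volumetry oracles against analytic solids, and
end-to-end cohort directional comparisons are all included; see
`docs/methods.md` for the numerical methods, frozen benchmark settings, and
known limitations (including one documented directional discrepancy in
left-ventricular particle retention).
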