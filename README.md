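# fiberclot

Tools for studying how the geometric design of an artificial-lung hollow
fiber bundle — fiber packing density, blood path length, and blood velocity
(the knob a larger frontal area turns down) — shapes thrombus formation,
and for quantifying that thrombus from volumetric (micro-CT-style) scans of
rod-array flow chambers.

Artificial lungs fail when clot fills the fiber bundle, and bench studies of
this process image 3D-printed chambers of vertical 380 μm rods (packing
densities 40–60 %, path lengths 2–4 cm, velocities 16–25 cm/min) after
pumping donor blood through them.  `fiberclot` provides, as a pipeline of
composable modules:

* **geometry** — parametric rod-array chambers; flow-rate/velocity
  conversion `Q = u_s·W·H`, interstitial velocity `u_s/(1−PD)`, hydraulic
  diameter `d_f(1−PD)/PD`, Reynolds number, cumulative fiber surface
  `S(z) = 4·PD·W·H·z/d_f`, and matched-surface "equivalent distances";
* **synthetic** — voxel phantoms of clean and clotted chambers.  Clot grows
  by seeded stochastic surface accretion with rate
  `β0·exp(β_z z/L)·(1+β_in·1[z<z_in])·exp(−gap/δ)·(u_ref/u_i)^α`,
  reproducing outlet-dominant deposition, secondary inlet capture, fibrin
  bridging of narrow inter-fiber gaps, and shear cleaning; paired-donor
  cohorts and Kozeny–Carman resistance trajectories
  `R = R0·((1−PD)/(1−PD−φ))²` complete the generator;
* **quantify** — the scan-analysis chain: Otsu segmentation, clean-mask
  subtraction, the standard edge crops (0.4 / 1.3 / 1.0 mm), 2 mm
  longitudinal slice profiles normalised by available void volume,
  replicate-averaged clot probability maps, plan-view projections, and 1 mm
  slab volumes at equivalent distances from the inlet;
* **hemodynamics** — resistance `R = ΔP/Q` (mmHg·min/mL), ln-resistance
  trajectories, clot-free baseline fixtures and excess-over-baseline flags;
* **stats** — donor-paired sign-flip permutation tests (exact or sampled),
  Bonferroni adjustment, and trend-direction measures.

## Worked example

Six synthetic donors, each run through a 40 % and a 60 % packing-density
chamber at 20 cm/min (scaled-down 10 mm chambers at 40 μm voxels):

```python
import numpy as np
from fiberclot import (
    ChamberSpec, FlowCondition, ClotSimParams, CohortDesign, generate_cohort,
    crop_volume, paired_permutation_test, flow_rate_for_velocity,
    hydraulic_diameter,
)

spec40 = ChamberSpec(packing_density=0.40, path_length=10.0, height=1.5)
spec60 = ChamberSpec(packing_density=0.60, path_length=10.0, height=1.5)
design = CohortDesign(
    conditions=(
        (spec40, FlowCondition.for_velocity(20.0, spec40)),
        (spec60, FlowCondition.for_velocity(20.0, spec60)),
    ),
    donors=6, seed=1, voxel_size=40.0, params=ClotSimParams(steps=15),
)
vols = {0: {}, 1: {}}
for run in generate_cohort(design):
    c, d = run.covariates["condition_index"], run.covariates["donor_id"]
    vols[c][d] = crop_volume(run.segmentation.clot).binary_volume_mm3()

v40 = [vols[0][d] for d in range(6)]
v60 = [vols[1][d] for d in range(6)]
print(f"Q at 20 cm/min: {flow_rate_for_velocity(20.0, ChamberSpec()):.2f} mL/min")
print(f"D_h at 60% packing: {hydraulic_diameter(spec60):.4f} mm")
print(f"mean clot volume, 40%: {np.mean(v40):.2f} mm^3")
print(f"mean clot volume, 60%: {np.mean(v60):.2f} mm^3")
res = paired_permutation_test(v60, v40, exact=True)
print(f"paired difference: {res.statistic:.2f} mm^3, p = {res.p_value:.4f} "
      f"({res.n_permutations} sign patterns)")
```

prints

```
Q at 20 cm/min: 4.38 mL/min
D_h at 60% packing: 0.2533 mm
mean clot volume, 40%: 0.75 mm^3
mean clot volume, 60%: 1.39 mm^3
paired difference: 0.64 mm^3, p = 0.0312 (64 sign patterns)
```

The 20 cm/min superficial velocity through the 7.3 × 3 mm frontal area is
exactly the 4.38 mL/min pump rate; the denser bundle catches roughly twice
the clot of the looser one in every donor, and with six donors the exact
sign-flip test's p-value of 2/64 ≈ 0.031 is the strongest evidence a paired
design of that size can give.

A command-line interface wraps the same chain:

```sh
fiberclot design --pd 0.5 --path-length-mm 20 --out chamber.json --plot plan.png
fiberclot simulate --spec chamber.json --velocity 20 --seed 3 --out sim/
fiberclot quantify --clean sim/clean_mask.tif --scan sim/grayscale.tif \
    --spec chamber.json --out quant/
fiberclot analyze-resistance --series sim/resistance.csv --spec chamber.json
fiberclot run --config study.yaml
```

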