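# Methods

`fiberclot` models how the geometry of an artificial-lung fiber bundle —
packing density, path length, and blood velocity (a proxy for frontal
area) — shapes thrombus deposition, and re-implements the micro-CT analysis
used to quantify that deposition in bench flow-chamber experiments.  Because
no scanner data are deposited for such experiments, the package couples the
analysis pipeline to a synthetic phantom generator so every stage can be
validated against known ground truth.

## Chamber model

A chamber is a rectangular duct of width `W` (default 7.3 mm), height `H`
(3 mm) and path length `L` (20 or 40 mm) containing vertical rods of
diameter `d_f` (380 μm) that span the full height, standing in for hollow
gas-exchange fibers.  Rods are laid on a square lattice aligned with the
flow (hexagonal optional); the lattice constant follows from the areal
packing density `PD`:

    s = d_f * sqrt(pi / (4 PD))          (square lattice)

valid for `PD < pi/4`.  Rods crossing the walls are kept and clipped by the
voxelizer, mirroring the downstream exclusion of wall regions from
analysis.  Realized packing density is measured by fine-grid rasterization
of an interior window snapped to whole lattice cells, where periodicity
makes the expected value exactly `PD`.

Derived quantities, all in the package's working units (mm, min, mmHg,
velocities in cm/min, flow in mL/min):

* flow rate `Q = u_s · W · H` with `u_s` the superficial velocity
  (20 cm/min through 7.3 × 3 mm gives exactly 4.38 mL/min — the convention
  is fixed by that identity; a quoted pump rate inconsistent with its
  quoted velocity by more than 0.5 % is rejected, and velocity is treated
  as primary);
* interstitial velocity `u_i = u_s / (1 − PD)`;
* hydraulic diameter of the infinite rod bundle
  `D_h = 4 · void / wetted surface = d_f (1 − PD)/PD` (walls excluded);
* Reynolds number `ρ u D_h / μ` evaluated in SI units, which collapses to
  `ρ u D_h / (6 μ)` in working units.  For the glycerol-analogue baseline
  at 50 % packing (interstitial 40 cm/min, 3.4 cP, 1.09 g/mL) this is
  ≈ 0.81, i.e. firmly creeping flow.  Published figures for comparable rigs
  sometimes quote values two orders of magnitude larger; these cannot be
  recovered from the stated formula under any standard velocity/length
  convention we tried, so the package reports only the SI evaluation;
* cumulative fiber surface from the inlet, `S(z) = 4 PD W H z / d_f`.

**Equivalent distances.**  To compare clot across conditions at matched
fiber-surface exposure, depths from the inlet are looked up from the
published table (16/20/25 cm/min → 6.8/5.7/4.5 mm; 40/50/60 % packing →
10.0/5.7/3.2 mm), which is the default and what acceptance checks.  An
analytic criterion is also provided: matching cumulative surface per
volumetric throughput `S(d)/Q` against the (20 cm/min, 50 %, 5.7 mm)
reference gives `d = 5.7 · (0.5/PD) · (u/20)`.  It reproduces the reference
point but not the published packing-density depths (it yields 7.1 mm at
40 % and 4.75 mm at 60 %), so it is clearly labelled exploratory; the
published matching rule is not derivable from the available description.

## Synthetic phantoms and clot accretion

Chambers are voxelized on isotropic grids (axis order: width, height/rod
axis, flow with the inlet at index 0).  The default 20 μm voxel — not the
3 μm of a real scanner — keeps a full 2 cm chamber around 55 M voxels;
convergence tests go down to 10 μm.  Voxels must satisfy
`voxel ≤ d_f/4` so fibers stay resolved.

Clot grows by stochastic surface accretion: at each step every fluid voxel
face-adjacent (6-connectivity) to solid or clot converts with probability
`1 − exp(−λ)`, with

    λ = β0 · exp(β_z z/L) · (1 + β_in · 1[z < z_in]) · exp(−gap/δ) · (u_ref/u_i)^α

where `gap(x, z)` is the distance to the surface of the nearest rod *other*
than the closest one (computed from the analytic rod centers via a k-d
tree: second-nearest center minus radius).  The factors encode, in order:
surface-nucleated deposition; preferential downstream/outlet accumulation;
secondary embolus capture over the first `z_in` mm of the inlet; easier
fibrin bridging across narrow inter-fiber gaps; and shear cleaning that
slows deposition as interstitial velocity rises.

Defaults: `β0 = 0.01` per step, `β_z = 2`, `β_in = 1` over `z_in = 1` mm
(matching the 1 mm inlet crop), `δ = 0.1` mm (comparable to the 55–153 μm
surface-to-surface gaps at 60–40 % packing, so bridging discriminates
between packings), `α = 1`, `u_ref = 40` cm/min (the 20 cm/min, 50 %
baseline's interstitial velocity), 30 steps mapped onto the 15-minute
protocol.  `β0` was set so a default run ends sub-saturated (clot occupies
roughly 5–10 % of the chamber): at much higher intensities the void fills
and the packing-density contrast *inverts*, because a 40 % chamber simply
has more void to fill.  The generator is phenomenological: it is designed
to reproduce effect signs (more clot at higher packing density and lower
velocity), the outlet-dominant spatial pattern with secondary inlet
capture, and paired-donor statistical structure — never absolute clot
volumes in mm³, which in the bench experiments depend on donor blood.

Candidate voxels are visited in flat-index order and all draws come from
one seeded PCG64 generator, so a fixed seed yields bit-identical volumes
across runs and platforms.

**Rendering.**  Grayscale stacks map fluid/clot/solid to 0.2/0.6/1.0,
blurred with an 8 μm Gaussian point-spread (sub-voxel at the 20 μm
emulation scale, as the real scanner's PSF is sub-voxel at its own 3 μm
scale) and corrupted with additive Gaussian noise (σ = 0.05), clipped to
[0, 1].  What the renderer does *not* emulate: beam hardening, ring
artifacts, partial-volume bias at sub-voxel PSF, registration error between
scan and clean mask, or intensity overlap between clot and resin.  Passing
the imaging round trip therefore shows the quantification chain is
self-consistent, not that it would segment a real reconstruction without a
tuned threshold.

**Resistance coupling.**  The bench baselines (mmHg·min/mL) are shipped as
measured constants: 0.333/0.365/0.379 at 2 cm for 40/50/60 % packing and
0.615 at 4 cm/50 %.  Clot burden maps to resistance through a
Kozeny–Carman-style porosity square,

    R(t) = R0 · ((1 − PD) / (1 − PD − φ(t)))²,

with φ the clot fraction of total chamber volume; the exponent is a
modelling choice (the bench data constrain only monotone trends), and
`PD + φ ≥ 1` raises an occlusion error.  For scaled-down chambers the 2 cm
baseline is scaled proportionally in path length (Darcy flow through a
homogeneous bundle).  The model is monotone by construction and does not
reproduce the transient resistance dips reported at medium/high velocity,
for which no mechanism is available.

**Cohorts.**  A cohort crosses every donor with every condition, as the
paired bench protocol did (default 6 donors).  Donor-to-donor coagulability
is a single lognormal multiplier on `β0` (σ = 0.25) shared across a donor's
runs, which is exactly the structure a paired analysis cancels; aPTT
covariates are drawn uniformly on the 20–50 s inclusion window.  All
per-run seeds descend deterministically from the cohort seed.

## Quantification pipeline

* **Segmentation** — three-class Otsu on the grayscale volume, cutting at
  the lower threshold (fluid vs denser-than-fluid); a fixed absolute
  threshold is available.  Flat images are rejected.
* **Mask subtraction** — `clot = segmented AND NOT clean-chamber mask`,
  requiring identical grid geometry.
* **Crop** — 0.4 mm top and bottom, 1.3 mm each side, 1 mm at the inlet;
  the outlet face is untouched.  Margins snap to whole voxels toward the
  interior and the volume origin is advanced, so later distances are still
  measured from the true inlet.
* **Slice profiles** — clot volume in 2 mm longitudinal segments, either
  five segments centred at 5/25/50/75/95 % of the cropped length
  (entrance, first quarter, middle, third quarter, downstream end) or a
  contiguous tiling that exactly partitions the total.  Each segment's
  volume is normalised by its available void volume,
  `region volume × (1 − PD)`; voxelization can leave a cropped segment's
  true void slightly above the nominal fraction, so profile fractions are
  capped at 1 (the standalone normaliser rejects physically impossible
  volumes outright).
* **Probability maps** — voxelwise mean of replicate binary masks; the map
  mean equals the mean input clot fraction, and the result is invariant to
  replicate order.
* **Projections** — mean along the rod axis (plan view, inlet→outlet) by
  default, or along the flow axis; both axes are exposed because the
  source descriptions of the 2D averaging axis are inconsistent.
* **Equivalent-distance slabs** — clot volume in a 1 mm slab at a stated
  depth, attributed by voxel centers, measured pre-crop from the true
  inlet (published depths such as 3.2 mm fall inside the cropped inlet
  margin's coordinate frame, not outside the retained data).

## Statistics

Mixed models with donor as subject and aPTT as covariate require the
original donor data and a specified covariance structure; the package
instead provides donor-paired sign-flip permutation tests.  The statistic
is the mean within-donor difference; the null flips each donor's difference
sign independently (exchangeable under the paired null).  Enumeration is
exhaustive when `2^donors` fits the permutation budget (p = #{|T*| ≥ |T|}/2^n;
the two-sided floor at 6 donors is 2/64 ≈ 0.031), otherwise Monte-Carlo
with the +1 correction so p is never 0.  Bonferroni adjustment and a
Kendall-tau trend direction measure complete the module.

## Problem sizes and numerical choices

Tests and the acceptance script run simulations on scaled-down chambers —
10 mm path, 1.5 mm height, 40 μm voxels, 15 accretion steps, 10 six-donor
cohorts — chosen so the full suite and script each run in well under ten
minutes on one CPU; geometry convergence checks use 10 μm voxels on a
3 × 0.8 mm section.  Tie handling in permutation tests uses a 1e-12
tolerance on |T|; crop margins round toward the interior; segment bounds
are clipped to the volume.  Known limitations: no CFD flow or shear fields,
no gas-exchange modelling, no coagulation biochemistry, no scan
registration, and no attempt to reproduce bench mm³ volumes, printed
p-values, or the published Reynolds numbers.
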