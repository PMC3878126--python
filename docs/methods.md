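# Methods

`lascar` re-implements the classic family of left-atrial (LA) scar and
fibrosis segmentation algorithms for late-gadolinium-enhancement (LGE)
CMR, the two reference standards they are usually compared against, the
standard evaluation metrics, and a synthetic phantom generator that
makes the whole benchmark reproducible without patient data.  This note
records the models, the numerical choices, and what the phantom does
and does not emulate.

## Image model and conventions

A case is a 3D scalar volume `I(x)` with anisotropic voxel spacing in
mm plus a binary endocardial mask (the LA blood pool and cavity).  All
distances, bands and dilations are computed on the physical grid with
the exact Euclidean distance transform — slice thickness up to 4 mm
makes voxel-count morphology wrong.  The signed distance `d(x)` is
measured to the nearest boundary-voxel centre: the surface layer of the
endocardial mask sits at `d = 0`, the strict interior is negative, the
exterior positive.  A voxel index `(i, j, k)` maps to physical
coordinates `origin + index * spacing`.

Intensity normalisation is `Î(x) = (I(x) − μ_B) / σ_B` with `μ_B, σ_B`
the mean and *population* (N-denominator) SD of the blood pool.  The
population convention matters because every n-SD threshold inherits it.

## The segmentation algorithms

All ten methods share one contract:
`segment_*(volume, endo-or-manual-wall, params…) → scar mask`, with the
output confined to the method's declared wall search region.

- **IC (hysteresis sigmoid map).**  `p(x) = p_i(Î(x)) · p_d(d(x))` with
  logistic sigmoids `p_i = σ((Î − c_i)/h_i)` and `p_d = σ((d − c_d)/h_d)`.
  Defaults `c_i = 2` SD units, `h_i = 0.5`, `c_d = 3` mm, `h_d = −1` mm:
  the intensity centre sits at the diffuse-enhancement level and the
  distance sigmoid decays past the wall.  These four constants are not
  published (the original used empirically fitted models), so they are
  configuration, not science.  Hysteresis keeps voxels with `p ≥ 0.5`
  plus any `p ≥ 0.25` voxels 26-connected to them (3D connectivity; the
  2D/3D choice was unstated and is exposed).
- **MV (mixture-seeded region growing).**  A 3-component Gaussian
  mixture (components tagged blood / neighbouring / LGE by ascending
  mean) is fitted by EM to the LA-region intensities.  Seeds are band
  voxels above `I_s = 0.15 μ_B + 0.85 μ_LGE`; growth admits 26-connected
  voxels above `I_R = min(μ_LGE, I_t)` where `I_t` is the crossing of
  the weighted blood and LGE densities (bisection to 1e-6; if the two
  densities do not cross between the means the code warns and uses
  `μ_LGE`).  The search band allows 1 mm inside and 5 mm outside the
  endocardial surface.  Note the tag names order components by mean
  only; on LGE images the lowest-mean component is typically
  non-enhanced wall/background rather than blood — the thresholds use
  the lowest and highest components and are insensitive to the naming.
- **SY (fuzzy c-means + graph cut).**  Fuzzy c-means (C = 2, m = 2; the
  original leaves C unstated) on the wall intensities gives memberships
  `u`; unary costs are `1 − u`.  The boundary term is
  `B_xy = exp(−β|I_x − I_y|²)/d(x,y)` with β = 5.  Because β was tuned
  for values of order one, the boundary term uses min–max rescaled wall
  intensities; the unaries see raw intensities (raw-vs-normalised was
  unstated; both are flags).  The wall is the 4 mm dilation of the
  endocardium minus the blood pool; the energy is solved exactly by
  min-cut and clusters smaller than 3 voxels are removed (no cutoff was
  published; configurable).
- **HB (active-surface wall + 2-Gaussian EM).**  The epicardium is the
  surface minimising `∫_S (1−λ) f + λ (d − w)² dS` with
  `f = 1/(1 + |G_σ ∗ ∇I|)` (σ = 1 mm) and `w = 3` mm the expected wall
  scale.  Rather than evolving a contour by descent, the discrete
  minimiser is computed exactly as a weighted minimal surface: a
  min-cut through the narrow band `0 < d ≤ 2w` whose face weights are
  the local energy density times the face area, with the endocardium as
  source and the far field as sink.  Same energy, global optimum,
  deterministic — at the price of not reproducing any particular
  descent trajectory.  The wall (surface minus endocardium) is then
  split by a 2-component EM and the higher-mean component is scar.
- **YL (manual wall + global threshold).**  Wall voxels above a single
  volume-wide threshold.  The threshold is an input; the benchmark
  harness derives it as the minimum intensity of the observer-selected
  enhanced region ("include an entire region of prominent scar").
- **KCL (ratio-prior graph cut).**  The scar unary is the Gaussian
  density of `I(x)/μ_B` under a scar-to-blood-ratio prior (converted to
  intensity units so both unaries share a scale); the healthy unary is
  a BIC-selected mixture (K = 1…5) fitted to the ±3 mm band, which is
  also the search space.  Densities become costs via `−log max(p, 1e−12)`.
  The original's leave-one-out training is out of scope: the prior is a
  required parameter, and the phantom harness derives it from the
  generator statistics, playing the role of training on cases with
  known scar.
- **UTA (bimodal n-SD threshold).**  A 2-component EM on the manual-wall
  histogram estimates the non-enhanced (lower) mode; the threshold is
  its mean + n SD (n = 2…4, default 3).  EM replaces raw histogram-peak
  detection for robustness (a smoothing alternative would be easy to
  add).  The original operator adjusted the threshold per slice; that
  loop is replaced by an optional per-slice offset table.
- **UTB (k-means).**  k-means with k = 4 on blood-pool-normalised wall
  intensities; the cluster with the highest centre is scar.  The
  normalisation is affine and does not change the partition.
- **n-SD fixed model.**  Threshold at healthy-region mean + n·SD
  (n ∈ {2, 3, 4, 6}, default 4) inside the 3 mm dilated wall.
- **FWHM fixed model.**  Threshold at 50% (re-adjustable to 60/70%) of
  the maximum intensity of an observer-selected enhanced region; output
  voxels must be 26-connected to that region through above-threshold
  tissue (region growing).

The "dilated wall" of the fixed models and SY excludes the blood-pool
interior by default (scar lives in the wall); whether the original
included the interior is unstated, so the alternative is a flag.

## Graph-cut engine

The shared energy is
`E(L) = λ Σ_x R_x(L_x) + (1−λ) Σ_{(x,y)∈N, L_x≠L_y} B_xy` with
non-negative unaries and Potts-form boundary weights — the boundary
term applies only across label discontinuities, which is what the
min-cut construction requires and the standard reading of the cited
framework.  λ defaults to 0.5 (unpublished) and is per-method
configuration; connectivity defaults to 6 (the 3D analogue of the
4-neighbour convention; 26 is available — the mm denominator in `B_xy`
already discounts diagonals).

The solver maps the energy to an s–t network (source-side = scar,
`cap(s→x) = λR_x(healthy)`, `cap(x→t) = λR_x(scar)`, symmetric
neighbour arcs `(1−λ)B_xy`) and runs a C max-flow implementation with
32-bit integer capacities.  Float weights are scaled so that both every
capacity and the flow bound fit; the labelling is the residual-graph
BFS from the source, which also breaks ties toward the healthy label
(the minimal source side).  Optimality is verified exhaustively on
random ≤ 12-node problems.  Solutions are invariant under uniform
scaling of all weights and under per-node constant shifts of both
unaries.

## Reference standards

**STAPLE.**  Each rater j is a Bernoulli channel with sensitivity `p_j`
and specificity `q_j`; EM alternates the voxelwise posterior `W` of the
hidden true label with closed-form performance updates.  Initialisation
`p_j = q_j = 0.9`, scalar prior = mean rater foreground fraction (both
configurable), tolerance 1e-6 on the parameter change, and computation
restricted to the union of the raters dilated 10 mm so the background
class stays informative on large grids.  The consensus mask thresholds
`W` at 0.7.  The implementation is cross-checked against an independent
library STAPLE filter in the test suite.

**Fixed models** (n-SD, FWHM) double as reference standards; their
thresholds are exact arithmetic on the supplied regions, so exactness
and the n-SD nesting property (6-SD ⊆ 4-SD ⊆ 2-SD) are asserted
directly.

## Evaluation metrics

- **Dice** on the 0–100 scale, `100 · 2|X∩Y|/(|X|+|Y|)`; defined as 100
  (with a warning) when both masks are empty.  Regional Dice restricts
  both masks to supplied region masks; empty regions are flagged, not
  scored.
- **Surface RMSE.**  The LA surface is a marching-cubes iso-surface at
  level 0.5 of the binary endocardial field.  Both the reference and
  the test scar labels are projected onto this one anatomy mesh
  (whether the original used one or two meshes is unstated), a vertex
  being labelled scar when a scar-voxel centre lies within 3 mm (the
  wall scale; an inward-normal ray-casting projection is available
  behind a flag).  The metric is the RMS of directed nearest-neighbour
  distances from reference scar vertices to the test scar vertex set.
  The index pairing in the usual formula is ill-posed when the two
  vertex sets differ in size; the directed form is consistent with the
  metric's known failure mode — extra false-positive vertices can only
  shrink it — which is why the harness always reports it next to the
  volume error.  An empty test scar set yields a flagged infinite
  result rather than a silently substituted distance.
  Meshing note: the raw binary iso-surface carries the resolution-independent
  staircase area bias (~8% on a sphere).  `extract_isosurface` keeps
  the binary field as its default and offers indicator anti-aliasing
  (Gaussian σ ≈ 0.8 voxels) that recovers analytic areas to well under
  5%, at the cost of erasing structures smaller than the kernel.
- **Volume error** `|V_T − V_G|` in ml, voxel count × voxel volume.
- **Artefact inclusion**: percentage of observer-labelled artefact
  voxels (navigator beam, aortic wall) included in a segmentation.
- **Quality-stratified report**: mean (SD) Dice per good/average/poor
  tag.

## The phantom

The generator emulates the anatomy and first-order intensity
statistics of an LGE LA scan:

- **Geometry.**  96×96×48 grid at 1.25×1.25×2.5 mm (a typical
  acquisition resolution at desk scale).  Blood pool: ellipsoid with
  semi-axes 34/28/22 mm plus two pulmonary-vein tubes (radius 5.5 mm)
  along ±x; wall: the 2.5 mm dilation shell (the anatomical LA wall
  thickness); everything is seeded and bitwise reproducible.
- **Intensities** (arbitrary units): blood 100 ± 15, healthy wall
  70 ± 17, background 40 ± 10, each voxel drawn independently.  The
  wall is deliberately heterogeneous relative to its contrast with
  enhancement: this is what makes a fixed 4-SD threshold overshoot
  diffuse fibrosis while adaptive methods succeed — the central
  pre/post phenomenon the benchmark exists to show.  A quieter wall
  would make the 4-SD model a perfect pre-ablation segmenter, which is
  not what LGE data look like.
- **Scar.**  Patch anchors sit on an equatorial ring of the ellipsoid
  (8 anchors, ball radii 12–15 mm) so neighbouring patches merge into
  one connected lesion belt — the textbook contiguous encircling
  pattern of ablation injury, and the regime in which a
  region-growing FWHM reference is meaningful.  Scar intensities are
  `N(μ_B + L·σ_B, (0.5 σ_B)²)`: the *pre* preset pins the enhancement
  level `L = 2.1` SD above blood pool and the *post* preset `L = 4.7`,
  the reported per-centre enhancement means.  The reported ±0.9/±1.3
  spreads are across-patient variation of pooled images, not
  within-lesion texture, so the within-lesion spread is a separate knob
  (default 0.5 SD units).
- **Confounders.**  A navigator-beam band (3 mm slab crossing the
  right-PV wall, enhancement 4 SD) that automatic wall regions do
  include, and an enhancing aortic-wall tube with a 4.5 mm background
  gap from the endocardium — inside the widest automatic search band
  but unreachable by any method's connectivity, and absent from the
  manual wall by construction.  Both carry truth masks for the
  artefact-inclusion metric.
- **Auxiliary "manual" masks** are emitted from truth so pipelines run
  unattended: the wall delineation (the true wall — aorta-free, but
  crossed by the navigator band exactly as a real observer's wall
  would be), a healthy-wall region (wall at least 2.5 mm away from scar
  and the navigator), and an enhanced region (the largest patch).
- **Raters** for consensus testing flip truth voxels independently
  (keep foreground with probability = sensitivity, background with
  probability = specificity).
- **Noise.**  The per-tissue draws are the noise model; optional extra
  additive Gaussian or Rician noise is available (LGE magnitude
  statistics at these SNRs are near-Gaussian, so Gaussian is the
  default).

What the phantom does **not** emulate: k-space/acquisition physics,
surface-coil intensity gradients, motion blurring, partial-volume mixing
at tissue interfaces, inversion-time variation, and patient-specific
anatomy.  Passing the phantom floors therefore shows that an
implementation is faithful and well-behaved under controlled contrast —
not that it would reach the same Dice on clinical scans.

## Benchmark harness

A YAML config lists cases (phantom presets/specs or NIfTI paths) and
methods with parameter blocks.  Per-(case, method) seeds are derived
from the single global seed by a stable CRC hash, so runs are
reproducible and case order is irrelevant.  One failing (case, method)
pair is logged and skipped.  Outputs: one JSON report per (case,
method), an aggregate CSV of per-method medians/quartiles, and a run
log with the config and failures.  Exit codes: 0 success, 1 config
error, 2 partial failures.

## Test-suite problem sizes

The acceptance suite runs both full-size presets through all ten
methods once (module-scoped fixture), verifies min-cut optimality on
100 random ≤ 12-node problems against exhaustive enumeration, metric
agreement on random ≤ 32³ masks, STAPLE recovery on a 64³ truth with 5
raters, and full-benchmark determinism on two reduced-grid (64×64×32)
phantom cases × 4 methods run twice.  These sizes were chosen as the
smallest at which each property is non-trivially exercised.

## Known limitations

- The sigmoid (IC), λ, and small-cluster parameters are defaults for
  unpublished constants; results on real data will depend on them.
- UTA's per-slice adjustment and YL's threshold picking are operator
  steps; the offset table and threshold inputs reproduce their effect,
  not the operator.
- The HB realisation minimises the published energy exactly but is not
  a re-implementation of the original spline-surface code.
- The directed surface RMSE inherits the metric's insensitivity to
  false positives; read it together with the volume error.
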