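# lascar

Left-atrial (LA) scar and fibrosis segmentation from late
gadolinium-enhancement (LGE) cardiac MR, as a benchmarking toolkit: the
classic family of segmentation algorithms, the consensus and fixed-model
reference standards they are compared against, the standard evaluation
metrics, and a synthetic LA phantom so the entire pipeline runs and is
testable without patient data.

**Who it is for.**  People developing or evaluating atrial scar
quantification: LGE enhancement is the imaging signature of fibrosis
(before ablation) and scar (after radio-frequency ablation) in the thin
(~2.5 mm) LA wall, and no single segmentation approach is established —
so new methods need a common yardstick.

## What is implemented

Ten segmentation methods behind one interface
(`segment(volume, endo_or_wall, params…) → scar mask`):

| method | idea | wall region |
|--------|------|-------------|
| `ic`   | hysteresis thresholding of a sigmoid intensity × distance probability map | distance sigmoid (~4 mm) |
| `mv`   | region growing, seeds/thresholds from a 3-Gaussian mixture | band −1…+5 mm |
| `sy`   | fuzzy c-means unaries + graph cut | 4 mm dilated wall |
| `hb`   | minimal-surface epicardium estimate, then 2-Gaussian EM | ≤ 6 mm band |
| `yl`   | single global threshold | manual wall |
| `kcl`  | graph cut with a scar/blood-ratio Gaussian prior | ±3 mm band |
| `uta`  | bimodal-histogram lower-mode mean + n·SD threshold | manual wall |
| `utb`  | k-means (k = 4), top-mean cluster = scar | manual wall |
| `nsd`  | healthy-region mean + n·SD (n ∈ {2,3,4,6}) | 3 mm dilated wall |
| `fwhm` | 50% of an enhanced region's maximum, with region growing | 3 mm dilated wall |

Around them: a STAPLE consensus builder (per-rater sensitivity and
specificity via EM, posterior thresholded at 0.7), evaluation metrics
(Dice on the 0–100 scale, regional Dice, marching-cubes surface RMSE,
volume error in ml, artefact-inclusion percentage, quality-stratified
tables), an exact min-cut engine, a seeded phantom generator with
"pre" (fibrosis ≈ 2.1 SD above blood pool) and "post" (scar ≈ 4.7 SD)
presets including navigator-beam and aortic-wall confounders, and a
benchmark harness (`lascar benchmark`) that runs cases × methods and
aggregates medians.

The core statistical machinery — blood-pool normalisation
`Î = (I − μ_B)/σ_B`, 1-D Gaussian-mixture EM with BIC selection, fuzzy
c-means, the two-label MRF energy
`E(L) = λ Σ R_x(L_x) + (1−λ) Σ_{cut} exp(−β|I_x−I_y|²)/d(x,y)`
solved exactly by min-cut — lives in `intensity_models` and `graphcut`
and is shared by the methods.  See `docs/methods.md` for the models,
conventions and design choices.

## Worked example

Generate a post-ablation phantom and run a few methods against the
generator truth:

```python
from lascar import ScarPrior, dice, volume_difference_ml, artefact_inclusion_pct
from lascar.bench import yl_threshold
from lascar.phantom import generate_phantom, preset, scar_prior_for
from lascar.segmenters import run_method

spec = preset("post", seed=42)
case = generate_phantom(spec)
inputs = {"endo": case.endo, "wall": case.wall_manual,
          "healthy": case.healthy_region, "enhanced": case.enhanced_region,
          "prior": ScarPrior(*scar_prior_for(spec)),
          "threshold": yl_threshold(case.volume, case.enhanced_region)}
print(f"truth: {case.scar_gt.count} scar voxels ({case.scar_gt.volume_ml:.2f} ml)")
for method in ("mv", "sy", "kcl", "nsd", "fwhm"):
    seg = run_method(method, case.volume, inputs, seed=7)
    print(f"{method:4s} dice={dice(case.scar_gt, seg):5.1f} "
          f"dV={volume_difference_ml(seg, case.scar_gt):5.2f} ml "
          f"navigator={artefact_inclusion_pct(seg, case.artefacts['navigator']):4.1f}%")
```

prints

```
truth: 2645 scar voxels (10.33 ml)
mv   dice= 92.6 dV= 1.66 ml navigator= 9.3%
sy   dice= 97.7 dV= 0.48 ml navigator= 5.6%
kcl  dice= 98.6 dV= 0.30 ml navigator= 3.4%
nsd  dice= 98.3 dV= 0.35 ml navigator= 4.1%
fwhm dice= 97.6 dV= 0.50 ml navigator= 4.1%
```

Dice is overlap with the known scar truth (out of 100), `dV` the
absolute volume error, and the last column how much of the simulated
navigator-beam artefact each method wrongly includes — the phantom's
false-enhancement trap.  On the low-contrast "pre" preset the fixed
models (`nsd`, `fwhm`) drop far below the adaptive methods, which is
the behaviour that motivates adaptive segmentation in the first place.

The same workflow is available from the shell:

```sh
lascar phantom --preset post --seed 42 --out case/
lascar segment --method nsd --image case/image.nii.gz \
       --endo case/endo.nii.gz --healthy case/healthy_region.nii.gz \
       --out scar.nii.gz
lascar evaluate --seg scar.nii.gz --gt case/scar_gt.nii.gz \
       --endo case/endo.nii.gz
lascar consensus --raters r1.nii.gz --raters r2.nii.gz --raters r3.nii.gz \
       --threshold 0.7 --out gt.nii.gz
lascar benchmark --config bench.yaml --out results/
```

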