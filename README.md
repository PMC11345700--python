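# awsom

Adaptive-weights smoothing and local inference for single-subject fMRI,
with a ground-truth phantom benchmark and a null-hypothesis false-positive
battery.

High-resolution fMRI buys spatial detail at the price of temporal
signal-to-noise (tSNR), and the standard remedy — Gaussian smoothing plus
Gaussian-random-field (GRF) cluster correction — blurs exactly the detail
the acquisition was meant to resolve while inflating familywise error in
individual subjects. This package implements the alternative:
**propagation–separation adaptive-weights smoothing (AWS)** of the
statistical maps themselves, and its small-cluster-optimized variant
**AWSOM**, alongside everything needed to evaluate them against ground
truth: a synthetic BOLD phantom with known regions of activation (ROAs), a
voxelwise GLM, Gaussian smoothing and GRF cluster inference as the
comparator chain, the spatial-accuracy / sensitivity / signal-integrity
metrics, and a resting-state-style null battery.

It is written for methods researchers and analysts who want a transparent,
scriptable implementation of structural adaptive smoothing with a
benchmark harness around it.

## The model in brief

A first-level GLM `Y_v = X β_v + ε_v` per voxel yields the contrast
estimate (COPE) `θ̂_v = cᵀβ̂_v` and its variance `s²_v` (varcope). AWS
smooths θ̂ with iteratively growing bandwidths `h_k = h₀ g^k`; at each step
the weight between voxels i and j is

    w_ij = K_loc(‖x_i−x_j‖²/h_k²) · K_stat(s_ij/λ),
    s_ij = n_eff,i (θ̃_i − θ̃_j)² / (S κ s²_i),

a non-adaptive location kernel times a statistical penalty that compares
the current estimates θ̃ at the precision already achieved
(`n_eff = s²/σ̃²`). Neighbours whose values differ more than noise allows
are excluded, so variance falls inside homogeneous regions (propagation)
while genuine boundaries are never averaged across (separation). λ steers
the adaptation: λ→∞ recovers plain kernel smoothing, λ→0 leaves the data
untouched; λ = 1 is the calibrated default (AWS) and λ = 0.8 the
small-cluster preset (AWSOM). Inference is local: `z̃ = θ̃/σ̃` against the
larger of 3.1 and the expected-Euler-characteristic FWE threshold of the
residual field; AWSOM additionally reports the smoothed COPE masked to the
significant voxels, preserving effect-size topography.

Detection quality against a phantom with ground-truth ROAs is scored by
spatial accuracy (Sørensen–Dice × 100), BOLD sensitivity (recall × 100)
and signal integrity (correlation × 100 between true magnitudes and the
masked COPE). See `docs/methods.md` for the full account.

## Worked example

Simulate a phantom at 2 % noise (tSNR 20) with a homogeneous 6 % BOLD
magnitude, fit the GLM, run AWSOM, and score it:

```python
import awsom

phantom = awsom.make_phantom(
    bold_pct=6.0, noise=awsom.NoiseSpec(kind="gaussian", level_pct=2.0, seed=1),
)
res = awsom.GLMModel(
    phantom.data, awsom.build_design_matrix(phantom.regressor),
    phantom.brain_mask,
).fit()
print(res.summary())

state = awsom.AdaptiveWeightsModel.from_glm(res, awsom.AWSParams.awsom()).fit()
print(state.summary())

smooth = awsom.estimate_smoothness(res.residuals, phantom.brain_mask)
sig = state.significance(smooth)
counts = awsom.confusion(sig.mask, phantom.truth_union, phantom.brain_mask)
print(f"SA {awsom.spatial_accuracy(counts):.1f}  "
      f"BS {awsom.bold_sensitivity(counts):.1f}  "
      f"threshold {sig.threshold:.2f}")
```

prints

```
General linear model (voxelwise OLS)
  voxels fitted     : 39456
  volumes / dof     : 600 / 596
  prewhitening      : none
  cope  mean (mask) : 2.3087
  |z|   max  (mask) : 7.421
Adaptive-weights smoothing (propagation-separation)
  lambda / kappa    : 0.8 / 1.000
  bandwidth schedule: h0=1, growth=1.0772, hmax=5 (22 iterations)
  mean n_eff (mask) : 299.55
  max |z~|   (mask) : 79.69
SA 99.1  BS 98.9  threshold 5.34
```

Reading it: the unsmoothed GLM peaks at z ≈ 7.4, not far above the 3.1
cluster-forming threshold at tSNR 20; adaptive smoothing raises the
effective sample size ~300-fold in homogeneous territory while keeping the
activation boundaries sharp, so at the stricter local threshold (5.34) the
detected voxels recover 98.9 % of the 1450 ground-truth voxels with almost
no false positives (Dice 99.1).

The same pipelines are scriptable from the shell (`awsom --help`):

```sh
awsom phantom --grid 48 --noise-level 2 --bold 6 --seed 1 --out run/
awsom glm --series run/phantom.nii.gz --events run/events.tsv \
          --mask run/brain_mask.nii.gz --out run/glm/
awsom aws --cope run/glm/cope1.nii.gz --varcope run/glm/varcope1.nii.gz \
          --res run/glm/res4d.nii.gz --mask run/brain_mask.nii.gz \
          --preset awsom --out run/aws/
awsom nulltest --n-series 16 --families E1 --filters awsom --seed 1 --out null/
awsom benchmark --seed 0 --out bench/
```

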