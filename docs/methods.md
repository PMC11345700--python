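# Methods

This note describes the models and procedures implemented in `awsom`, the
choices made where the design was genuinely open, and what the synthetic
benchmarks do and do not demonstrate.

## The problem

Single-subject fMRI at high spatial resolution trades voxel size against
temporal signal-to-noise (tSNR). Spatial smoothing recovers sensitivity to
the BOLD effect but conventional Gaussian smoothing blurs the very
anatomical detail high-resolution imaging is meant to resolve, and
cluster-corrected inference on smoothed maps can inflate false positives in
the individual brain. Adaptive-weights smoothing (AWS), a
propagation–separation procedure, smooths the *statistical maps* (not the
time series) with data-dependent weights that stop averaging across
boundaries the data can distinguish. AWSOM is the small-cluster-optimized
variant (λ = 0.8 instead of 1.0) that additionally reports the smoothed
effect size (COPE) at significant voxels rather than only a z map.

## Synthetic phantoms (`awsom.phantom`)

The phantom is a 4D series on an isotropic grid (default 48³ voxels of
1.5 mm, 600 volumes at TR 1.2 s):

* **Brain**: a parametric ellipsoid with semi-axes 0.44 of each grid extent
  (≈36 % of the field of view). `uniform` baseline is flat (1000 a.u.);
  `shell` adds a radial gradient (surface twice as bright as the centre) to
  emulate a receive-coil profile. A parametric brain replaces an acquired
  reference volume so the package has no data dependency.
* **Regions of activation (ROAs)**: four ground-truth masks — an inclusive
  digital sphere of radius 2 (exactly 33 voxels), two of radius 4 (257
  voxels each), and an irregular region grown deterministically from a
  radius-4 sphere by adding 6-connected boundary voxels in raster order
  until 903 voxels. Mask centres sit on the mid-axial plane at 30 %/70 % of
  each axis; this layout needs grids of roughly 46³ or larger to keep an
  8-voxel gap between masks.
* **HRF**: a three-gamma composite (response minus scaled undershoot minus
  scaled initial dip, shapes 20/35/60). A damped coordinate search shifts
  the three component modes until the *composite* attains its landmarks —
  initial dip at 1.2 s, peak at 4.8 s, undershoot minimum at 8.4 s — and a
  cosine taper over the last 15 % of the support returns it to exactly zero
  at 20 s. A two-gamma kernel cannot produce an initial dip, hence the
  third component.
* **Design**: eight impulse events at 90 s inter-stimulus interval, first
  onset at 30 s (chosen to leave a pre-stimulus baseline and to let the
  last response die out before scan end), convolved on a 0.1 s super-grid
  and sampled at the TR; max-normalized.
* **BOLD signal**: a mask voxel with magnitude m (percent) follows
  `baseline · (1 + m/100 · regressor)`. Homogeneous phantoms use one
  magnitude (0.5–6 %); heterogeneous phantoms mix 6/3/1.5 % as concentric
  tertiles per mask (innermost largest), a deterministic layout standing in
  for the mixing whose exact geometry is not published.
* **Noise**: Gaussian (i.i.d. per voxel-timepoint) or "Rician", the latter
  built as the Rayleigh magnitude `σ√(n₁²+n₂²)` of two independent Gaussian
  draws *added* to the signal without mean-centring (a positive offset of
  σ√(π/2) the GLM intercept absorbs) — deliberately not the physical Rician
  of a complex signal, so both noise kinds share one additive pathway. Two
  scalings: `target_tsnr` (default, σ(v) = baseline(v)·level/40, so levels
  1/2/4/8/16 % give tSNR 40/20/10/5/2.5 — the nominal ladder quotes 2 at
  the top level, i.e. 2.5 rounded down) and `percent_of_baseline` (global
  σ = level % of the mean in-brain baseline).

## First-level GLM (`awsom.glm`)

`GLMModel` fits voxelwise OLS of the series on the task regressor plus a
Legendre intercept/drift basis (quadratic by default), contrast fixed to
the task column. `fit(prewhiten="ar1")` applies one Cochrane–Orcutt pass
with the lag-1 autocorrelation pooled over all in-mask residuals — a
desk-scale stand-in for locally regularized prewhitening. Outputs
(`GLMResults`) are the COPE, its variance (varcope = σ̂²·cᵀ(XᵀX)⁻¹c), the
residual field, degrees of freedom and a z map obtained through the exact
t→normal quantile transform (clamped at |z| = 38).

## Gaussian smoothing (`awsom.smoothing`)

Volume-wise 3D Gaussian convolution at the three benchmark kernels 1.5,
2.5 and 3.5 mm FWHM (presets `g1x`, `g15x`, `g25x`; the conventional size
labels 1×/1.5×/2.5× the 1.5 mm voxel are kept although 2.5/1.5 ≈ 1.67).
Convolution is mask-renormalized (data×mask and mask smoothed separately,
then divided): constants are preserved exactly and intensity does not
bleed across the brain edge. The in-mask *mean* of a noise field is
conserved only to ~10⁻³ of its SD, since renormalization redistributes
mass near the boundary.

## Cluster-corrected inference (`awsom.grf`)

Smoothness is estimated from the standardized GLM residuals: per axis,
`FWHM_d = sqrt(4 ln 2 / λ_d)` with λ_d the mean squared forward difference
(clipped to [0.5, 20] voxels); resels = V/∏FWHM. Cluster correction
thresholds the z map at 3.1, labels components (26-connectivity by
default), and assigns each cluster the familywise p

    p = 1 − exp(−E[m] · P(extent ≥ k)),   P(extent ≥ k) = exp(−β k_r^{2/3}),

with `E[m] = R (4 ln 2)^{3/2} (2π)^{−2} (z²−1) e^{−z²/2}` the expected
cluster count, `β = (Γ(5/2)/n̄_r)^{2/3}`, and k_r, n̄_r cluster size and
expected cluster size in resel units. Inference is one-sided on positive z.

**Calibration caveat.** At cluster-forming z = 3.1 the expected cluster
size is ~0.1 resel and the stretched-exponential extent distribution is
heavy-tailed relative to a Gaussian field, so the corrected test is
*conservative*: on smoothed-white-noise nulls (48³, FWHM ≈ 2 voxels) the
empirical familywise rate is below 1 % at nominal 5 %. The suite asserts
validity (rate ≤ nominal), not exact attainment.

## Adaptive-weights smoothing (`awsom.aws`)

`AdaptiveWeightsModel.fit()` iterates k = 1…k* with bandwidths
h_k = h₀·g^k (defaults h₀ = 1 voxel, g = 1.25^{1/3}, h_max = 5, giving 22
iterations and a final variance reduction comparable to a 3.5 mm Gaussian).
At each step the weight between voxel i and neighbour j (‖x_i−x_j‖ < h_k)
is

    w_ij = K_loc(‖x_i−x_j‖²/h_k²) · K_stat(s_ij / λ),
    s_ij = n_eff,i · (θ̃_i − θ̃_j)² / (S · κ · varcope_i),

with K_loc Epanechnikov, K_stat triangular (both compactly supported, so
outliers are excluded outright), θ̃ the current smoothed COPE and
n_eff = varcope/σ̃² the variance-reduction factor. The new estimate
averages the *raw* COPE with these weights; its variance uses the
independence formula Σw²·varcope/W² times a correlation inflation factor
(below). There is no memory step.

Two calibration constants make λ the dimensionless steering parameter the
method advertises (λ→∞ non-adaptive smoothing at h_max, λ→0 identity,
λ = 1 default, λ = 0.8 the small-cluster preset):

* **Penalty scale S = 30** — the *propagation condition*. The raw
  discrepancy n_eff·Δθ̃²/varcope is of order 2χ²₁ between voxels of one
  homogeneous region; comparing it with λ directly lets adaptation lock
  onto smoothed-noise structure (measured null z̃ SD ≈ 3 instead of 1). S
  is the smallest value in a coarse ladder (10/16/22/30/45/70) for which
  the null z̃ SD at λ = 1 on a pure-noise reference field stays within 1 %
  of the non-adaptive limit; the choice depends only on the noise model,
  never on a dataset, and `calibrate_penalty_scale()` re-derives it.
* **Variance inflation under spatial correlation.** For spatially
  correlated COPEs (acquired or pre-smoothed data) the independence
  formula understates the variance of a kernel mean. The field correlation
  is modelled as separable squared-exponential per axis anchored at the
  measured lag-1 residual correlation (ρ(d)=∏ρ_ax^{d²}), and each
  iteration's variance is multiplied by the inflation of the non-adaptive
  location kernel, κ_h = Σᵢⱼwᵢwⱼρ(xᵢ−xⱼ)/Σᵢwᵢ². The approximation is exact
  under propagation and conservative under separation; for white phantoms
  the factor is 1. The penalty additionally carries the classical
  variance-inflation factor κ = ∏(1+ρ)/(1−ρ) (clipped to [1, 10]).

**Local inference** (`aws_inference`): z̃ = θ̃/σ̃ is thresholded at the
larger of 3.1 and the voxelwise FWE-0.05 threshold implied by the expected
Euler characteristic of the *pre-smoothing* residual field; isolated
significant voxels (no significant 26-neighbour) are removed. The
masked-COPE output sets θ̃ to zero outside the significant set.

**Small-cluster behaviour.** The λ = 0.8 preset trades a little
propagation for earlier separation. In the phantom benchmark its advantage
over λ = 1 on the 33-voxel mask appears at the intermediate condition
(2 % noise with 2 % BOLD, i.e. per-voxel CNR ≈ 1, the regime the preset
was designed for); at 4 % noise with 3 % BOLD both settings mostly miss
the smallest mask and the contrast is neutral. The property test pins the
supported condition.

## Evaluation metrics (`awsom.metrics`)

Confusion counts are taken inside the brain mask. Spatial accuracy is the
Sørensen–Dice coefficient ×100; BOLD sensitivity is recall ×100. Signal
integrity is the Pearson correlation ×100 between the ground-truth
magnitude map and `cope × significance`, computed over *all* brain voxels
(zeros included): a within-ROA-only convention would make the perfect
homogeneous case 0/0 rather than 100. Per-mask reports attribute each
false positive to the nearest mask centroid (ties to the lower label) so
whole-brain counts are exactly the per-mask sums. Note Dice and recall are
not ordered in general: Dice ≤ recall iff FP ≥ FN.

## Null-hypothesis battery (`awsom.nulltest`)

Paradigm families follow the shifted-variant scheme: B1 (10 s on/off,
shifts 0/5/10/15 s → 4), B2 (30 s on/off, shifts 0…60 s → 13), E1 (2 s
on / 6 s off, shifts 0/4 s → 2), E2 (16 seeded pseudorandom schedules,
on ~ U[1,4] s, off ~ U[3,6] s snapped to 0.1 s). With 16 series this gives
64/208/32/256 = 560 analyses per chain.

Because the acquired resting-state scans behind the original battery are
not redistributable, a synthetic generator stands in: AR(1) innovations
(ρ = 0.3) smoothed to 2 voxels FWHM on the ellipsoid brain, plus two
cosine drifts (periods 240/120 s, amplitudes 1.0/0.6 noise-SD with smooth
random spatial profiles) at tSNR 20, 300 volumes at TR 2 s. The default
analysis prewhitens with AR(1).

What this stand-in shows and does not show: with AR(1) prewhitening the
Gaussian-noise null is essentially fully modelled, so all chains control
FWER near zero — absolute FWER levels of real single-subject data (where
unmodelled physiological low-frequency noise inflates block designs) are
*not* reproduced. The characteristic ordering FWER(B2) ≥ FWER(B1) ≥
FWER(E1) re-emerges when the generator adds a near-unit-root noise
component (`slow_noise_amplitude`) and the analysis is run without
prewhitening — the cluster-failure mechanism in its cleanest form
(measured t-SD inflation 1.41/1.03/0.74 for B2/B1/E1). The bound that *is*
asserted as a headline: the adaptive chains keep FWER ≤ 5 % on the
event-related battery under the default, honestly whitened conditions.

## Problem sizes and determinism

The shipped benchmarks use 48³ grids (600 volumes for phantoms, 300 for
null series), 10 seeds per phantom condition and 16 null series — sizes at
which every headline quantity is reproducible on a single CPU. All
randomness flows from one master seed through `SeedSequence`-based per-cell
spawning (`cell_seed`), so any cell can be re-run independently and full
runs are byte-identical.

## Known limitations

* No physiological noise model (cardiac/respiratory aliasing), motion, or
  EPI distortion in the phantom; noise is spatially white by construction.
* The AR(1) Cochrane–Orcutt prewhitening is global, not locally
  regularized.
* GRF cluster p-values are conservative at the z = 3.1 cluster-forming
  threshold (see above).
* The adaptive filter's variance correction under spatial correlation uses
  the non-adaptive kernel approximation; strongly separated regions in
  highly correlated data get conservative z̃.
* Anisotropic voxels are handled by measuring distances in voxel units;
  the benchmark geometry is isotropic.
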