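# Methods

## Overview

`disface` reimplements, at desk scale, an encoding-model analysis in which
the latent dimensions of a disentangled variational autoencoder serve as
GLM regressors for face-selective voxel responses, followed by per-dimension
preference mapping, pseudo-inverse identity decoding over dimension
subsets, and permutation inference. Real stimulus sets and scanner data are
replaced by a synthetic generator whose ground truth (generative factors,
encoding weights, noise) is known exactly, so every stage has a recovery
test with a known answer.

## Synthetic stimuli

Images are procedural faces governed by eight independent factors, sampled
i.i.d. uniformly within their ranges: rotation, lighting, background and
smile (identity-irrelevant) and face width, skin tone, hair size and a
gender proxy (identity-relevant). A test image's identity is its vector of
identity-relevant factor values. Each factor maps to a distinct image
property: background fills the region outside the face ellipse, lighting is
a horizontal multiplicative gradient, rotation shifts the internal
features, the smile factor bows the mouth's upper lip (the dark mouth area
is an analytic, monotone function of the factor, used as a rendering
oracle), and so on. Rendering is deterministic and bitwise-reproducible.

The default study layout mirrors the condition-rich design the analysis is
built for: several hundred to a few thousand single-presentation training
faces (configurable up to ~8000) and exactly 20 test faces repeated 40–60
times. The repeat count is drawn once per dataset from that interval.

What the generator does **not** emulate: photorealism, correlated natural
face statistics (factors are independent by construction), cortical
geometry, physiological noise, or temporal autocorrelation. Passing
recovery tests therefore demonstrates correctness of the estimators under
the model's own assumptions, not robustness to real-data violations of
them.

## Simulated responses

Each presentation of a stimulus with latent vector x evokes
y = xᵀW\* + b\* + ε with i.i.d. Gaussian noise per voxel; averaged test
responses average the repeats. Defaults: signal scale 1, noise SD 0.1 (a
10:1 amplitude SNR for recovery tests; higher-noise settings are used where
an analysis needs a non-trivial noise regime), and half of the voxels
driven by a single latent dimension (for preference-map recovery), the
rest dense.

The time-series form places one face every 3 s (1 s on screen, 2 s ISI),
convolves latent-weighted impulses with a canonical double-gamma HRF
(response peak 6 s, undershoot peak 16 s, ratio 1/6, 32-s support), and
adds per-run linear drift, motion contributions from smooth random-walk
traces (3 axes), and white noise. TR defaults to 2 s. The HRF, TR, and
noise structure are declared package defaults, not claims about any
particular dataset.

Split-half reliability of the averaged test responses follows the averaged-
repeats closed form: with per-trial signal/noise SDs s and n, halves of R/2
averaged repeats correlate at s²/(s² + 2n²/R), which the simulator's output
matches by Monte-Carlo.

## Encoding GLM

Two design modes share one fitting path (per-voxel OLS, minimum-norm with a
warning when rank-deficient; no penalty by default):

* **amplitude**: one row per presentation (or repeat-averaged stimulus);
  latent columns carry the stimulus's latent values (parametric
  modulation).
* **hrf**: one row per time point; each latent column is the HRF-convolved
  impulse train with event amplitudes equal to the latent values; per-run
  linear drift (a centered ramp) and per-run motion traces are nuisance
  columns.

The 20 test faces get one indicator regressor each, so their single-trial
structure does not bias the latent weights; latent columns carry
training-face events only, since a test event's latent contribution is
exactly representable by its indicator and including both would add
nothing. The face-bias regressor is a constant column in both modes: with
faces every 3 s the convolved all-events train is indistinguishable from a
constant baseline, and the constant reading makes amplitude-mode and
hrf-mode fits of matched data agree exactly. Predictions for test images
are X_test·W + b, nuisance excluded; evaluation is per-voxel Spearman
correlation across the 20 test images (constant columns are flagged and
recorded as r = 0).

## VAE implementation

No deep-learning framework is used: the encoder and decoder are
fully-connected multilayer perceptrons (two hidden layers, 256/128 units)
over flattened grayscale images, with a Bernoulli reconstruction likelihood
on [0,1] pixels and hand-written backpropagation trained by Adam. A
fully-connected architecture keeps CPU training of the small procedural
images fast and exactly reproducible; the objectives are independent of the
architecture choice. The posterior heads are zero-initialized so an
untrained model emits the prior.

Objectives: β-VAE = recon + β·KL; FactorVAE = recon + KL + γ·TC, with TC
estimated by a 2-hidden-layer discriminator trained to separate latent
samples from dimension-permuted batches (density-ratio trick); γ = 0
reduces exactly to the β = 1 β-VAE. The published hyperparameter grid
(latent dims 24/32/48/64; β ∈ {1,2,4,6,8,16}; γ ∈ {0,10,…,100}; 10 seeds,
with the γ = 0 cell aliased to the β = 1 cell) is enumerable in full; the
pipeline presets train 2–4 small configurations.

Model selection uses a supervised disentanglement gap score, available
because synthetic factors are known: importance = |Spearman r| between each
latent and each factor; per factor, the gap is (top − runner-up)/top over
latents; the score is the mean gap. It is 1 exactly when each factor aligns
with a unique latent with zero cross-talk and 0 under full mixing, and is
invariant to latent permutation and sign. Ties in selection break toward
smaller latent dimensionality, then smaller seed. An unsupervised metric
requiring many trained model pairs would add nothing on synthetic data
where factors are observable.

Latent traversals sweep one dimension over [−2, +2] (configurable) with all
other dimensions at the image's posterior mean, exported as GIF.

## ROI selection

Selectivity (a simulated localizer statistic; −log10 p when real p-values
are supplied, so small p ranks high) and split-half reliability are
z-scored within parcel (population SD) and summed, v = v_s + v_r. Parcel
selection takes the top ⌈fraction·n⌉ voxels (default 10%), ties broken by
voxel index; whole-brain selection thresholds at mean + 1.5 SD. Selection
is invariant to affine rescaling of either raw score.

## Decoding

x̂ = pinv(W)(y − b) with the Moore–Penrose pseudo-inverse (W is
dims × voxels, generally non-square; a warning is issued when voxels <
dims). Pairwise scoring uses Pearson correlation by default (Spearman
optional); ties count ½; pairs whose subset vector is constant are skipped
with a warning and removed from the denominator. Dimension subsets are
applied after decoding with the full W; a subset-restricted pinv mode is
not the default. When latents come from a trained model, subsets are
derived from the latent-factor importance matrix: a latent dominated by one
factor (gap ≥ 0.5) inherits that factor's identity relevance, others are
labeled entangled.

A note on when the relevant/irrelevant split separates: if every factor
varies freely across the 20 test identities, irrelevant dimensions decode
identity as well as relevant ones — identity information is whatever
distinguishes the test images. The split separates when irrelevant factors
vary within identity (changing per presentation, so they average out over
repeats) or are held constant across identities (no information, chance
performance with exact ties scored ½).

## Permutation inference

Add-one p-values, p = (1 + #{null ≥ obs})/(1 + B), never zero; B = 1000 by
default. Above-chance tests permute the 20 test-image labels of the
observed data (one-tailed); model comparisons swap the two models'
predictions per test image (two-tailed), preserving voxelwise structure;
ROI comparisons shuffle the voxel-to-ROI assignment (two-tailed). Group
statistics average subjects' observed statistics and their aligned null
samples. No multiple-comparison correction is applied by default. All
tests calibrate to the nominal 5% type-I rate under their matched nulls.

## Numerical choices

* CCA similarity: columns standardized, within-set covariances ridged at
  1e-8 (rank deficiency warns and relies on the ridge), classical
  whitened-SVD canonical correlations, summarized by the mean over
  min(dims) components (first-component summary available). The ridge
  leaves self-similarity ≈ 1 − 1e-8, not exactly 1.
* PCA: column-centered, full SVD; variance explained is the top-k ratio.
* OLS via `numpy.linalg.lstsq`; residual orthogonality holds to 1e-8.
* HRF convolution on a 0.1-s grid, sampled at the TR; event onsets need not
  align with the TR grid.
* Seeding: every pipeline stage derives an independent substream from the
  global seed, so stages re-run identically in isolation.

## Problem sizes

The test suite and pipeline presets run at deliberately small scale —
hundreds of training stimuli, tens to ~100 voxels, 32-px images, 200–1000
permutation resamples, 30 training epochs — chosen so the full suite
completes in minutes on one CPU while every statistical assertion retains
comfortable Monte-Carlo margins. The `full` preset exposes the full
published grid (480 configurations) and ~8000-stimulus layout for users
with the budget to run them.

## Known limitations

* Gaussian i.i.d. noise only; no temporal autocorrelation or physiological
  noise, so time-series GLM efficiency is optimistic relative to real BOLD.
* Independent uniform factors: no natural covariance between face
  attributes.
* The MLP VAE at CI scale reaches modest disentanglement scores; the
  selection machinery is exercised, but high-quality disentanglement like
  that reported for large-scale conv-VAE training is not expected at this
  scale.
* Surface geometry, smoothing, and multi-subject anatomy are out of scope;
  "voxels" are abstract response channels.
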