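# Methods

## Overview

The pipeline compares the layer-wise internal representation of a
convolutional saliency-map network with the population representation of
visual cortical areas over a fixed stimulus set.  It has five stages:
synthetic input generation, network training and activation recording,
neural preprocessing, representational similarity analysis (RSA), and
saliency-map evaluation.  Everything runs on one CPU; no stage requires
external data.

## The saliency network

The network maps a 320×240 RGB image with intensities in [0, 1] to a
single-channel saliency map of the same size.  The full-scale architecture
(`salrsa/specs/reference.yaml`) has nine convolutional layers — the first
with 96 filters of 7×7×3 — each a stride-1 zero-padded **cross-correlation**

    F(x, y, c) = Σ_k Σ_i Σ_j m_c(i, j, k) · F′(x+i, y+j, k) + b_c ,

followed by ReLU; the first two convolutions are followed by 2×2/stride-2
max pools (spatial downsampling ×4 in total); a final 8×8/stride-4
transposed convolution restores canvas resolution with one output channel.
Implementation notes:

* The operation is implemented exactly as the formula above, i.e. without
  kernel flipping.  It is checked against an explicit triple-loop oracle.
* Pooling kernel/stride (2, 2) for both pools is the simplest scheme
  consistent with the stated total factor of four.
* The transposed convolution uses a **learned** 8×8 kernel with stride 4
  (kernel = 2×stride avoids checkerboard gaps; the kernel size is a config
  field, any kernel ≥ stride with an even kernel−stride gap is accepted).
  `deconv` output values are clipped to [0, 1] only at evaluation time;
  gradients flow through the unclipped values.
* Filters are initialised zero-mean uniform with limit √(3/fan-in)
  (variance 1/fan-in), seeded; per-filter biases start at 0 and can be
  disabled.
* An optional normalisation stage between pooling and the next convolution
  is deliberately **not** implemented; the spec file format is the
  extension point if one is ever needed.
* Every recording point is exposed separately: each convolution both
  before (`layerN`) and after (`layerN_relu`) rectification, each pool,
  and the deconvolution output.  Activations are indexed (height, width,
  channel); each element is one "model neuron".

Training minimises the Euclidean loss (half the per-sample sum of squared
differences, averaged over the batch — the classic EuclideanLoss
convention) with Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8).  Full-scale
defaults: learning rate 5·10⁻⁵, batch 20, 250 epochs, batch order
reshuffled every epoch from the run seed.  Backpropagation is verified
against central finite differences (relative error < 1e-4 asserted; in
practice ~1e-6).  Training monotonicity is not asserted per step — only
start-vs-end loss decrease on fixtures.

A "tiny" architecture (32×24 canvas, ≤16 channels, identical layer-kind
sequence) ships alongside the full-scale one so that training-dependent
properties run in seconds.  Desk-scale runs use a larger Adam step
(1e-3) than the full-scale default, because with tens of epochs, tens of
images and a network four orders of magnitude smaller the full-scale step
barely moves the loss; this is a scale choice, not a statement about the
full-scale procedure.

Stimuli of 256×256 are embedded on the 0.5-gray canvas by removing 8 pixel
rows from top and bottom and centring horizontally (32 gray columns per
side).  Stimuli of other sizes (used with the tiny canvas) are centred
with the same gray background, cropping only if oversized.

## Neural preprocessing

Rate tables are stimuli × neurons matrices of mean firing rates.  When
trial-level data (stimuli × neurons × trials) exist, neurons are screened
for visual responsiveness with the Kruskal–Wallis test across stimuli
(tie-corrected H, χ²(k−1) approximation), keeping p < α with α = 0.01 by
default; with only mean rates the screen is skipped and logged.  Screening
precedes standardisation.  Each surviving neuron is z-scored across the
stimulus set using the population (divide-by-n) variance — "variance one"
over a fixed stimulus set reads as a population statement; the convention
is switchable (`ddof`).  Zero-variance (silent) neurons cannot be
standardised and are dropped with a warning; a strict mode raises instead.
Because the RDM is correlation-based, the combination screen → z-score
leaves the downstream RDM invariant to per-neuron affine rescaling of the
raw rates, which is asserted as a property test.

## Representational similarity analysis

For each pair of stimuli the dissimilarity is the correlation distance
between the two population pattern vectors; the mean subtracted is the
across-unit mean for that stimulus, so RD ranges over [0, 2] with 0 for
identical and 2 for exactly anti-correlated patterns.  Model-layer RDMs
use **all model neurons of all channels** of the layer flattened into one
pattern; per-channel analysis restricts the pattern to one channel's
units.  Numerical choices:

* Values within 1e-12 of the anchors 0 and 2 are snapped exactly.
* A constant pattern makes the correlation undefined.  The default policy
  is to raise naming the stimulus; `drop_degenerate` removes the offending
  stimuli instead.  NaNs are never propagated silently, because they would
  corrupt percentile ranks.
* Percentile summarisation rank-transforms the n(n−1)/2 upper-triangle
  values (average ranks on ties) and scales to (0, 1], mirroring to keep
  symmetry.  Any strictly monotone scale yields identical correspondence
  on tie-free data; average ranks is the standard tie rule, and makes the
  correspondence of percentile forms exactly Spearman's correlation of the
  raw forms (asserted to 1e-10).
* Whether correspondence is computed on raw or percentile forms is a
  config switch (`rdm_form`); the pipeline defaults to percentile, and
  mixing forms in one comparison is rejected.

Correspondence is the Pearson correlation over the off-diagonal upper
triangles (2016 elements for 64 stimuli); the zero diagonal is excluded.
The partial correlation r_lx·y = (r_lx − r_xy·r_ly)/√((1−r_xy²)(1−r_ly²))
is checked against a residualise-and-correlate oracle; a zero denominator
(|r_xy| = 1 or |r_ly| = 1) yields a flagged undefined result, carried
through reports as a flagged null rather than dropped.  Profiles over
independently trained replicate models report mean and SEM (sd/√m,
ddof = 1); a single replicate reports SEM 0 with a warning.  Per-channel
histograms are normalised to the total channel count of the layer,
counting excluded (constant-pattern, e.g. ReLU-silenced) channels in the
denominator.

## Synthetic data: what it emulates and what it does not

The original recordings (64 natural-object stimuli; V1/V4/IT populations
of 691/494/294 neurons) and fixation corpora (11,580 training pairs after
left–right mirror doubling; a 120-image evaluation set) are not deposited,
so the generators emulate their statistical structure:

* **Stimuli** — texture images whose amplitude spectra share a random
  orientation/frequency band per category (8 categories × 8 images by
  default), giving category-level pixel statistics with per-image
  variation.  They are not photorealistic object photographs.
* **Populations** — rates = baseline + gain · (tuning · features) +
  Gaussian noise, rectified at zero.  V1-like tuning is driven by local
  oriented-energy features of the images, IT-like tuning by category
  identity, V4-like by a 50/50 mix, giving the three areas distinct,
  recoverable RDM geometries.  Feature vectors are centred per stimulus
  before tuning is applied so random linear tuning transmits the
  *correlation* geometry of the features (otherwise it transmits their
  cosine geometry, which differs when feature means vary across stimuli).
  Defaults: baseline 10 spikes/s, gain 4 (so each neuron's stimulus-driven
  sd is ~4 spikes/s), noise sd 1.  These are calibration knobs of the
  simulation, not estimates of the original data.
* **Planted-RDM populations** — patterns drawn from a multivariate
  Gaussian across stimuli whose correlation matrix is 1 − latent RDM, one
  draw per neuron, plus independent noise with sd 1/SNR relative to the
  unit-variance signal.  Finite noise attenuates all inter-stimulus
  correlations by snr²/(1+snr²) — an affine map, so the *correspondence*
  between empirical and latent RDM converges to 1 with population size
  while the matrix itself converges only in the noiseless limit.  A
  non-PSD implied correlation matrix is rejected with an explanation.
  `random_latent_rdm` provides continuous-valued latents (the RDM of
  random prototype patterns, PSD by construction); these are preferred for
  rank-based recovery tests because a two-valued block latent is degraded
  by tied ranks under percentile summarisation (block designs are instead
  recovered in raw form).
* **Fixations** — per-image saliency densities are mixtures of three 2D
  Gaussians (matching the sparse multi-peak structure of empirical
  fixation maps); fixation points are i.i.d. samples from the density;
  images are 1/f textures.  Real gaze data have centre bias, saccadic
  dependencies and observer effects that are not modelled.

Passing recovery tests therefore shows the *analysis chain* is correct and
sensitive at realistic population sizes — not that the synthetic data
match the original recordings.

All generators are pure functions of (parameters, seed); there is no
hidden global randomness.

## Saliency evaluation

Ground-truth maps convolve the fixation raster with an isotropic sampled
Gaussian truncated at 4σ (zero outside the canvas, so results are
bit-stable), then divide by the maximum (peak 1; sum-normalisation
available).  σ defaults to 10 px at 320×240 — on the order of 1° of visual
angle for typical viewing geometry, explicitly a knob — and is rescaled
proportionally for smaller canvases.

AUC uses the fixation-ROC convention: pixels containing ≥1 fixation are
positives, all remaining pixels negatives, all unique thresholds swept,
trapezoidal integration (equivalently the Mann–Whitney statistic with ties
counted ½, asserted against an exhaustive pixel-pair oracle).  Shuffled
AUC variants are out of scope; the variant is recorded in report metadata.
Model comparison reports are descriptive only: per-model mean/SEM,
pairwise Welch t, one-way ANOVA F.

## Study orchestration

`run_study` chains the stages with per-stage seeds derived from one run
seed, snapshots each network at configurable checkpoint epochs (default
epoch 10, the "partially trained" model) for the trained-vs-partially
trained comparison, and writes tidy TSV reports plus a manifest (config
hash, all seeds, recording points, fired degenerate-data policies,
wall time) sufficient to replay a run bit-identically.  Default replicate
count is 10 independently initialised models; desk-scale runs typically
use 2–3.

## Problem sizes used in checks

Recovery checks use 64 stimuli, 2000 neurons and SNR 10 (10 seeds);
null checks use SNR 0 over 100 seeds; oracle-equivalence checks use 100
random convolutions, 200 random trivariate Gaussian datasets and 100
random saliency maps up to 32×32; training checks use the tiny network on
10 pairs for 50 epochs; the end-to-end study in the acceptance script uses
3 replicates, 20 training images and 60 epochs.

## Known limitations

* Full-scale (GPU, 11,580-image, 250-epoch) training is out of scope; the
  full-scale spec is validated structurally and its forward/backward path
  is identical code to the tiny spec.
* Correspondence magnitudes obtained on the tiny study are small: a
  briefly trained 16-channel network on 16×16 synthetic textures has
  little representational structure to share with the synthetic
  populations.  The pipeline reports them honestly rather than tuning the
  generators to inflate them.
* Trial-level neural data are synthesised only where a test needs them;
  the rate table is the contract boundary (latency windows and spike
  sorting are upstream concerns).
* No significance machinery beyond the descriptive Welch/ANOVA report; no
  bootstrap bands; no figure rendering.
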