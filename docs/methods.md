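# Methods

This note documents the models implemented in `deepradiomics`, the
parameters that matter, what the synthetic data does and does not emulate,
and the numerical choices made where the design was open.

## Synthetic cohort

Each patient carries `n_latent` (default 3) independent standard-normal
latent factors. Factor 0 drives tumor radius, factor 1 tumor peak
intensity, factor 2 background texture amplitude. A slice is rendered as a
smooth breast-like background (intensity ≈ 0.12), a Gaussian-smoothed
texture field whose amplitude is monotone in the texture factor, and an
additive Gaussian-profile tumor blob:

* radius (pixels) = `0.18 · s/2 · exp(0.35 · tanh(z₀/1.5))` — equal to the
  baseline radius at z₀ = 0 and strictly monotone in z₀;
* peak intensity = `0.9 + 0.4 · tanh(z₁/2)`, kept well above the
  background so the above-half-maximum area is governed by the radius
  factor (measured Spearman ≈ 0.98 across patients);
* per-image jitter: a Gaussian pixel field (sd 0.02) plus a sub-pixel
  tumor-center shift, so a patient's repeated slices correlate strongly
  but are not identical — this is what makes the patient random intercept
  in the association model meaningful.

Expression: planted gene *j* (assigned to latent *k = j mod n_latent*) has
`effect_size · z_k + N(0, gene_noise_sd)` per patient; null genes are pure
noise. Pathway gene sets are sampled without replacement from the risk
genes; a pathway is flagged as planted when it contains at least one
planted gene. Clinical labels are Bernoulli draws of a logistic model with
one dominant latent weight (2.0) per label and 0.3 elsewhere, so labels are
predictable but noisy. HER2 missingness, when configured, removes the
first `her2_missing_n` patients from clinical analyses.

Defaults mirror the emulated study: 2–8 images per patient (uniform), 64×64
slices, 288 risk genes, five labels (T, N, ER, PR, HER2). The generator
does **not** emulate MRI physics, 3-D volumes, acquisition artifacts,
inter-gene correlation beyond shared latents, or realistic expression
distributions; passing tests therefore demonstrate the correctness and
calibration of the pipeline's statistics, not clinical performance on real
cohorts.

`simulate_drf_matrix` additionally produces an image-level feature matrix
directly from the latents (per-feature patient intercept sd 0.3, image
noise sd 0.3, unit latent loadings on the informative columns). It exists
so the association scan can be calibrated at an arbitrary feature count,
decoupled from the autoencoder's bottleneck width.

## Preprocessing

Images are min–max scaled per image to [0, 1]; a constant image maps to
zeros (it carries no signal). Scaling is per image rather than global
because slices come from heterogeneous acquisitions. Corruption adds
`noise_level · N(0, 1)` per pixel (default 0.05) with no clipping — the
reconstruction loss is always computed against the clean image, so clipped
corruption would only bias the noise distribution. The train/test split is
image-level by default, with a patient-grouped option because image-level
splitting leaks patients across sets.

## Denoising autoencoder

Encoder: conv 3×3 (32 filters, ReLU, same padding) → 2×2 max-pool →
conv 3×3 (16, ReLU) → 2×2 max-pool. Decoder: conv 3×3 (16, ReLU) →
upsample ×2 → conv 3×3 (32, ReLU) → upsample ×2 → conv 3×3 (1, sigmoid).
The 16-kernel bottleneck is fixed; the first-layer width (32), kernel size
(3×3) and sigmoid output were open choices — 32 halves smoothly into 16,
3×3 with same padding preserves the stated spatial shapes, and the sigmoid
matches [0, 1] targets. Hidden activations are ReLU, so extracted features
are non-negative by construction.

The implementation is plain numpy: im2col convolutions with explicit
backprop (verified against numerical gradients), max-pool argmax routing,
nearest-neighbor upsampling, and Adam. This keeps training bit-reproducible
for a given seed on any machine. Transient im2col buffers are chunked to
~64 MB so 64×64 batches stay within ordinary memory.

Defaults follow the emulated study's setup (noise 0.05, batch 64, 100 epochs,
learning rate 0.1). **The 0.1 learning rate is unstable for this
architecture** and is retained only for fidelity; the bundled pipeline and
the test suite train at 1e-3, which converges reliably. The suite's
training-quality check uses ~200 images of 32×32 at batch 32 for 30 epochs
(≈240 optimizer steps), chosen as the smallest setup at which the model
reliably beats the per-pixel-mean constant predictor.

Feature extraction feeds *clean* scaled images through the encoder
(corrupted extraction would inject noise into every downstream
association). One consequence, visible in the tests: the trained network
operates at its training noise level, so reconstruction from corrupted
input is the meaningful quality metric; clean-input reconstructions sit at
a slightly different operating point. Features are flattened kernel-major
and 1-based (`fea_1` … `fea_F`, F = 16·(s/4)²), so `fea_4043` at s = 64
lies in kernel 16.

## Feature normalization and unsupervised structure

Quantile normalization treats rows (images or patients) as samples: each
row's empirical distribution is replaced by the mean-order-statistic
reference; ties receive the mean of their tied reference values. The axis
convention (rows = samples) and the order of operations (normalize at image
level, then average to patient level) were open choices; both are
configurable in the pipeline. Patient-level features are the arithmetic
mean of the patient's image rows.

Hierarchical clustering is agglomerative with Euclidean distance and
complete linkage; t-SNE uses PCA initialization and a recorded seed
(perplexity must satisfy units > 3·perplexity). Cluster–clinical
enrichment uses Fisher's exact test on the 2×k cluster-by-label table:
exact hypergeometric for k = 2, Freeman–Halton enumeration for k > 2, with
a seeded Patefield Monte Carlo fallback when the table space exceeds ~2×10⁶
tables (the Monte Carlo p includes the +1 correction so it is never
exactly zero). Missing clinical values are excluded before tabulation.

## Genomic features

Three categories share one patients × GFs table: raw risk-gene expression,
weighted-sum signature scores, and ssGSEA pathway activities. The ssGSEA
statistic ranks a patient's genes by descending expression (ties broken by
gene id) and sums, over ranked positions, the difference between the
rank^α-weighted in-set cumulative fraction and the unweighted out-of-set
cumulative fraction (α = 0.25 by default, exposed). No cross-sample
rescaling is applied — scores are strictly single-sample and invariant to
any strictly increasing transform of the profile.

Signature scoring implements the generic weighted-sum contract; the
commercial prognostic panels it stands in for have proprietary coefficient
pipelines, so reproduction of their exact scores is out of scope. Missing
weighted genes are logged and skipped; an entirely absent panel is an
error.

Quartile binarization marks the top quarter positive: the threshold is the
k-th largest score with k = ⌈n/4⌉, ties at the threshold all positive
(n = 8 → 2 positives; n = 110 → 28). Constant score vectors admit no split
and are rejected.

## Association scan

For each (DRF, GF) pair the model `X_ij = β0 + β1·G_i + u_i + e_ij` is
fitted by REML. Because G is constant within a patient, the restricted
likelihood profiles to a one-dimensional criterion in θ = σ_u²/σ_e²
operating on per-patient means and within-patient sums of squares; the
solver evaluates the criterion on a 72-point log-spaced θ grid (including
θ = 0 and ratios up to 10⁸) with local quadratic refinement, fully
vectorized across DRF columns. Agreement with `statsmodels` MixedLM is at
the 1e-3 level on slopes and ~1 % on standard errors; with one image per
patient the fit is exactly OLS (the profile is flat and the GLS estimate
collapses to the closed form).

Inference uses the Wald statistic β1/se(β1) against Student's t. Two
small-sample corrections matter at mass-univariate scale, where BH probes
p-values near α/m ≈ 10⁻⁵:

* **Kackar–Harville** variance inflation `(∂β̂1/∂θ)²·Var(θ̂)`, with
  Var(θ̂) from the curvature of the REML deviance;
* **Satterthwaite** per-pair denominator df
  `2·Var(β̂1)²/Var(V̂ar(β̂1))` from the (θ, σ_e²) REML information,
  capped at n_patients − 2 (the predictor varies only between patients),
  with an OLS fallback (df = N − 2) when the profile is flat or the
  information matrix is not positive definite.

Without these corrections the plug-in normal (or fixed-df t) reference was
measurably anti-conservative in the far tail (≈1.4× at p ≈ 10⁻⁵),
inflating the family-wise null rejection rate of a 2,000-pair scan from
the nominal 0.05 to ≈0.085; with them the measured long-run rate is 0.045
and planted-effect recovery is unaffected.

GFs are z-scored per column before fitting (numerical stability; slope
sign and p unchanged), DRFs enter as given post-normalization. BH
adjustment is applied within each GF category by default (a global-family
switch exists), and `significant` means adjusted p < α (default 0.05).
Aggregation views report counts per kernel × category, the top DRFs by
number of significant genomic partners (ties broken by feature id), and
the top GFs per category with their five highest-contributing kernels.

The scan's calibration tests run at 50 patients × 200 features × 10 genes
over 20 seeds — small enough to complete in seconds while giving the
family size (2,000 tests) at which far-tail behavior is visible.

## Classification

The lasso-path classifier standardizes features on the training split and
computes λ_max = max_j |x_jᵀ(y − ȳ)|/N (exact for centered features), then
fits L1-penalized logistic regression at 100 log-spaced λ down to
λ_max·10⁻³ via liblinear with C = 1/(N·λ). Per-λ performance is 5-fold
cross-validated AUC on the 70 % training split; the best λ maximizes mean
CV AUC and is scored on the held-out 30 %. At λ ≥ λ_max every slope is
zero and the model scores all samples identically (AUC 0.5 under the tie
rule); within CV folds the fold-specific λ_max can be slightly larger, so
fold AUCs at the top of the grid need not be exactly 0.5. AUC is the
Mann–Whitney statistic with ties counted one half. Image-level
classification propagates patient labels to images; a patient-grouped
split option is exposed because image-level splits leak patients.

Signature/TIL classification exposes two backends behind one fit/score
contract: a small multilayer perceptron (one hidden layer of 32) and
gradient-boosted trees (100 trees, depth 3). Hyperparameters are
deliberately modest defaults; the contract, not the tuning, is the tested
surface.

## Pipeline

`run_pipeline` executes simulate → preprocess → train/extract →
normalize/cluster → GF assembly → association scan → classification from
one YAML config. Stage seeds derive deterministically from the global seed
(`(seed·1000003 + 7919·stage_index) mod 2³¹`). Every artifact is a TSV (or
PNG/NPZ for images and weights) with a SHA-256 checksum in
`manifest.json`; two runs with the same config produce identical
checksums. The bundled minimal configuration (10 patients, 32×32 slices,
5 epochs, 20-λ paths) completes in well under a minute and is the
smoke-test scale used throughout.

## Known limitations

* The synthetic tumor model is 2-D and geometric; kernels learned on it
  separate scale/intensity/texture factors but will not reproduce the
  anatomical semantics (breast edge, diaphragm) described for real MRI.
* The ssGSEA replica omits cross-cohort score rescaling; absolute score
  magnitudes are not comparable to implementations that rescale.
* Signature scoring is a generic weighted sum, not the commercial panels.
* The lasso path refits at each λ (no warm starts); at the default 100-λ
  grid with thousands of features this is the slowest pipeline stage.
* Patient-level genomic features make the per-patient random intercept
  unidentifiable when each patient has one image; the solver then reduces
  to OLS, which is the correct degenerate behavior, but users should
  prefer patient-level regression when features are patient-level.
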