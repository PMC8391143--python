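# Methods

## Model

Each voxel is modeled as a linearizing encoding model: a stimulus is mapped
through a fixed nonlinear hierarchy into per-layer feature vectors, and the
voxel response is a linear function of one layer's features plus noise,
`y = X w + ε`, with the intercept carried as the last weight. One sparse
linear model is fit per (voxel, layer) pair on the training stimuli;
prediction accuracy ρ is the Pearson correlation between measured and
predicted responses on the held-out validation stimuli, and the voxel's
optimal feature layer is the ρ-argmax over layers (ties to the lowest
layer id). Selecting the argmax on validation data mirrors how optimal
layers are reported in encoding studies; a leakage-free alternative
(`selection_mode="cv"`, 5-fold cross-validation within the training split)
is provided for analyses where the validation set must stay untouched.

## Sparse solver (ROMP)

`ROMPRegressor` implements regularized orthogonal matching pursuit. Per
round: correlate the residual with all centered, unit-norm columns; keep the
`s` largest magnitudes; among contiguous windows of the sorted magnitudes
whose largest entry is at most twice the smallest, admit the window with the
largest energy; refit the admitted support by ordinary least squares
(original feature scale, intercept via centering); stop when the support
reaches `2s` columns or the relative residual falls below `tol`. Window
admissions are truncated so the support never exceeds `2s`. After
convergence, support columns whose least-squares contribution is numerically
zero (below `1e-9·‖y‖`) are pruned and the remainder refit — a window can
sweep in a column that carries none of the signal, and reporting it would
misstate the support.

Defaults `s = 20`, `tol = 1e-4` (both configurable). The solver is exact on
noiseless sparse targets over well-conditioned designs (verified against
exhaustive best-subset enumeration and large Gaussian recovery trials). Its
known limitation is shared with all budgeted greedy pursuits: on strongly
coherent dictionaries — here, the deepest cascade layers — the `2s` budget
can be exhausted before every true coordinate is admitted, leaving isolated
voxels just below perfect recovery (≈1% of deep-layer voxels at `k_true=10`;
raising `s` resolves them at extra cost).

## Dimensionality reduction

`reduce_pca` compresses each layer with PCA fit on the training split only
(mean-centering, no variance scaling), retaining
`min(n_components, d, n_train − 1)` components, validation rows projected
with training means/loadings, and a deterministic sign convention (each
component's largest-magnitude loading positive). PCA exists in this pipeline
to make `n_features >> n_samples` designs (real network layers, 10^3–10^5
dims) tractable; the default pipeline configuration applies no reduction to
the synthetic study's 200-dimensional layers, because rotating an already
well-conditioned `d < m` design destroys the coordinate sparsity of the
generative readout that the sparse solver is meant to find — a k-sparse
readout is dense in any rotated basis, and a support capped at `2s`
coordinates can then represent only a fraction of its energy. Set
`reduction: pca` to compress genuinely wide feature sources.

## Evaluation statistics

**Randomization threshold.** For each voxel the predicted validation vector
is permuted `n_perm = 1000` times and ρ recomputed; all null values are
pooled and the accuracy cutoff is the higher nearest-rank `1 − α` quantile
(α = 0.001). Pooling is the default because a single cutoff for all voxels
is the reporting convention; per-voxel thresholds are available. The
permutation null of ρ has mean exactly 0 (each permuted entry is marginally
uniform over a zero-mean standardized vector) and variance ≈ 1/(n−1); at
n = 50 the pooled 99.9th percentile lands near 0.42. Zero-variance inputs
score ρ = 0 and can never pass.

**Model advantage.** Restricted to voxels accurately predicted by both
models, the advantage of model A is the percentage with higher accuracy
(ties split 50/50 so fractions sum to 100%). The critical advantage `x` is
the `1 − α` (α = 0.05) higher nearest-rank quantile of `n_perm` sign-flip
null draws — each voxel's winner flipped independently with probability
0.5 — which converges to the Binomial(n, ½) upper quantile. An empty
intersection flags the result undefined.

**Noise ceiling.** From the runs × stimuli × voxels validation stack:
per-voxel noise variance is the pooled squared standard error of the run
mean (across-run sample variance averaged over stimuli, divided by the run
count); signal variance is the across-stimulus variance of the run mean
minus the noise variance, clipped at zero (negative estimates occur when
noise dominates); the ceiling is the median, over `n_sim = 1000`
simulations, of the correlation between a Gaussian signal vector and
signal-plus-noise. The simulation median matches the closed form
σ_s/√(σ_s² + σ_n²) to within ±0.02 at 50 stimuli. Pooling of the squared
standard error is over stimuli, per voxel.

## RSA

RDMs use correlation distance (1 − Pearson) between stimulus
representations: all voxels of an ROI (run-averaged responses) for brain
RDMs, raw unreduced layer features for model RDMs. RDM comparison uses
Kendall's tau-a over strict upper triangles — tau-a rather than tau-b
because tied dissimilarities are negligible for continuous data and tau-a is
the convention for RDM comparison; it is implemented by vectorized pair
counting (scipy offers only tau-b/tau-c, which coincide with tau-a in the
tie-free case and serve as the cross-check). The inter-subject ceiling is
the mean tau over unordered subject pairs.

## Synthetic studies

The generator emulates the layout of a multi-subject object-vision encoding
study: 1200 training / 50 validation stimuli, 18 feature layers, 35 repeated
validation runs, five subjects, seven ROIs (V1–V4, LOC, PPA, FFA) by
default; `desk_config()` scales this to 300 training stimuli, 8 layers × 200
dims and 60 voxels per ROI so the full pipeline runs in minutes on one core.

*Features* form a random ReLU cascade: layer 1 i.i.d. Gaussian, layer
`l+1 = relu(layer_l · A_l + b_l)` with `A_l ~ N(0, 1/d_l)` entries and
biases `b_l ~ N(0, 0.25²)`; the same maps are applied to both splits, and
every column is standardized on training statistics with the divisor floored
at 0.05. These numerical choices keep the cascade stationary in depth: wide
biases breed rarely-active units whose spiky, mutually coherent columns
degrade deep-layer conditioning, and amplifying a unit that is silent on the
training split (raw sd ≈ 0) explodes validation tail samples, compounding
exponentially with depth. Cascade weights are drawn before the sample
blocks, so enlarging the validation split never perturbs the training
features.

*Voxels* draw a generating layer from their ROI's layer-preference
distribution (default: 70% mass on the ROI's modal layer, the rest on its
neighbors, with modal depth increasing from V1 to FFA), a support of
`k_true = 10` columns uniformly, and standard Gaussian weights. The clean
response is standardized to unit variance on training statistics, so
`snr` (signal sd / noise sd) has a single meaning across layers and
`corr(clean, observed) = snr/√(snr²+1)`. Each validation run adds
independent `N(0, run_noise_sd²)` noise on top of the observed validation
signal; the observation noise itself is therefore shared across runs, as in
a session-level noise component.

*Sub-seeding* derives child seeds from the master seed by a fixed
`SeedSequence.spawn` counter — features from child 0, subject `s` from child
`s+1` — so adding a subject never changes earlier subjects. Category labels
(8 images per training category, one per validation category) are generated
for schema fidelity but unused by the pipeline.

What the generator does **not** emulate: hemodynamics, spatial voxel
correlation, retinotopy, non-Gaussian or temporally structured noise, and
voxels mixing several layers. Passing tests therefore certify the pipeline's
statistical machinery and its ability to recover planted structure, not
performance on real fMRI.

A consequence of the generative design worth knowing: subject brain RDMs are
finite-voxel, noise-attenuated realizations of their ROI's layer geometry
while model RDMs are noiseless, so the inter-subject ceiling (≈0.08–0.18 at
60 voxels, snr 2) sits *below* the model-to-brain tau of layers adjacent to
the modal one (≈0.2) — unlike real data, where shared non-model structure
lifts brain-brain agreement above model-brain agreement. The run-shared
observation noise cannot be removed by run averaging, which caps the
ceiling.

## Pipeline defaults

| parameter | default | meaning |
| --- | --- | --- |
| `sparsity` (s) | 20 | ROMP round size; support ≤ 2s |
| `tol` | 1e-4 | relative residual stop |
| `reduction` / `n_components` | none / 1249 | per-layer PCA when enabled |
| `selection_mode` | "paper" | validation argmax (vs "cv") |
| `n_perm` | 1000 | permutations for both nulls |
| `alpha_accuracy` / `alpha_advantage` | 0.001 / 0.05 | test levels |
| `top_k` | 100 | voxels per subject in ROI summaries |
| `n_sim` | 1000 | noise-ceiling simulations |

The default model pair is `true_features` (the study's own cascade — the
correct feature model) against `control_features` (an independent cascade of
the same shape — a structurally matched control). The control predicts
almost no voxels above the randomization cutoff, so advantage tables on
synthetic data are near-degenerate (tiny commonly-accurate sets); comparing
two comparably good models requires feature sources that both overlap the
generative hierarchy.

All randomness is seeded: the pipeline master seed spawns fixed-role
children (control features, randomization nulls, advantage nulls, ceiling
simulations), making every report byte-reproducible. Degenerate inputs are
handled explicitly: all-zero targets return intercept-only models, constant
layers raise with the layer named, zero-variance accuracy inputs return 0
with a warning, ROIs smaller than `top_k` use all voxels with a warning,
empty advantage intersections and ROIs with no accurate voxels are flagged
rather than dropped.
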