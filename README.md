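# ventralenc

Voxel-wise visual encoding models on hierarchical features: sparse linear
readout fitting (regularized orthogonal matching pursuit), randomization-test
significance, noise ceilings, and representational similarity analysis — with
a synthetic-study generator that provides full ground truth.

## The problem

Linearizing encoding models ask how well a feature space explains visually
evoked brain activity: images are passed through a nonlinear hierarchical
feature map (in practice, a deep network), and each fMRI voxel's response is
modeled as a linear function of one layer's features,

```
y = X w + ε
```

where `y` (m x 1) holds a voxel's responses to m stimuli, `X` (m x (n+1)) a
layer's features with a constant column last, and `w` the weights. Because
n >> m, the weights are fit sparsely with regularized orthogonal matching
pursuit (ROMP): select small groups of columns whose residual correlations
are within a factor of two of each other, refit by least squares, stop when
the support reaches `2s` columns or the residual vanishes. Per voxel, one
model is fit per layer; prediction accuracy ρ is the Pearson correlation
between measured and predicted held-out responses, and the layer with the
highest ρ is the voxel's *optimal feature layer*. Mapping optimal layers
across regions of interest (V1–V4, LOC, PPA, FFA) exposes the
hierarchy-to-hierarchy correspondence between a feature model and the
ventral visual stream.

Around the per-voxel fits the package provides the study-level statistics
such analyses report:

* **Randomization test** — scrambling the measured/predicted correspondence
  (1000 permutations per voxel, pooled) yields the accuracy cutoff for
  "accurately predicted" voxels at p < 0.001 (≈ 0.42 for 50 validation
  stimuli).
* **Model advantage** — among voxels accurately predicted by two competing
  models, the percentage better predicted by each; significance via a
  0.5-probability sign-flip permutation null.
* **Noise ceiling** — Monte-Carlo simulation from variance components of
  repeated validation runs: the accuracy a perfect model could reach given
  measurement noise.
* **RSA** — 50 x 50 representational dissimilarity matrices
  (1 − Pearson correlation between stimulus representations) for brain ROIs
  and model layers, compared by Kendall's tau-a, with an inter-subject
  ceiling.

Since real fMRI recordings and pretrained networks are deliberately out of
scope, a seedable generator builds studies with the same structure — an
L-layer random ReLU cascade, voxels as k-sparse readouts of single layers
with ROI-specific layer preferences (early layers in lower visual cortex,
late layers in higher), repeated noisy validation runs — so every pipeline
stage can be scored against known ground truth. Real feature extractors can
be plugged in through the extractor registry.

## Worked example

```python
import numpy as np
from ventralenc import (
    make_layer_features, make_voxel_responses, ROISpec,
    encode_roi, randomization_threshold,
)

# a 4-layer feature hierarchy and one ROI of 20 voxels that mostly read layer 2
features = make_layer_features(n_train=300, n_val=50, layer_dims=[120] * 4, seed=0)
roi = ROISpec("V2", n_voxels=20, layer_preference=[0.15, 0.7, 0.15, 0.0])
responses, truth = make_voxel_responses(
    features, roi, k_true=8, snr=2.0, n_runs=35, run_noise_sd=1.0, seed=1
)

# fit every voxel against every layer; test significance of the accuracies
result = encode_roi(features, responses.train, responses.val, sparsity_s=12)
sig = randomization_threshold(responses.val, result.predicted_val, seed=2)

print("accuracy threshold (p < 0.001):", round(float(sig.threshold), 3))
print("accurately predicted voxels:   ", int(sig.mask.sum()), "/", roi.n_voxels)
recovered = (result.optimal_layer == truth.generating_layer)[sig.mask]
print("optimal layer == generating layer:", int(recovered.sum()), "/", int(sig.mask.sum()))
print("median accuracy:", round(float(np.median(result.best_accuracy)), 3))
```

prints

```
accuracy threshold (p < 0.001): 0.419
accurately predicted voxels:    20 / 20
optimal layer == generating layer: 20 / 20
median accuracy: 0.865
```

The permutation cutoff (0.419 at 50 validation stimuli) separates voxels
whose predictions beat chance; every voxel clears it at snr = 2, and the
validation-accuracy argmax identifies each voxel's generating layer.

## Full pipeline and CLI

`run_pipeline` (or the `ventral-encode` CLI) executes
simulate → encode → evaluate → RSA → report on a YAML config and writes
figure/table-shaped CSVs — per-ROI accuracy summaries with noise ceilings,
model-advantage tables, optimal-layer distributions, per-layer accuracy
curves, and RDM correlations with inter-subject ceilings:

```sh
ventral-encode run-all --config study.yaml --out results/
# or staged:
ventral-encode simulate --config study.yaml --out results/
ventral-encode encode   --config study.yaml --out results/
ventral-encode evaluate --config study.yaml --out results/
ventral-encode rsa      --config study.yaml --out results/
ventral-encode report   --config study.yaml --out results/
```

Every run is deterministic given the config: rerunning reproduces the CSVs
byte for byte. Studies round-trip through an HDF5 container with a JSON
config sidecar.

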