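"""Per-voxel encoding models across feature layers.

Every voxel gets one sparse linear model per feature layer; prediction
accuracy on the validation split (Pearson correlation between measured and
predicted responses) determines the voxel's optimal feature layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import KFold

from .evaluation import prediction_accuracy
from .features import LayerFeatureSet, ReducedFeatures
from .romp import SparseLinearModel, fit_romp

__all__ = [
    "EncodingResult",
    "fit_voxel_all_layers",
    "predict",
    "select_optimal_layer",
    "encode_roi",
]


@dataclass
class EncodingResult:
    """Encoding outcome for a set of voxels.

    ``accuracy`` is voxels x layers (Pearson rho per layer); ``optimal_layer``
    holds each voxel's best layer id, ``best_accuracy`` the accuracy at that
    layer, and ``predicted_val`` the validation predictions of the
    optimal-layer model (n_val x voxels).
    """

    layer_ids: list[int]
    accuracy: np.ndarray
    optimal_layer: np.ndarray
    best_accuracy: np.ndarray
    predicted_val: np.ndarray

    @property
    def n_voxels(self) -> int:
        return self.accuracy.shape[0]


def _layer_matrices(features: LayerFeatureSet | ReducedFeatures):
    return features.layer_ids, features.train, features.val


def fit_voxel_all_layers(
    features: LayerFeatureSet | ReducedFeatures,
    y_train: np.ndarray,
    sparsity_s: int = 20,
    tol: float = 1e-4,
) -> list[SparseLinearModel]:
    """Fit one ROMP model per layer for a single voxel (independent fits)."""
    layer_ids, train, _ = _layer_matrices(features)
    y_train = np.asarray(y_train, dtype=float)
    if y_train.shape[0] != train[layer_ids[0]].shape[0]:
        raise ValueError("y_train length does not match training rows")
    return [
        fit_romp(train[l], y_train, sparsity_s=sparsity_s, tol=tol, layer_id=l)
        for l in layer_ids
    ]


def predict(model: SparseLinearModel, X_val: np.ndarray) -> np.ndarray:
    """Predicted responses ``X_val @ w[:-1] + w[-1]``."""
    return model.predict(X_val)


def select_optimal_layer(
    per_layer_accuracies,
    mode: str = "paper",
    layer_ids=None,
    cv_context=None,
) -> int:
    """Pick a voxel's optimal feature layer.

    mode="paper" takes the argmax of validation accuracy; mode="cv" takes the
    argmax of 5-fold training-set cross-validated accuracy (leakage-free
    alternative), for which ``cv_context=(features, y_train, sparsity_s, tol)``
    must be supplied.  Ties break toward the lowest layer id.
    """
    if mode == "cv":
        if cv_context is None:
            raise ValueError("mode='cv' requires cv_context=(features, y_train, s, tol)")
        features, y_train, sparsity_s, tol = cv_context
        per_layer_accuracies = cross_validated_accuracies(
            features, y_train, sparsity_s=sparsity_s, tol=tol
        )
        layer_ids = features.layer_ids
    elif mode != "paper":
        raise ValueError(f"unknown layer-selection mode {mode!r}")
    acc = np.asarray(per_layer_accuracies, dtype=float)
    if acc.size == 0:
        raise ValueError("no layer accuracies supplied")
    if layer_ids is None:
        layer_ids = list(range(1, acc.size + 1))
    order = np.argsort(layer_ids)  # tie-break toward the lowest layer id
    acc_sorted = acc[order]
    return int(np.asarray(layer_ids)[order][int(np.argmax(acc_sorted))])


def cross_validated_accuracies(
    features: LayerFeatureSet | ReducedFeatures,
    y_train: np.ndarray,
    sparsity_s: int = 20,
    tol: float = 1e-4,
    n_splits: int = 5,
    seed: int = 0,
) -> np.ndarray:
    """Mean held-out accuracy per layer under K-fold CV on the training split."""
    layer_ids, train, _ = _layer_matrices(features)
    y_train = np.asarray(y_train, dtype=float)
    kf = KFold(n_splits=n_splits, shuffle=True, random_state=seed)
    out = np.zeros(len(layer_ids))
    for i, l in enumerate(layer_ids):
        X = train[l]
        accs = []
        for tr_idx, te_idx in kf.split(X):
            m = fit_romp(X[tr_idx], y_train[tr_idx], sparsity_s=sparsity_s, tol=tol)
            accs.append(prediction_accuracy(y_train[te_idx], m.predict(X[te_idx])))
        out[i] = float(np.mean(accs))
    return out


def encode_roi(
    features: LayerFeatureSet | ReducedFeatures,
    y_train: np.ndarray,
    y_val: np.ndarray,
    sparsity_s: int = 20,
    tol: float = 1e-4,
    selection_mode: str = "paper",
) -> EncodingResult:
    """Fit all voxels of an ROI against every layer and select optimal layers.

    ``y_train``/``y_val`` are stimuli x voxels response matrices.
    """
    layer_ids, _, val = _layer_matrices(features)
    y_train = np.atleast_2d(np.asarray(y_train, dtype=float))
    y_val = np.atleast_2d(np.asarray(y_val, dtype=float))
    n_vox = y_train.shape[1]
    L = len(layer_ids)
    accuracy = np.zeros((n_vox, L))
    optimal = np.zeros(n_vox, dtype=int)
    best_acc = np.zeros(n_vox)
    predicted = np.zeros((y_val.shape[0], n_vox))
    for v in range(n_vox):
        models = fit_voxel_all_layers(
            features, y_train[:, v], sparsity_s=sparsity_s, tol=tol
        )
        preds = {l: m.predict(val[l]) for l, m in zip(layer_ids, models)}
        accuracy[v] = [prediction_accuracy(y_val[:, v], preds[l]) for l in layer_ids]
        if selection_mode == "cv":
            opt = select_optimal_layer(
                None,
                mode="cv",
                cv_context=(features, y_train[:, v], sparsity_s, tol),
            )
        else:
            opt = select_optimal_layer(accuracy[v], mode=selection_mode, layer_ids=layer_ids)
        optimal[v] = opt
        best_acc[v] = accuracy[v][layer_ids.index(opt)]
        predicted[:, v] = preds[opt]
    return EncodingResult(
        layer_ids=list(layer_ids),
        accuracy=accuracy,
        optimal_layer=optimal,
        best_accuracy=best_acc,
        predicted_val=predicted,
    )
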