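"""Layer feature containers and dimensionality reduction.

A hierarchical feature extractor yields one matrix per layer for the training
and validation stimulus splits.  Before the per-voxel regressions the layer
matrices may be compressed by PCA, fit on the training split only so nothing
about the validation stimuli leaks into the design.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
from sklearn.decomposition import PCA

__all__ = [
    "LayerFeatureSet",
    "ReducedFeatures",
    "reduce_pca",
    "register_extractor",
    "extract_layers",
]


@dataclass
class LayerFeatureSet:
    """Per-layer stimulus x feature matrices for the train/validation splits."""

    layer_ids: list[int]
    train: dict[int, np.ndarray]
    val: dict[int, np.ndarray]
    train_ids: np.ndarray = field(default=None)  # type: ignore[assignment]
    val_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.layer_ids:
            raise ValueError("LayerFeatureSet needs at least one layer")
        n_train = {self.train[l].shape[0] for l in self.layer_ids}
        n_val = {self.val[l].shape[0] for l in self.layer_ids}
        if len(n_train) != 1 or len(n_val) != 1:
            raise ValueError("row counts differ across layers")
        for l in self.layer_ids:
            if np.isnan(self.train[l]).any() or np.isnan(self.val[l]).any():
                raise ValueError(f"layer {l} contains missing values")
        if self.train_ids is None:
            self.train_ids = np.arange(next(iter(n_train)))
        if self.val_ids is None:
            self.val_ids = np.arange(next(iter(n_val)))

    @property
    def n_train(self) -> int:
        return self.train[self.layer_ids[0]].shape[0]

    @property
    def n_val(self) -> int:
        return self.val[self.layer_ids[0]].shape[0]

    def layer_dim(self, layer_id: int) -> int:
        return self.train[layer_id].shape[1]


@dataclass
class ReducedFeatures:
    """PCA-compressed layer features; validation rows are projected with the
    training means and loadings only."""

    layer_ids: list[int]
    train: dict[int, np.ndarray]
    val: dict[int, np.ndarray]
    means: dict[int, np.ndarray]
    loadings: dict[int, np.ndarray]  # n_components x original dim

    @property
    def n_train(self) -> int:
        return self.train[self.layer_ids[0]].shape[0]


def reduce_pca(features: LayerFeatureSet, n_components: int) -> ReducedFeatures:
    """Compress each layer with PCA fit on the training split.

    The retained dimensionality per layer is
    ``p = min(n_components, d_layer, n_train - 1)`` (the centered training
    matrix has rank at most ``n_train - 1``).  Features are mean-centered but
    not variance-scaled, and each component's sign is fixed so its
    largest-magnitude loading is positive, making the projection
    deterministic.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    train_out: dict[int, np.ndarray] = {}
    val_out: dict[int, np.ndarray] = {}
    means: dict[int, np.ndarray] = {}
    loadings: dict[int, np.ndarray] = {}
    for l in features.layer_ids:
        Xtr = np.asarray(features.train[l], dtype=float)
        if np.allclose(Xtr.var(axis=0), 0.0):
            raise ValueError(f"layer {l} is constant (zero variance); cannot reduce")
        p = min(n_components, Xtr.shape[1], Xtr.shape[0] - 1)
        pca = PCA(n_components=p, svd_solver="full")
        Ztr = pca.fit_transform(Xtr)
        comps = pca.components_
        # deterministic sign: largest-|loading| entry of each component positive
        flip = np.sign(comps[np.arange(p), np.argmax(np.abs(comps), axis=1)])
        flip[flip == 0] = 1.0
        comps = comps * flip[:, None]
        Ztr = Ztr * flip[None, :]
        Zval = (np.asarray(features.val[l], dtype=float) - pca.mean_) @ comps.T
        train_out[l] = Ztr
        val_out[l] = Zval
        means[l] = pca.mean_
        loadings[l] = comps
    return ReducedFeatures(
        layer_ids=list(features.layer_ids),
        train=train_out,
        val=val_out,
        means=means,
        loadings=loadings,
    )


_EXTRACTORS: dict[str, Callable[..., LayerFeatureSet]] = {}


def register_extractor(name: str, fn: Callable[..., LayerFeatureSet]) -> None:
    """Register a feature extractor plug-in under ``name``.

    An extractor is any callable returning a :class:`LayerFeatureSet`; real
    pretrained-network extractors plug in through this registry alongside the
    built-in synthetic cascade.
    """
    _EXTRACTORS[name] = fn


def extract_layers(extractor: str, stimuli: Mapping | None = None, **kwargs) -> LayerFeatureSet:
    """Run a registered extractor and validate its output contract."""
    if extractor not in _EXTRACTORS:
        raise ValueError(
            f"unknown extractor {extractor!r}; registered: {sorted(_EXTRACTORS)}"
        )
    params = dict(stimuli or {})
    params.update(kwargs)
    out = _EXTRACTORS[extractor](**params)
    if not isinstance(out, LayerFeatureSet):
        out = LayerFeatureSet(**out)  # re-validate plug-in output
    return out
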