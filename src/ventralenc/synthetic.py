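"""Synthetic visual-encoding studies with known ground truth.

Real studies of this kind pair hierarchical network features of natural
images with fMRI voxel responses from retinotopic and category-selective
visual areas (V1-V4, LOC, PPA, FFA; 1200 training and 50 validation stimuli,
35 repeated validation runs).  The generator emulates exactly that structure:

* an ``L``-layer feature hierarchy built as a random ReLU cascade, so deeper
  layers are nonlinear functions of earlier ones (nested, but not identical,
  information);
* voxels that are sparse linear readouts of one layer plus i.i.d. Gaussian
  noise, with per-ROI layer-preference distributions that place early layers
  in lower visual cortex and late layers in higher visual cortex;
* repeated noisy validation runs for noise-ceiling estimation.

Because every voxel's generating layer, support and weights are recorded,
the downstream pipeline can be scored against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import LayerFeatureSet, register_extractor

__all__ = [
    "ROISpec",
    "SyntheticStudyConfig",
    "ROIResponses",
    "VoxelTruth",
    "VoxelDataset",
    "SyntheticStudy",
    "default_rois",
    "make_layer_features",
    "make_voxel_responses",
    "make_study",
    "desk_config",
]

ROI_NAMES = ("V1", "V2", "V3", "V4", "LOC", "PPA", "FFA")
LVC_ROIS = ("V1", "V2", "V3")
HVC_ROIS = ("LOC", "PPA", "FFA")

# relative depth of each area's modal feature layer along the ventral stream
_ROI_DEPTH = {"V1": 0.0, "V2": 0.15, "V3": 0.3, "V4": 0.45, "LOC": 0.7, "PPA": 0.85, "FFA": 1.0}


@dataclass
class ROISpec:
    """A region of interest: voxel count plus a distribution over the layer
    each voxel reads out."""

    name: str
    n_voxels: int
    layer_preference: np.ndarray  # probability over layers 1..L

    def __post_init__(self) -> None:
        self.layer_preference = np.asarray(self.layer_preference, dtype=float)
        if self.n_voxels < 1:
            raise ValueError(f"ROI {self.name}: n_voxels must be >= 1")
        if np.any(self.layer_preference < 0) or not np.isclose(
            self.layer_preference.sum(), 1.0
        ):
            raise ValueError(f"ROI {self.name}: layer_preference must sum to 1")


def default_rois(n_layers: int, n_voxels: int = 60, concentration: float = 0.7) -> list[ROISpec]:
    """The canonical seven-ROI set with an early-to-late layer gradient.

    Each ROI's preference puts ``concentration`` mass on its modal layer and
    splits the rest over the adjacent layers, so lower visual cortex (V1-V3)
    reads out early layers and higher visual cortex (LOC/PPA/FFA) late ones.
    """
    rois = []
    for name in ROI_NAMES:
        mode = int(round(_ROI_DEPTH[name] * (n_layers - 1)))
        pref = np.zeros(n_layers)
        pref[mode] = concentration
        side = (1.0 - concentration) / 2.0
        for nb in (mode - 1, mode + 1):
            if 0 <= nb < n_layers:
                pref[nb] += side
        pref /= pref.sum()
        rois.append(ROISpec(name=name, n_voxels=n_voxels, layer_preference=pref))
    return rois


@dataclass
class SyntheticStudyConfig:
    """Parameters of a synthetic multi-subject encoding study.

    Defaults mirror the real study layout: 1200 training / 50 validation
    stimuli, 18 feature layers, 35 repeated validation runs, five subjects.
    ``snr`` is the ratio of clean-signal sd to noise sd (clean responses are
    standardized to unit variance, so noise sd is ``1/snr``).
    """

    n_subjects: int = 5
    n_train: int = 1200
    n_val: int = 50
    n_layers: int = 18
    layer_dims: list[int] | None = None
    rois: list[ROISpec] | None = None
    k_true: int = 10
    snr: float = 2.0
    n_runs: int = 35
    run_noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.layer_dims is None:
            self.layer_dims = [200] * self.n_layers
        if self.rois is None:
            self.rois = default_rois(self.n_layers)
        if min(self.n_subjects, self.n_train, self.n_val, self.n_layers, self.k_true, self.n_runs) < 1:
            raise ValueError("all counts must be >= 1")
        if self.snr <= 0:
            raise ValueError("snr must be > 0")
        if len(self.layer_dims) != self.n_layers:
            raise ValueError("len(layer_dims) must equal n_layers")
        for roi in self.rois:
            if roi.layer_preference.size != self.n_layers:
                raise ValueError(f"ROI {roi.name}: preference length != n_layers")


def desk_config(seed: int = 0, **overrides) -> SyntheticStudyConfig:
    """A desk-scale study: 8 layers x 200 dims, 300 train / 50 val stimuli,
    7 ROIs x 60 voxels, snr=2 — small enough to run end-to-end in minutes."""
    params = dict(
        n_subjects=5,
        n_train=300,
        n_val=50,
        n_layers=8,
        layer_dims=[200] * 8,
        k_true=10,
        snr=2.0,
        n_runs=35,
        run_noise_sd=1.0,
        seed=seed,
    )
    params.update(overrides)
    return SyntheticStudyConfig(**params)


@dataclass
class ROIResponses:
    """Observed responses of one ROI: training and validation matrices plus
    the stack of repeated validation runs (runs x stimuli x voxels)."""

    name: str
    train: np.ndarray
    val: np.ndarray
    runs: np.ndarray
    clean_train: np.ndarray | None = None
    clean_val: np.ndarray | None = None

    @property
    def n_voxels(self) -> int:
        return self.train.shape[1]


@dataclass
class VoxelTruth:
    """Generative ground truth for each voxel of an ROI."""

    generating_layer: np.ndarray  # (V,), layer ids 1..L
    support: np.ndarray  # (V, k_true) column indices into the layer
    weights: np.ndarray  # (V, k_true)
    noise_sd: float = 0.0


@dataclass
class VoxelDataset:
    """One subject's responses across ROIs, with generative truth attached."""

    subject: str
    rois: dict[str, ROIResponses]
    truth: dict[str, VoxelTruth] = field(default_factory=dict)


@dataclass
class SyntheticStudy:
    """A full synthetic study: shared features plus per-subject voxel data."""

    config: SyntheticStudyConfig
    features: LayerFeatureSet
    subjects: list[VoxelDataset]
    train_categories: np.ndarray | None = None
    val_categories: np.ndarray | None = None


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def make_layer_features(
    n_train: int, n_val: int, layer_dims: list[int], seed
) -> LayerFeatureSet:
    """Build a hierarchical feature set as a random ReLU cascade.

    Layer 1 is i.i.d. standard Gaussian; layer ``l+1 = relu(layer_l A_l + b_l)``
    with ``A_l`` Gaussian scaled by ``1/sqrt(d_l)`` and Gaussian biases.  The
    same maps are applied to the training and validation stimuli, and every
    column is rescaled to unit variance over the training split so layers are
    on a common scale.  Deterministic given ``seed``.
    """
    if not layer_dims:
        raise ValueError("layer_dims must be non-empty")
    if any(d < 2 for d in layer_dims):
        raise ValueError("all layer dims must be >= 2")
    rng = _rng(seed)
    train: dict[int, np.ndarray] = {}
    val: dict[int, np.ndarray] = {}
    layer_ids = list(range(1, len(layer_dims) + 1))
    # cascade weights are drawn before the sample blocks, and the training
    # block before the validation block, so growing the validation split
    # leaves the training features untouched
    maps = []
    for i in range(len(layer_dims) - 1):
        d_in, d_out = layer_dims[i], layer_dims[i + 1]
        A = rng.standard_normal((d_in, d_out)) / np.sqrt(d_in)
        # modest bias spread keeps ReLU activation probabilities near 1/2;
        # wide biases breed rarely-active units whose spiky, mutually
        # coherent columns degrade the deep layers' conditioning
        b = 0.25 * rng.standard_normal(d_out)
        maps.append((A, b))
    base_train = rng.standard_normal((n_train, layer_dims[0]))
    base_val = rng.standard_normal((n_val, layer_dims[0]))
    current = np.concatenate([base_train, base_val], axis=0)
    for i, l in enumerate(layer_ids):
        # standardize on train statistics so the cascade is stationary in
        # depth; (near-)dead ReLU units are not amplified, else a unit silent
        # on train but active on a validation tail sample blows up and the
        # explosion compounds with depth
        mu = current[:n_train].mean(axis=0)
        sd = current[:n_train].std(axis=0)
        scaled = (current - mu) / np.maximum(sd, 0.05)
        train[l] = scaled[:n_train].copy()
        val[l] = scaled[n_train:].copy()
        if i + 1 < len(layer_dims):
            A, b = maps[i]
            current = np.maximum(0.0, scaled @ A + b)
    return LayerFeatureSet(layer_ids=layer_ids, train=train, val=val)


def make_voxel_responses(
    features: LayerFeatureSet,
    roi_spec: ROISpec,
    k_true: int,
    snr: float,
    n_runs: int,
    run_noise_sd: float,
    seed,
) -> tuple[ROIResponses, VoxelTruth]:
    """Generate one ROI's voxels as sparse linear readouts of single layers.

    Each voxel draws a generating layer from the ROI's preference
    distribution, a support of ``k_true`` columns, and Gaussian weights.  The
    clean response is standardized (training-split statistics) to unit
    variance, so the observation noise sd is ``1/snr`` and
    ``corr(clean, observed) = snr / sqrt(snr^2 + 1)`` in expectation.  Each of
    the ``n_runs`` validation runs adds independent run noise of sd
    ``run_noise_sd`` to the observed validation signal.
    """
    min_dim = min(features.layer_dim(l) for l in features.layer_ids)
    if k_true > min_dim:
        raise ValueError(f"k_true={k_true} exceeds smallest layer dim {min_dim}")
    rng = _rng(seed)
    V = roi_spec.n_voxels
    n_train, n_val = features.n_train, features.n_val
    layers = np.asarray(features.layer_ids)
    gen_layers = rng.choice(layers, size=V, p=roi_spec.layer_preference)
    supports = np.empty((V, k_true), dtype=int)
    weights = rng.standard_normal((V, k_true))
    clean_train = np.empty((n_train, V))
    clean_val = np.empty((n_val, V))
    for v in range(V):
        l = int(gen_layers[v])
        d = features.layer_dim(l)
        sup = rng.choice(d, size=k_true, replace=False)
        supports[v] = sup
        raw_tr = features.train[l][:, sup] @ weights[v]
        raw_va = features.val[l][:, sup] @ weights[v]
        mu, sd = raw_tr.mean(), raw_tr.std()
        sd = max(sd, 1e-12)
        clean_train[:, v] = (raw_tr - mu) / sd
        clean_val[:, v] = (raw_va - mu) / sd
    noise_sd = 1.0 / snr
    obs_train = clean_train + rng.normal(0.0, noise_sd, size=clean_train.shape)
    obs_val = clean_val + rng.normal(0.0, noise_sd, size=clean_val.shape)
    runs = obs_val[None, :, :] + rng.normal(0.0, 1.0, size=(n_runs, n_val, V)) * run_noise_sd
    responses = ROIResponses(
        name=roi_spec.name,
        train=obs_train,
        val=obs_val,
        runs=runs,
        clean_train=clean_train,
        clean_val=clean_val,
    )
    truth = VoxelTruth(
        generating_layer=gen_layers,
        support=supports,
        weights=weights,
        noise_sd=noise_sd,
    )
    return responses, truth


def make_study(config: SyntheticStudyConfig) -> SyntheticStudy:
    """Generate a full multi-subject study from one configuration.

    Sub-seeds are derived from the master seed with a fixed counter scheme
    (``SeedSequence.spawn``): the feature cascade uses child 0 and subject
    ``s`` uses child ``s+1``, so adding subjects never perturbs earlier ones.
    """
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_subjects + 1)
    features = make_layer_features(
        config.n_train, config.n_val, config.layer_dims, np.random.default_rng(children[0])
    )
    subjects = []
    for s in range(config.n_subjects):
        sub_ss = children[s + 1].spawn(len(config.rois))
        rois: dict[str, ROIResponses] = {}
        truth: dict[str, VoxelTruth] = {}
        for r, roi_spec in enumerate(config.rois):
            resp, tr = make_voxel_responses(
                features,
                roi_spec,
                config.k_true,
                config.snr,
                config.n_runs,
                config.run_noise_sd,
                np.random.default_rng(sub_ss[r]),
            )
            rois[roi_spec.name] = resp
            truth[roi_spec.name] = tr
        subjects.append(VoxelDataset(subject=f"S{s + 1}", rois=rois, truth=truth))
    # category labels kept for schema fidelity (8 images/category in training,
    # one per category in validation); the pipeline itself never uses them
    train_categories = np.arange(config.n_train) // 8
    val_categories = np.arange(config.n_val)
    return SyntheticStudy(
        config=config,
        features=features,
        subjects=subjects,
        train_categories=train_categories,
        val_categories=val_categories,
    )


def _synthetic_extractor(n_train=300, n_val=50, layer_dims=(200,) * 8, seed=0):
    return make_layer_features(n_train, n_val, list(layer_dims), seed)


register_extractor("synthetic", _synthetic_extractor)
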