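"""HDF5 container for studies and encoding results.

Layout::

    /features/layer{l}/{train,val}
    /subjects/{s}/rois/{name}/{train,val,runs}
    /truth/{s}/{name}/{generating_layer,support,weights}
    /categories/{train,val}

A JSON sidecar (``<path>.json``) stores the generating configuration so a
saved study is fully reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np

from .features import LayerFeatureSet
from .synthetic import (
    ROIResponses,
    ROISpec,
    SyntheticStudy,
    SyntheticStudyConfig,
    VoxelDataset,
    VoxelTruth,
)

__all__ = [
    "save_study",
    "load_study",
    "save_encodings",
    "load_encodings",
    "config_to_dict",
    "config_from_dict",
]


def config_to_dict(config: SyntheticStudyConfig) -> dict:
    d = dataclasses.asdict(config)
    d["rois"] = [
        {
            "name": str(r["name"]),
            "n_voxels": int(r["n_voxels"]),
            "layer_preference": [float(x) for x in np.asarray(r["layer_preference"])],
        }
        for r in d["rois"]
    ]
    return d


def config_from_dict(d: dict) -> SyntheticStudyConfig:
    d = dict(d)
    if d.get("rois") is not None:
        d["rois"] = [ROISpec(**r) for r in d["rois"]]
    return SyntheticStudyConfig(**d)


def save_study(study: SyntheticStudy, path: str | Path) -> None:
    path = Path(path)
    with h5py.File(path, "w") as f:
        feat = f.create_group("features")
        for l in study.features.layer_ids:
            g = feat.create_group(f"layer{l}")
            g.create_dataset("train", data=study.features.train[l])
            g.create_dataset("val", data=study.features.val[l])
        subs = f.create_group("subjects")
        tru = f.create_group("truth")
        for ds in study.subjects:
            sg = subs.create_group(ds.subject).create_group("rois")
            tg = tru.create_group(ds.subject)
            for name, roi in ds.rois.items():
                rg = sg.create_group(name)
                rg.create_dataset("train", data=roi.train)
                rg.create_dataset("val", data=roi.val)
                rg.create_dataset("runs", data=roi.runs)
                t = ds.truth[name]
                vg = tg.create_group(name)
                vg.create_dataset("generating_layer", data=t.generating_layer)
                vg.create_dataset("support", data=t.support)
                vg.create_dataset("weights", data=t.weights)
                vg.attrs["noise_sd"] = t.noise_sd
        cats = f.create_group("categories")
        if study.train_categories is not None:
            cats.create_dataset("train", data=study.train_categories)
        if study.val_categories is not None:
            cats.create_dataset("val", data=study.val_categories)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(config_to_dict(study.config), indent=2))


def load_study(path: str | Path) -> SyntheticStudy:
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    config = config_from_dict(json.loads(sidecar.read_text()))
    with h5py.File(path, "r") as f:
        layer_ids = sorted(int(k[len("layer"):]) for k in f["features"])
        train = {l: f[f"features/layer{l}/train"][()] for l in layer_ids}
        val = {l: f[f"features/layer{l}/val"][()] for l in layer_ids}
        features = LayerFeatureSet(layer_ids=layer_ids, train=train, val=val)
        subjects = []
        for s in sorted(f["subjects"]):
            rois: dict[str, ROIResponses] = {}
            truth: dict[str, VoxelTruth] = {}
            for name in f[f"subjects/{s}/rois"]:
                rg = f[f"subjects/{s}/rois/{name}"]
                rois[name] = ROIResponses(
                    name=name,
                    train=rg["train"][()],
                    val=rg["val"][()],
                    runs=rg["runs"][()],
                )
                vg = f[f"truth/{s}/{name}"]
                truth[name] = VoxelTruth(
                    generating_layer=vg["generating_layer"][()],
                    support=vg["support"][()],
                    weights=vg["weights"][()],
                    noise_sd=float(vg.attrs["noise_sd"]),
                )
            subjects.append(VoxelDataset(subject=s, rois=rois, truth=truth))
        train_categories = f["categories/train"][()] if "categories/train" in f else None
        val_categories = f["categories/val"][()] if "categories/val" in f else None
    # keep the configured subject/ROI order (h5 groups iterate alphabetically)
    subjects.sort(key=lambda ds: (len(ds.subject), ds.subject))
    order = [r.name for r in config.rois]
    for ds in subjects:
        ds.rois = {n: ds.rois[n] for n in order if n in ds.rois}
        ds.truth = {n: ds.truth[n] for n in order if n in ds.truth}
    return SyntheticStudy(
        config=config,
        features=features,
        subjects=subjects,
        train_categories=train_categories,
        val_categories=val_categories,
    )


def save_encodings(encodings: dict, path: str | Path) -> None:
    """Persist nested encoding results: /models/{model}/{subject}/{roi}/..."""
    from .encoding import EncodingResult

    with h5py.File(path, "w") as f:
        models = f.create_group("models")
        for model_name, per_subject in encodings.items():
            mg = models.create_group(model_name)
            for subject, per_roi in per_subject.items():
                sg = mg.create_group(subject)
                for roi_name, res in per_roi.items():
                    rg = sg.create_group(roi_name)
                    rg.create_dataset("accuracy", data=res.accuracy)
                    rg.create_dataset("optimal_layer", data=res.optimal_layer)
                    rg.create_dataset("best_accuracy", data=res.best_accuracy)
                    rg.create_dataset("predicted_val", data=res.predicted_val)
                    rg.attrs["layer_ids"] = np.asarray(res.layer_ids)


def load_encodings(path: str | Path) -> dict:
    from .encoding import EncodingResult

    out: dict = {}
    with h5py.File(path, "r") as f:
        for model_name in f["models"]:
            out[model_name] = {}
            for subject in sorted(f[f"models/{model_name}"], key=lambda s: (len(s), s)):
                out[model_name][subject] = {}
                for roi_name in f[f"models/{model_name}/{subject}"]:
                    rg = f[f"models/{model_name}/{subject}/{roi_name}"]
                    out[model_name][subject][roi_name] = EncodingResult(
                        layer_ids=[int(l) for l in rg.attrs["layer_ids"]],
                        accuracy=rg["accuracy"][()],
                        optimal_layer=rg["optimal_layer"][()],
                        best_accuracy=rg["best_accuracy"][()],
                        predicted_val=rg["predicted_val"][()],
                    )
    return out
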