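"""Pipeline orchestration and report generation.

``run_pipeline`` executes the whole analysis on one configuration —
simulate -> (reduce) -> encode -> evaluate -> RSA -> report — and writes
figure/table-shaped CSVs:

* ``fig2_roi_summary.csv`` — per-ROI mean/variance of top-k voxel accuracy
  per model, with the median noise ceiling;
* ``fig3_rsa.csv`` — per-ROI best-layer RDM correlation per model, with the
  inter-subject ceiling;
* ``table1_advantage.csv`` — per-subject model-advantage fractions on
  commonly-accurate voxels, with the sign-flip significance threshold;
* ``fig5_layer_distribution.csv`` — distribution of optimal layers among
  accurately predicted voxels, per ROI;
* ``fig6_layer_accuracy.csv`` — per-layer mean accuracy of the top-k voxels;
* ``voxel_accuracy.csv`` — the per-voxel table everything is derived from.

Every run is deterministic given the configuration: all null distributions
and simulations draw from seeds derived from the master seed by fixed roles,
so rerunning a config reproduces the report bundle byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .encoding import EncodingResult, encode_roi
from .evaluation import (
    advantage_permutation_threshold,
    model_advantage,
    noise_ceiling,
    randomization_threshold,
    roi_summary,
)
from .features import LayerFeatureSet, reduce_pca
from .rsa import best_layer_correlation, compute_rdm, inter_subject_ceiling
from .synthetic import (
    HVC_ROIS,
    LVC_ROIS,
    SyntheticStudy,
    SyntheticStudyConfig,
    desk_config,
    make_layer_features,
    make_study,
)

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "report_layer_distribution",
    "report_layer_accuracy_curves",
    "stage_simulate",
    "stage_encode",
    "stage_evaluate",
    "stage_rsa",
    "stage_report",
]

logger = logging.getLogger(__name__)

ADVANTAGE_GROUPS = {"LVC+V4": list(LVC_ROIS) + ["V4"], "HVC": list(HVC_ROIS)}

# fixed roles for seeds derived from the master seed (sub-seeding scheme:
# each role gets its own SeedSequence child, so stages never share streams)
_SEED_CONTROL_FEATURES = 0
_SEED_RANDOMIZATION = 1
_SEED_ADVANTAGE = 2
_SEED_CEILING = 3


@dataclass
class PipelineConfig:
    """Everything needed to run the analysis end to end."""

    study: SyntheticStudyConfig = field(default_factory=desk_config)
    study_path: str | None = None  # load a saved container instead of simulating
    models: dict = field(
        default_factory=lambda: {"true_features": "study", "control_features": "cascade"}
    )
    sparsity: int = 20
    tol: float = 1e-4
    reduction: str = "none"  # "none" | "pca"
    n_components: int = 1249
    selection_mode: str = "paper"  # "paper" | "cv"
    n_perm: int = 1000
    alpha_accuracy: float = 0.001
    alpha_advantage: float = 0.05
    top_k: int = 100
    n_sim: int = 1000
    seed: int = 0
    out_dir: str = "results"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for a in (self.alpha_accuracy, self.alpha_advantage):
            if not 0.0 < a < 1.0:
                raise ValueError("alphas must be in (0, 1)")
        if self.reduction not in ("none", "pca"):
            raise ValueError("reduction must be 'none' or 'pca'")

    def role_seed(self, role: int):
        return np.random.SeedSequence(self.seed).spawn(4)[role]

    def to_dict(self) -> dict:
        from .io import config_to_dict

        d = dataclasses.asdict(self)
        d["study"] = config_to_dict(self.study)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        from .io import config_from_dict

        d = dict(d)
        if isinstance(d.get("study"), dict):
            d["study"] = config_from_dict(d["study"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _model_features(study: SyntheticStudy, source, seed_seq) -> LayerFeatureSet:
    """Resolve a model's feature source.

    ``"study"`` uses the study's own (ground-truth) features; ``"cascade"``
    generates an independent random cascade of the same shape, serving as a
    control model whose hierarchy never saw the voxel-generating features.
    """
    if source == "study":
        return study.features
    if source == "cascade":
        cfg = study.config
        return make_layer_features(
            cfg.n_train, cfg.n_val, cfg.layer_dims, np.random.default_rng(seed_seq)
        )
    raise ValueError(f"unknown feature source {source!r}")


def model_feature_sets(study: SyntheticStudy, config: PipelineConfig) -> dict[str, LayerFeatureSet]:
    """The feature set of every configured model, deterministically seeded."""
    seeds = config.role_seed(_SEED_CONTROL_FEATURES).spawn(len(config.models))
    return {
        name: _model_features(study, source, seeds[i])
        for i, (name, source) in enumerate(config.models.items())
    }


def stage_simulate(config: PipelineConfig) -> SyntheticStudy:
    """Build (or load) the study the pipeline analyzes."""
    if config.study_path is not None:
        from .io import load_study

        return load_study(config.study_path)
    return make_study(config.study)


def stage_encode(study: SyntheticStudy, config: PipelineConfig):
    """Fit per-voxel models for every configured model, subject and ROI."""
    feature_sets = model_feature_sets(study, config)
    encodings: dict[str, dict] = {}
    for name, feats in feature_sets.items():
        design = reduce_pca(feats, config.n_components) if config.reduction == "pca" else feats
        per_subject: dict[str, dict[str, EncodingResult]] = {}
        for ds in study.subjects:
            per_subject[ds.subject] = {}
            for roi_name, roi in ds.rois.items():
                per_subject[ds.subject][roi_name] = encode_roi(
                    design,
                    roi.train,
                    roi.val,
                    sparsity_s=config.sparsity,
                    tol=config.tol,
                    selection_mode=config.selection_mode,
                )
            logger.info("encoded %s / %s", name, ds.subject)
        encodings[name] = per_subject
    return feature_sets, encodings


def pooled_significance(study, results, config, seed_seq):
    """One pooled randomization threshold per model across all subjects/ROIs,
    split back into per-(subject, ROI) accurate-voxel masks."""
    measured, predicted, keys, sizes = [], [], [], []
    for ds in study.subjects:
        for name, roi in ds.rois.items():
            res = results[ds.subject][name]
            measured.append(roi.val)
            predicted.append(res.predicted_val)
            keys.append((ds.subject, name))
            sizes.append(roi.val.shape[1])
    sig = randomization_threshold(
        np.concatenate(measured, axis=1),
        np.concatenate(predicted, axis=1),
        n_perm=config.n_perm,
        alpha=config.alpha_accuracy,
        pooling="pooled",
        seed=np.random.default_rng(seed_seq),
    )
    masks: dict[tuple, np.ndarray] = {}
    off = 0
    for key, n in zip(keys, sizes):
        masks[key] = sig.mask[off : off + n]
        off += n
    return sig, masks


def stage_evaluate(study: SyntheticStudy, config: PipelineConfig, encodings: dict):
    """Significance thresholds, ROI summaries, noise ceilings, advantage table."""
    roi_order = [r.name for r in study.config.rois]
    rand_seeds = config.role_seed(_SEED_RANDOMIZATION).spawn(len(config.models))
    significance, masks = {}, {}
    for i, name in enumerate(config.models):
        sig, m = pooled_significance(study, encodings[name], config, rand_seeds[i])
        significance[name] = sig
        masks[name] = m

    ceil_seeds = config.role_seed(_SEED_CEILING).spawn(len(study.subjects))
    roi_ceilings: dict[str, list] = {r: [] for r in roi_order}
    for i, ds in enumerate(study.subjects):
        sub_seeds = ceil_seeds[i].spawn(len(roi_order))
        for j, roi_name in enumerate(roi_order):
            nc = noise_ceiling(
                ds.rois[roi_name].runs, n_sim=config.n_sim, seed=sub_seeds[j]
            )
            roi_ceilings[roi_name].append(nc.ceiling)

    fig2_rows = []
    for name in config.models:
        for roi_name in roi_order:
            by_subject = {
                ds.subject: encodings[name][ds.subject][roi_name].best_accuracy
                for ds in study.subjects
            }
            mean, var = roi_summary(by_subject, top_k=config.top_k)
            fig2_rows.append(
                {
                    "model": name,
                    "roi": roi_name,
                    "mean_accuracy": mean,
                    "variance": var,
                    "noise_ceiling_median": float(
                        np.median(np.concatenate(roi_ceilings[roi_name]))
                    ),
                }
            )
    fig2 = pd.DataFrame(fig2_rows)

    model_names = list(config.models)
    table1_rows = []
    if len(model_names) >= 2:
        a, b = model_names[:2]
        adv_rng = np.random.default_rng(config.role_seed(_SEED_ADVANTAGE))
        for ds in study.subjects:
            for group, members in ADVANTAGE_GROUPS.items():
                members = [m for m in members if m in roi_order]
                if not members:
                    continue
                acc_a = np.concatenate(
                    [encodings[a][ds.subject][m].best_accuracy for m in members]
                )
                acc_b = np.concatenate(
                    [encodings[b][ds.subject][m].best_accuracy for m in members]
                )
                mask_a = np.concatenate([masks[a][(ds.subject, m)] for m in members])
                mask_b = np.concatenate([masks[b][(ds.subject, m)] for m in members])
                adv = model_advantage(acc_a, acc_b, mask_a, mask_b)
                if not adv.undefined:
                    adv.threshold_x = advantage_permutation_threshold(
                        adv.n_common,
                        n_perm=config.n_perm,
                        alpha=config.alpha_advantage,
                        seed=adv_rng,
                    )
                    adv.significant_a = adv.fraction_a > adv.threshold_x
                    adv.significant_b = adv.fraction_b > adv.threshold_x
                table1_rows.append(
                    {
                        "subject": ds.subject,
                        "group": group,
                        "model_a": a,
                        "model_b": b,
                        "fraction_a": adv.fraction_a,
                        "fraction_b": adv.fraction_b,
                        "n_common": adv.n_common,
                        "threshold_x": adv.threshold_x,
                        "significant_a": adv.significant_a,
                        "significant_b": adv.significant_b,
                    }
                )
    table1 = pd.DataFrame(table1_rows)
    return significance, masks, fig2, table1


def report_layer_distribution(results, masks, layer_ids) -> pd.DataFrame:
    """Optimal-layer distribution among accurately predicted voxels.

    ``results``/``masks`` map (subject, roi) to an :class:`EncodingResult`
    and its accurate-voxel mask; fractions are pooled across subjects and sum
    to 1 per ROI (rows with no accurate voxels are flagged empty).
    """
    rois = sorted({roi for _, roi in results}, key=str)
    rows = []
    for roi in rois:
        opt = np.concatenate(
            [results[k].optimal_layer[masks[k]] for k in results if k[1] == roi]
        )
        if opt.size == 0:
            logger.warning("ROI %s has no accurately predicted voxels", roi)
        for l in layer_ids:
            rows.append(
                {
                    "roi": roi,
                    "layer": l,
                    "fraction": float((opt == l).mean()) if opt.size else np.nan,
                    "n_accurate": int(opt.size),
                    "is_empty": opt.size == 0,
                }
            )
    return pd.DataFrame(rows)


def report_layer_accuracy_curves(results, layer_ids, top_k: int = 100) -> pd.DataFrame:
    """Per-layer mean accuracy of each subject's top-k voxels, pooled per ROI."""
    rois = sorted({roi for _, roi in results}, key=str)
    rows = []
    for roi in rois:
        for j, l in enumerate(layer_ids):
            by_subject = {
                k[0]: results[k].accuracy[:, j] for k in results if k[1] == roi
            }
            mean, _ = roi_summary(by_subject, top_k=top_k)
            rows.append({"roi": roi, "layer": l, "mean_top_accuracy": mean})
    return pd.DataFrame(rows)


def stage_rsa(study: SyntheticStudy, config: PipelineConfig, feature_sets: dict):
    """Brain and model RDMs, best-layer correlations, inter-subject ceilings."""
    roi_order = [r.name for r in study.config.rois]
    brain_rdms: dict[str, list] = {}
    for roi_name in roi_order:
        rdms = []
        for ds in study.subjects:
            rep = ds.rois[roi_name].runs.mean(axis=0)  # run-averaged responses
            rdms.append(compute_rdm(rep, label=f"{ds.subject}/{roi_name}"))
        brain_rdms[roi_name] = rdms
    per_subject_best: dict[tuple, tuple] = {}
    rows = []
    for model_name, feats in feature_sets.items():
        model_rdms = {
            l: compute_rdm(feats.val[l], label=f"{model_name}/layer{l}")
            for l in feats.layer_ids
        }
        for roi_name in roi_order:
            taus, best_layers = [], []
            for i, ds in enumerate(study.subjects):
                layer, tau = best_layer_correlation(model_rdms, brain_rdms[roi_name][i])
                per_subject_best[(model_name, roi_name, ds.subject)] = (layer, tau)
                taus.append(tau)
                best_layers.append(layer)
            ceiling = (
                inter_subject_ceiling(brain_rdms[roi_name])
                if len(study.subjects) >= 2
                else np.nan
            )
            rows.append(
                {
                    "model": model_name,
                    "roi": roi_name,
                    "mean_max_tau": float(np.mean(taus)),
                    "variance": float(np.var(taus, ddof=1)) if len(taus) > 1 else 0.0,
                    "inter_subject_ceiling": ceiling,
                    "modal_best_layer": int(np.bincount(best_layers).argmax()),
                }
            )
    return pd.DataFrame(rows), per_subject_best, brain_rdms


def stage_report(study, config, encodings, significance, masks):
    """Figure-shaped layer tables and the per-voxel accuracy table."""
    roi_order = [r.name for r in study.config.rois]
    layer_ids = study.features.layer_ids
    fig5_parts, fig6_parts, voxel_rows = [], [], []
    for name in config.models:
        flat = {
            (ds.subject, roi_name): encodings[name][ds.subject][roi_name]
            for ds in study.subjects
            for roi_name in roi_order
        }
        flat_masks = {k: masks[name][k] for k in flat}
        d5 = report_layer_distribution(flat, flat_masks, layer_ids)
        d5.insert(0, "model", name)
        fig5_parts.append(d5)
        d6 = report_layer_accuracy_curves(flat, layer_ids, top_k=config.top_k)
        d6.insert(0, "model", name)
        fig6_parts.append(d6)
        thr = float(significance[name].threshold)
        for (subject, roi_name), res in flat.items():
            for v in range(res.n_voxels):
                voxel_rows.append(
                    {
                        "model": name,
                        "subject": subject,
                        "roi": roi_name,
                        "voxel": v,
                        "optimal_layer": int(res.optimal_layer[v]),
                        "accuracy": float(res.best_accuracy[v]),
                        "threshold": thr,
                        "accurate": bool(flat_masks[(subject, roi_name)][v]),
                    }
                )
    fig5 = pd.concat(fig5_parts, ignore_index=True)
    fig6 = pd.concat(fig6_parts, ignore_index=True)
    return fig5, fig6, pd.DataFrame(voxel_rows)


def write_tables(tables: dict[str, pd.DataFrame], out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    for stem, df in tables.items():
        df.to_csv(out / f"{stem}.csv", index=False, float_format="%.6f")


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Execute the full analysis and write the report bundle.

    Returns a dict with the study, per-model encoding results, significance
    results, and every report table.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(out_dir if out_dir is not None else config.out_dir)

    logger.info("stage simulate")
    study = stage_simulate(config)
    logger.info("stage encode")
    feature_sets, encodings = stage_encode(study, config)
    logger.info("stage evaluate")
    significance, masks, fig2, table1 = stage_evaluate(study, config, encodings)
    logger.info("stage rsa")
    fig3, per_subject_best, _ = stage_rsa(study, config, feature_sets)
    logger.info("stage report")
    fig5, fig6, voxel_table = stage_report(study, config, encodings, significance, masks)

    cfg_dict = config.to_dict()
    cfg_json = json.dumps(cfg_dict, sort_keys=True)
    provenance = {
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": config.seed,
        "package_version": __version__,
        "numpy_version": np.__version__,
        "thresholds": {m: float(significance[m].threshold) for m in config.models},
    }
    tables = {
        "fig2_roi_summary": fig2,
        "fig3_rsa": fig3,
        "table1_advantage": table1,
        "fig5_layer_distribution": fig5,
        "fig6_layer_accuracy": fig6,
        "voxel_accuracy": voxel_table,
    }
    write_tables(tables, out)
    out.mkdir(parents=True, exist_ok=True)
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2, sort_keys=True))

    return {
        "study": study,
        "feature_sets": feature_sets,
        "encodings": encodings,
        "significance": significance,
        "masks": masks,
        "rsa_per_subject_best": per_subject_best,
        **tables,
    }
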