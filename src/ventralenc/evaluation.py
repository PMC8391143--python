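"""Prediction-accuracy evaluation: randomization tests, ROI summaries,
model-advantage permutation tests, and Monte-Carlo noise ceilings.

Significance of per-voxel prediction accuracy is assessed without parametric
assumptions: the measured/predicted correspondence is scrambled many times to
build an empirical null of the Pearson correlation, and a voxel is "accurately
predicted" when its accuracy exceeds the null's upper quantile.  Model
comparisons on commonly-accurate voxels use a sign-flip permutation null for
the advantage fraction, and attainable accuracy given measurement noise is
bounded by a simulated noise ceiling built from repeated-run variance
components.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SignificanceResult",
    "AdvantageResult",
    "NoiseCeilingResult",
    "prediction_accuracy",
    "randomization_threshold",
    "roi_summary",
    "model_advantage",
    "advantage_permutation_threshold",
    "noise_ceiling",
    "simulate_ceiling",
]

logger = logging.getLogger(__name__)


@dataclass
class SignificanceResult:
    """Randomization-test outcome: the accuracy cutoff and the voxel mask."""

    threshold: float | np.ndarray
    alpha: float
    pooling: str
    accuracy: np.ndarray
    mask: np.ndarray
    null_mean: float = np.nan
    null_var: float = np.nan


@dataclass
class AdvantageResult:
    """Advantage of model A over model B on commonly-accurate voxels (%)."""

    fraction_a: float
    fraction_b: float
    n_common: int
    threshold_x: float = np.nan
    significant_a: bool = False
    significant_b: bool = False
    undefined: bool = False


@dataclass
class NoiseCeilingResult:
    """Per-voxel variance components and simulated accuracy ceilings."""

    signal_mean: np.ndarray
    signal_var: np.ndarray
    noise_var: np.ndarray
    ceiling: np.ndarray

    @property
    def median_ceiling(self) -> float:
        return float(np.median(self.ceiling))


def prediction_accuracy(r: np.ndarray, r_hat: np.ndarray) -> float:
    """Pearson correlation between measured and predicted responses.

    Returns 0 (with a warning) when either vector has zero variance, so
    degenerate predictions never count as accurate.
    """
    r = np.asarray(r, dtype=float).ravel()
    r_hat = np.asarray(r_hat, dtype=float).ravel()
    if r.size != r_hat.size:
        raise ValueError(f"length mismatch: {r.size} vs {r_hat.size}")
    if r.size < 3:
        raise ValueError("need at least 3 samples")
    sr, sh = r.std(), r_hat.std()
    if sr < 1e-12 or sh < 1e-12:
        logger.warning("zero-variance input to prediction_accuracy; returning 0")
        return 0.0
    return float(np.corrcoef(r, r_hat)[0, 1])


def _nearest_rank_quantile(values: np.ndarray, q: float) -> float:
    """Higher nearest-rank empirical quantile (conservative, reproducible)."""
    v = np.sort(np.asarray(values).ravel())
    k = int(np.ceil(q * v.size))
    k = min(max(k, 1), v.size)
    return float(v[k - 1])


def randomization_threshold(
    measured: np.ndarray,
    predicted: np.ndarray,
    n_perm: int = 1000,
    alpha: float = 0.001,
    pooling: str = "pooled",
    seed=None,
) -> SignificanceResult:
    """Accuracy cutoff from scrambling the measured/predicted correspondence.

    For each voxel the predicted vector is permuted ``n_perm`` times and the
    correlation recomputed.  With ``pooling="pooled"`` (default) all null
    correlations are pooled into one global threshold at the ``1 - alpha``
    higher nearest-rank quantile — matching the convention of quoting a
    single cutoff for all voxels; ``pooling="per-voxel"`` thresholds each
    voxel against its own null.
    """
    measured = np.atleast_2d(np.asarray(measured, dtype=float))
    predicted = np.atleast_2d(np.asarray(predicted, dtype=float))
    if measured.ndim == 2 and measured.shape[0] == 1:
        measured, predicted = measured.T, predicted.T
    if measured.shape != predicted.shape:
        raise ValueError("measured and predicted must have the same shape")
    n, n_vox = measured.shape
    if n < 3:
        raise ValueError("need at least 3 validation samples")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if pooling not in ("pooled", "per-voxel"):
        raise ValueError(f"unknown pooling mode {pooling!r}")
    rng = np.random.default_rng(seed)

    def _z(a: np.ndarray) -> np.ndarray:
        c = a - a.mean(axis=0)
        s = np.linalg.norm(c, axis=0)
        good = s > 1e-12
        if not good.all():
            logger.warning("zero-variance voxels present; their accuracy is 0")
        return np.where(good, 1.0, 0.0) * c / np.where(good, s, 1.0)

    zm = _z(measured)
    zp = _z(predicted)
    accuracy = np.einsum("ij,ij->j", zm, zp)
    null = np.empty((n_vox, n_perm))
    base = np.tile(np.arange(n), (n_perm, 1))
    for v in range(n_vox):
        perms = rng.permuted(base, axis=1)
        null[v] = zp[perms, v] @ zm[:, v]
    q = 1.0 - alpha
    if pooling == "pooled":
        threshold: float | np.ndarray = _nearest_rank_quantile(null, q)
    else:
        threshold = np.array([_nearest_rank_quantile(null[v], q) for v in range(n_vox)])
    mask = accuracy > threshold
    return SignificanceResult(
        threshold=threshold,
        alpha=alpha,
        pooling=pooling,
        accuracy=accuracy,
        mask=mask,
        null_mean=float(null.mean()),
        null_var=float(null.var(ddof=1)),
    )


def roi_summary(accuracies_by_subject: dict, top_k: int = 100):
    """Mean and variance of the pooled top-k voxel accuracies per subject.

    Takes each subject's ``top_k`` most accurate voxels in the ROI, pools the
    values across subjects, and returns their mean and (sample) variance.
    Subjects with fewer than ``top_k`` voxels contribute all of them.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    pooled = []
    for subject, acc in accuracies_by_subject.items():
        acc = np.sort(np.asarray(acc, dtype=float).ravel())
        if acc.size < top_k:
            logger.warning(
                "subject %s: only %d voxels (< top_k=%d); using all",
                subject, acc.size, top_k,
            )
        pooled.append(acc[-top_k:])
    values = np.concatenate(pooled)
    return float(values.mean()), float(values.var(ddof=1)) if values.size > 1 else 0.0


def model_advantage(
    acc_a: np.ndarray,
    acc_b: np.ndarray,
    mask_a: np.ndarray,
    mask_b: np.ndarray,
) -> AdvantageResult:
    """Fraction of commonly-accurate voxels better predicted by each model.

    Restricted to voxels accurate under both models; ties are split 50/50
    (and logged) so the two fractions always sum to 100%.
    """
    acc_a = np.asarray(acc_a, dtype=float).ravel()
    acc_b = np.asarray(acc_b, dtype=float).ravel()
    common = np.asarray(mask_a, bool).ravel() & np.asarray(mask_b, bool).ravel()
    n = int(common.sum())
    if n == 0:
        return AdvantageResult(
            fraction_a=np.nan, fraction_b=np.nan, n_common=0, undefined=True
        )
    a, b = acc_a[common], acc_b[common]
    ties = int((a == b).sum())
    if ties:
        logger.info("model_advantage: %d tied voxels split 50/50", ties)
    wins_a = float((a > b).sum()) + 0.5 * ties
    frac_a = 100.0 * wins_a / n
    return AdvantageResult(fraction_a=frac_a, fraction_b=100.0 - frac_a, n_common=n)


def advantage_permutation_threshold(
    n_common_voxels: int,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed=None,
) -> float:
    """Critical advantage ``x`` (%) from the sign-flip permutation null.

    Under the null each voxel's winner is flipped independently with
    probability 0.5; ``x`` is the ``1 - alpha`` higher nearest-rank quantile
    of the resulting advantage fractions.  For ``n`` common voxels this
    approaches the Binomial(n, 1/2) upper quantile in percent.
    """
    if n_common_voxels < 1:
        raise ValueError("need at least one common voxel")
    rng = np.random.default_rng(seed)
    wins = rng.binomial(n_common_voxels, 0.5, size=n_perm)
    null_adv = 100.0 * wins / n_common_voxels
    return _nearest_rank_quantile(null_adv, 1.0 - alpha)


def simulate_ceiling(
    signal_mean: float,
    signal_var: float,
    noise_var: float,
    n_stimuli: int,
    n_sim: int = 1000,
    seed=None,
) -> float:
    """Median accuracy of a perfect model under Gaussian signal and noise.

    Draws ``n_sim`` signal vectors from ``N(signal_mean, signal_var)``, adds
    independent ``N(0, noise_var)`` measurement noise, and returns the median
    correlation between signal and measurement — approaching
    ``sigma_s / sqrt(sigma_s^2 + sigma_n^2)`` for large stimulus counts.
    """
    rng = np.random.default_rng(seed)
    sig = signal_mean + np.sqrt(max(signal_var, 0.0)) * rng.standard_normal((n_sim, n_stimuli))
    meas = sig + np.sqrt(max(noise_var, 0.0)) * rng.standard_normal((n_sim, n_stimuli))
    sc = sig - sig.mean(axis=1, keepdims=True)
    mc = meas - meas.mean(axis=1, keepdims=True)
    denom = np.linalg.norm(sc, axis=1) * np.linalg.norm(mc, axis=1)
    denom = np.where(denom > 1e-12, denom, np.inf)
    corr = np.einsum("ij,ij->i", sc, mc) / denom
    return float(np.median(corr))


def noise_ceiling(run_stack: np.ndarray, n_sim: int = 1000, seed=None) -> NoiseCeilingResult:
    """Per-voxel noise ceilings from repeated validation runs.

    ``run_stack`` is runs x stimuli x voxels.  Per voxel the noise variance
    is the pooled squared standard error of the run mean (across-run sample
    variance averaged over stimuli, divided by the number of runs); the
    signal variance is the across-stimulus variance of the run-mean response
    minus the noise variance, clipped at zero.  The ceiling is the median
    correlation over ``n_sim`` simulated signal/measurement pairs.
    """
    run_stack = np.asarray(run_stack, dtype=float)
    if run_stack.ndim != 3 or run_stack.shape[0] < 2:
        raise ValueError("run_stack must be runs x stimuli x voxels with >= 2 runs")
    n_runs, n_stim, n_vox = run_stack.shape
    run_mean = run_stack.mean(axis=0)  # stimuli x voxels
    noise_var = run_stack.var(axis=0, ddof=1).mean(axis=0) / n_runs
    signal_mean = run_mean.mean(axis=0)
    signal_var = np.maximum(run_mean.var(axis=0, ddof=1) - noise_var, 0.0)
    if isinstance(seed, np.random.SeedSequence):
        ss = seed
    elif isinstance(seed, np.random.Generator):
        ss = seed.bit_generator.seed_seq  # type: ignore[attr-defined]
    else:
        ss = np.random.SeedSequence(seed if seed is not None else 0)
    children = ss.spawn(n_vox)
    ceiling = np.array(
        [
            simulate_ceiling(
                signal_mean[v], signal_var[v], noise_var[v], n_stim, n_sim,
                np.random.default_rng(children[v]),
            )
            for v in range(n_vox)
        ]
    )
    return NoiseCeilingResult(
        signal_mean=signal_mean,
        signal_var=signal_var,
        noise_var=noise_var,
        ceiling=ceiling,
    )
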