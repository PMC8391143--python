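"""Representational similarity analysis.

A representational dissimilarity matrix (RDM) summarizes how a system — a
brain region or a model layer — distinguishes stimuli: entry (i, j) is the
correlation distance ``1 - Pearson(rep_i, rep_j)`` between the two stimulus
representations.  RDMs from different systems are compared with Kendall's
rank correlation over their upper triangles; the tau-a variant is used, the
convention for RDM comparison when tied dissimilarities are rare.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

__all__ = [
    "RDM",
    "compute_rdm",
    "rdm_correlation",
    "kendall_tau_a",
    "inter_subject_ceiling",
    "best_layer_correlation",
]


@dataclass
class RDM:
    """A symmetric, zero-diagonal stimulus dissimilarity matrix in [0, 2]."""

    matrix: np.ndarray
    stimulus_ids: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        self.stimulus_ids = np.asarray(self.stimulus_ids)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("RDM matrix must be square")
        if m.shape[0] != self.stimulus_ids.size:
            raise ValueError("stimulus_ids length must match matrix size")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("RDM must be symmetric")
        if not np.allclose(np.diag(m), 0.0, atol=1e-10):
            raise ValueError("RDM diagonal must be zero")
        if m.min() < -1e-10 or m.max() > 2.0 + 1e-10:
            raise ValueError("RDM entries must lie in [0, 2]")
        self.matrix = m

    @property
    def n_stimuli(self) -> int:
        return self.matrix.shape[0]

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(self.n_stimuli, k=1)
        return self.matrix[iu]


def compute_rdm(representations: np.ndarray, stimulus_ids=None, label: str = "") -> RDM:
    """Correlation-distance RDM of a stimuli x features representation matrix."""
    rep = np.asarray(representations, dtype=float)
    if rep.ndim != 2 or rep.shape[0] < 3:
        raise ValueError("need at least 3 stimulus representations")
    if rep.shape[1] < 2:
        raise ValueError("representations need at least 2 features")
    sds = rep.std(axis=1)
    if (bad := np.flatnonzero(sds < 1e-12)).size:
        ids = stimulus_ids if stimulus_ids is not None else np.arange(rep.shape[0])
        raise ValueError(
            f"constant representation for stimulus {np.asarray(ids)[bad[0]]!r}"
        )
    m = 1.0 - np.corrcoef(rep)
    m = np.clip((m + m.T) / 2.0, 0.0, 2.0)
    np.fill_diagonal(m, 0.0)
    if stimulus_ids is None:
        stimulus_ids = np.arange(rep.shape[0])
    return RDM(matrix=m, stimulus_ids=stimulus_ids, label=label)


def kendall_tau_a(x: np.ndarray, y: np.ndarray) -> float:
    """Kendall's tau-a: (concordant - discordant) / (m choose 2).

    Unlike tau-b, tied pairs are counted in the denominator, which is the
    standard choice for comparing RDMs (ties are rare for continuous
    dissimilarities, where tau-a and tau-b coincide).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size or x.size < 2:
        raise ValueError("inputs must have equal length >= 2")
    sx = np.sign(x[:, None] - x[None, :])
    sy = np.sign(y[:, None] - y[None, :])
    m = x.size
    num = float(np.sum(sx * sy)) / 2.0  # each pair counted twice
    return num / (m * (m - 1) / 2.0)


def rdm_correlation(rdm_a: RDM, rdm_b: RDM) -> float:
    """Kendall tau-a between two RDMs' strict upper triangles."""
    if rdm_a.n_stimuli != rdm_b.n_stimuli or not np.array_equal(
        rdm_a.stimulus_ids, rdm_b.stimulus_ids
    ):
        raise ValueError("RDMs must share stimulus ids and order")
    return kendall_tau_a(rdm_a.upper_triangle(), rdm_b.upper_triangle())


def inter_subject_ceiling(brain_rdms: list[RDM]) -> float:
    """Mean tau over all unordered subject pairs — the bar a model RDM would
    have to clear to explain a region as well as another brain does."""
    if len(brain_rdms) < 2:
        raise ValueError("need at least 2 subject RDMs")
    taus = [rdm_correlation(a, b) for a, b in combinations(brain_rdms, 2)]
    return float(np.mean(taus))


def best_layer_correlation(model_rdms_by_layer: dict[int, RDM], brain_rdm: RDM):
    """Layer whose RDM best matches the brain RDM, with its tau.

    Ties break toward the lowest layer id.
    """
    if not model_rdms_by_layer:
        raise ValueError("no model RDMs supplied")
    best_layer, best_tau = None, -np.inf
    for layer in sorted(model_rdms_by_layer):
        tau = rdm_correlation(model_rdms_by_layer[layer], brain_rdm)
        if tau > best_tau:
            best_layer, best_tau = layer, tau
    return int(best_layer), float(best_tau)
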