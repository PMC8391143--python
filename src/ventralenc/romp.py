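"""Regularized orthogonal matching pursuit (ROMP) sparse regression.

ROMP is a greedy sparse solver for ``y = X w + eps`` when only a small number
of columns of ``X`` carry signal.  Each round it correlates the residual with
all candidate columns, keeps the ``s`` strongest correlations, and — the
"regularization" step — admits only a window of them whose magnitudes are
within a factor of two of each other, choosing the window with the largest
energy.  The admitted columns are added to the support and the coefficients
are refit by ordinary least squares.  The pursuit stops once the support
reaches ``2 s`` columns or the residual is negligible.

The estimator follows the scikit-learn API (``fit`` / ``predict`` /
``get_params``) so it composes with pipelines and model selection.  Column
normalization is applied only to the selection inner products; reported
coefficients are on the original feature scale, and the intercept is handled
by centering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted, check_X_y

__all__ = ["ROMPRegressor", "SparseLinearModel", "fit_romp"]

_EPS = 1e-12


@dataclass
class SparseLinearModel:
    """A fitted per-voxel sparse linear readout.

    ``weights`` has length ``p + 1``: one coefficient per design column
    (zero off the support) with the intercept stored as the final entry,
    mirroring a design matrix whose last column is the constant term.
    """

    weights: np.ndarray
    support: np.ndarray
    layer_id: int | None = None
    residual_norm: float = 0.0
    n_iter: int = 0

    @property
    def coef(self) -> np.ndarray:
        """Feature coefficients, excluding the intercept."""
        return self.weights[:-1]

    @property
    def intercept(self) -> float:
        return float(self.weights[-1])

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.weights.size - 1:
            raise ValueError(
                f"design has {X.shape[1] if X.ndim == 2 else '?'} columns, "
                f"model expects {self.weights.size - 1}"
            )
        return X @ self.weights[:-1] + self.weights[-1]


def _regularized_window(idx_sorted: np.ndarray, absu_sorted: np.ndarray) -> np.ndarray:
    """Pick the maximal-energy contiguous window with comparable magnitudes.

    ``absu_sorted`` is in non-increasing order; a window [i..j] is admissible
    when its largest entry is at most twice its smallest.
    """
    best_energy = -1.0
    best = idx_sorted[:1]
    m = absu_sorted.size
    energy_csum = np.concatenate([[0.0], np.cumsum(absu_sorted**2)])
    for i in range(m):
        # largest j with absu[i] <= 2 * absu[j]
        j = i
        while j + 1 < m and absu_sorted[i] <= 2.0 * absu_sorted[j + 1]:
            j += 1
        energy = energy_csum[j + 1] - energy_csum[i]
        if energy > best_energy:
            best_energy = energy
            best = idx_sorted[i : j + 1]
    return best


class ROMPRegressor(RegressorMixin, BaseEstimator):
    """Sparse linear regression via regularized orthogonal matching pursuit.

    Parameters
    ----------
    sparsity : int, default=20
        Target sparsity level ``s``.  Each round considers the ``s`` largest
        residual correlations; the pursuit stops when the support reaches
        ``2 s`` columns.
    tol : float, default=1e-4
        Relative residual tolerance: stop when ``||y - Xw|| <= tol * ||y||``.

    Attributes
    ----------
    coef_ : ndarray of shape (n_features,)
        Coefficients on the original feature scale; exactly zero off the
        selected support.
    intercept_ : float
    support_ : ndarray of int
        Indices of the selected columns, in selection order.
    residual_norm_ : float
        Euclidean norm of the training residual at convergence.
    n_iter_ : int
    """

    def __init__(self, sparsity: int = 20, tol: float = 1e-4):
        self.sparsity = sparsity
        self.tol = tol

    def fit(self, X, y):
        X, y = check_X_y(X, y, y_numeric=True)
        if self.sparsity < 1:
            raise ValueError("sparsity must be >= 1")
        n, p = X.shape
        s = int(self.sparsity)

        y_mean = float(y.mean())
        yc = y - y_mean
        x_mean = X.mean(axis=0)
        Xc = X - x_mean
        col_norms = np.linalg.norm(Xc, axis=0)
        selectable = col_norms > _EPS
        inv_norms = np.where(selectable, 1.0 / np.where(selectable, col_norms, 1.0), 0.0)

        y_norm = float(np.linalg.norm(y))
        support: list[int] = []
        coef_sub = np.zeros(0)
        residual = yc.copy()
        n_iter = 0
        residual_norms = [float(np.linalg.norm(residual))]

        if np.linalg.norm(yc) > _EPS * max(1.0, y_norm):
            in_support = np.zeros(p, dtype=bool)
            while len(support) < 2 * s:
                u = (Xc.T @ residual) * inv_norms
                u[in_support] = 0.0
                absu = np.abs(u)
                cand = np.flatnonzero(absu > _EPS * max(1.0, y_norm))
                if cand.size == 0:
                    break
                top = cand[np.argsort(absu[cand])[::-1][:s]]
                order = np.argsort(absu[top])[::-1]
                top = top[order]
                window = _regularized_window(top, absu[top])
                window = window[: 2 * s - len(support)]  # support never exceeds 2s
                support.extend(int(i) for i in window)
                in_support[window] = True
                n_iter += 1
                sub = Xc[:, support]
                coef_sub, *_ = np.linalg.lstsq(sub, yc, rcond=None)
                residual = yc - sub @ coef_sub
                residual_norms.append(float(np.linalg.norm(residual)))
                if np.linalg.norm(residual) <= self.tol * y_norm:
                    break
            # drop columns the refit assigns (numerically) zero weight: a
            # window can sweep in a column that carries none of the signal
            if support:
                contrib = np.abs(coef_sub) * col_norms[support]
                keep = contrib > 1e-9 * max(y_norm, _EPS)
                if not keep.all():
                    support = [i for i, k in zip(support, keep) if k]
                    if support:
                        coef_sub, *_ = np.linalg.lstsq(Xc[:, support], yc, rcond=None)
                        residual = yc - Xc[:, support] @ coef_sub
                    else:
                        coef_sub = np.zeros(0)
                        residual = yc.copy()

        coef = np.zeros(p)
        if support:
            coef[support] = coef_sub
        self.coef_ = coef
        self.intercept_ = y_mean - float(x_mean @ coef)
        self.support_ = np.asarray(support, dtype=int)
        self.residual_norm_ = float(np.linalg.norm(residual))
        self.residual_norms_ = residual_norms
        self.n_iter_ = n_iter
        self.n_features_in_ = p
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.coef_.size:
            raise ValueError(
                f"X has {X.shape[1] if X.ndim == 2 else '?'} features, "
                f"ROMPRegressor was fit with {self.coef_.size}"
            )
        return X @ self.coef_ + self.intercept_


def fit_romp(
    X: np.ndarray,
    y: np.ndarray,
    sparsity_s: int = 20,
    tol: float = 1e-4,
    layer_id: int | None = None,
) -> SparseLinearModel:
    """Fit ROMP and package the result as a :class:`SparseLinearModel`.

    The returned weight vector has length ``p + 1`` with the intercept last.
    An all-zero target returns zero weights with the intercept equal to the
    target mean; NaNs in either input raise.
    """
    est = ROMPRegressor(sparsity=sparsity_s, tol=tol).fit(X, y)
    weights = np.concatenate([est.coef_, [est.intercept_]])
    return SparseLinearModel(
        weights=weights,
        support=est.support_,
        layer_id=layer_id,
        residual_norm=est.residual_norm_,
        n_iter=est.n_iter_,
    )
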