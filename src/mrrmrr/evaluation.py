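"""LDA classification, leave-one-out cross-validation, and gamma search.

Classification performance of a selected variable set is judged by linear
discriminant analysis in a leave-one-out cross-validation: each sample in
turn is held out, LDA (pooled within-class covariance, equal priors by
default) is learned on the remaining n-1 samples, and the held-out sample
is classified.  Sensitivity is the correct-classification rate in group 1,
specificity the rate in group 2, and accuracy = (SE + SP)/2.  The
redundancy penalty gamma of the selection criterion is chosen by scanning a
grid and keeping the gamma with the best LOOCV accuracy (ties -> smallest
gamma).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import linalg

from .data import DataMatrix
from .selection import SelectionConfig, SelectionEngine, mrmr_forward

__all__ = ["LDAModel", "CVReport", "lda_fit", "loocv", "gamma_search"]


class SingularCovarianceError(np.linalg.LinAlgError):
    pass


@dataclass
class LDAModel:
    """Fitted two-class LDA with pooled within-class covariance."""

    class_means: np.ndarray  # (2, d)
    pooled_covariance: np.ndarray  # (d, d), after any ridge inflation
    log_priors: np.ndarray  # (2,)
    ridge_used: float
    _chol: object = field(default=None, repr=False)

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        """delta_2(x) - delta_1(x); positive -> group 2."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        diffs = []
        for c in range(2):
            mu = self.class_means[c]
            a = linalg.cho_solve(self._chol, mu)
            diffs.append(X @ a - 0.5 * float(mu @ a) + self.log_priors[c])
        return diffs[1] - diffs[0]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.where(self.decision_values(X) > 0, 2, 1)


def lda_fit(
    X_train: np.ndarray,
    Y_train: np.ndarray,
    ridge: Optional[float] = None,
    priors: str = "equal",
) -> LDAModel:
    """Fit two-class LDA with pooled covariance and optional ridge guard.

    ``ridge=None`` (default) fits without inflation and, only if the pooled
    covariance is numerically singular, retries with 1e-6 * trace/d on the
    diagonal; ``ridge=0`` turns the guard off and raises on singularity;
    any positive value is always added.
    """
    X = np.atleast_2d(np.asarray(X_train, dtype=float))
    Y = np.asarray(Y_train)
    n, d = X.shape
    classes = np.unique(Y)
    if not np.array_equal(classes, np.array([1, 2])):
        raise ValueError("Y_train must contain both labels 1 and 2")
    means = np.vstack([X[Y == c].mean(axis=0) for c in (1, 2)])
    pooled = np.zeros((d, d))
    for c in (1, 2):
        D = X[Y == c] - means[c - 1]
        pooled += D.T @ D
    pooled /= n - 2

    if priors == "equal":
        log_priors = np.log(np.array([0.5, 0.5]))
    else:
        log_priors = np.log(np.array([(Y == c).mean() for c in (1, 2)]))

    ridge_used = 0.0
    if ridge is not None and ridge > 0:
        ridge_used = ridge
    cov = pooled + ridge_used * np.eye(d)
    try:
        chol = linalg.cho_factor(cov)
    except np.linalg.LinAlgError:
        if ridge == 0:
            raise SingularCovarianceError(
                "pooled covariance is singular; pass a positive ridge"
            ) from None
        ridge_used = 1e-6 * float(np.trace(pooled)) / max(d, 1)
        if ridge_used <= 0:
            ridge_used = 1e-6
        cov = pooled + ridge_used * np.eye(d)
        chol = linalg.cho_factor(cov)
    return LDAModel(
        class_means=means,
        pooled_covariance=cov,
        log_priors=log_priors,
        ridge_used=ridge_used,
        _chol=chol,
    )


def _se_sp(Y: np.ndarray, pred: np.ndarray):
    se = float((pred[Y == 1] == 1).mean())
    sp = float((pred[Y == 2] == 2).mean())
    return se, sp, (se + sp) / 2.0


def loocv(
    data: DataMatrix,
    config: SelectionConfig,
    nested: bool = False,
    ridge: Optional[float] = None,
    engine: Optional[SelectionEngine] = None,
    selection: Optional[Sequence[int]] = None,
):
    """Leave-one-out cross-validated (SE, SP, accuracy) after selection.

    By default selection is run once on the full data and LDA is
    cross-validated on the selected columns (the protocol of selecting a
    reduced variable set first); this is optimistically biased because the
    held-out sample influenced the selection.  With ``nested=True``
    selection is rerun inside every fold, which is slower but unbiased.
    ``selection`` short-circuits the non-nested selection with a
    precomputed column set.

    Returns ``(sensitivity, specificity, accuracy, selected)`` where
    ``selected`` is the full-data selection (empty list when nested).
    """
    n = data.n
    Y = data.Y
    if min((Y == 1).sum(), (Y == 2).sum()) < 2:
        raise ValueError("each group needs >= 2 samples for LOOCV")
    preds = np.empty(n, dtype=int)
    if not nested:
        if selection is None:
            selection = mrmr_forward(data, config, engine=engine).selected
        cols = list(selection)
        Xs = data.X[:, cols]
        for i in range(n):
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            model = lda_fit(Xs[mask], Y[mask], ridge=ridge)
            preds[i] = model.predict(Xs[i])[0]
        se, sp, acc = _se_sp(Y, preds)
        return se, sp, acc, cols
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        fold = DataMatrix(
            X=data.X[mask],
            Y=Y[mask],
            variable_names=data.variable_names,
            sample_ids=[s for k, s in enumerate(data.sample_ids) if k != i],
        )
        cols = mrmr_forward(fold, config).selected
        model = lda_fit(fold.X[:, cols], fold.Y, ridge=ridge)
        preds[i] = model.predict(data.X[i, cols])[0]
    se, sp, acc = _se_sp(Y, preds)
    return se, sp, acc, []


@dataclass
class CVReport:
    """Per-gamma LOOCV performance and the best gamma found."""

    per_gamma: list
    best_gamma: float
    best_accuracy: float


def gamma_search(
    data: DataMatrix,
    base_config: SelectionConfig,
    gamma_grid: Sequence[float],
    nested: bool = False,
    ridge: Optional[float] = None,
) -> CVReport:
    """LOOCV over a gamma grid; best gamma maximizes accuracy (ties -> smallest).

    A single caching engine is shared across the grid so relevance values
    and shrunken-correlation building blocks are computed once.
    """
    grid = list(gamma_grid)
    if not grid:
        raise ValueError("gamma grid must be nonempty")
    engine = None
    if not nested:
        engine = SelectionEngine(
            data.X,
            data.Y,
            base_config.relevance,
            base_config.redundancy,
            base_config.redundancy_mode,
            base_config.seed,
        )
    records = []
    best_gamma, best_acc = None, -1.0
    for g in grid:
        cfg = replace(base_config, gamma=float(g))
        se, sp, acc, cols = loocv(data, cfg, nested=nested, ridge=ridge, engine=engine)
        records.append(
            {
                "gamma": float(g),
                "sensitivity": se,
                "specificity": sp,
                "accuracy": acc,
                "selected": cols,
            }
        )
        if acc > best_acc or (acc == best_acc and best_gamma is not None and g < best_gamma):
            best_gamma, best_acc = float(g), acc
    return CVReport(per_gamma=records, best_gamma=best_gamma, best_accuracy=best_acc)
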