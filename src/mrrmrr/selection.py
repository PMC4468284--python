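"""Greedy forward minimum-redundancy maximum-relevance variable selection.

The search starts from the single most relevant variable and repeatedly adds
the candidate Z maximizing

    relevance(Y, Z) - gamma * redundancy(Z, S),

until the selected set S holds a fixed number m of variables.  With the
robust LWS relevance and the regularized multiple-correlation redundancy
this is the MRRMRR criterion; classical measure choices reproduce the MRMR
baselines.  Ties are always broken by the smallest column index, and the
whole trace is deterministic given the seed.

``SelectionEngine`` caches per-column relevance values and the standardized
cross-product matrices from which the shrinkage intensity and shrunken
correlations of every candidate set are assembled in O(s^2), so that a gamma
grid can be scanned cheaply; :func:`step_score` is the direct, uncached
reference path through the measure modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin

from .data import DataMatrix, DEFAULT_SEED
from .measures import MeasureSpec, relevance_one, redundancy_pairwise
from . import shrinkage

__all__ = [
    "SelectionConfig",
    "SelectionResult",
    "SelectionEngine",
    "MRRMRRSelector",
    "first_variable",
    "step_score",
    "mrmr_forward",
]


@dataclass(frozen=True)
class SelectionConfig:
    """Configuration of one forward-selection run.

    ``redundancy_mode`` applies only to the ``reg_multiple`` redundancy:
    ``"multiple"`` uses the set-level regularized squared multiple
    correlation of the candidate with S; ``"pairwise_mean"`` averages the
    jointly shrunken pairwise correlations |(1 - lambda*) r(X_k, Z)|.
    """

    m: int = 10
    gamma: float = 1.0
    relevance: MeasureSpec = field(
        default_factory=lambda: MeasureSpec("relevance", "lws_adaptive_abs")
    )
    redundancy: MeasureSpec = field(
        default_factory=lambda: MeasureSpec("redundancy", "reg_multiple")
    )
    redundancy_mode: str = "multiple"
    seed: int = DEFAULT_SEED

    def __post_init__(self):
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.redundancy_mode not in ("multiple", "pairwise_mean"):
            raise ValueError("redundancy_mode must be 'multiple' or 'pairwise_mean'")


@dataclass
class SelectionResult:
    """Ordered selected variables with per-step diagnostics."""

    selected: list
    steps: list
    config: SelectionConfig
    variable_names: list = field(default_factory=list)


class SelectionEngine:
    """Caching evaluator for one data matrix and one measure configuration.

    Relevance values are computed once per column; for the regularized
    redundancy the standardized column products are precomputed so that the
    shrinkage intensity of any candidate set falls out of two cached p x p
    matrices.  One engine can serve many gamma values.
    """

    def __init__(
        self,
        X: np.ndarray,
        Y: np.ndarray,
        relevance: MeasureSpec,
        redundancy: MeasureSpec,
        redundancy_mode: str = "multiple",
        seed: int = DEFAULT_SEED,
    ):
        self.X = np.asarray(X, dtype=float)
        self.Y = np.asarray(Y, dtype=float)
        self.relevance_measure = relevance
        self.redundancy_measure = redundancy
        self.redundancy_mode = redundancy_mode
        self.seed = seed
        self.n, self.p = self.X.shape
        self._relevance = None
        self._pair_cache: dict = {}
        self._eig_cache: dict = {}
        self._corr = None
        if redundancy.name == "reg_multiple":
            n = self.n
            sd = self.X.std(axis=0, ddof=1)
            sd = np.where(sd > 0, sd, 1.0)  # constant columns -> zero z-scores
            Z = (self.X - self.X.mean(axis=0)) / sd
            self._C = (Z.T @ Z) / (n - 1)
            self._A = (Z * Z).T @ (Z * Z)

    # -- relevance ---------------------------------------------------------
    def relevance_values(self) -> np.ndarray:
        if self._relevance is None:
            self._relevance = np.array(
                [
                    relevance_one(self.Y, self.X[:, j], self.relevance_measure, seed=self.seed)
                    for j in range(self.p)
                ]
            )
        return self._relevance

    # -- regularized redundancy from cached cross-products -----------------
    def _lambda_star_subset(self, idx: np.ndarray) -> float:
        n = self.n
        S = self._C[np.ix_(idx, idx)]
        W2 = self._A[np.ix_(idx, idx)]
        wbar = S * (n - 1) / n
        var_hat = n / (n - 1) ** 3 * (W2 - n * wbar * wbar)
        iu = np.triu_indices(len(idx), k=1)
        den = float((S[iu] ** 2).sum())
        if den == 0:
            return 1.0
        return float(np.clip(float(var_hat[iu].sum()) / den, 0.0, 1.0))

    def redundancy_value(self, S: Sequence[int], j: int) -> float:
        """Redundancy of candidate column j with the selected set S."""
        S = tuple(S)
        meas = self.redundancy_measure
        if meas.name == "reg_multiple":
            idx = np.array(S + (j,))
            lam = self._lambda_star_subset(idx)
            r_zt = (1.0 - lam) * self._C[np.array(S), j]
            if self.redundancy_mode == "pairwise_mean":
                return float(np.abs(r_zt).mean())
            if S not in self._eig_cache:
                self._eig_cache[S] = np.linalg.eigh(self._C[np.ix_(np.array(S), np.array(S))])
            theta, Q = self._eig_cache[S]
            d = (1.0 - lam) * theta + lam
            proj = Q.T @ r_zt
            keep = d > 1e-12
            return float(np.clip(np.sum(proj[keep] ** 2 / d[keep]), 0.0, 1.0))
        total = 0.0
        for k in S:
            key = (min(k, j), max(k, j))
            if key not in self._pair_cache:
                self._pair_cache[key] = redundancy_pairwise(
                    self.X[:, k], self.X[:, j], meas
                )
            total += self._pair_cache[key]
        return total / len(S)

    def score(self, S: Sequence[int], j: int, gamma: float) -> float:
        return float(self.relevance_values()[j] - gamma * self.redundancy_value(S, j))


def first_variable(
    data: DataMatrix, relevance: MeasureSpec, seed: int = DEFAULT_SEED
) -> int:
    """Index of the single most relevant variable (ties -> smallest index)."""
    rel = [
        relevance_one(data.Y, data.X[:, j], relevance, seed=seed) for j in range(data.p)
    ]
    return int(np.argmax(rel))


def step_score(
    Z: np.ndarray,
    S: Sequence[int],
    data: DataMatrix,
    config: SelectionConfig,
) -> float:
    """Forward-step criterion for one candidate column (reference path).

    relevance(Y, Z) minus gamma times the redundancy of Z with the current
    set S, evaluated directly through the measure modules without caching.
    """
    S = list(S)
    if not S:
        raise ValueError("S must be nonempty; use first_variable for the first step")
    rel = relevance_one(data.Y, Z, config.relevance, seed=config.seed)
    meas = config.redundancy
    if meas.name == "reg_multiple":
        T = data.X[:, S]
        if config.redundancy_mode == "multiple":
            red = shrinkage.reg_multiple_corr(Z, T).value
        else:
            joint = np.column_stack([T, Z])
            lam = shrinkage.lambda_star(joint)
            R = shrinkage.sample_correlation(joint)
            red = float(np.abs((1.0 - lam) * R[len(S), : len(S)]).mean())
    else:
        red = float(
            np.mean([redundancy_pairwise(data.X[:, k], Z, meas) for k in S])
        )
    return float(rel - config.gamma * red)


def mrmr_forward(
    data: DataMatrix,
    config: SelectionConfig,
    engine: Optional[SelectionEngine] = None,
) -> SelectionResult:
    """Greedy forward MRMR/MRRMRR selection of ``config.m`` variables."""
    if config.m > data.p:
        raise ValueError(f"cannot select m={config.m} from p={data.p} variables")
    if engine is None:
        engine = SelectionEngine(
            data.X,
            data.Y,
            config.relevance,
            config.redundancy,
            config.redundancy_mode,
            config.seed,
        )
    rel = engine.relevance_values()
    selected = [int(np.argmax(rel))]
    steps = [
        {
            "index": selected[0],
            "name": data.variable_names[selected[0]],
            "relevance": float(rel[selected[0]]),
            "redundancy": 0.0,
            "score": float(rel[selected[0]]),
        }
    ]
    while len(selected) < config.m:
        best_j, best_score, best_red = -1, -np.inf, 0.0
        in_set = set(selected)
        for j in range(data.p):
            if j in in_set:
                continue
            red = engine.redundancy_value(selected, j)
            score = float(rel[j] - config.gamma * red)
            if score > best_score:
                best_j, best_score, best_red = j, score, red
        selected.append(best_j)
        steps.append(
            {
                "index": best_j,
                "name": data.variable_names[best_j],
                "relevance": float(rel[best_j]),
                "redundancy": float(best_red),
                "score": float(best_score),
            }
        )
    return SelectionResult(
        selected=selected,
        steps=steps,
        config=config,
        variable_names=[data.variable_names[j] for j in selected],
    )


class MRRMRRSelector(SelectorMixin, BaseEstimator):
    """Robust regularized MRMR variable selection as a sklearn transformer.

    Parameters
    ----------
    n_features_to_select : int
        Number of variables m in the selected set.
    gamma : float
        Redundancy penalty weight (gamma >= 0; values above 1 are allowed
        because relevance and redundancy need not share a scale).
    relevance : str
        One of ``lws_adaptive_abs`` (default), ``lws_linear_abs``,
        ``lws_logistic_abs``, ``pearson_abs``, ``spearman_abs``,
        ``mutual_information``.
    redundancy : str
        One of ``reg_multiple`` (default), ``pearson_abs``,
        ``spearman_abs``, ``mutual_information``, ``ks_pvalue``,
        ``sign_pvalue``.
    redundancy_mode : {"multiple", "pairwise_mean"}
        Set-level multiple correlation vs the mean of jointly shrunken
        pairwise correlations (only with ``reg_multiple``).
    mi_bins : int
        Equal-frequency bins of the mutual-information baseline.
    random_state : int or None
        Seed for the LWS subset sampling.

    Attributes
    ----------
    support_ : bool ndarray of shape (p,)
    selected_ : list of int
        Selected column indices in selection order.
    steps_ : list of dict
        Per-step relevance/redundancy/score diagnostics.
    relevance_values_ : ndarray of shape (p,)

    Examples
    --------
    >>> sel = MRRMRRSelector(n_features_to_select=5, gamma=0.5, random_state=0)
    >>> Xr = sel.fit_transform(X, y)   # doctest: +SKIP
    """

    def __init__(
        self,
        n_features_to_select: int = 10,
        gamma: float = 1.0,
        relevance: str = "lws_adaptive_abs",
        redundancy: str = "reg_multiple",
        redundancy_mode: str = "multiple",
        mi_bins: int = 3,
        random_state: Optional[int] = None,
    ):
        self.n_features_to_select = n_features_to_select
        self.gamma = gamma
        self.relevance = relevance
        self.redundancy = redundancy
        self.redundancy_mode = redundancy_mode
        self.mi_bins = mi_bins
        self.random_state = random_state

    def _config(self) -> SelectionConfig:
        seed = DEFAULT_SEED if self.random_state is None else self.random_state
        return SelectionConfig(
            m=self.n_features_to_select,
            gamma=self.gamma,
            relevance=MeasureSpec("relevance", self.relevance, mi_bins=self.mi_bins),
            redundancy=MeasureSpec("redundancy", self.redundancy, mi_bins=self.mi_bins),
            redundancy_mode=self.redundancy_mode,
            seed=seed,
        )

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        uniq = sorted(np.unique(y).tolist(), key=str)
        if len(uniq) != 2:
            raise ValueError("y must contain exactly two classes")
        Y = np.where(y == uniq[0], 1, 2)
        data = DataMatrix(X=X, Y=Y)
        result = mrmr_forward(data, self._config())
        self.selected_ = result.selected
        self.steps_ = result.steps
        self.relevance_values_ = None
        self.n_features_in_ = X.shape[1]
        mask = np.zeros(X.shape[1], dtype=bool)
        mask[result.selected] = True
        self.support_ = mask
        return self

    def _get_support_mask(self):
        return self.support_
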