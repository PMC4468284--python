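"""Relevance and redundancy measures behind one uniform interface.

Relevance measures quantify association between a continuous variable and
the binary group labels; redundancy measures quantify similarity between
two continuous variables (or, for the regularized multiple correlation,
between a candidate and a whole set).  All measures return nonnegative
values; for the correlation-based measures the absolute value is taken per
pair.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import mutual_info_score

from .robust import WeightScheme, r_lws
from . import shrinkage

logger = logging.getLogger("mrrmrr")

RELEVANCE_MEASURES = (
    "mutual_information",
    "pearson_abs",
    "spearman_abs",
    "lws_adaptive_abs",
    "lws_linear_abs",
    "lws_logistic_abs",
)
REDUNDANCY_MEASURES = (
    "mutual_information",
    "pearson_abs",
    "spearman_abs",
    "ks_pvalue",
    "sign_pvalue",
    "reg_multiple",
)

_LWS_KINDS = {
    "lws_adaptive_abs": "adaptive",
    "lws_linear_abs": "linear",
    "lws_logistic_abs": "logistic",
}


@dataclass(frozen=True)
class MeasureSpec:
    """A named relevance or redundancy measure with its parameters.

    ``mi_bins`` controls the equal-frequency discretization used by the
    mutual-information baseline; ``weight_params`` configures the LWS
    weight scheme of the robust relevance measures.
    """

    role: str
    name: str
    mi_bins: int = 3
    weight_params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.role == "relevance":
            if self.name not in RELEVANCE_MEASURES:
                raise ValueError(f"{self.name!r} is not a relevance measure")
        elif self.role == "redundancy":
            if self.name not in REDUNDANCY_MEASURES:
                raise ValueError(f"{self.name!r} is not a redundancy measure")
        else:
            raise ValueError("role must be 'relevance' or 'redundancy'")
        if self.mi_bins < 2:
            raise ValueError("mi_bins must be >= 2")

    def weight_scheme(self) -> WeightScheme:
        return WeightScheme(kind=_LWS_KINDS[self.name], **self.weight_params)


def _discretize(x: np.ndarray, bins: int) -> np.ndarray:
    """Equal-frequency binning into `bins` categories (ties share a bin)."""
    ranks = stats.rankdata(x, method="average")
    return np.minimum((ranks - 1) * bins / len(x), bins - 1).astype(int)


def _mutual_information(a: np.ndarray, b: np.ndarray, bins: int, discrete_a: bool) -> float:
    ca = a.astype(int) if discrete_a else _discretize(a, bins)
    cb = _discretize(b, bins)
    return float(mutual_info_score(ca, cb))


def relevance_one(
    Y: np.ndarray,
    Xk: np.ndarray,
    measure: MeasureSpec,
    seed: Optional[int] = None,
) -> float:
    """Relevance of a single variable for the binary labels (nonnegative).

    The LWS measures regress the label vector on the variable (labels are
    the response) and return |r_LWS|; a constant variable carries no
    relevance and returns 0 with a warning.
    """
    if measure.role != "relevance":
        raise ValueError("measure role must be 'relevance'")
    Y = np.asarray(Y, dtype=float)
    Xk = np.asarray(Xk, dtype=float)
    if np.ptp(Xk) == 0:
        warnings.warn("constant variable has zero relevance", stacklevel=2)
        return 0.0
    if measure.name == "pearson_abs":
        return abs(float(stats.pearsonr(Xk, Y).statistic))
    if measure.name == "spearman_abs":
        return abs(float(stats.spearmanr(Xk, Y).statistic))
    if measure.name == "mutual_information":
        return _mutual_information(Y, Xk, measure.mi_bins, discrete_a=True)
    est = r_lws(Xk, Y, scheme=measure.weight_scheme(), seed=seed)
    return abs(est.value)


def relevance_set(
    Y: np.ndarray,
    S: Sequence[int],
    X: np.ndarray,
    measure: MeasureSpec,
    seed: Optional[int] = None,
) -> float:
    """Mean relevance over the variables in S."""
    S = list(S)
    if not S:
        raise ValueError("S must be nonempty")
    return float(np.mean([relevance_one(Y, X[:, k], measure, seed=seed) for k in S]))


def redundancy_pairwise(Xk: np.ndarray, Xl: np.ndarray, measure: MeasureSpec) -> float:
    """Similarity of two continuous variables under a pairwise measure.

    ``ks_pvalue`` is the two-sample Kolmogorov-Smirnov p-value (high when
    the two empirical distributions agree, i.e. when the variables are
    interchangeable); ``sign_pvalue`` is the exact two-sided sign-test
    p-value on the nonzero paired differences.
    """
    if measure.role != "redundancy":
        raise ValueError("measure role must be 'redundancy'")
    if measure.name == "reg_multiple":
        raise ValueError("reg_multiple is a set-level measure; use redundancy_set")
    Xk = np.asarray(Xk, dtype=float)
    Xl = np.asarray(Xl, dtype=float)
    if Xk.size != Xl.size:
        raise ValueError("length mismatch")
    if measure.name == "pearson_abs":
        if np.ptp(Xk) == 0 or np.ptp(Xl) == 0:
            return 0.0
        return abs(float(stats.pearsonr(Xk, Xl).statistic))
    if measure.name == "spearman_abs":
        if np.ptp(Xk) == 0 or np.ptp(Xl) == 0:
            return 0.0
        return abs(float(stats.spearmanr(Xk, Xl).statistic))
    if measure.name == "mutual_information":
        return _mutual_information(Xk, Xl, measure.mi_bins, discrete_a=False)
    if measure.name == "ks_pvalue":
        return float(stats.ks_2samp(Xk, Xl).pvalue)
    # sign test on paired differences, zeros dropped
    diff = Xk - Xl
    nz = diff != 0
    m = int(nz.sum())
    if m == 0:
        return 1.0
    pos = int((diff[nz] > 0).sum())
    return float(stats.binomtest(pos, m, 0.5).pvalue)


def redundancy_set(
    S: Sequence[int],
    X: np.ndarray,
    measure: MeasureSpec,
    candidate: Optional[np.ndarray] = None,
) -> float:
    """Redundancy of the set S (classical) or of a candidate with S.

    Classical pairwise measures average over *all* ordered pairs of S
    including the diagonal, 1/|S|^2 sum_{k,l in S} R2(X_k, X_l); the
    constant diagonal offset does not change the forward-search argmax.
    ``reg_multiple`` instead returns the regularized squared multiple
    correlation of the candidate with the columns of S.
    """
    S = list(S)
    if not S:
        raise ValueError("S must be nonempty")
    if measure.name == "reg_multiple":
        if candidate is None:
            raise ValueError("reg_multiple redundancy needs a candidate variable")
        return shrinkage.reg_multiple_corr(candidate, X[:, S]).value
    total = 0.0
    for k in S:
        for l in S:
            total += redundancy_pairwise(X[:, k], X[:, l], measure)
    return total / len(S) ** 2
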