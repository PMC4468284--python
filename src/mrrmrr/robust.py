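"""Least weighted squares (LWS) regression and the robust correlation r_LWS.

The LWS estimator fits a simple linear regression by minimizing a weighted
sum of *ordered* squared residuals, with weights nonincreasing in residual
rank, so that the observations fitting worst receive the smallest weights.
With data-adaptive weights the estimator keeps a high breakdown point while
attaining full asymptotic efficiency of least squares on clean normal data.
A robust correlation coefficient r_LWS(U, V) is derived from the fitted
slope and the weighted standard deviations of U and V under the final
weights:

    r_LWS = b1 * sqrt(sum_i w_i (U_i - U_bar_w)^2) / sqrt(sum_i w_i (V_i - V_bar_w)^2)

which reduces to the Pearson coefficient when all weights are one.  The fit
is initialized by least trimmed squares (LTS, sum of the h smallest squared
residuals, h = floor((n+3)/2)) computed with the standard fast random-subset
/ concentration-step algorithm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

__all__ = [
    "WeightScheme",
    "LWSFit",
    "CorrelationEstimate",
    "LWSRegressor",
    "rank_weights",
    "adaptive_weights",
    "lts_initial_fit",
    "lws_fit",
    "r_lws",
    "breakdown_bound",
]


class DegenerateInputError(ValueError):
    """Raised when a sample is too degenerate to define a fit or correlation."""


@dataclass(frozen=True)
class WeightScheme:
    """Rule producing rank weights for the LWS objective.

    kind:
        ``"adaptive"``  -- data-dependent 0/1 trimming weights estimated by
        comparing quantiles of scaled squared residuals with their
        normal-theory (chi-square, 1 df) counterparts;
        ``"linear"``    -- linearly decreasing, w_i = (n - i + 1)/n;
        ``"logistic"``  -- logistic decreasing in the normalized rank
        t = (i - 1/2)/n, w(t) = 1/(1 + exp(s (t - c)));
        ``"uniform"``   -- all ones (reduces LWS to ordinary least squares,
        useful for checking the classical limit).
    """

    kind: str = "adaptive"
    logistic_steepness: float = 20.0
    logistic_center: float = 0.5
    adaptive_margin: float = 2.5

    def __post_init__(self):
        if self.kind not in ("adaptive", "linear", "logistic", "uniform"):
            raise ValueError(f"unknown weight scheme {self.kind!r}")
        if self.logistic_steepness <= 0:
            raise ValueError("logistic_steepness must be positive")
        if not 0 < self.logistic_center < 1:
            raise ValueError("logistic_center must lie in (0, 1)")


@dataclass
class LWSFit:
    """Result of an LWS (or LTS) simple-regression fit.

    ``weights`` and ``residuals`` are aligned to the input observations
    (not to residual ranks).  ``weighted_mean_U`` / ``weighted_mean_V`` are
    the weight-averaged means entering the r_LWS formula.
    """

    beta0: float
    beta1: float
    weights: np.ndarray
    residuals: np.ndarray
    weighted_mean_U: float
    weighted_mean_V: float
    n_concentration_steps: int = 0
    n_iterations: int = 0
    converged: bool = True
    seed: Optional[int] = None
    objective: float = math.nan


@dataclass
class CorrelationEstimate:
    """A robust correlation value in [-1, 1] with its weighting scheme."""

    value: float
    scheme: WeightScheme
    n: int
    fit: Optional[LWSFit] = field(default=None, repr=False)


def rank_weights(scheme: WeightScheme, n: int) -> np.ndarray:
    """Weights for residual ranks 1..n (nonincreasing, in [0, 1]).

    Rank 1 is the observation with the smallest squared residual.  The
    adaptive scheme has no fixed rank weights (they depend on the data);
    use :func:`adaptive_weights` instead.
    """
    if n < 3:
        raise ValueError(f"need n >= 3, got {n}")
    if scheme.kind == "linear":
        i = np.arange(1, n + 1)
        return (n - i + 1) / n
    if scheme.kind == "logistic":
        t = (np.arange(1, n + 1) - 0.5) / n
        return 1.0 / (1.0 + np.exp(scheme.logistic_steepness * (t - scheme.logistic_center)))
    if scheme.kind == "uniform":
        return np.ones(n)
    raise ValueError("adaptive weights are data-dependent; use adaptive_weights()")


# chi-square(1) median, used to turn a residual median into a scale estimate
_CHI2_1_MEDIAN = stats.chi2.ppf(0.5, 1)


def adaptive_weights(squared_residuals: np.ndarray, margin: float = 2.5) -> np.ndarray:
    """Data-dependent 0/1 trimming weights, aligned to observations.

    The contamination fraction is estimated by comparing order statistics of
    the squared residuals, scaled by a high-breakdown (median-based) scale
    estimate, against chi-square(1 df) quantiles: observations in the upper
    tail whose scaled squared residual exceeds ``margin`` times its
    normal-theory quantile are trimmed (weight 0).  The trimmed fraction
    never exceeds (n - floor((n+3)/2))/n, preserving the breakdown point of
    the h-subset initialization.  A perfect fit (zero residual variance)
    returns all ones.
    """
    sq = np.asarray(squared_residuals, dtype=float)
    n = sq.size
    if n < 3:
        raise ValueError(f"need n >= 3, got {n}")
    order = np.argsort(sq, kind="stable")
    sq_sorted = sq[order]
    med = np.median(sq_sorted)
    if med <= 0 or sq_sorted[-1] == sq_sorted[0]:
        return np.ones(n)
    s2 = med / _CHI2_1_MEDIAN
    t = sq_sorted / s2
    q = stats.chi2.ppf((np.arange(1, n + 1) - 0.5) / n, 1)
    flagged = t > margin * q
    # trim only a contiguous upper tail
    n_trim = 0
    for i in range(n - 1, -1, -1):
        if flagged[i]:
            n_trim += 1
        else:
            break
    h = (n + 3) // 2
    n_trim = min(n_trim, n - h)
    w = np.ones(n)
    if n_trim > 0:
        w[order[n - n_trim:]] = 0.0
    return w


def _weighted_ls(U: np.ndarray, V: np.ndarray, w: np.ndarray):
    """Closed-form weighted least squares for V = b0 + b1 U."""
    sw = w.sum()
    if sw <= 0:
        raise DegenerateInputError("all weights are zero")
    mu = float(w @ U) / sw
    mv = float(w @ V) / sw
    du = U - mu
    suu = float(w @ (du * du))
    if suu <= 0:
        raise DegenerateInputError("zero weighted variance of the regressor")
    b1 = float(w @ (du * (V - mv))) / suu
    b0 = mv - b1 * mu
    return b0, b1, mu, mv


def lts_initial_fit(
    U: np.ndarray,
    V: np.ndarray,
    n_subsets: int = 500,
    n_csteps: int = 2,
    seed: Optional[int] = None,
    n_refine: int = 10,
    max_refine_iter: int = 50,
) -> LWSFit:
    """Fast least-trimmed-squares fit of V on U (high-breakdown initializer).

    Random 2-point subsets give candidate lines; each candidate is improved
    by ``n_csteps`` concentration steps (refit on the h observations with the
    smallest squared residuals, h = floor((n+3)/2)); the ``n_refine`` best
    candidates are concentrated to convergence and the overall best (smallest
    trimmed sum of squares) is returned.  Deterministic given ``seed``.
    """
    U = np.asarray(U, dtype=float)
    V = np.asarray(V, dtype=float)
    n = U.size
    if n < 3:
        raise ValueError(f"need n >= 3, got {n}")
    if n_subsets < 1:
        raise ValueError("n_subsets must be >= 1")
    if np.ptp(U) == 0:
        raise DegenerateInputError("regressor U is constant; no slope is identified")
    rng = np.random.default_rng(seed)
    h = (n + 3) // 2

    # candidate lines through random pairs of distinct points
    i1 = rng.integers(0, n, size=n_subsets)
    i2 = rng.integers(0, n - 1, size=n_subsets)
    i2 = np.where(i2 >= i1, i2 + 1, i2)
    du = U[i2] - U[i1]
    ok = du != 0
    if not ok.any():
        # degenerate pairs only; fall back to the global OLS line
        b0, b1, _, _ = _weighted_ls(U, V, np.ones(n))
        slopes = np.array([b1])
        inters = np.array([b0])
    else:
        slopes = (V[i2] - V[i1])[ok] / du[ok]
        inters = V[i1][ok] - slopes * U[i1][ok]

    def _cstep_batch(b0s, b1s):
        # one concentration step for every candidate at once
        E = V[:, None] - b0s[None, :] - np.outer(U, b1s)
        E2 = E * E
        part = np.argpartition(E2, h - 1, axis=0)[:h]
        M = np.zeros(E2.shape, dtype=bool)
        np.put_along_axis(M, part, True, axis=0)
        su = M.T.astype(float) @ U
        sv = M.T.astype(float) @ V
        suu = M.T.astype(float) @ (U * U)
        suv = M.T.astype(float) @ (U * V)
        den = h * suu - su * su
        good = den > 0
        nb1 = np.where(good, (h * suv - su * sv) / np.where(good, den, 1.0), b1s)
        nb0 = np.where(good, (sv - nb1 * su) / h, b0s)
        obj = np.take_along_axis(np.sort(E2, axis=0), np.arange(h)[:, None], axis=0).sum(axis=0)
        return nb0, nb1, obj

    b0s, b1s = inters, slopes
    for _ in range(n_csteps):
        b0s, b1s, _ = _cstep_batch(b0s, b1s)

    # objective after the cheap c-steps, then full concentration on the best few
    E = V[:, None] - b0s[None, :] - np.outer(U, b1s)
    E2 = E * E
    obj = np.sort(E2, axis=0)[:h].sum(axis=0)
    best = np.argsort(obj, kind="stable")[: min(n_refine, obj.size)]

    best_obj = math.inf
    best_fit = None
    total_csteps = n_csteps
    for k in best:
        b0, b1 = float(b0s[k]), float(b1s[k])
        prev_set = None
        for _it in range(max_refine_iter):
            e2 = (V - b0 - b1 * U) ** 2
            idx = np.argsort(e2, kind="stable")[:h]
            key = frozenset(idx.tolist())
            if key == prev_set:
                break
            prev_set = key
            w = np.zeros(n)
            w[idx] = 1.0
            try:
                b0, b1, _, _ = _weighted_ls(U, V, w)
            except DegenerateInputError:
                break
            total_csteps += 1
        e2 = (V - b0 - b1 * U) ** 2
        o = np.sort(e2)[:h].sum()
        if o < best_obj:
            best_obj = o
            best_fit = (b0, b1)

    b0, b1 = best_fit
    res = V - b0 - b1 * U
    w = np.zeros(n)
    w[np.argsort(res * res, kind="stable")[:h]] = 1.0
    sw = w.sum()
    return LWSFit(
        beta0=b0,
        beta1=b1,
        weights=w,
        residuals=res,
        weighted_mean_U=float(w @ U) / sw,
        weighted_mean_V=float(w @ V) / sw,
        n_concentration_steps=total_csteps,
        converged=True,
        seed=seed,
        objective=float(best_obj),
    )


def _weights_for(e2: np.ndarray, scheme: WeightScheme) -> np.ndarray:
    """Per-observation weights for the current residuals (ties by index)."""
    n = e2.size
    order = np.argsort(e2, kind="stable")
    w = np.empty(n)
    if scheme.kind == "adaptive":
        return adaptive_weights(e2, margin=scheme.adaptive_margin)
    w[order] = rank_weights(scheme, n)
    return w


def lws_fit(
    U: np.ndarray,
    V: np.ndarray,
    scheme: WeightScheme = WeightScheme(),
    seed: Optional[int] = None,
    max_iter: int = 100,
    n_subsets: int = 500,
    n_csteps: int = 2,
) -> LWSFit:
    """Least weighted squares fit of V = beta0 + beta1 U + e.

    Starting from the LTS initializer, iterate: rank the squared residuals
    ascending (ties broken by observation index), assign the scheme's rank
    weights to observations, refit by weighted least squares.  The fixed
    point is defined on the observation-to-rank permutation, not on the
    coefficients, so floating-point chatter cannot prevent convergence.  If
    the iteration cap is hit, the iterate with the best weighted objective
    is returned with ``converged=False``.
    """
    U = np.asarray(U, dtype=float)
    V = np.asarray(V, dtype=float)
    n = U.size
    if n < 3:
        raise ValueError(f"need n >= 3, got {n}")

    init = lts_initial_fit(U, V, n_subsets=n_subsets, n_csteps=n_csteps, seed=seed)
    b0, b1 = init.beta0, init.beta1

    prev_order = None
    best = None
    best_obj = math.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        res = V - b0 - b1 * U
        e2 = res * res
        order = np.argsort(e2, kind="stable")
        w = _weights_for(e2, scheme)
        obj = float(w @ e2)
        if obj < best_obj:
            best_obj = obj
            best = (b0, b1, w, res)
        if prev_order is not None and np.array_equal(order, prev_order):
            converged = True
            best = (b0, b1, w, res)
            best_obj = obj
            break
        prev_order = order
        try:
            b0, b1, _, _ = _weighted_ls(U, V, w)
        except DegenerateInputError:
            converged = True
            best = (b0, b1, w, res)
            break

    b0, b1, w, res = best
    sw = w.sum()
    return LWSFit(
        beta0=float(b0),
        beta1=float(b1),
        weights=w,
        residuals=res,
        weighted_mean_U=float(w @ U) / sw,
        weighted_mean_V=float(w @ V) / sw,
        n_concentration_steps=init.n_concentration_steps,
        n_iterations=it,
        converged=converged,
        seed=seed,
        objective=float(best_obj),
    )


def r_lws(
    U: np.ndarray,
    V: np.ndarray,
    scheme: WeightScheme = WeightScheme(),
    seed: Optional[int] = None,
    **fit_kwargs,
) -> CorrelationEstimate:
    """Robust correlation of U and V from the LWS regression of V on U.

    The value is the fitted slope rescaled by the ratio of weighted standard
    deviations of U and V under the final LWS weights, clipped to [-1, 1].
    V is the regression response.  With uniform weights this is exactly the
    Pearson coefficient.
    """
    U = np.asarray(U, dtype=float)
    V = np.asarray(V, dtype=float)
    fit = lws_fit(U, V, scheme=scheme, seed=seed, **fit_kwargs)
    w = fit.weights
    su2 = float(w @ (U - fit.weighted_mean_U) ** 2)
    sv2 = float(w @ (V - fit.weighted_mean_V) ** 2)
    if su2 <= 0 or sv2 <= 0:
        raise DegenerateInputError(
            "zero weighted variance; correlation undefined on the weighted sample"
        )
    value = fit.beta1 * math.sqrt(su2) / math.sqrt(sv2)
    value = float(np.clip(value, -1.0, 1.0))
    return CorrelationEstimate(value=value, scheme=scheme, n=U.size, fit=fit)


def breakdown_bound(n: int, eps0: float = 1.0) -> float:
    """Lower bound on the finite-sample breakdown point of adaptive r_LWS.

    Equals ``min(eps0, (floor((n+1)/2) - 2)/n)`` where ``eps0`` is the
    breakdown point of the initial estimator: the robust correlation cannot
    break down under a smaller contamination fraction.
    """
    if n <= 2:
        raise ValueError(f"need n > 2, got {n}")
    if not 0 <= eps0 <= 1:
        raise ValueError("eps0 must lie in [0, 1]")
    return min(eps0, ((n + 1) // 2 - 2) / n)


class LWSRegressor:
    """Least weighted squares simple regression, scikit-learn style.

    Parameters
    ----------
    weights : {"adaptive", "linear", "logistic", "uniform"}
        Rank-weight scheme for the ordered squared residuals.
    logistic_steepness, logistic_center : float
        Shape of the logistic rank-weight curve.
    adaptive_margin : float
        Trimming margin of the quantile-comparison adaptive rule.
    n_subsets, n_csteps : int
        Random 2-point subsets and concentration steps of the LTS
        initializer.
    max_iter : int
        Cap on LWS reweighting iterations.
    random_state : int or None
        Seed for the subset sampling.

    Attributes
    ----------
    coef_ : ndarray of shape (1,)
        Fitted slope.
    intercept_ : float
    weights_ : ndarray
        Final per-observation LWS weights.
    residuals_ : ndarray
    n_iter_ : int
    converged_ : bool
    """

    def __init__(
        self,
        weights: str = "adaptive",
        logistic_steepness: float = 20.0,
        logistic_center: float = 0.5,
        adaptive_margin: float = 2.5,
        n_subsets: int = 500,
        n_csteps: int = 2,
        max_iter: int = 100,
        random_state: Optional[int] = None,
    ):
        self.weights = weights
        self.logistic_steepness = logistic_steepness
        self.logistic_center = logistic_center
        self.adaptive_margin = adaptive_margin
        self.n_subsets = n_subsets
        self.n_csteps = n_csteps
        self.max_iter = max_iter
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {
            k: getattr(self, k)
            for k in (
                "weights",
                "logistic_steepness",
                "logistic_center",
                "adaptive_margin",
                "n_subsets",
                "n_csteps",
                "max_iter",
                "random_state",
            )
        }

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def _scheme(self) -> WeightScheme:
        return WeightScheme(
            kind=self.weights,
            logistic_steepness=self.logistic_steepness,
            logistic_center=self.logistic_center,
            adaptive_margin=self.adaptive_margin,
        )

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[1] != 1:
            raise ValueError("LWSRegressor fits a simple (one-regressor) model")
        y = np.asarray(y, dtype=float)
        fit = lws_fit(
            X[:, 0],
            y,
            scheme=self._scheme(),
            seed=self.random_state,
            max_iter=self.max_iter,
            n_subsets=self.n_subsets,
            n_csteps=self.n_csteps,
        )
        self.coef_ = np.array([fit.beta1])
        self.intercept_ = fit.beta0
        self.weights_ = fit.weights
        self.residuals_ = fit.residuals
        self.n_iter_ = fit.n_iterations
        self.converged_ = fit.converged
        self.fit_ = fit
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return self.intercept_ + X[:, 0] * self.coef_[0]

    def score(self, X, y):
        """Coefficient of determination on the (unweighted) sample."""
        y = np.asarray(y, dtype=float)
        resid = y - self.predict(X)
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        return 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
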