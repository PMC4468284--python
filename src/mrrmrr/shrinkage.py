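"""Shrinkage-regularized correlation matrix and multiple correlation.

The sample correlation matrix of s+1 columns is shrunk toward the identity,

    R* = (1 - lambda) R~ + lambda I,

with the analytic, distribution-free intensity lambda* that minimizes the
mean squared error of R* (the standard analytic shrinkage of a correlation
matrix toward identity): writing z_ki for the standardized data and
w_kij = z_ki z_kj,

    S*_ij      = n/(n-1) * mean_k w_kij          (the sample correlation)
    var^(S*_ij) = n/(n-1)^3 * sum_k (w_kij - w_bar_ij)^2
    lambda*    = clamp( sum_{i<j} var^(S*_ij) / sum_{i<j} (S*_ij)^2 , 0, 1 ).

Because R* has eigenvalues (1-lambda) theta_i + lambda >= lambda, it is
invertible even when the number of columns exceeds n, which makes the
regularized squared multiple correlation

    r~*(Z, T) = R*_ZT' (R*_TT)^{-1} R*_ZT

well defined for arbitrarily many predictors T; it serves as the redundancy
measure of the MRRMRR criterion.  The inverse is computed through the
eigendecomposition of the empirical correlation of T (the fast path), since
eig(R*_TT) = (1-lambda) theta_i + lambda with unchanged eigenvectors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

__all__ = [
    "ShrinkageResult",
    "MultipleCorrResult",
    "sample_correlation",
    "lambda_star",
    "shrink",
    "reg_multiple_corr",
]


class DegenerateVariableError(ValueError):
    """Raised when a column is constant and a correlation is undefined."""


def _check_columns(M: np.ndarray, min_n: int = 3) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.ndim != 2:
        raise ValueError("expected a 2-d matrix of columns")
    n, m = M.shape
    if n < min_n:
        raise ValueError(f"need at least {min_n} rows, got {n}")
    spread = np.ptp(M, axis=0)
    if np.any(spread == 0):
        j = int(np.argmax(spread == 0))
        raise DegenerateVariableError(f"column {j} is constant")
    return M


def sample_correlation(columns: np.ndarray) -> np.ndarray:
    """Empirical correlation matrix of the columns (symmetric, unit diagonal)."""
    M = _check_columns(columns)
    R = np.corrcoef(M, rowvar=False)
    R = np.atleast_2d(R)
    np.fill_diagonal(R, 1.0)
    return np.clip((R + R.T) / 2.0, -1.0, 1.0)


def _standardize(M: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-variance columns with the unbiased (n-1) denominator."""
    return (M - M.mean(axis=0)) / M.std(axis=0, ddof=1)


def lambda_star(columns: np.ndarray) -> float:
    """Analytic shrinkage intensity toward the identity, clamped to [0, 1].

    A ratio of the summed estimated variances of the pairwise sample
    correlations to their summed squares, over all unordered off-diagonal
    pairs; 1 when the denominator vanishes (pure-noise limit: full
    shrinkage is optimal when all true correlations are zero).
    """
    M = _check_columns(columns, min_n=4)
    n, m = M.shape
    if m < 2:
        raise ValueError("need at least two columns")
    Z = _standardize(M)
    S = (Z.T @ Z) / (n - 1)  # sample correlations, S*_ij
    W2 = (Z * Z).T @ (Z * Z)  # sum_k w_kij^2
    wbar = S * (n - 1) / n  # mean_k w_kij
    var_hat = n / (n - 1) ** 3 * (W2 - n * wbar * wbar)
    iu = np.triu_indices(m, k=1)
    num = float(var_hat[iu].sum())
    den = float((S[iu] ** 2).sum())
    if den == 0:
        return 1.0
    return float(np.clip(num / den, 0.0, 1.0))


def shrink(R_tilde: np.ndarray, lam: float) -> np.ndarray:
    """Convex combination (1 - lam) R~ + lam I of a correlation matrix with I."""
    R_tilde = np.asarray(R_tilde, dtype=float)
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lam must lie in [0, 1], got {lam}")
    if R_tilde.shape[0] != R_tilde.shape[1] or not np.allclose(R_tilde, R_tilde.T):
        raise ValueError("R_tilde must be symmetric")
    if not np.allclose(np.diag(R_tilde), 1.0):
        raise ValueError("R_tilde must have a unit diagonal")
    return (1.0 - lam) * R_tilde + lam * np.eye(R_tilde.shape[0])


@dataclass
class ShrinkageResult:
    """Regularized correlation matrix with its analytic intensity."""

    R_tilde: np.ndarray
    lambda_star: float
    R_star: np.ndarray


def shrink_analytic(columns: np.ndarray) -> ShrinkageResult:
    """Sample correlation of the columns shrunk by the analytic intensity."""
    R = sample_correlation(columns)
    lam = lambda_star(columns)
    return ShrinkageResult(R_tilde=R, lambda_star=lam, R_star=shrink(R, lam))


@dataclass
class MultipleCorrResult:
    """Regularized squared multiple correlation of Z with a set of columns T.

    ``value`` is the quadratic form R*_ZT' (R*_TT)^{-1} R*_ZT in [0, 1];
    ``eigenvalues_theta`` are the eigenvalues of the *unshrunken* empirical
    correlation of T, from which eig(R*_TT) = (1-lambda) theta + lambda.
    """

    value: float
    lambda_used: float
    eigenvalues_theta: np.ndarray
    R_ZT: np.ndarray
    mode: str


def reg_multiple_corr(
    Z: np.ndarray,
    T: np.ndarray,
    lam: Union[float, str] = "analytic",
    rcond: float = 1e-12,
) -> MultipleCorrResult:
    """Regularized squared multiple correlation between Z and the columns of T.

    The full (s+1) x (s+1) correlation matrix of (T, Z) is shrunk jointly --
    with the analytic intensity, every entry of R* depends on all columns --
    and the quadratic form is evaluated through the eigendecomposition of
    the empirical correlation of T.  With ``lam=0`` near-null eigenvalues
    (below ``rcond``) are dropped, i.e. a pseudo-inverse is used.
    """
    Z = np.asarray(Z, dtype=float).ravel()
    T = np.asarray(T, dtype=float)
    if T.ndim == 1:
        T = T[:, None]
    n, s = T.shape
    if Z.size != n:
        raise ValueError("Z and T have different numbers of rows")
    if n < 4:
        raise ValueError(f"need n >= 4, got {n}")
    joint = np.column_stack([T, Z])
    _check_columns(joint, min_n=4)

    R = sample_correlation(joint)
    if lam == "analytic":
        lam_val = lambda_star(joint)
        mode = "analytic-lambda"
    else:
        lam_val = float(lam)
        if not 0.0 <= lam_val <= 1.0:
            raise ValueError("lam must lie in [0, 1]")
        mode = "fixed-lambda"

    r_zt_star = (1.0 - lam_val) * R[s, :s]
    theta, Q = np.linalg.eigh(R[:s, :s])
    d = (1.0 - lam_val) * theta + lam_val
    proj = Q.T @ r_zt_star
    keep = d > rcond
    value = float(np.sum(proj[keep] ** 2 / d[keep]))
    value = float(np.clip(value, 0.0, 1.0))
    return MultipleCorrResult(
        value=value,
        lambda_used=lam_val,
        eigenvalues_theta=theta,
        R_ZT=r_zt_star,
        mode=mode,
    )
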