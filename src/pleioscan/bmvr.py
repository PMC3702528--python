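"""Bayesian multivariate regression (BMVR) marginal likelihoods and Bayes factors.

The model for an ``n x d`` response matrix ``Y`` with covariates ``X``
(``n x p``) is

    Y = X B + E,    rows of E iid N_d(0, Sigma),

with the conjugate prior ``Sigma ~ InvWishart(H, m)`` and
``B | Sigma ~ MatrixNormal(0, K, Sigma)`` where ``K`` is a diagonal matrix
of per-covariate prior variances.  Integrating out ``(B, Sigma)`` gives a
matrix-t marginal density for ``Y``, computed here entirely through
Cholesky log-determinants.

The Bayes factor for a partition ``gamma = (U, D, I)`` against the global
null compares the regression of ``Y_D`` on ``(intercept, Y_U, g)`` with the
regression of ``Y_D`` on ``(intercept, Y_U)``; the indirectly associated
traits drop out of the ratio.  In the limiting prior (intercept and
``Y_U``-coefficient scales to infinity, inverse-Wishart scale to zero) the
log Bayes factor has the closed form

    ln BF = ((n - d_D)/2) ln(1 + nu) - (n/2) ln(1 + nu * Lambda**(-2/n))

with ``nu = sigma_a**2 * g~'g~``, where ``g~`` is the genotype residual
after OLS on ``(intercept, Y_U)`` and ``Lambda`` is the classical Gaussian
likelihood-ratio statistic for the same comparison.  Both quantities — and
hence the BF — depend on the data only through the sample size and the
mean-centered cross-products ``(g'g, g'Y, Y'Y)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.special import gammaln

from .partitions import Partition

__all__ = [
    "Hyperparams",
    "SufficientStats",
    "LrtResult",
    "DegenerateCovariateError",
    "CollinearityError",
    "multivariate_gamma_log",
    "log_marginal_bmvr",
    "log_bf_partition",
    "log_bf_limit",
    "log_bf_limit_grid",
    "lrt_statistic",
    "prop1_bf_from_lrt",
]

LN10 = math.log(10.0)


class DegenerateCovariateError(ValueError):
    """Raised when the (centered) genotype has no variance."""


class CollinearityError(ValueError):
    """Raised when a design matrix is rank deficient."""


def multivariate_gamma_log(a: float, d: int) -> float:
    """log of the multivariate gamma function Gamma_d(a).

    ``log Gamma_d(a) = d(d-1)/4 * log(pi) + sum_{j=1}^{d} log Gamma(a + (1-j)/2)``.
    Requires ``a > (d-1)/2``.
    """
    if d < 1:
        raise ValueError("d must be >= 1")
    if a <= (d - 1) / 2.0:
        raise ValueError(f"multivariate gamma needs a > (d-1)/2, got a={a}, d={d}")
    j = np.arange(1, d + 1)
    return d * (d - 1) / 4.0 * math.log(math.pi) + float(np.sum(gammaln(a + (1.0 - j) / 2.0)))


# ---------------------------------------------------------------------------
# numerically-safe symmetric linear algebra


def _sym(M: np.ndarray) -> np.ndarray:
    return (M + M.T) / 2.0


def _chol(M: np.ndarray):
    """Cholesky factor of a symmetric PSD matrix, with escalating jitter
    (up to 1e-10 * trace) before failing."""
    M = _sym(np.asarray(M, dtype=float))
    scale = max(np.trace(M), 1.0)
    jitter = 0.0
    for _ in range(4):
        try:
            return cho_factor(M + jitter * np.eye(M.shape[0]), lower=True)
        except np.linalg.LinAlgError:
            jitter = max(jitter * 100.0, 1e-14 * scale)
            if jitter > 1e-10 * scale:
                break
    raise np.linalg.LinAlgError("matrix not positive definite (after jitter)")


def _chol_logdet(M: np.ndarray) -> float:
    c, _ = _chol(M)
    return 2.0 * float(np.sum(np.log(np.diag(c))))


@dataclass
class Hyperparams:
    """Prior hyperparameters for the BMVR Bayes factors.

    Parameters
    ----------
    sigma_a:
        Prior SD scale of the genotype effect sizes, in units of the
        residual SD of each trait.
    sigma_b:
        Prior SD scale for intercept / nuisance-covariate coefficients
        (finite mode only; the limit mode sends it to infinity, which is
        implemented by mean-centering).
    lambda_h:
        Inverse-Wishart scale multiplier, ``H = lambda_h * I`` (finite
        mode; the limit mode sends it to zero).
    m_df:
        Inverse-Wishart degrees of freedom.  A proper prior needs
        ``m_df > d - 1``; Bayes-factor ratios remain well defined down to
        ``m_df = 0`` because the prior normalization cancels.
    limit_mode:
        Use the limiting prior (sigma_b -> inf, lambda_h -> 0, m_df -> 0).
    """

    sigma_a: float = 0.4
    sigma_b: float = 1e6
    lambda_h: float = 1e-6
    m_df: float = 0.0
    limit_mode: bool = True

    def __post_init__(self):
        if self.sigma_a < 0:
            raise ValueError("sigma_a must be non-negative")
        if self.limit_mode:
            if self.sigma_a <= 0:
                raise ValueError("limit mode requires sigma_a > 0")
        else:
            if self.sigma_b <= 0 or self.lambda_h <= 0:
                raise ValueError("finite mode requires sigma_b > 0 and lambda_h > 0")
            if self.m_df < 0:
                raise ValueError("m_df must be non-negative")


@dataclass
class SufficientStats:
    """Per-SNP sufficient statistics: mean-centered cross-products.

    ``gtg = sum (g_i - gbar)^2``; ``gty[j] = sum (g_i - gbar)(y_ij - ybar_j)``;
    ``yty[j,k] = sum (y_ij - ybar_j)(y_ik - ybar_k)``.  Together with the
    sample size ``n`` these are the entire data interface of the Bayes
    factor computations.
    """

    n: int
    gtg: float
    gty: np.ndarray
    yty: np.ndarray
    trait_names: Optional[List[str]] = None

    def __post_init__(self):
        self.gty = np.asarray(self.gty, dtype=float).ravel()
        self.yty = _sym(np.asarray(self.yty, dtype=float))
        d = self.gty.shape[0]
        if self.yty.shape != (d, d):
            raise ValueError("gty and yty dimensions disagree")
        if self.gtg < 0:
            raise ValueError("gtg must be non-negative")
        scale = max(float(np.trace(self.yty)), 1.0)
        if float(np.linalg.eigvalsh(self.yty).min()) < -1e-8 * scale:
            raise ValueError("yty is not positive semi-definite")
        if self.trait_names is None:
            self.trait_names = [f"trait{j+1}" for j in range(d)]

    @property
    def d(self) -> int:
        return self.gty.shape[0]


@dataclass
class LrtResult:
    """Likelihood-ratio statistic for Y_D on (intercept, Y_U, g) vs (intercept, Y_U).

    ``wilks`` is the residual-determinant ratio |RSS_1|/|RSS_0| in (0, 1];
    ``lambda_stat = wilks**(-n/2) >= 1`` is the maximized likelihood ratio;
    ``g_resid_ss`` is the squared norm of the genotype residuals after OLS
    on (intercept, Y_U).
    """

    lambda_stat: float
    log_lambda: float
    wilks: float
    g_resid_ss: float
    n: int
    d_d: int
    p_u: int


# ---------------------------------------------------------------------------
# exact (finite-prior) matrix-t marginal likelihood


def log_marginal_bmvr(
    Y: np.ndarray,
    X: Optional[np.ndarray],
    k_diag: Union[Sequence[float], np.ndarray, None],
    lambda_h: float,
    m_df: float,
) -> float:
    """Exact log marginal likelihood of the conjugate BMVR (matrix-t density).

    ``k_diag`` holds the prior variances of the coefficient rows (one per
    column of ``X``); the caller includes an explicit intercept column if
    one is wanted.  ``X=None`` (or zero columns) gives the covariate-free
    model.  Requires a proper inverse-Wishart prior: ``m_df > d - 1``.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.ndim != 2:
        raise ValueError("Y must be an n x d matrix")
    n, d = Y.shape
    if lambda_h <= 0:
        raise ValueError("lambda_h must be positive")
    if m_df <= d - 1:
        raise ValueError(f"inverse-Wishart proper prior needs m_df > d-1 = {d-1}")
    if n + m_df <= d - 1:
        raise ValueError("insufficient rows for the matrix-t normalizer")

    yty = Y.T @ Y
    if X is None or (hasattr(X, "shape") and np.size(X) == 0):
        p = 0
        logdet_v = 0.0
        S = lambda_h * np.eye(d) + yty
    else:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        p = X.shape[1]
        k = np.asarray(k_diag, dtype=float).ravel()
        if k.shape[0] != p:
            raise ValueError("k_diag must have one entry per covariate column")
        if np.any(k <= 0):
            raise ValueError("prior variances must be positive")
        xtx = X.T @ X
        xty = X.T @ Y
        # |I_p + K X'X| and S = lambda I + Y'Y - Y'X (K^-1 + X'X)^-1 X'Y
        A = np.diag(1.0 / k) + xtx
        logdet_v = _chol_logdet(A) + float(np.sum(np.log(k)))
        cA = _chol(A)
        S = lambda_h * np.eye(d) + yty - xty.T @ cho_solve(cA, xty)

    return (
        -n * d / 2.0 * math.log(math.pi)
        + multivariate_gamma_log((n + m_df) / 2.0, d)
        - multivariate_gamma_log(m_df / 2.0, d)
        + d * m_df / 2.0 * math.log(lambda_h)
        - d / 2.0 * logdet_v
        - (n + m_df) / 2.0 * _chol_logdet(S)
    )


# ---------------------------------------------------------------------------
# partition Bayes factors


def _residual_blocks(stats: SufficientStats, gamma: Partition):
    """Cross-products of (g, Y_D) residualized on (intercept, Y_U).

    Returns ``(g2, b, W)`` where ``g2 = g~'g~``, ``b = Y_D~' g~`` and
    ``W = Y_D~' Y_D~`` (the null-model residual SSP matrix).
    """
    U = sorted(gamma.U)
    D = sorted(gamma.D)
    gty = stats.gty
    yty = stats.yty
    if U:
        cU = _chol(yty[np.ix_(U, U)])
        sol_g = cho_solve(cU, gty[U])
        sol_Y = cho_solve(cU, yty[np.ix_(U, D)])
        g2 = stats.gtg - float(gty[U] @ sol_g)
        b = gty[D] - yty[np.ix_(D, U)] @ sol_g
        W = yty[np.ix_(D, D)] - yty[np.ix_(D, U)] @ sol_Y
    else:
        g2 = stats.gtg
        b = gty[D].copy()
        W = yty[np.ix_(D, D)].copy()
    return g2, b, _sym(W)


def log_bf_limit(stats: SufficientStats, gamma: Partition, sigma_a: float) -> float:
    """log10 Bayes factor for partition ``gamma`` vs the global null, limiting prior.

    Requires ``n > d + 1`` and a non-degenerate centered genotype.
    """
    if gamma.d != stats.d:
        raise IndexError("partition dimension does not match the statistics")
    if gamma.is_null:
        return 0.0
    if sigma_a <= 0:
        raise ValueError("sigma_a must be positive")
    if stats.n <= stats.d + 1:
        raise ValueError("limit-mode BF needs n > d + 1")
    if stats.gtg <= 0:
        raise DegenerateCovariateError("genotype has zero variance after centering")

    g2, b, W = _residual_blocks(stats, gamma)
    if g2 <= 0:
        raise DegenerateCovariateError(
            "genotype is collinear with the unassociated traits"
        )
    d_d = len(gamma.D)
    nu = sigma_a ** 2 * g2
    cW = _chol(W)
    t = float(b @ cho_solve(cW, b)) / g2
    t = min(max(t, 0.0), 1.0 - 1e-15)  # Wilks ratio 1 - t lies in (0, 1]
    n = stats.n
    # ln BF = ((n - d_D)/2) ln(1+nu) - (n/2) ln(1 + nu (1 - t))
    ln_bf = (n - d_d) / 2.0 * math.log1p(nu) - n / 2.0 * math.log1p(nu * (1.0 - t))
    return ln_bf / LN10


def log_bf_limit_grid(
    stats: SufficientStats, gamma: Partition, sigma_grid: Sequence[float]
) -> np.ndarray:
    """log10 limiting BFs over a grid of ``sigma_a`` values (shared algebra)."""
    if gamma.is_null:
        return np.zeros(len(sigma_grid))
    g2, b, W = _residual_blocks(stats, gamma)
    if g2 <= 0:
        raise DegenerateCovariateError("degenerate genotype")
    cW = _chol(W)
    t = float(b @ cho_solve(cW, b)) / g2
    t = min(max(t, 0.0), 1.0 - 1e-15)
    n, d_d = stats.n, len(gamma.D)
    nu = np.asarray(sigma_grid, dtype=float) ** 2 * g2
    return ((n - d_d) / 2.0 * np.log1p(nu) - n / 2.0 * np.log1p(nu * (1.0 - t))) / LN10


def _log_bf_finite_centered(stats: SufficientStats, gamma: Partition, hyper: Hyperparams) -> float:
    """Finite-prior log10 BF from centered sufficient statistics.

    The intercept is handled by the centering (its flat limit); the
    ``Y_U`` coefficients carry prior variance ``sigma_b**2`` and the
    genotype coefficient ``sigma_a**2``.  Normalizing constants shared by
    the two models cancel, so the ratio is well defined for any
    ``m_df >= 0``, and converges to :func:`log_bf_limit` as
    ``sigma_b -> inf`` and ``lambda_h, m_df -> 0``.
    """
    U = sorted(gamma.U)
    D = sorted(gamma.D)
    d_d = len(D)
    lam, m = hyper.lambda_h, hyper.m_df
    yty = stats.yty

    def model(with_g: bool) -> Tuple[float, float]:
        cols_k = [hyper.sigma_b ** 2] * len(U) + ([hyper.sigma_a ** 2] if with_g else [])
        p = len(cols_k)
        ytyDD = yty[np.ix_(D, D)]
        if p == 0:
            return 0.0, _chol_logdet(lam * np.eye(d_d) + ytyDD)
        # X'X and X'Y blocks for X = [Y_U (, g)], all centered
        xtx = np.zeros((p, p))
        xty = np.zeros((p, d_d))
        nu_u = len(U)
        if nu_u:
            xtx[:nu_u, :nu_u] = yty[np.ix_(U, U)]
            xty[:nu_u, :] = yty[np.ix_(U, D)]
        if with_g:
            xtx[-1, -1] = stats.gtg
            if nu_u:
                xtx[:nu_u, -1] = stats.gty[U]
                xtx[-1, :nu_u] = stats.gty[U]
            xty[-1, :] = stats.gty[D]
        k = np.asarray(cols_k)
        A = np.diag(1.0 / k) + xtx
        logdet_v = _chol_logdet(A) + float(np.sum(np.log(k)))
        cA = _chol(A)
        S = lam * np.eye(d_d) + ytyDD - xty.T @ cho_solve(cA, xty)
        return logdet_v, _chol_logdet(S)

    ldv1, lds1 = model(True)
    ldv0, lds0 = model(False)
    ln_bf = -d_d / 2.0 * (ldv1 - ldv0) - (stats.n + m) / 2.0 * (lds1 - lds0)
    return ln_bf / LN10


def log_bf_partition(stats: SufficientStats, gamma: Partition, hyper: Hyperparams) -> float:
    """log10 Bayes factor of the partition model against the global null.

    In limit mode this is the closed-form limiting BF; in finite mode the
    exact conjugate-prior BF computed from the centered sufficient
    statistics.  Either way the value depends on the data only through
    ``(n, g'g, g'Y, Y'Y)``.
    """
    if gamma.d != stats.d:
        raise IndexError("partition dimension does not match the statistics")
    if gamma.is_null:
        return 0.0
    if hyper.limit_mode:
        return log_bf_limit(stats, gamma, hyper.sigma_a)
    return _log_bf_finite_centered(stats, gamma, hyper)


# ---------------------------------------------------------------------------
# classical likelihood-ratio statistic and the bridge to the limiting BF


def _ols_residuals(Y: np.ndarray, X: np.ndarray, what: str) -> np.ndarray:
    coef, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    if rank < X.shape[1]:
        raise CollinearityError(f"rank-deficient design matrix ({what})")
    return Y - X @ coef


def lrt_statistic(Y: np.ndarray, g: np.ndarray, gamma: Partition) -> LrtResult:
    """Gaussian likelihood-ratio statistic Lambda_gamma and the genotype residuals.

    Compares Y_D ~ (intercept, Y_U, g) against Y_D ~ (intercept, Y_U),
    maximizing over coefficients and the (unstructured) error covariance.
    ``Lambda = (|RSS_0| / |RSS_1|)**(n/2) >= 1``.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    g = np.asarray(g, dtype=float).ravel()
    n = Y.shape[0]
    if g.shape[0] != n:
        raise ValueError("Y and g row counts disagree")
    U = sorted(gamma.U)
    D = sorted(gamma.D)
    if not D:
        raise ValueError("the global null has no likelihood-ratio statistic")
    if n <= len(U) + 2:
        raise ValueError("need n > |U| + 2 observations")

    X0 = np.column_stack([np.ones(n)] + [Y[:, j] for j in U])
    X1 = np.column_stack([X0, g])
    Yd = Y[:, D]
    E0 = _ols_residuals(Yd, X0, "intercept+Y_U")
    E1 = _ols_residuals(Yd, X1, "intercept+Y_U+g")
    g_res = _ols_residuals(g[:, None], X0, "genotype on intercept+Y_U").ravel()

    ld0 = _chol_logdet(E0.T @ E0)
    ld1 = _chol_logdet(E1.T @ E1)
    log_lambda = max(n / 2.0 * (ld0 - ld1), 0.0)
    wilks = math.exp(-2.0 * log_lambda / n)
    lam = math.exp(log_lambda) if log_lambda < 700 else math.inf
    return LrtResult(
        lambda_stat=lam,
        log_lambda=log_lambda,
        wilks=wilks,
        g_resid_ss=float(g_res @ g_res),
        n=n,
        d_d=len(D),
        p_u=len(U),
    )


def prop1_bf_from_lrt(
    lrt: LrtResult,
    sigma_a: float,
    n: Optional[int] = None,
    d_d: Optional[int] = None,
) -> float:
    """log10 limiting BF reconstructed from the likelihood-ratio statistic.

    With ``nu = sigma_a**2 * g~'g~``:
    ``log10 BF = [((n - d_D)/2) ln(1+nu) - (n/2) ln(1 + nu Lambda**(-2/n))] / ln 10``.
    Equals :func:`log_bf_limit` on the same data.
    """
    if sigma_a <= 0:
        raise ValueError("sigma_a must be positive")
    n = lrt.n if n is None else n
    d_d = lrt.d_d if d_d is None else d_d
    nu = sigma_a ** 2 * lrt.g_resid_ss
    ln_bf = (n - d_d) / 2.0 * math.log1p(nu) - n / 2.0 * math.log1p(nu * lrt.wilks)
    return ln_bf / LN10
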