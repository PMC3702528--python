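"""Independent brute-force oracles for the conjugate-regression marginal likelihood.

These integrate the normal / matrix-normal / inverse-Wishart prior
numerically (dense-grid quadrature for d=1, plain Monte Carlo prior
averaging for d=2) and are deliberately independent of the analytic
matrix-t implementation they validate.
"""

import math

import numpy as np
from numpy import trapezoid
from scipy.special import logsumexp
from scipy.stats import invgamma, invwishart, norm


def quadrature_log_marginal_d1(Y, X, k_diag, lambda_h, m_df,
                               n_s2=240, n_coef=241):
    """Dense-grid integration of the d=1 normal-inverse-gamma marginal.

    p(y) = ∫∫∫ N(y; X b, s2 I) N(b; 0, s2 K) InvGamma(s2; m/2, lambda/2) db ds2
    """
    y = np.asarray(Y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = y.size
    assert X.shape[1] == 2, "oracle written for two coefficients"
    sb2, sa2 = k_diag
    s2g = np.exp(np.linspace(math.log(0.01), math.log(60.0), n_s2))
    mug = np.linspace(-12, 12, n_coef)
    beg = np.linspace(-8, 8, n_coef)
    MU, BE = np.meshgrid(mug, beg, indexing="ij")
    fitted = MU[..., None] * X[:, 0] + BE[..., None] * X[:, 1]
    rss = np.sum((y[None, None, :] - fitted) ** 2, axis=-1)
    vals = np.empty(n_s2)
    for i, s2 in enumerate(s2g):
        L = np.exp(-0.5 * rss / s2) / (2 * math.pi * s2) ** (n / 2)
        pB = norm.pdf(MU, 0, math.sqrt(s2 * sb2)) * norm.pdf(BE, 0, math.sqrt(s2 * sa2))
        inner = trapezoid(trapezoid(L * pB, beg, axis=1), mug)
        vals[i] = inner * invgamma.pdf(s2, m_df / 2.0, scale=lambda_h / 2.0)
    return math.log(trapezoid(vals, s2g))


def mc_log_marginal(Y, X, k_diag, lambda_h, m_df, n_draws=300_000, seed=0):
    """Prior-draw Monte Carlo average of the likelihood, with its log-scale SE.

    Returns (log estimate, standard error of the log estimate).
    """
    rng = np.random.default_rng(seed)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, d = Y.shape
    p = X.shape[1]
    k = np.asarray(k_diag, dtype=float)

    Sig = invwishart.rvs(df=m_df, scale=lambda_h * np.eye(d), size=n_draws,
                         random_state=rng)
    Sig = Sig.reshape(n_draws, d, d)
    Ls = np.linalg.cholesky(Sig)
    Z = rng.standard_normal((n_draws, p, d))
    B = (np.sqrt(k)[None, :, None] * Z) @ np.transpose(Ls, (0, 2, 1))
    R = Y[None] - np.einsum("np,bpd->bnd", X, B)
    Rt = np.transpose(R, (0, 2, 1))
    sol = np.linalg.solve(Sig, Rt)
    quad = np.einsum("bdn,bdn->b", Rt, sol)
    logdet = 2 * np.sum(np.log(np.diagonal(Ls, axis1=1, axis2=2)), axis=1)
    loglik = -0.5 * quad - n / 2.0 * logdet - n * d / 2.0 * math.log(2 * math.pi)

    log_mc = float(logsumexp(loglik) - math.log(n_draws))
    w = np.exp(loglik - loglik.max())
    se_log = float(np.std(w) / math.sqrt(n_draws) / np.mean(w))
    return log_mc, se_log


def reverse_regression_log_lambda(Y, g, gamma):
    """Note-2 oracle: LR statistic for g regressed on (Y_D, Y_U) vs Y_U alone.

    Plain scalar OLS on residual sums of squares, independent of
    lrt_statistic's multivariate determinant route.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    g = np.asarray(g, dtype=float).ravel()
    n = g.size
    U = sorted(gamma.U)
    D = sorted(gamma.D)
    X0 = np.column_stack([np.ones(n)] + [Y[:, j] for j in U])
    X1 = np.column_stack([X0] + [Y[:, j] for j in D])
    r0 = g - X0 @ np.linalg.lstsq(X0, g, rcond=None)[0]
    r1 = g - X1 @ np.linalg.lstsq(X1, g, rcond=None)[0]
    return n / 2.0 * (math.log(r0 @ r0) - math.log(r1 @ r1))
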