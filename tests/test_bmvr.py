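import math

import numpy as np
import pytest
from scipy.special import gammaln, multigammaln

from pleioscan import (
    Hyperparams,
    Partition,
    RawDataset,
    enumerate_partitions,
    log_bf_limit,
    log_bf_limit_grid,
    log_bf_partition,
    log_marginal_bmvr,
    lrt_statistic,
    multivariate_gamma_log,
    prop1_bf_from_lrt,
    special_partitions,
    sufficient_from_raw,
)
from pleioscan.bmvr import CollinearityError, DegenerateCovariateError

from helpers_oracles import (
    mc_log_marginal,
    quadrature_log_marginal_d1,
    reverse_regression_log_lambda,
)


def random_dataset(rng, n, d, effects=None, maf=0.3, rho=0.3):
    g = rng.binomial(2, maf, n).astype(float)
    R = np.full((d, d), rho) + (1 - rho) * np.eye(d)
    Y = rng.standard_normal((n, d)) @ np.linalg.cholesky(R).T
    if effects is not None:
        Y = Y + np.outer(g, effects)
    return Y, g


# ---------------------------------------------------------------------------
# multivariate gamma


def test_multivariate_gamma_reduces_to_scalar():
    for a in (0.7, 2.0, 13.5):
        assert multivariate_gamma_log(a, 1) == pytest.approx(float(gammaln(a)))


def test_multivariate_gamma_term_by_term():
    # Gamma_2(2) = pi^{1/2} Gamma(2) Gamma(1.5)
    expect = 0.5 * math.log(math.pi) + gammaln(2.0) + gammaln(1.5)
    assert multivariate_gamma_log(2.0, 2) == pytest.approx(float(expect))
    assert expect == pytest.approx(0.45158, abs=1e-5)
    # independent library oracle
    for a, d in [(2.3, 3), (5.0, 4), (1.1, 2)]:
        assert multivariate_gamma_log(a, d) == pytest.approx(float(multigammaln(a, d)))


def test_multivariate_gamma_monotone_and_domain():
    # monotone once every gamma-term argument passes the digamma root (~1.46)
    grid = np.linspace(2.5, 8.0, 30)
    vals = [multivariate_gamma_log(a, 3) for a in grid]
    assert np.all(np.diff(vals) > 0)
    with pytest.raises(ValueError):
        multivariate_gamma_log(1.0, 3)  # a <= (d-1)/2


# ---------------------------------------------------------------------------
# exact marginal likelihood vs integration oracles


def test_log_marginal_matches_quadrature_d1(rng):
    n = 5
    Y = rng.standard_normal((n, 1))
    X = np.column_stack([np.ones(n), rng.binomial(2, 0.3, n).astype(float)])
    k = (1.5 ** 2, 0.7 ** 2)
    mine = log_marginal_bmvr(Y, X, k, lambda_h=0.8, m_df=3.0)
    oracle = quadrature_log_marginal_d1(Y, X, k, lambda_h=0.8, m_df=3.0)
    assert abs(mine - oracle) < 1e-3


def test_log_marginal_matches_mc_d2(rng):
    n = 8
    Y = rng.standard_normal((n, 2))
    X = np.column_stack([np.ones(n), rng.binomial(2, 0.3, n).astype(float)])
    k = (2.0 ** 2, 0.5 ** 2)
    mine = log_marginal_bmvr(Y, X, k, lambda_h=1.2, m_df=4.0)
    mc, se = mc_log_marginal(Y, X, k, lambda_h=1.2, m_df=4.0,
                             n_draws=200_000, seed=5)
    assert abs(mine - mc) < 3 * se


def test_log_marginal_row_permutation_invariance(rng):
    n = 12
    Y = rng.standard_normal((n, 2))
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    v1 = log_marginal_bmvr(Y, X, (4.0, 0.25), 1.0, 3.0)
    perm = rng.permutation(n)
    v2 = log_marginal_bmvr(Y[perm], X[perm], (4.0, 0.25), 1.0, 3.0)
    assert v1 == pytest.approx(v2, abs=1e-10)


def test_log_marginal_df_validation(rng):
    Y = rng.standard_normal((6, 3))
    with pytest.raises(ValueError):
        log_marginal_bmvr(Y, None, None, lambda_h=1.0, m_df=1.0)  # improper IW


# ---------------------------------------------------------------------------
# partition Bayes factors


def test_null_partition_bf_is_zero(toy_raw):
    stats = sufficient_from_raw(toy_raw)
    assert log_bf_limit(stats, Partition(d=3), 0.4) == 0.0
    hyp = Hyperparams(sigma_a=0.4, limit_mode=False, sigma_b=10.0,
                      lambda_h=0.5, m_df=4.0)
    assert log_bf_partition(stats, Partition(d=3), hyp) == 0.0


def test_all_direct_partition_equals_bf_all(toy_raw):
    """A partition with U = I = empty is definitionally the full multivariate BF."""
    stats = sufficient_from_raw(toy_raw)
    gamma_all, _ = special_partitions(3)
    direct = Partition(d=3, D=frozenset({0, 1, 2}))
    assert log_bf_limit(stats, direct, 0.3) == log_bf_limit(stats, gamma_all, 0.3)


def test_finite_bf_matches_mc_oracle_ratio(rng):
    """BF as the ratio of two marginal likelihoods, each integrated by MC."""
    n, d = 6, 2
    Y, g = random_dataset(rng, n, d, effects=[0.8, 0.0])
    gamma = Partition(d=2, D=frozenset({0}), I=frozenset({1}))
    # numerator: Y_D on (1, g); denominator: Y_D on (1) -- U empty here
    Yd = Y[:, [0]]
    X1 = np.column_stack([np.ones(n), g])
    X0 = np.ones((n, 1))
    sb2, sa2, lam, m = 100.0, 0.5 ** 2, 0.7, 2.0
    analytic = (log_marginal_bmvr(Yd, X1, (sb2, sa2), lam, m)
                - log_marginal_bmvr(Yd, X0, (sb2,), lam, m))
    num, se1 = mc_log_marginal(Yd, X1, (sb2, sa2), lam, m, n_draws=200_000, seed=1)
    den, se2 = mc_log_marginal(Yd, X0, (sb2,), lam, m, n_draws=200_000, seed=2)
    se = math.hypot(se1, se2)
    assert abs(analytic - (num - den)) < max(3 * se, 0.01 * math.log(10))


def test_finite_prior_converges_to_limit(toy_raw):
    """Monotone approach to the limiting BF as sigma_b -> inf, lambda, m -> 0."""
    stats = sufficient_from_raw(toy_raw)
    gamma = Partition(d=3, D=frozenset({0, 2}), I=frozenset({1}))
    target = log_bf_limit(stats, gamma, 0.4)
    errs = []
    for sb, lam, m in [(1e2, 1e-2, 1e-2), (1e4, 1e-4, 1e-4), (1e6, 1e-6, 1e-6)]:
        hyp = Hyperparams(sigma_a=0.4, sigma_b=sb, lambda_h=lam, m_df=m,
                          limit_mode=False)
        errs.append(abs(log_bf_partition(stats, gamma, hyp) - target))
    assert errs[0] > errs[1] > errs[2]
    assert errs[2] < 1e-4


def test_bf_depends_only_on_sufficient_stats(rng):
    """Lemma-style contract: identical (n, g'g, g'Y, Y'Y) -> identical BFs."""
    n, d = 40, 3
    Y, g = random_dataset(rng, n, d, effects=[0.4, 0.2, 0.0])
    stats = sufficient_from_raw(RawDataset(Y=Y, g=g))
    # a different dataset realizing the same cross-products: rotate rows by
    # an orthogonal matrix fixing the all-ones direction (centering-safe)
    from scipy.stats import ortho_group

    M = np.eye(n)
    Q = ortho_group.rvs(n - 1, random_state=7)
    # basis of the centered subspace
    A = np.linalg.qr(np.column_stack([np.ones(n), rng.standard_normal((n, n - 1))]))[0]
    M = A @ np.block([[np.ones((1, 1)), np.zeros((1, n - 1))],
                      [np.zeros((n - 1, 1)), Q]]) @ A.T
    Y2, g2 = M @ Y, M @ g
    stats2 = sufficient_from_raw(RawDataset(Y=Y2, g=g2))
    for gamma in enumerate_partitions(d)[1:]:
        assert log_bf_limit(stats, gamma, 0.3) == pytest.approx(
            log_bf_limit(stats2, gamma, 0.3), abs=1e-8
        )


def test_degenerate_genotype_raises(rng):
    Y = rng.standard_normal((20, 2))
    with pytest.raises(DegenerateCovariateError):
        sufficient_from_raw(RawDataset(Y=Y, g=np.ones(20)))


# ---------------------------------------------------------------------------
# likelihood-ratio statistic


def test_lrt_zero_coefficient_gives_lambda_one():
    # orthogonal genotype: g residual exactly uncorrelated with the response
    n = 8
    g = np.array([1.0, -1.0] * 4)
    y = np.array([1.0, 1.0, -1.0, -1.0] * 2)
    res = lrt_statistic(y[:, None], g, Partition(d=1, D=frozenset({0})))
    assert res.lambda_stat == pytest.approx(1.0, abs=1e-10)
    assert res.wilks == pytest.approx(1.0, abs=1e-12)


def test_lrt_scalar_ols_oracle(rng):
    """d=1: Lambda^(2/n) must equal RSS_null / RSS_full from scalar OLS."""
    n = 30
    Y, g = random_dataset(rng, n, 1, effects=[0.5])
    res = lrt_statistic(Y, g, Partition(d=1, D=frozenset({0})))
    y = Y[:, 0]
    X0, X1 = np.ones((n, 1)), np.column_stack([np.ones(n), g])
    r0 = y - X0 @ np.linalg.lstsq(X0, y, rcond=None)[0]
    r1 = y - X1 @ np.linalg.lstsq(X1, y, rcond=None)[0]
    assert res.lambda_stat ** (2.0 / n) == pytest.approx((r0 @ r0) / (r1 @ r1),
                                                         rel=1e-10)
    assert res.g_resid_ss == pytest.approx(np.sum((g - g.mean()) ** 2), rel=1e-10)


@pytest.mark.parametrize("seed", range(5))
def test_reverse_regression_equality(seed):
    """Forward and reverse regressions give the same likelihood-ratio statistic."""
    rng = np.random.default_rng(seed)
    Y, g = random_dataset(rng, 50, 4, effects=[0.4, 0.3, 0.0, 0.0])
    gamma = Partition(d=4, D=frozenset({0, 1}), I=frozenset({2}))
    forward = lrt_statistic(Y, g, gamma).log_lambda
    reverse = reverse_regression_log_lambda(Y, g, gamma)
    assert forward == pytest.approx(reverse, abs=1e-8)


def test_lrt_collinearity_error(rng):
    # a constant U trait is collinear with the intercept
    Y = np.column_stack([rng.standard_normal(20), np.ones(20)])
    g = rng.binomial(2, 0.4, 20).astype(float)
    with pytest.raises(CollinearityError):
        lrt_statistic(Y, g, Partition(d=2, D=frozenset({0})))


def test_manova_concordance(rng):
    """Wilks' lambda and its F-test match statsmodels MANOVA."""
    sm = pytest.importorskip("statsmodels.multivariate.manova")
    n = 80
    Y, g = random_dataset(rng, n, 3, effects=[0.3, 0.2, 0.0])
    gamma = Partition(d=3, D=frozenset({0, 1, 2}))
    res = lrt_statistic(Y, g, gamma)
    mv = sm.MANOVA(endog=Y, exog=np.column_stack([np.ones(n), g]))
    tab = mv.mv_test().results["x1"]["stat"]
    wilks_sm = float(tab.loc["Wilks' lambda", "Value"])
    p_sm = float(tab.loc["Wilks' lambda", "Pr > F"])
    assert res.wilks == pytest.approx(wilks_sm, abs=1e-8)
    # exact F transform for a single-df hypothesis
    from scipy.stats import f as fdist

    d_d, q = 3, 2  # responses; columns of the null design (intercept only + g?)
    df2 = n - 2 - d_d + 1
    F = (1 - res.wilks) / res.wilks * df2 / d_d
    p_mine = fdist.sf(F, d_d, df2)
    assert p_mine == pytest.approx(p_sm, abs=1e-8)


# ---------------------------------------------------------------------------
# the bridge between the limiting BF and the LRT


@pytest.mark.parametrize("seed", range(10))
def test_dual_path_equality(seed):
    """Closed-form limiting BF equals the LRT-bridge reconstruction."""
    rng = np.random.default_rng(seed)
    Y, g = random_dataset(rng, 50, 3, effects=[0.4, 0.0, 0.2])
    stats = sufficient_from_raw(RawDataset(Y=Y, g=g))
    for gamma in enumerate_partitions(3)[1:]:
        direct = log_bf_limit(stats, gamma, 0.35)
        bridge = prop1_bf_from_lrt(lrt_statistic(Y, g, gamma), 0.35)
        assert direct == pytest.approx(bridge, abs=1e-8)


def test_lambda_one_bf_never_exceeds_one(rng):
    """With no likelihood gain the prior penalty makes BF <= 1."""
    from pleioscan.bmvr import LrtResult

    for nu_scale in (0.1, 1.0, 10.0):
        lrt = LrtResult(lambda_stat=1.0, log_lambda=0.0, wilks=1.0,
                        g_resid_ss=50.0, n=100, d_d=2, p_u=1)
        assert prop1_bf_from_lrt(lrt, nu_scale) <= 0.0


def test_bf_monotone_in_lambda():
    """Fixed data scale: BF strictly increases with the LR statistic."""
    from pleioscan.bmvr import LrtResult

    n = 100
    vals = []
    for log_lambda in np.linspace(0.0, 40.0, 15):
        lrt = LrtResult(lambda_stat=math.exp(min(log_lambda, 700)),
                        log_lambda=log_lambda,
                        wilks=math.exp(-2 * log_lambda / n),
                        g_resid_ss=60.0, n=n, d_d=2, p_u=0)
        vals.append(prop1_bf_from_lrt(lrt, 0.4))
    assert np.all(np.diff(vals) > 0)


def test_affine_invariance_of_bf_all(rng):
    """BF for the all-direct partition is invariant to invertible affine maps of Y."""
    n, d = 60, 3
    Y, g = random_dataset(rng, n, d, effects=[0.3, 0.2, 0.1])
    gamma_all, _ = special_partitions(d)
    base = log_bf_limit(sufficient_from_raw(RawDataset(Y=Y, g=g)), gamma_all, 0.4)
    for seed in range(5):
        r2 = np.random.default_rng(seed)
        A = r2.standard_normal((d, d)) + 2 * np.eye(d)
        shift = r2.standard_normal(d)
        Yt = Y @ A.T + shift
        val = log_bf_limit(sufficient_from_raw(RawDataset(Y=Yt, g=g)), gamma_all, 0.4)
        assert abs(val - base) <= 1e-6 * max(abs(base), 1.0)


def test_rank_equivalence_with_lrt(rng):
    """With per-SNP sigma_a = c / ||g~||, BF_all ranks SNPs exactly as Lambda."""
    n, d = 120, 3
    gamma_all, _ = special_partitions(d)
    log_lams, bfs = [], []
    for _ in range(60):
        Y, g = random_dataset(rng, n, d,
                              effects=rng.normal(0, 0.15, d))
        lrt = lrt_statistic(Y, g, gamma_all)
        sigma = 0.5 / math.sqrt(lrt.g_resid_ss)
        bfs.append(prop1_bf_from_lrt(lrt, sigma))
        log_lams.append(lrt.log_lambda)
    order_bf = np.argsort(bfs)
    order_lam = np.argsort(log_lams)
    assert np.array_equal(order_bf, order_lam)


def test_grid_variant_matches_scalar(toy_raw):
    stats = sufficient_from_raw(toy_raw)
    gamma = Partition(d=3, D=frozenset({0}), I=frozenset({1}))
    grid = [0.05, 0.2, 0.8]
    vals = log_bf_limit_grid(stats, gamma, grid)
    for s, v in zip(grid, vals):
        assert v == pytest.approx(log_bf_limit(stats, gamma, s), abs=1e-12)
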