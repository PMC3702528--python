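"""Combining partition Bayes factors: averaging, posteriors, screening, scanning.

The overall evidence against the global null is the prior-weighted average

    BF_av = sum_gamma sum_k w_gamma pi_k BF(gamma, sigma_k),

with two classical special cases: ``BF_all`` (all prior weight on the
all-direct partition — the standard multivariate test) and ``BF_uni``
(weight 1/d on each univariate-test partition).  Posterior partition
probabilities follow Bayes' rule, ``P(gamma | data) ∝ prior(gamma) BF(gamma)``,
and the posterior null probability is
``p_null = pi0 / (pi0 + (1 - pi0) BF_av)``.

A genome scan applies a cheap chi-square screen (the multivariate statistic
``z' R^-1 z`` on d df and each ``z_j**2`` on 1 df) and then evaluates every
partition for the surviving SNPs; reported top hits are de-duplicated by a
greedy distance rule (drop any SNP within a window of a higher-ranked one).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.special import logsumexp
from scipy.stats import chi2

from .bmvr import LN10, DegenerateCovariateError, SufficientStats, _chol, log_bf_limit_grid
from .partitions import Partition, PartitionPrior, enumerate_partitions, special_partitions
from .summary import CorrelationEstimate, SnpSummaryRecord, sufficient_from_z

__all__ = [
    "BFTable",
    "PosteriorSummary",
    "bf_av",
    "compute_bf_table",
    "posterior_partitions",
    "permutation_pvalue",
    "stage1_pvalues",
    "stage1_screen",
    "ld_prune_by_distance",
    "scan",
    "ScanOutput",
]


@dataclass
class BFTable:
    """Per-SNP log10 Bayes factors over (partition, sigma_a grid) cells."""

    snp_id: str
    partitions: List[Partition]
    sigma_grid: np.ndarray
    log10_bf: np.ndarray  # shape (n_partitions, n_grid)
    log10_bf_av: float
    log10_bf_all: float
    log10_bf_uni: float
    chrom: str = ""
    pos: int = 0

    def cell(self, gamma: Partition, k: int) -> float:
        return float(self.log10_bf[self.partitions.index(gamma), k])


@dataclass
class PosteriorSummary:
    """Posterior over partitions and per-trait category membership."""

    p_null: float
    partition_probs: Dict[Partition, float]
    trait_category_probs: np.ndarray  # d x 3, columns (U, D, I)
    p_assoc_per_trait: np.ndarray
    trait_names: Optional[List[str]] = None

    def top_partitions(self, k: int = 3) -> List[Tuple[Partition, float]]:
        items = sorted(self.partition_probs.items(), key=lambda t: -t[1])
        return items[:k]


def _weight_vectors(
    partitions: Sequence[Partition],
    prior: PartitionPrior,
    sigma_weights: Sequence[float],
) -> Tuple[np.ndarray, np.ndarray]:
    w = np.array([prior.weight(g) if not g.is_null else 0.0 for g in partitions])
    pk = np.asarray(sigma_weights, dtype=float)
    if pk.size and not math.isclose(pk.sum(), 1.0, abs_tol=1e-8):
        raise ValueError("sigma grid weights must sum to 1")
    if w.sum() <= 0:
        raise ValueError("prior places no weight on any non-null partition")
    return w, pk


def bf_av(
    partitions: Sequence[Partition],
    log10_bfs: np.ndarray,
    prior: PartitionPrior,
    sigma_weights: Sequence[float],
) -> float:
    """log10 of the prior-weighted average BF (log-sum-exp, never overflows)."""
    log10_bfs = np.atleast_2d(np.asarray(log10_bfs, dtype=float))
    w, pk = _weight_vectors(partitions, prior, sigma_weights)
    lw = np.log(np.outer(w, pk), where=np.outer(w, pk) > 0,
                out=np.full((w.size, pk.size), -np.inf))
    return float(logsumexp(log10_bfs * LN10 + lw)) / LN10


def _log10_bf_per_partition(log10_bfs: np.ndarray, sigma_weights: np.ndarray) -> np.ndarray:
    """Average each partition's BF over the sigma_a grid (in log10 space)."""
    lpk = np.log(sigma_weights, where=sigma_weights > 0,
                 out=np.full(len(sigma_weights), -np.inf))
    return logsumexp(log10_bfs * LN10 + lpk[None, :], axis=1) / LN10


def posterior_partitions(
    partitions: Sequence[Partition],
    log10_bfs: np.ndarray,
    prior: PartitionPrior,
    sigma_weights: Sequence[float],
    trait_names: Optional[List[str]] = None,
) -> PosteriorSummary:
    """Posterior partition probabilities and per-trait {U, D, I} marginals."""
    log10_bfs = np.atleast_2d(np.asarray(log10_bfs, dtype=float))
    w, pk = _weight_vectors(partitions, prior, sigma_weights)
    d = partitions[0].d

    bf_gamma = _log10_bf_per_partition(log10_bfs, pk)  # log10 BF per partition
    lw = np.log(w, where=w > 0, out=np.full(w.size, -np.inf))
    log_alt = bf_gamma * LN10 + lw  # ln(w_gamma * BF_gamma)

    pi0 = prior.pi0
    log_terms = np.concatenate([[math.log(pi0) if pi0 > 0 else -np.inf],
                                (math.log1p(-pi0) if pi0 < 1 else -np.inf) + log_alt])
    log_norm = logsumexp(log_terms)
    probs = np.exp(log_terms - log_norm)
    p_null = float(probs[0])

    # Eq.-(9)-style p_null from BF_av must agree with the normalized table.
    log10_bf_av = float(logsumexp(log_alt)) / LN10
    if 0 < pi0 < 1:
        p_null_eq9 = pi0 / (pi0 + (1 - pi0) * 10 ** log10_bf_av)
        if 10 ** log10_bf_av < np.inf and abs(p_null - p_null_eq9) > 1e-10:
            raise AssertionError("posterior null mass disagrees with the BF_av route")

    partition_probs: Dict[Partition, float] = {}
    cat = np.zeros((d, 3))  # columns U, D, I
    null_gamma = None
    for gamma, p in zip(partitions, probs[1:]):
        if gamma.is_null:
            null_gamma = gamma
            continue
        partition_probs[gamma] = float(p)
        for j in range(d):
            cat[j, "UDI".index(gamma.category(j))] += p
    cat[:, 0] += p_null  # the null partition has every trait in U
    # w assigns 0 to the null partition, so its table entry carries no mass
    if null_gamma is not None:
        partition_probs.pop(null_gamma, None)

    row_sums = cat.sum(axis=1, keepdims=True)
    cat = cat / np.where(row_sums > 0, row_sums, 1.0)
    p_assoc = 1.0 - cat[:, 0]
    return PosteriorSummary(
        p_null=p_null,
        partition_probs=partition_probs,
        trait_category_probs=cat,
        p_assoc_per_trait=p_assoc,
        trait_names=trait_names,
    )


def compute_bf_table(
    stats: SufficientStats,
    sigma_grid: Sequence[float],
    prior: PartitionPrior,
    sigma_weights: Optional[Sequence[float]] = None,
    partitions: Optional[List[Partition]] = None,
    snp_id: str = "",
    chrom: str = "",
    pos: int = 0,
) -> BFTable:
    """Limiting-prior log10 BFs for every partition over the sigma_a grid."""
    d = stats.d
    if partitions is None:
        partitions = enumerate_partitions(d)
    sigma_grid = np.asarray(sigma_grid, dtype=float)
    if sigma_weights is None:
        sigma_weights = np.full(sigma_grid.size, 1.0 / sigma_grid.size)
    bf = np.zeros((len(partitions), sigma_grid.size))
    for i, gamma in enumerate(partitions):
        if not gamma.is_null:
            bf[i] = log_bf_limit_grid(stats, gamma, sigma_grid)

    gamma_all, gamma_uni = special_partitions(d)
    idx = {g: i for i, g in enumerate(partitions)}
    pk = np.asarray(sigma_weights, dtype=float)
    per_part = _log10_bf_per_partition(bf, pk)

    def _per_partition_bf(gamma: Partition) -> float:
        if gamma in idx:
            return float(per_part[idx[gamma]])
        row = log_bf_limit_grid(stats, gamma, sigma_grid)
        return float(_log10_bf_per_partition(row[None, :], pk)[0])

    log10_all = _per_partition_bf(gamma_all)
    log10_uni = float(
        logsumexp([_per_partition_bf(g) * LN10 for g in gamma_uni]) - math.log(d)
    ) / LN10
    log10_av = bf_av(partitions, bf, prior, pk)
    return BFTable(
        snp_id=snp_id,
        partitions=list(partitions),
        sigma_grid=sigma_grid,
        log10_bf=bf,
        log10_bf_av=log10_av,
        log10_bf_all=log10_all,
        log10_bf_uni=log10_uni,
        chrom=chrom,
        pos=pos,
    )


# ---------------------------------------------------------------------------
# vectorized limiting BFs for many genotype cross-product vectors at once


class _PartitionProjector:
    """Precomputed projections for one partition, reused across many
    genotype vectors sharing the phenotype cross-product structure.

    Supports two regimes: a fixed ``yty`` matrix with scalar ``n``
    (e.g. permutations of one dataset), or ``yty_i = n_i * R`` with per-SNP
    sample sizes (summary-statistic scans).
    """

    def __init__(self, gamma: Partition, yty_base: np.ndarray):
        self.gamma = gamma
        self.U = sorted(gamma.U)
        self.D = sorted(gamma.D)
        B = np.asarray(yty_base, dtype=float)
        if self.U:
            cU = cho_factor((B[np.ix_(self.U, self.U)] +
                             B[np.ix_(self.U, self.U)].T) / 2.0, lower=True)
            self._cU = cU
            self._M = cho_solve(cU, B[np.ix_(self.U, self.D)])
            Ws = B[np.ix_(self.D, self.D)] - B[np.ix_(self.D, self.U)] @ self._M
        else:
            self._cU = None
            self._M = None
            Ws = B[np.ix_(self.D, self.D)]
        self._cW = cho_factor((Ws + Ws.T) / 2.0, lower=True)

    def log10bf(
        self,
        gtg: np.ndarray,
        gty: np.ndarray,
        n: np.ndarray,
        sigma_grid: np.ndarray,
        yty_scales_with_n: bool,
    ) -> np.ndarray:
        """log10 BFs, shape (batch, n_grid)."""
        gty = np.atleast_2d(gty)
        gtg = np.broadcast_to(np.asarray(gtg, dtype=float), (gty.shape[0],))
        n = np.broadcast_to(np.asarray(n, dtype=float), (gty.shape[0],))
        c = n if yty_scales_with_n else np.ones_like(n)

        gU = gty[:, self.U]
        gD = gty[:, self.D]
        if self.U:
            sol = cho_solve(self._cU, gU.T)  # |U| x B
            g2 = gtg - np.einsum("bu,ub->b", gU, sol) / c
            b = gD - gU @ self._M
        else:
            g2 = gtg.astype(float).copy()
            b = gD
        bad = g2 <= 0
        g2 = np.where(bad, np.nan, g2)
        q = np.einsum("bd,db->b", b, cho_solve(self._cW, b.T)) / c
        t = np.clip(q / g2, 0.0, 1.0 - 1e-15)
        nu = np.asarray(sigma_grid, dtype=float)[None, :] ** 2 * g2[:, None]
        d_d = len(self.D)
        out = ((n[:, None] - d_d) / 2.0 * np.log1p(nu)
               - n[:, None] / 2.0 * np.log1p(nu * (1.0 - t)[:, None])) / LN10
        out[bad] = np.nan
        return out


def permutation_pvalue(
    Y: np.ndarray,
    g: np.ndarray,
    prior: PartitionPrior,
    sigma_grid: Sequence[float],
    sigma_weights: Optional[Sequence[float]] = None,
    n_perm: int = 999,
    seed: int = 0,
) -> Tuple[float, np.ndarray]:
    """Permutation p-value for log10 BF_av against the global null.

    The genotype vector is permuted against the phenotype rows; the add-one
    estimator ``p = (1 + #{permuted >= observed}) / (n_perm + 1)`` avoids
    zero p-values.  Only the genotype-phenotype cross-products change under
    permutation, so the null draws are computed in a vectorized batch.
    """
    if n_perm < 99:
        import warnings

        warnings.warn("n_perm < 99 gives a coarse permutation p-value")
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    g = np.asarray(g, dtype=float).ravel()
    n, d = Y.shape
    sigma_grid = np.asarray(sigma_grid, dtype=float)
    if sigma_weights is None:
        sigma_weights = np.full(sigma_grid.size, 1.0 / sigma_grid.size)
    pk = np.asarray(sigma_weights, dtype=float)

    rng = np.random.default_rng(seed)
    gc = g - g.mean()
    Yc = Y - Y.mean(axis=0)
    yty = Yc.T @ Yc
    gtg = float(gc @ gc)
    if gtg <= 0:
        raise DegenerateCovariateError("genotype has zero variance")

    partitions = enumerate_partitions(d)
    nonnull = [gm for gm in partitions if not gm.is_null]
    projectors = [_PartitionProjector(gm, yty) for gm in nonnull]
    w = np.array([prior.weight(gm) for gm in nonnull])
    lw = np.log(np.outer(w, pk), where=np.outer(w, pk) > 0,
                out=np.full((w.size, pk.size), -np.inf))

    G = np.empty((n_perm + 1, n))
    G[0] = gc
    for i in range(1, n_perm + 1):
        G[i] = gc[rng.permutation(n)]
    GTY = G @ Yc  # (B, d); centering is permutation-invariant

    log_cells = np.stack(
        [pr.log10bf(gtg, GTY, n, sigma_grid, yty_scales_with_n=False)
         for pr in projectors], axis=1,
    )  # (B, P, K)
    stats_all = logsumexp(log_cells * LN10 + lw[None, :, :], axis=(1, 2)) / LN10
    observed, null_draws = stats_all[0], stats_all[1:]
    p = (1.0 + float(np.sum(null_draws >= observed))) / (n_perm + 1.0)
    return p, null_draws


# ---------------------------------------------------------------------------
# two-stage genome scan


def stage1_pvalues(records: Sequence[SnpSummaryRecord], R: CorrelationEstimate) -> pd.DataFrame:
    """Multivariate (chi^2 on d df) and univariate (chi^2 on 1 df) screen p-values."""
    d = R.d
    Z = np.array([r.z for r in records])
    cR = _chol(R.R)
    mv = np.einsum("md,dm->m", Z, cho_solve(cR, Z.T))
    p_mv = chi2.sf(mv, df=d)
    p_uni = chi2.sf(Z ** 2, df=1)
    return pd.DataFrame({
        "snp_id": [r.snp_id for r in records],
        "stat_mv": mv,
        "p_mv": p_mv,
        "p_min_uni": p_uni.min(axis=1),
        "p_min": np.minimum(p_mv, p_uni.min(axis=1)),
    })


def stage1_screen(
    records: Sequence[SnpSummaryRecord],
    R: CorrelationEstimate,
    p_threshold: float = 1e-4,
) -> List[SnpSummaryRecord]:
    """Keep SNPs whose best screen p-value falls below the threshold."""
    if not records:
        return []
    tab = stage1_pvalues(records, R)
    keep = tab["p_min"].to_numpy() < p_threshold
    return [r for r, k in zip(records, keep) if k]


def ld_prune_by_distance(results: pd.DataFrame, window: int = 500_000) -> pd.DataFrame:
    """Greedy distance de-duplication of ranked scan results.

    Expects columns ``snp_id, chrom, pos, log10_bf_av``; keeps a SNP iff no
    previously kept SNP on the same chromosome lies within ``window`` bp.
    Ties in BF are broken by (chrom, pos).
    """
    for col in ("chrom", "pos", "log10_bf_av"):
        if col not in results.columns:
            raise ValueError(f"results must carry a {col!r} column")
    if results["pos"].isna().any():
        raise ValueError("missing positions")
    ranked = results.sort_values(
        ["log10_bf_av", "chrom", "pos"], ascending=[False, True, True],
        kind="mergesort",
    )
    kept_pos: Dict[str, List[int]] = {}
    keep_idx = []
    for idx, row in ranked.iterrows():
        positions = kept_pos.setdefault(str(row["chrom"]), [])
        if all(abs(int(row["pos"]) - p) > window for p in positions):
            keep_idx.append(idx)
            positions.append(int(row["pos"]))
    return ranked.loc[keep_idx]


@dataclass
class ScanOutput:
    table: pd.DataFrame
    bf_tables: List[BFTable] = field(default_factory=list)


def scan(
    records: Sequence[SnpSummaryRecord],
    R: CorrelationEstimate,
    prior: PartitionPrior,
    sigma_grid: Sequence[float],
    sigma_weights: Optional[Sequence[float]] = None,
    pi0: Optional[float] = None,
    stage1_p: float = 1e-4,
    prune_window: Optional[int] = None,
    trait_names: Optional[List[str]] = None,
) -> ScanOutput:
    """Two-stage scan: chi-square screen, then all-partition BFs for survivors.

    Output rows are sorted by descending log10 BF_av and carry the posterior
    null probability, per-trait {U, D, I} probabilities and the top-3
    partitions.  ``prune_window`` applies the greedy distance rule.
    """
    d = R.d
    partitions = enumerate_partitions(d)
    sigma_grid = np.asarray(sigma_grid, dtype=float)
    if sigma_weights is None:
        sigma_weights = np.full(sigma_grid.size, 1.0 / sigma_grid.size)
    if pi0 is not None:
        prior = PartitionPrior(d=d, pi0=pi0, weights=prior.weights)

    promising = stage1_screen(records, R, stage1_p)
    rows = []
    tables: List[BFTable] = []
    for rec in promising:
        stats = sufficient_from_z(rec, R)
        if trait_names is not None:
            stats.trait_names = list(trait_names)
        tab = compute_bf_table(
            stats, sigma_grid, prior, sigma_weights,
            partitions=partitions, snp_id=rec.snp_id, chrom=rec.chrom, pos=rec.pos,
        )
        post = posterior_partitions(partitions, tab.log10_bf, prior, sigma_weights)
        row = {
            "snp_id": rec.snp_id,
            "chrom": rec.chrom,
            "pos": rec.pos,
            "log10_bf_av": tab.log10_bf_av,
            "log10_bf_all": tab.log10_bf_all,
            "log10_bf_uni": tab.log10_bf_uni,
            "p_null": post.p_null,
        }
        for j, name in enumerate(stats.trait_names):
            for ci, cname in enumerate("UDI"):
                row[f"p_{cname}_{name}"] = post.trait_category_probs[j, ci]
        for rank, (gm, p) in enumerate(post.top_partitions(3), start=1):
            row[f"top{rank}_partition"] = gm.to_string()
            row[f"top{rank}_prob"] = p
        rows.append(row)
        tables.append(tab)

    if rows:
        table = pd.DataFrame(rows).sort_values(
            ["log10_bf_av", "chrom", "pos"], ascending=[False, True, True],
            kind="mergesort",
        ).reset_index(drop=True)
    else:
        table = pd.DataFrame(
            columns=["snp_id", "chrom", "pos", "log10_bf_av", "log10_bf_all",
                     "log10_bf_uni", "p_null"]
        )
    if prune_window is not None and len(table):
        table = ld_prune_by_distance(table, prune_window).reset_index(drop=True)
    return ScanOutput(table=table, bf_tables=tables)
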