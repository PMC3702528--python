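"""Empirical-Bayes mixture weights over (partition, sigma_a) cells, fit by EM.

Given per-SNP Bayes factors BF_i(gamma, k) for a set of (presumed
associated) SNPs, the mixture likelihood

    L(w) = prod_i sum_{gamma,k} w_{gamma,k} BF_i(gamma, k)

is maximized over the probability vector ``w`` by
expectation-maximization: responsibilities ``r_i ∝ w * BF_i`` (E-step),
then ``w = mean_i r_i`` (M-step).  Because the selected SNPs are the
strongest associations, the fitted weights are biased towards larger
effects and richer partitions; they remain useful as a data-driven prior
for classifying those same SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.special import logsumexp

from .bmvr import LN10
from .inference import BFTable
from .partitions import Partition, PartitionPrior, enumerate_partitions

__all__ = ["EBWeights", "em_fit", "posterior_with_eb", "bf_matrix_from_tables"]

WEIGHT_FLOOR = 1e-12


@dataclass
class EBWeights:
    """Fitted mixture weights over the (partition, sigma grid) cells."""

    weights: np.ndarray  # shape (n_components,)
    loglik_trace: List[float]
    n_snps: int
    converged: bool
    labels: Optional[List[Tuple[str, float]]] = None  # (partition string, sigma_a)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if abs(self.weights.sum() - 1.0) > 1e-8:
            raise ValueError("weights must sum to 1")
        for a, b in zip(self.loglik_trace, self.loglik_trace[1:]):
            if b < a - 1e-9:
                raise ValueError("EM log-likelihood decreased")


def _em_single(
    log_bf_ln: np.ndarray, w0: np.ndarray, tol: float, max_iter: int
) -> Tuple[np.ndarray, List[float]]:
    """One EM run.  ``log_bf_ln`` is natural-log BF, shape (snps, components)."""
    w = w0.copy()
    trace: List[float] = []
    for _ in range(max_iter):
        logw = np.log(np.maximum(w, WEIGHT_FLOOR))
        log_joint = log_bf_ln + logw[None, :]
        log_marg = logsumexp(log_joint, axis=1)
        ll = float(log_marg.sum())
        resp = np.exp(log_joint - log_marg[:, None])
        w_new = resp.mean(axis=0)
        w_new = np.maximum(w_new, WEIGHT_FLOOR)
        w_new /= w_new.sum()
        if trace and ll - trace[-1] < tol * max(abs(ll), 1.0):
            trace.append(ll)
            w = w_new
            break
        trace.append(ll)
        w = w_new
    return w, trace


def em_fit(
    bf_matrix: np.ndarray,
    init: Union[str, np.ndarray] = "uniform",
    tol: float = 1e-8,
    max_iter: int = 2000,
    n_starts: int = 4,
    seed: int = 0,
    labels: Optional[List[Tuple[str, float]]] = None,
) -> EBWeights:
    """Maximum-likelihood mixture weights from a SNPs x components matrix of
    log10 Bayes factors.

    The best of ``n_starts`` EM runs is returned (first start is the given
    or uniform initialization, the rest are flat-Dirichlet draws, seeded).
    The log-likelihood trace is non-decreasing within 1e-9.
    """
    bf = np.atleast_2d(np.asarray(bf_matrix, dtype=float))
    if bf.shape[0] < 1:
        raise ValueError("need at least one SNP")
    if not np.all(np.isfinite(bf)):
        bad = int(np.where(~np.isfinite(bf).all(axis=1))[0][0])
        raise ValueError(f"non-finite Bayes factor in SNP row {bad}")
    n_snps, n_comp = bf.shape
    log_bf_ln = bf * LN10

    if isinstance(init, str):
        if init != "uniform":
            raise ValueError("init must be 'uniform' or a weight vector")
        w0 = np.full(n_comp, 1.0 / n_comp)
    else:
        w0 = np.asarray(init, dtype=float)
        w0 = w0 / w0.sum()

    rng = np.random.default_rng(seed)
    best: Optional[Tuple[np.ndarray, List[float]]] = None
    for s in range(max(n_starts, 1)):
        start = w0 if s == 0 else rng.dirichlet(np.ones(n_comp))
        w, trace = _em_single(log_bf_ln, start, tol, max_iter)
        if best is None or trace[-1] > best[1][-1]:
            best = (w, trace)
    w, trace = best
    converged = len(trace) < max_iter
    return EBWeights(
        weights=w, loglik_trace=trace, n_snps=n_snps, converged=converged,
        labels=labels,
    )


def bf_matrix_from_tables(tables: Sequence[BFTable]) -> Tuple[np.ndarray, List[Tuple[str, float]]]:
    """Stack per-SNP BF tables into the (snps, partition x grid) EM input.

    The global-null column is excluded (the mixture is over associated
    SNPs); column labels are (partition string, sigma_a) pairs.
    """
    ref = tables[0]
    keep = [i for i, g in enumerate(ref.partitions) if not g.is_null]
    labels = [
        (ref.partitions[i].to_string(), float(s))
        for i in keep for s in ref.sigma_grid
    ]
    rows = [t.log10_bf[keep, :].ravel() for t in tables]
    return np.array(rows), labels


def posterior_with_eb(
    bf_table: BFTable,
    eb: EBWeights,
    pi0: float = 0.0,
):
    """Posterior partition probabilities using the fitted weights as prior.

    The (partition, sigma) weights are collapsed to partition weights and a
    per-partition sigma-grid profile.  Note the fitted weights are upward
    biased when estimated on SNPs selected for strong association.
    """
    from .inference import posterior_partitions

    parts = [g for g in bf_table.partitions if not g.is_null]
    K = bf_table.sigma_grid.size
    W = eb.weights.reshape(len(parts), K)
    if W.size != eb.weights.size:
        raise ValueError("weight vector does not match the BF table index space")
    part_w = W.sum(axis=1)
    part_w = part_w / part_w.sum()
    prior = PartitionPrior(d=parts[0].d, pi0=pi0,
                           weights={g: float(v) for g, v in zip(parts, part_w)})

    # collapse each partition's grid with its own conditional sigma weights
    cond = np.where(W.sum(axis=1, keepdims=True) > 0,
                    W / np.maximum(W.sum(axis=1, keepdims=True), WEIGHT_FLOOR),
                    1.0 / K)
    collapsed = np.full((len(bf_table.partitions), 1), 0.0)
    j = 0
    for g_idx, gamma in enumerate(bf_table.partitions):
        if gamma.is_null:
            collapsed[g_idx, 0] = 0.0
            continue
        row = bf_table.log10_bf[g_idx] * LN10
        collapsed[g_idx, 0] = logsumexp(row, b=np.maximum(cond[j], WEIGHT_FLOOR)) / LN10
        j += 1
    return posterior_partitions(
        bf_table.partitions, collapsed, prior, np.ones(1),
    )
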