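"""Building sufficient statistics from raw data or GWAS summary statistics.

The Bayes factor engine consumes only ``(n, g'g, g'Y, Y'Y)`` (mean-centered
cross-products).  These can be computed exactly from raw phenotype/genotype
data, or approximated from the quantities typically released by GWAS
meta-analyses: per-SNP Z-scores, a minor allele frequency, a sample size,
and a phenotype correlation matrix estimated from putatively null SNPs.

Approximations used for summary data (phenotypes treated as standardized):

* ``g'g ~= 2 n f (1 - f)`` — the Hardy-Weinberg genotype variance,
* ``g'y_j = z_j * sqrt(g'g * y'y_jj / (n - 2 + z_j**2))`` — inverting the
  definition of the univariate t/Z statistic ``z = (g'y/sqrt(g'g)) / s``
  with ``s**2`` the residual variance on ``n - 2`` df,
* ``Y'Y = n R`` with ``R`` the null-SNP Z-score correlation matrix (under
  the null the correlation of Z statistics equals the phenotype
  correlation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .bmvr import DegenerateCovariateError, SufficientStats

__all__ = [
    "RawDataset",
    "SnpSummaryRecord",
    "CorrelationEstimate",
    "InsufficientNullSnpsError",
    "sufficient_from_raw",
    "sufficient_from_effects",
    "sufficient_from_z",
    "estimate_null_correlation",
    "handle_missing",
]


class InsufficientNullSnpsError(ValueError):
    """Too few putative null SNPs to estimate the phenotype correlation."""


@dataclass
class RawDataset:
    """An n x d phenotype matrix (NaN = missing) and an n-vector of genotypes."""

    Y: np.ndarray
    g: np.ndarray
    trait_names: Optional[List[str]] = None

    def __post_init__(self):
        self.Y = np.atleast_2d(np.asarray(self.Y, dtype=float))
        self.g = np.asarray(self.g, dtype=float).ravel()
        if self.Y.shape[0] != self.g.shape[0]:
            raise ValueError("Y and g row counts disagree")
        if np.any(np.all(np.isnan(self.Y), axis=0)):
            raise ValueError("a trait column is entirely missing")
        if self.trait_names is None:
            self.trait_names = [f"trait{j+1}" for j in range(self.Y.shape[1])]

    @property
    def n(self) -> int:
        return self.Y.shape[0]

    @property
    def d(self) -> int:
        return self.Y.shape[1]


@dataclass
class SnpSummaryRecord:
    """One SNP's summary-statistic record: identifier, location, MAF, n, Z-scores."""

    snp_id: str
    chrom: str
    pos: int
    maf: float
    n: int
    z: np.ndarray

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float).ravel()
        if self.maf > 0.5:  # fold to the minor allele
            self.maf = 1.0 - self.maf
        if not (0.0 < self.maf <= 0.5):
            raise ValueError(f"maf must lie in (0, 0.5], got {self.maf}")
        if self.n < 1:
            raise ValueError("sample size must be >= 1")
        if not np.all(np.isfinite(self.z)):
            raise ValueError(f"non-finite Z-score for SNP {self.snp_id}")
        self.pos = int(self.pos)


@dataclass
class CorrelationEstimate:
    """Phenotype correlation matrix estimated from putative null SNPs."""

    R: np.ndarray
    n_null_snps: int = 0
    z_threshold: float = float("nan")

    def __post_init__(self):
        self.R = np.asarray(self.R, dtype=float)
        d = self.R.shape[0]
        if self.R.shape != (d, d):
            raise ValueError("R must be square")
        if not np.allclose(self.R, self.R.T, atol=1e-10):
            raise ValueError("R must be symmetric")
        if not np.allclose(np.diag(self.R), 1.0, atol=1e-8):
            raise ValueError("R must have unit diagonal")
        if float(np.linalg.eigvalsh(self.R).min()) < -1e-8:
            raise ValueError("R must be positive semi-definite")

    @property
    def d(self) -> int:
        return self.R.shape[0]


def _repair_correlation(R: np.ndarray) -> np.ndarray:
    """Clip negative eigenvalues at zero and rescale to unit diagonal."""
    R = (R + R.T) / 2.0
    w, V = np.linalg.eigh(R)
    if w.min() < 0:
        R = (V * np.clip(w, 0.0, None)) @ V.T
        s = np.sqrt(np.clip(np.diag(R), 1e-12, None))
        R = R / np.outer(s, s)
        R = (R + R.T) / 2.0
    np.fill_diagonal(R, 1.0)
    return R


def sufficient_from_raw(data: RawDataset) -> SufficientStats:
    """Exact centered cross-products from complete raw data."""
    if np.any(np.isnan(data.Y)) or np.any(np.isnan(data.g)):
        raise ValueError("missing values present; use handle_missing first")
    gc = data.g - data.g.mean()
    Yc = data.Y - data.Y.mean(axis=0)
    gtg = float(gc @ gc)
    if gtg <= 0:
        raise DegenerateCovariateError("genotype has zero variance")
    return SufficientStats(
        n=data.n,
        gtg=gtg,
        gty=Yc.T @ gc,
        yty=Yc.T @ Yc,
        trait_names=list(data.trait_names),
    )


def sufficient_from_effects(
    betahat: Sequence[float],
    maf: float,
    n: int,
    R: CorrelationEstimate,
) -> SufficientStats:
    """Approximate sufficient statistics from univariate effect estimates.

    ``g'g ~= 2 n f (1-f)`` under Hardy-Weinberg equilibrium and
    ``g'y_j = betahat_j * g'g`` (inverting the OLS slope); phenotypes are
    treated as standardized so ``Y'Y = n R``.
    """
    betahat = np.asarray(betahat, dtype=float).ravel()
    if maf > 0.5:
        maf = 1.0 - maf
    if not (0.0 < maf <= 0.5):
        raise ValueError("maf must lie in (0, 0.5]")
    if betahat.shape[0] != R.d:
        raise ValueError("betahat and R dimensions disagree")
    gtg = 2.0 * n * maf * (1.0 - maf)
    return SufficientStats(n=n, gtg=gtg, gty=betahat * gtg, yty=n * R.R)


def sufficient_from_z(rec: SnpSummaryRecord, R: CorrelationEstimate) -> SufficientStats:
    """Approximate sufficient statistics from Z-scores, MAF and sample size."""
    if rec.z.shape[0] != R.d:
        raise ValueError("Z-score vector and R dimensions disagree")
    n = rec.n
    gtg = 2.0 * n * rec.maf * (1.0 - rec.maf)
    ytyjj = float(n)  # standardized phenotypes
    denom = np.maximum(n - 2.0 + rec.z ** 2, 1e-12)
    gty = rec.z * np.sqrt(gtg * ytyjj / denom)
    return SufficientStats(n=n, gtg=gtg, gty=gty, yty=n * R.R)


def estimate_null_correlation(
    Z: np.ndarray, z_threshold: float = 2.0
) -> CorrelationEstimate:
    """Phenotype correlation estimated from SNPs with every |z| below a threshold.

    Under the global null the correlation of the Z statistics across traits
    equals the phenotype correlation, so the sample correlation matrix of
    putatively null rows estimates R.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    d = Z.shape[1]
    keep = np.all(np.abs(Z) < z_threshold, axis=1)
    m = int(keep.sum())
    if m < d + 1:
        raise InsufficientNullSnpsError(
            f"only {m} putative null SNPs below |z| < {z_threshold}; need > {d}"
        )
    Zn = Z[keep]
    sd = Zn.std(axis=0)
    if np.any(sd <= 0):
        R = np.ones((d, d))
    else:
        R = np.corrcoef(Zn, rowvar=False)
        R = np.atleast_2d(R)
    R = _repair_correlation(R)
    return CorrelationEstimate(R=R, n_null_snps=m, z_threshold=z_threshold)


def handle_missing(data: RawDataset) -> Tuple[SufficientStats, np.ndarray]:
    """Sufficient statistics under missing phenotype data.

    Cross-products are computed from pairwise-complete observations (each
    centered by the mean over its own observed rows, accumulated as
    per-observation averages and rescaled to a common sample size); the
    sample size used in the BFs is the smallest per-trait count.  Returns
    the statistics and the per-trait observation counts.
    """
    Y, g = data.Y, data.g
    n, d = Y.shape
    obs = ~np.isnan(Y)
    n_trait = obs.sum(axis=0).astype(int)
    g_ok = ~np.isnan(g)
    n_eff = int(min(n_trait.min(), g_ok.sum()))
    if n_eff < 2:
        raise ValueError("need at least 2 observations per trait")

    gm = g[g_ok].mean()
    gv = float(np.mean((g[g_ok] - gm) ** 2))
    if gv <= 0:
        raise DegenerateCovariateError("genotype has zero variance")
    mu = np.array([Y[obs[:, j], j].mean() for j in range(d)])

    gty = np.empty(d)
    for j in range(d):
        both = obs[:, j] & g_ok
        if both.sum() < 2:
            raise ValueError(f"trait {j} and genotype share < 2 observations")
        gty[j] = np.mean((g[both] - gm) * (Y[both, j] - mu[j]))

    yty = np.empty((d, d))
    for j in range(d):
        for k in range(j, d):
            both = obs[:, j] & obs[:, k]
            if both.sum() < 2:
                raise ValueError(f"traits {j} and {k} share < 2 joint observations")
            v = np.mean((Y[both, j] - mu[j]) * (Y[both, k] - mu[k]))
            yty[j, k] = yty[k, j] = v

    # repair possible non-PSD pairwise covariance, preserving the variances
    s = np.sqrt(np.clip(np.diag(yty), 1e-12, None))
    C = _repair_correlation(yty / np.outer(s, s))
    yty = C * np.outer(s, s)

    stats = SufficientStats(
        n=n_eff,
        gtg=n_eff * gv,
        gty=n_eff * gty,
        yty=n_eff * yty,
        trait_names=list(data.trait_names),
    )
    return stats, n_trait
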