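"""Synthetic data generators for the bivariate and five-dimensional study designs.

Genotypes are drawn as ``g ~ Binomial(2, f)`` (Hardy-Weinberg, default
minor allele frequency 0.2).  Phenotypes are Gaussian with unit residual
scale; effect sizes are in residual-SD units per allele.

Bivariate scenarios share the generating equation ``Y_j = b_j g + e_j``
with correlated errors ``corr(e_1, e_2) = rho``; the second trait's
coefficient determines its category:

* ``bivariate-D``: ``b_2 = b`` — directly associated,
* ``bivariate-U``: ``b_2 = 0`` — unassociated,
* ``bivariate-I``: ``b_2 = rho * b_1`` — the unique coefficient making
  ``Y_2`` independent of ``g`` given ``Y_1`` (indirect association).

The six five-dimensional scenarios realize the designs compared in the
power study: a lone associated trait among independent traits; one direct
trait correlated with four unassociated ones; one direct trait with four
noisy copies (indirect); two mixed multi-trait designs; and a
genotype-associated latent factor shared by all traits (all direct).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .partitions import Partition
from .summary import CorrelationEstimate, RawDataset, SnpSummaryRecord

__all__ = [
    "ScenarioSpec",
    "SimulatedStudy",
    "BIVARIATE_SCENARIOS",
    "FIVE_D_SCENARIOS",
    "simulate_bivariate",
    "simulate_5d",
    "simulate_null_matched",
    "power_size_curves",
    "power_at_size",
    "simulate_summary_records",
]

BIVARIATE_SCENARIOS = ("bivariate-D", "bivariate-U", "bivariate-I")
FIVE_D_SCENARIOS = (
    "independence",
    "one-direct-rest-unassoc",
    "one-direct-rest-indirect",
    "multivariate-1",
    "multivariate-2",
    "latent-factor",
)

#: noise-SD ratios for "noisy copy" traits
NOISE_SD_RATIOS = (0.5, 1.0, 2.0, 4.0)


@dataclass
class ScenarioSpec:
    """Parameters of one simulation scenario.

    ``effects`` are genotype effect sizes in residual-SD units per allele;
    ``rho`` is the residual correlation (bivariate designs).  Defaults:
    n=1000 individuals, MAF 0.2, effect 0.25 (bivariate) with mid-range
    power at n=1000.
    """

    name: str
    n: int = 1000
    maf: float = 0.2
    effects: Tuple[float, ...] = (0.25, -0.25)
    rho: float = 0.4
    seed: int = 0

    def __post_init__(self):
        if self.name not in BIVARIATE_SCENARIOS + FIVE_D_SCENARIOS:
            raise ValueError(f"unknown scenario {self.name!r}")
        if not (0 < self.maf < 1):
            raise ValueError("maf must lie in (0, 1)")


@dataclass
class SimulatedStudy:
    data: RawDataset
    truth: Partition
    scenario: ScenarioSpec


def _genotypes(rng: np.random.Generator, n: int, maf: float) -> np.ndarray:
    return rng.binomial(2, maf, size=n).astype(float)


def simulate_bivariate(spec: ScenarioSpec, rng: Optional[np.random.Generator] = None,
                       null: bool = False) -> SimulatedStudy:
    """One bivariate dataset: Y_j = b_j g + e_j with corr(e_1, e_2) = rho."""
    if spec.name not in BIVARIATE_SCENARIOS:
        raise ValueError(f"not a bivariate scenario: {spec.name!r}")
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    n, rho = spec.n, spec.rho
    b1 = spec.effects[0]
    if spec.name == "bivariate-D":
        b2 = spec.effects[1] if len(spec.effects) > 1 else b1
        truth = Partition(d=2, D=frozenset({0, 1}))
    elif spec.name == "bivariate-U":
        b2 = 0.0
        truth = Partition(d=2, D=frozenset({0}))
    else:  # bivariate-I: Y2 indep of g given Y1 requires b2 = rho * b1
        b2 = rho * b1
        truth = Partition(d=2, D=frozenset({0}), I=frozenset({1}))
    if null:
        b1 = b2 = 0.0
        truth = Partition(d=2)

    g = _genotypes(rng, n, spec.maf)
    L = np.linalg.cholesky(np.array([[1.0, rho], [rho, 1.0]]))
    e = rng.standard_normal((n, 2)) @ L.T
    Y = np.column_stack([b1 * g + e[:, 0], b2 * g + e[:, 1]])
    return SimulatedStudy(data=RawDataset(Y=Y, g=g), truth=truth, scenario=spec)


def _simulate_5d_core(spec: ScenarioSpec, rng: np.random.Generator,
                      b: float) -> Tuple[np.ndarray, np.ndarray, Partition]:
    n = spec.n
    g = _genotypes(rng, n, spec.maf)
    E = rng.standard_normal((n, 5))
    name = spec.name

    if name == "independence":
        Y = E.copy()
        Y[:, 0] += b * g
        truth = Partition(d=5, D=frozenset({0}))
    elif name == "one-direct-rest-unassoc":
        # traits 2-5 iid; trait 1 loads on all of them and on g
        Y = E.copy()
        load = 0.4
        resid_sd = math.sqrt(max(1.0 - 4 * load ** 2, 0.04))
        Y[:, 0] = b * g + load * E[:, 1:5].sum(axis=1) + resid_sd * rng.standard_normal(n)
        truth = Partition(d=5, D=frozenset({0}))
    elif name == "one-direct-rest-indirect":
        y1 = b * g + E[:, 0]
        cols = [y1]
        for j, s in enumerate(NOISE_SD_RATIOS):
            cols.append(y1 + s * E[:, j + 1])
        Y = np.column_stack(cols)
        truth = Partition(d=5, D=frozenset({0}), I=frozenset({1, 2, 3, 4}))
    elif name == "multivariate-1":
        # 2 direct, 1 indirect, 2 unassociated-but-correlated
        y1 = b * g + E[:, 0]
        y2 = b * g + 0.5 * E[:, 0] + math.sqrt(0.75) * E[:, 1]
        y3 = 0.5 * (y1 + y2) + E[:, 2]  # indirect: depends on g through y1, y2
        f = rng.standard_normal(n)
        y4 = 0.6 * f + 0.8 * E[:, 3]
        y5 = 0.6 * f + 0.8 * E[:, 4]
        Y = np.column_stack([y1, y2, y3, y4, y5])
        truth = Partition(d=5, D=frozenset({0, 1}), I=frozenset({2}))
    elif name == "multivariate-2":
        y1 = b * g + E[:, 0]
        y2 = b * g + 0.5 * E[:, 0] + math.sqrt(0.75) * E[:, 1]
        f = rng.standard_normal(n)
        rest = 0.5 * f[:, None] + math.sqrt(0.75) * E[:, 2:5]
        Y = np.column_stack([y1, y2, rest])
        truth = Partition(d=5, D=frozenset({0, 1}))
    elif name == "latent-factor":
        fac = b * g + E[:, 0]
        sds = (0.5,) + NOISE_SD_RATIOS
        noise = rng.standard_normal((n, 5))
        Y = fac[:, None] + noise * np.asarray(sds)[None, :]
        truth = Partition(d=5, D=frozenset(range(5)))
    else:  # pragma: no cover
        raise ValueError(name)
    return Y, g, truth


def simulate_5d(spec: ScenarioSpec, rng: Optional[np.random.Generator] = None,
                null: bool = False) -> SimulatedStudy:
    """One five-trait dataset under the named scenario.

    Default effect size 0.15 SD/allele (mid-range power at n=1000 so that
    statistic orderings are distinguishable); ``null=True`` zeroes all
    genotype effects while keeping the error covariance of the alternative.
    """
    if spec.name not in FIVE_D_SCENARIOS:
        raise ValueError(f"not a 5-d scenario: {spec.name!r}")
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    b = 0.0 if null else (spec.effects[0] if spec.effects else 0.15)
    Y, g, truth = _simulate_5d_core(spec, rng, b)
    if null:
        truth = Partition(d=5)
    return SimulatedStudy(data=RawDataset(Y=Y, g=g), truth=truth, scenario=spec)


def simulate_null_matched(alt_spec: ScenarioSpec, n_reps: int,
                          seed: Optional[int] = None) -> List[RawDataset]:
    """Null datasets with the error covariance of the named alternative.

    Genotypes are still simulated; every genotype effect is zeroed.
    """
    rng = np.random.default_rng(alt_spec.seed if seed is None else seed)
    sim = simulate_bivariate if alt_spec.name in BIVARIATE_SCENARIOS else simulate_5d
    return [sim(alt_spec, rng=rng, null=True).data for _ in range(n_reps)]


def power_size_curves(
    alt_stats: Dict[str, np.ndarray],
    null_stats: Dict[str, np.ndarray],
) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
    """Size/power curves per statistic from simulated alternative/null draws.

    For every threshold on the pooled values, size is the null exceedance
    fraction and power the alternative exceedance fraction; both curves are
    monotone non-decreasing and invariant to strictly monotone transforms
    of the statistic.
    """
    if set(alt_stats) != set(null_stats):
        raise ValueError("alternative and null statistic sets disagree")
    out = {}
    for name in alt_stats:
        a = np.sort(np.asarray(alt_stats[name], dtype=float))
        z = np.sort(np.asarray(null_stats[name], dtype=float))
        thresholds = np.unique(np.concatenate([a, z]))
        # strict exceedance fractions at each threshold
        size = 1.0 - np.searchsorted(z, thresholds, side="right") / z.size
        power = 1.0 - np.searchsorted(a, thresholds, side="right") / a.size
        order = np.argsort(size)
        out[name] = (size[order], power[order])
    return out


def power_at_size(curve: Tuple[np.ndarray, np.ndarray], alpha: float) -> float:
    """Interpolated power at a target size from a (size, power) curve."""
    size, power = curve
    return float(np.interp(alpha, size, power))


def simulate_summary_records(
    n_snps: int,
    d: int,
    frac_assoc: float,
    partition_mix: Dict[Partition, float],
    effect_scale: float,
    R: np.ndarray,
    n: int = 10_000,
    seed: int = 0,
    chrom_count: int = 22,
) -> List[SnpSummaryRecord]:
    """Synthetic summary-statistic records emulating a meta-analysis table.

    Null SNPs draw ``z ~ N(0, R)``.  An associated SNP draws a partition
    from ``partition_mix`` and receives mean shifts: ``effect_scale`` (with
    random sign, shared across its direct traits) on D, the conditional-mean
    image ``R[I,D] R[D,D]^-1 mu_D`` on I, zero on U.  MAF ~ U(0.05, 0.5);
    positions are spread over ``chrom_count`` chromosomes.
    """
    if not (0.0 <= frac_assoc <= 1.0):
        raise ValueError("frac_assoc must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    R = np.asarray(R, dtype=float)
    L = np.linalg.cholesky(R + 1e-12 * np.eye(d))
    parts = list(partition_mix)
    pw = np.array([partition_mix[p] for p in parts], dtype=float)
    pw = pw / pw.sum() if parts else pw

    records = []
    n_assoc = int(round(frac_assoc * n_snps))
    assoc_flags = np.zeros(n_snps, dtype=bool)
    assoc_flags[:n_assoc] = True
    rng.shuffle(assoc_flags)
    for i in range(n_snps):
        z = L @ rng.standard_normal(d)
        if assoc_flags[i] and parts:
            gamma = parts[rng.choice(len(parts), p=pw)]
            mu = np.zeros(d)
            Dix = sorted(gamma.D)
            sign = rng.choice([-1.0, 1.0])
            mu[Dix] = sign * effect_scale
            Iix = sorted(gamma.I)
            if Iix:
                mu[Iix] = R[np.ix_(Iix, Dix)] @ np.linalg.solve(
                    R[np.ix_(Dix, Dix)], mu[Dix]
                )
            z = z + mu
        records.append(
            SnpSummaryRecord(
                snp_id=f"rs{i+1:06d}",
                chrom=str(i % chrom_count + 1),
                pos=1_000_000 + (i // chrom_count) * 1_000_000,
                maf=float(rng.uniform(0.05, 0.5)),
                n=n,
                z=z,
            )
        )
    return records
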