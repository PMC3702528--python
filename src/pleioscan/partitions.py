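"""Partitions of traits into unassociated / directly / indirectly associated sets.

A multivariate association model for ``d`` phenotypes and one genetic variant
is indexed by a partition ``gamma = (U, D, I)`` of the trait indices:

* ``U`` — unassociated: independent of the genotype,
* ``D`` — directly associated: depend on the genotype given the other traits,
* ``I`` — indirectly associated: conditionally independent of the genotype
  given the directly associated traits (association mediated through ``D``).

A trait can only be indirectly associated if something is directly
associated, so ``D`` empty forces ``I`` empty.  The partition with all
traits in ``U`` is the global null.  There are ``3**d - 2**d + 1`` valid
partitions.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Tuple

__all__ = [
    "Partition",
    "PartitionPrior",
    "enumerate_partitions",
    "count_partitions",
    "default_partition_prior",
    "special_partitions",
    "MAX_TRAITS",
]

#: Exhaustive enumeration is refused above this trait count (3^d growth).
MAX_TRAITS = 15


@dataclass(frozen=True)
class Partition:
    """Assignment of the traits ``0..d-1`` to the categories U, D, I."""

    d: int
    D: frozenset = field(default_factory=frozenset)
    I: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        D = frozenset(self.D)
        I = frozenset(self.I)
        object.__setattr__(self, "D", D)
        object.__setattr__(self, "I", I)
        if self.d < 1:
            raise ValueError("trait count d must be >= 1")
        universe = set(range(self.d))
        if not (D <= universe and I <= universe):
            raise IndexError("trait indices outside 0..d-1")
        if D & I:
            raise ValueError("D and I must be disjoint")
        if not D and I:
            raise ValueError("indirect associations require a non-empty D")

    @property
    def U(self) -> frozenset:
        return frozenset(range(self.d)) - self.D - self.I

    @property
    def is_null(self) -> bool:
        return not self.D

    @property
    def n_assoc(self) -> int:
        """Number of associated traits, |D| + |I|."""
        return len(self.D) + len(self.I)

    def category(self, j: int) -> str:
        if j in self.D:
            return "D"
        if j in self.I:
            return "I"
        return "U"

    # -- string serialization (1-based trait indices, human-auditable) ----
    def to_string(self) -> str:
        parts = []
        for name, s in (("D", self.D), ("I", self.I), ("U", self.U)):
            if s:
                parts.append(f"{name}:" + ",".join(str(j + 1) for j in sorted(s)))
        return "|".join(parts) if parts else "U:"

    @classmethod
    def from_string(cls, text: str, d: int) -> "Partition":
        sets: Dict[str, set] = {"U": set(), "D": set(), "I": set()}
        for chunk in text.strip().split("|"):
            if not chunk:
                continue
            name, _, members = chunk.partition(":")
            name = name.strip().upper()
            if name not in sets:
                raise ValueError(f"unknown category {name!r} in {text!r}")
            for tok in members.split(","):
                tok = tok.strip()
                if tok:
                    sets[name].add(int(tok) - 1)
        return cls(d=d, D=frozenset(sets["D"]), I=frozenset(sets["I"]))

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()

    def _sort_key(self) -> Tuple:
        return (self.n_assoc, len(self.D), tuple(sorted(self.D)), tuple(sorted(self.I)))


def _check_d(d: int) -> None:
    if not isinstance(d, (int,)) or isinstance(d, bool):
        raise ValueError("d must be an integer")
    if d < 1 or d > MAX_TRAITS:
        raise ValueError(f"d must be in 1..{MAX_TRAITS}, got {d}")


def enumerate_partitions(d: int) -> List[Partition]:
    """All valid partitions of ``d`` traits in canonical order.

    The order is deterministic: global null first, then sorted by
    (number of associated traits, |D|, lexicographic D, lexicographic I).
    """
    _check_d(d)
    out = []
    for labels in itertools.product("UDI", repeat=d):
        D = frozenset(j for j, c in enumerate(labels) if c == "D")
        I = frozenset(j for j, c in enumerate(labels) if c == "I")
        if not D and I:
            continue
        out.append(Partition(d=d, D=D, I=I))
    out = sorted(set(out), key=Partition._sort_key)
    return out


def count_partitions(d: int) -> int:
    """Number of valid partitions: ``3**d - 2**d + 1``."""
    _check_d(d)
    return 3 ** d - 2 ** d + 1


def special_partitions(d: int) -> Tuple[Partition, List[Partition]]:
    """The all-direct partition and the ``d`` univariate-test partitions.

    ``gamma_all`` places every trait in D (the standard multivariate test);
    ``gamma_uni[j]`` places trait ``j`` in D and every other trait in I
    (the standard univariate test of trait ``j``).
    """
    _check_d(d)
    gamma_all = Partition(d=d, D=frozenset(range(d)))
    gamma_uni = [
        Partition(d=d, D=frozenset([j]), I=frozenset(range(d)) - {j})
        for j in range(d)
    ]
    return gamma_all, gamma_uni


@dataclass
class PartitionPrior:
    """Prior over partitions: mass ``pi0`` on the global null, the rest
    distributed over non-null partitions by ``weights`` (which sum to 1)."""

    d: int
    pi0: float
    weights: Dict[Partition, float]

    def __post_init__(self):
        if not (0.0 <= self.pi0 <= 1.0):
            raise ValueError("pi0 must lie in [0, 1]")
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("partition weights must be non-negative")
        total = sum(self.weights.values())
        if self.weights and not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-8):
            raise ValueError(f"non-null weights must sum to 1, got {total}")

    def weight(self, gamma: Partition) -> float:
        return self.weights.get(gamma, 0.0)

    def nonnull_items(self) -> Iterable[Tuple[Partition, float]]:
        return self.weights.items()


def default_partition_prior(d: int, pi0: float = 0.5) -> PartitionPrior:
    """Exchangeable hierarchical-uniform prior over non-null partitions.

    Conditional on at least one association, the number of associated
    traits ``p = |D| + |I|`` is uniform on ``1..d``; given ``p``, ``|D|`` is
    uniform on ``1..p``; given the counts, all partitions with those counts
    are equally likely.  Under this prior the expected number of associated
    traits is ``(d+1)/2`` and the prior probability that any particular
    trait is associated is ``(d+1)/(2d)``.
    """
    _check_d(d)
    if pi0 == 1.0:
        import warnings

        warnings.warn("pi0 = 1 is a degenerate prior (testing use only)")
    weights: Dict[Partition, float] = {}
    for gamma in enumerate_partitions(d):
        if gamma.is_null:
            continue
        p = gamma.n_assoc
        dd = len(gamma.D)
        n_configs = math.comb(d, p) * math.comb(p, dd)
        weights[gamma] = (1.0 / d) * (1.0 / p) / n_configs
    return PartitionPrior(d=d, pi0=pi0, weights=weights)
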