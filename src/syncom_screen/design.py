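"""Combinatorial design of random fixed-size SynCom screens.

A screen draws ``N`` communities of ``k`` strains each, without replacement,
from a pool of ``n`` strains.  The expected number of communities containing
any given strain is ``E(X) = (k/n) * N``, which is the hypergeometric identity
``C(n-1, k-1) / C(n, k) * N``.  This expected prevalence is the quantity that
drives the choice of pool size for a fixed number of experimental units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DesignSpec",
    "StrainPool",
    "CommunitySet",
    "expected_prevalence",
    "prevalence_curve",
    "assemble_communities",
    "realized_prevalence",
]


@dataclass(frozen=True)
class DesignSpec:
    """Screen parameters: community size ``k``, pool size ``n``, count ``N``."""

    k: int
    n: int
    N: int

    def __post_init__(self) -> None:
        if not (isinstance(self.k, int) and isinstance(self.n, int) and isinstance(self.N, int)):
            raise TypeError("k, n, N must be integers")
        if self.k < 1 or self.n < 1 or self.N < 1:
            raise ValueError("k, n, N must be positive")
        if self.k > self.n:
            raise ValueError(f"community size k={self.k} exceeds pool size n={self.n}")

    @property
    def capacity(self) -> int:
        """Number of distinct k-subsets of the pool, C(n, k)."""
        return comb(self.n, self.k)


@dataclass(frozen=True)
class StrainPool:
    """Ordered collection of unique strain labels."""

    strain_ids: tuple[str, ...]

    def __init__(self, strain_ids: Iterable[str]):
        ids = tuple(str(s) for s in strain_ids)
        if len(set(ids)) != len(ids):
            raise ValueError("strain labels must be unique")
        object.__setattr__(self, "strain_ids", ids)

    @property
    def size(self) -> int:
        return len(self.strain_ids)

    @classmethod
    def numbered(cls, n: int, prefix: str = "S") -> "StrainPool":
        """Pool of ``n`` synthetic labels S01..Sn."""
        width = max(2, len(str(n)))
        return cls(f"{prefix}{i:0{width}d}" for i in range(1, n + 1))


@dataclass(frozen=True)
class CommunitySet:
    """Assembled strain memberships of one screen."""

    communities: tuple[frozenset[str], ...]
    spec: DesignSpec
    seed: int | None = None
    community_ids: tuple[str, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        for c in self.communities:
            if len(c) != self.spec.k:
                raise ValueError("every community must have exactly k members")
        if self.community_ids is None:
            width = max(3, len(str(len(self.communities))))
            ids = tuple(f"C{i:0{width}d}" for i in range(1, len(self.communities) + 1))
            object.__setattr__(self, "community_ids", ids)
        elif len(self.community_ids) != len(self.communities):
            raise ValueError("community_ids length mismatch")

    def __len__(self) -> int:
        return len(self.communities)

    def membership(self) -> dict[str, frozenset[str]]:
        return dict(zip(self.community_ids, self.communities))

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with columns community_id, strain_id."""
        rows = [
            (cid, s)
            for cid, comm in zip(self.community_ids, self.communities)
            for s in sorted(comm)
        ]
        return pd.DataFrame(rows, columns=["community_id", "strain_id"])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, spec: DesignSpec) -> "CommunitySet":
        grouped = frame.groupby("community_id", sort=True)["strain_id"]
        ids, comms = [], []
        for cid, strains in grouped:
            ids.append(str(cid))
            comms.append(frozenset(str(s) for s in strains))
        return cls(tuple(comms), spec, seed=None, community_ids=tuple(ids))


def expected_prevalence(spec: DesignSpec) -> float:
    """Expected number of communities containing a given strain, (k/n)*N."""
    return spec.k / spec.n * spec.N


def prevalence_curve(k: int, N: int, n_range: Sequence[int]) -> pd.DataFrame:
    """Expected prevalence as a function of pool size, for fixed k and N.

    Returns a table with columns ``n`` and ``expected_prevalence``; the
    curve is non-increasing in n.
    """
    n_values = sorted(set(int(n) for n in n_range))
    if not n_values:
        raise ValueError("n_range must be non-empty")
    rows = [(n, expected_prevalence(DesignSpec(k=k, n=n, N=N))) for n in n_values]
    return pd.DataFrame(rows, columns=["n", "expected_prevalence"])


def assemble_communities(
    pool: StrainPool,
    spec: DesignSpec,
    seed: int | None = 0,
    enforce_unique: bool = True,
) -> CommunitySet:
    """Draw ``N`` random k-strain communities from the pool without replacement.

    With ``enforce_unique`` (the default) no two communities share the same
    membership; duplicates are rejection-sampled away, which requires
    ``N <= C(n, k)``.
    """
    if pool.size != spec.n:
        raise ValueError(f"pool size {pool.size} != spec n={spec.n}")
    if enforce_unique and spec.N > spec.capacity:
        raise ValueError(
            f"cannot draw {spec.N} unique communities from C({spec.n},{spec.k})"
            f"={spec.capacity} possibilities"
        )
    rng = np.random.default_rng(seed)
    labels = np.asarray(pool.strain_ids, dtype=object)
    seen: set[frozenset[str]] = set()
    out: list[frozenset[str]] = []
    while len(out) < spec.N:
        draw = frozenset(rng.choice(labels, size=spec.k, replace=False))
        if enforce_unique:
            if draw in seen:
                continue
            seen.add(draw)
        out.append(draw)
    return CommunitySet(tuple(out), spec, seed=seed)


def realized_prevalence(cs: CommunitySet, pool: StrainPool | None = None) -> pd.Series:
    """Per-strain count of communities in which the strain appears.

    Counts sum to ``k * N``.  If a pool is given, absent strains appear
    with count zero and the index follows pool order.
    """
    counts: dict[str, int] = {}
    if pool is not None:
        counts = {s: 0 for s in pool.strain_ids}
    for comm in cs.communities:
        for s in comm:
            counts[s] = counts.get(s, 0) + 1
    ser = pd.Series(counts, name="n_communities")
    if pool is None:
        ser = ser.sort_index()
    ser.index.name = "strain_id"
    return ser
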