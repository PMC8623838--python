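"""Enumeration of two-coarse-level class hierarchies and co-merge statistics.

A "height-3" class hierarchy over C target classes is an ordered pair
(P1, P2) of set partitions of the classes where P2 strictly merges at least
one pair of classes (but keeps at least 2 blocks) and P1 strictly merges
blocks of P2 further (again keeping at least 2 blocks).  The number of such
pairs is

    sum_{k2=3}^{C-1}  S(C, k2) * sum_{k1=2}^{k2-1} S(k2, k1)

with S the Stirling numbers of the second kind; it grows so quickly with C
(18 at C=4, 205 at C=5) that exhaustive search over hierarchies is only
feasible for a handful of classes — the motivation for constructing the
hierarchy from data instead.

Partitions are encoded canonically as restricted-growth strings (RGS):
block ids appear in first-occurrence order, so equal partitions have equal
encodings regardless of block naming.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Iterator, Sequence

import numpy as np

from bcnnhar.hierarchy import HierarchicalLabelSet

__all__ = [
    "PartitionPair",
    "set_partitions",
    "enumerate_two_level_hierarchies",
    "count_two_level_hierarchies",
    "stirling2",
    "pair_merge_percentage",
    "accuracy_distribution_summary",
]


def _canonical(assignment: Sequence[int]) -> tuple[int, ...]:
    """Renumber block ids in first-occurrence order (restricted-growth form)."""
    order: dict[int, int] = {}
    for a in assignment:
        if a not in order:
            order[a] = len(order)
    return tuple(order[a] for a in assignment)


def _n_blocks(rgs: Sequence[int]) -> int:
    return max(rgs) + 1


def _strictly_coarser(p1: Sequence[int], p2: Sequence[int]) -> bool:
    """True iff every p2 block lies inside a p1 block and p1 != p2."""
    parent: dict[int, int] = {}
    for a1, a2 in zip(p1, p2):
        if a2 in parent and parent[a2] != a1:
            return False
        parent[a2] = a1
    return _n_blocks(p1) < _n_blocks(p2)


@dataclass(frozen=True)
class PartitionPair:
    """One two-coarse-level hierarchy: Level-1 and Level-2 partitions in RGS form."""

    p1: tuple[int, ...]
    p2: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.p1) != len(self.p2):
            raise ValueError("p1 and p2 must partition the same class set")
        if self.p1 != _canonical(self.p1) or self.p2 != _canonical(self.p2):
            raise ValueError("partitions must be in restricted-growth form")
        c = len(self.p2)
        if _n_blocks(self.p2) >= c:
            raise ValueError("Level 2 must merge at least one pair of classes")
        if _n_blocks(self.p1) < 2 or _n_blocks(self.p2) < 2:
            raise ValueError("both coarse levels need at least 2 blocks")
        if not _strictly_coarser(self.p1, self.p2):
            raise ValueError("Level 1 must be strictly coarser than Level 2")

    def blocks(self, level: int) -> frozenset[frozenset[int]]:
        rgs = self.p1 if level == 1 else self.p2
        groups: dict[int, set[int]] = {}
        for i, a in enumerate(rgs):
            groups.setdefault(a, set()).add(i)
        return frozenset(frozenset(g) for g in groups.values())


def set_partitions(n: int, min_blocks: int = 1, max_blocks: int | None = None) -> Iterator[tuple[int, ...]]:
    """All set partitions of {0..n-1} as RGS tuples, in lexicographic order."""
    max_blocks = n if max_blocks is None else max_blocks
    rgs = [0] * n

    def rec(i: int, k: int) -> Iterator[tuple[int, ...]]:
        if i == n:
            if min_blocks <= k <= max_blocks:
                yield tuple(rgs)
            return
        for b in range(min(k + 1, max_blocks)):
            rgs[i] = b
            yield from rec(i + 1, max(k, b + 1))

    return rec(1, 1)


def enumerate_two_level_hierarchies(n_classes: int) -> Iterator[PartitionPair]:
    """Yield every valid (P1, P2) pair exactly once, deterministically ordered.

    P2 runs over partitions with 3 to C-1 blocks (it must merge something,
    and must leave room for a strictly coarser non-trivial P1); P1 runs over
    partitions of P2's blocks with 2 to blocks(P2)-1 blocks, composed back
    onto the classes.
    """
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    for p2 in set_partitions(n_classes, min_blocks=3, max_blocks=n_classes - 1):
        k2 = _n_blocks(p2)
        for q in set_partitions(k2, min_blocks=2, max_blocks=k2 - 1):
            p1 = _canonical([q[b] for b in p2])
            yield PartitionPair(p1, p2)


@lru_cache(maxsize=None)
def stirling2(n: int, k: int) -> int:
    """Stirling number of the second kind S(n, k) by the standard recurrence."""
    if n == k == 0:
        return 1
    if n == 0 or k == 0 or k > n:
        return 0
    return k * stirling2(n - 1, k) + stirling2(n - 1, k - 1)


def count_two_level_hierarchies(n_classes: int) -> int:
    """Closed-form count of the enumeration above via Stirling numbers."""
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    return sum(
        stirling2(n_classes, k2) * sum(stirling2(k2, k1) for k1 in range(2, k2))
        for k2 in range(3, n_classes)
    )


def _level_blocks(h, level: int) -> frozenset[frozenset[int]]:
    if isinstance(h, PartitionPair):
        return h.blocks(level)
    if isinstance(h, HierarchicalLabelSet):
        return h.level_partition(level)
    raise TypeError(f"unsupported hierarchy type {type(h)!r}")


def pair_merge_percentage(hierarchies: Iterable, level: int, n_classes: int | None = None) -> np.ndarray:
    """Fraction of hierarchies in which each class pair shares a block at ``level``.

    Returns a symmetric (C, C) matrix with unit diagonal; entry (a, b) is
    the fraction of the supplied hierarchies whose given level puts classes
    a and b in the same coarse class.
    """
    hierarchies = list(hierarchies)
    if not hierarchies:
        raise ValueError("need at least one hierarchy")
    sizes = set()
    for h in hierarchies:
        if isinstance(h, PartitionPair):
            sizes.add(len(h.p2))
        else:
            sizes.add(len(h.class_names))
    if len(sizes) != 1:
        raise ValueError(f"inconsistent class counts across hierarchies: {sorted(sizes)}")
    c = sizes.pop()
    if n_classes is not None and n_classes != c:
        raise ValueError(f"expected {n_classes} classes, hierarchies have {c}")

    counts = np.zeros((c, c))
    for h in hierarchies:
        for block in _level_blocks(h, level):
            members = sorted(block)
            for i in members:
                for j in members:
                    counts[i, j] += 1
    return counts / len(hierarchies)


def accuracy_distribution_summary(
    results: Sequence[tuple[object, float]], n_bins: int = 20, q: float = 0.01
) -> dict:
    """Histogram and extremes of per-hierarchy accuracies from a grid search.

    Returns binned counts with cumulative relative frequencies, the min /
    max / median accuracy, the best and worst hierarchies, and the top-q and
    bottom-q subsets (subset size ``ceil(q * n)``) for downstream co-merge
    analysis.
    """
    if not results:
        raise ValueError("no results to summarize")
    accs = np.array([a for _, a in results], dtype=np.float64)
    counts, edges = np.histogram(accs, bins=n_bins)
    order = np.argsort(accs, kind="stable")
    k = math.ceil(q * len(results))
    return {
        "counts": counts,
        "bin_edges": edges,
        "cumulative_relative": np.cumsum(counts) / len(results),
        "min": float(accs.min()),
        "max": float(accs.max()),
        "median": float(np.median(accs)),
        "best": results[int(order[-1])][0],
        "worst": results[int(order[0])][0],
        "top": [results[int(i)] for i in order[-k:][::-1]],
        "bottom": [results[int(i)] for i in order[:k]],
    }
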