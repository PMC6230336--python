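"""Frequent genotype-pattern enumeration (Apriori) with closed-set reduction.

A genotype pattern is a conjunction of binary genotype items across distinct
SNPs.  Patterns are mined level-wise with the Apriori algorithm: candidate
(k+1)-patterns are generated by lexicographic prefix joins of frequent
k-patterns and pruned when any k-subset is infrequent.  Support counting is
complete-case: an individual contributes only if every item of the pattern is
observed and true.  The two items of one SNP are mutually exclusive, so they
are never joined.  The frequent set is optionally reduced to closed patterns
(no strict superset with identical support) to remove redundancy.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .genio import BinaryItemMatrix

__all__ = [
    "ItemPattern",
    "MiningConfig",
    "pattern_support",
    "apriori_frequent",
    "closed_filter",
]


@dataclass(frozen=True)
class ItemPattern:
    """A genotype pattern: sorted item IDs plus its absolute support."""

    items: tuple[str, ...]
    support: int

    def __post_init__(self) -> None:
        if not self.items:
            raise ValueError("pattern must contain at least one item")
        if tuple(sorted(self.items)) != self.items:
            object.__setattr__(self, "items", tuple(sorted(self.items)))
        if len(set(self.items)) != len(self.items):
            raise ValueError("pattern items must be unique")
        if self.support < 0:
            raise ValueError("support must be >= 0")

    def __len__(self) -> int:
        return len(self.items)


@dataclass(frozen=True)
class MiningConfig:
    """Mining thresholds.

    ``min_support`` is the absolute number of individuals that must match a
    pattern, ``max_lhs_len`` caps pattern length, ``z_min`` is the rule
    interestingness threshold applied downstream, and ``max_rhs_len`` caps the
    size of phenotype clusters used as rule consequents.
    """

    min_support: int = 50
    max_lhs_len: int = 3
    z_min: float = 5.0
    max_rhs_len: int = 2

    def __post_init__(self) -> None:
        if self.min_support < 1:
            raise ValueError("min_support must be >= 1")
        if self.max_lhs_len < 1:
            raise ValueError("max_lhs_len must be >= 1")
        if self.max_rhs_len < 1:
            raise ValueError("max_rhs_len must be >= 1")


def pattern_support(m: BinaryItemMatrix, items) -> int:
    """Number of individuals with every pattern item observed and true."""
    idx = [m.item_index(it) for it in items]
    if not idx:
        raise ValueError("empty pattern")
    ok = m.observed_true[:, idx].all(axis=1)
    return int(ok.sum())


def apriori_frequent(m: BinaryItemMatrix, cfg: MiningConfig) -> list[ItemPattern]:
    """Enumerate all frequent patterns up to ``cfg.max_lhs_len`` items.

    Returns exactly the patterns with support >= ``cfg.min_support`` and
    length <= ``cfg.max_lhs_len``, sorted lexicographically by item tuple.
    Patterns containing both items of a single SNP are never formed (their
    co-support is structurally zero).
    """
    order = np.argsort(np.asarray(m.items, dtype=object))
    items_sorted = [m.items[j] for j in order]
    V = m.observed_true[:, order]
    groups = np.asarray([m.item_group(it) for it in items_sorted], dtype=object)

    out: list[ItemPattern] = []
    # level 1
    supports = V.sum(axis=0)
    frequent = [
        (j,) for j in range(len(items_sorted)) if supports[j] >= cfg.min_support
    ]
    covers = {(j,): V[:, j] for (j,) in frequent}
    for (j,) in frequent:
        out.append(ItemPattern((items_sorted[j],), int(supports[j])))

    level = frequent
    for _ in range(1, cfg.max_lhs_len):
        if not level:
            break
        level_set = set(level)
        next_level: list[tuple[int, ...]] = []
        # prefix join: two k-patterns sharing their first k-1 indices
        for a, b in _prefix_pairs(level):
            cand = a + (b[-1],)
            if any(groups[cand[-1]] == groups[j] for j in a):
                continue  # same-SNP items never co-occur
            if any(
                cand[:i] + cand[i + 1:] not in level_set
                for i in range(len(cand) - 1)
            ):
                continue  # an infrequent subset exists
            vec = covers[a] & V[:, cand[-1]]
            sup = int(vec.sum())
            if sup >= cfg.min_support:
                next_level.append(cand)
                covers[cand] = vec
                out.append(
                    ItemPattern(tuple(items_sorted[j] for j in cand), sup)
                )
        level = next_level

    out.sort(key=lambda pat: pat.items)
    return out


def _prefix_pairs(level):
    """Yield ordered pairs of same-length patterns sharing all but the last item."""
    by_prefix: dict[tuple[int, ...], list[tuple[int, ...]]] = {}
    for pat in level:
        by_prefix.setdefault(pat[:-1], []).append(pat)
    for pats in by_prefix.values():
        pats.sort()
        for i, a in enumerate(pats):
            for b in pats[i + 1:]:
                yield a, b


def closed_filter(patterns: list[ItemPattern]) -> list[ItemPattern]:
    """Keep patterns with no strict superset of identical support.

    Closure is evaluated relative to the given (length-bounded) frequent set:
    a pattern is removed iff some strict superset *in the input* has the same
    support.  Output order and supports are unchanged.
    """
    by_support: dict[int, list[frozenset[str]]] = {}
    for pat in patterns:
        by_support.setdefault(pat.support, []).append(frozenset(pat.items))
    kept = []
    for pat in patterns:
        s = frozenset(pat.items)
        closed = not any(
            s < other for other in by_support[pat.support]
        )
        if closed:
            kept.append(pat)
    return kept


def brute_force_frequent(m: BinaryItemMatrix, cfg: MiningConfig) -> list[ItemPattern]:
    """Exhaustive reference enumeration over all item subsets (small inputs).

    Intended as an independent oracle for :func:`apriori_frequent`; cost is
    O(n_items^max_lhs_len) row scans.
    """
    out = []
    for k in range(1, cfg.max_lhs_len + 1):
        for combo in itertools.combinations(sorted(m.items), k):
            sup = pattern_support(m, combo)
            if sup >= cfg.min_support:
                out.append(ItemPattern(tuple(combo), sup))
    return out
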