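"""Permutation nulls for post-hoc validation of a single rule.

Two schemes estimate how extreme an observed pattern-phenotype association
is under randomness:

(a) *phenotype permutation*: phenotype rows are shuffled jointly across
    individuals (preserving inter-feature correlation), breaking any
    genotype-phenotype link while keeping both margins' structure;
(b) *random patterns*: random genotype patterns of the same size as the
    rule's antecedent (one item per SNP at most) are drawn and tested
    against the same phenotype cluster.

Both report the empirical exceedance probability n_exceed / n_perm of the
observed chi-square; the positively-biased add-one estimator
(n_exceed + 1) / (n_perm + 1) is available via ``add_one``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genio import BinaryItemMatrix, PhenotypeTable
from .rulestats import ContingencyTable, chi2_test

__all__ = ["PermutationResult", "permute_phenotype", "random_patterns"]


@dataclass(frozen=True)
class PermutationResult:
    observed_stat: float  # chi-square of the rule on the original data
    n_perm: int
    n_exceed: int
    p_empirical: float
    seed: int

    def to_dict(self) -> dict:
        return {
            "observed_stat": self.observed_stat,
            "n_perm": self.n_perm,
            "n_exceed": self.n_exceed,
            "p_empirical": self.p_empirical,
            "seed": self.seed,
        }


def _vectors(m: BinaryItemMatrix, p: PhenotypeTable, lhs, rhs):
    li = [m.item_index(it) for it in list(lhs)]
    ri = [p.feature_index(f) for f in list(rhs)]
    g_obs = ~m.missing_mask[:, li].any(axis=1)
    g = m.values[:, li].all(axis=1) & g_obs
    p_obs = ~p.missing_mask[:, ri].any(axis=1)
    ph = p.values[:, ri].all(axis=1) & p_obs
    return g, g_obs, ph, p_obs


def _chi2(g, g_obs, ph, p_obs) -> float:
    both = g_obs & p_obs
    a = int((g & ph & both).sum())
    b = int((g & ~ph & both).sum())
    c = int((~g & ph & both).sum())
    d = int((~g & ~ph & both).sum())
    return chi2_test(ContingencyTable(a, b, c, d))[0]


def _result(observed: float, perm_stats: np.ndarray, seed: int,
            add_one: bool) -> PermutationResult:
    n_perm = len(perm_stats)
    n_exceed = int((perm_stats >= observed).sum())
    p_emp = (n_exceed + 1) / (n_perm + 1) if add_one else n_exceed / n_perm
    return PermutationResult(observed_stat=float(observed), n_perm=n_perm,
                             n_exceed=n_exceed, p_empirical=float(p_emp),
                             seed=seed)


def permute_phenotype(lhs, rhs, m: BinaryItemMatrix, p: PhenotypeTable,
                      n_perm: int, seed: int,
                      add_one: bool = False) -> PermutationResult:
    """Scheme (a): re-sample the phenotype by shuffling individuals.

    Phenotype rows (values and missingness together) are permuted jointly
    across individuals ``n_perm`` times; ``n_exceed`` counts permutations
    whose chi-square is at least the observed one.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    g, g_obs, ph, p_obs = _vectors(m, p, lhs, rhs)
    observed = _chi2(g, g_obs, ph, p_obs)
    t_obs = ContingencyTable(
        a=int((g & ph & g_obs & p_obs).sum()),
        b=int((g & ~ph & g_obs & p_obs).sum()),
        c=int((~g & ph & g_obs & p_obs).sum()),
        d=int((~g & ~ph & g_obs & p_obs).sum()),
    )
    if t_obs.degenerate:
        raise ValueError("observed contingency table is degenerate")
    rng = np.random.default_rng(seed)
    n = m.n_individuals
    stats = np.empty(n_perm)
    for k in range(n_perm):
        idx = rng.permutation(n)
        stats[k] = _chi2(g, g_obs, ph[idx], p_obs[idx])
    return _result(observed, stats, seed, add_one)


def random_patterns(lhs, rhs, m: BinaryItemMatrix, p: PhenotypeTable,
                    n_perm: int, seed: int, add_one: bool = False,
                    min_support: int | None = None) -> PermutationResult:
    """Scheme (b): compare against random genotype patterns of equal size.

    Draws ``n_perm`` random item sets with the same cardinality as ``lhs``
    (items uniform, at most one item per SNP: a SNP contributes either its
    carrier or its non-carrier indicator), computes each one's chi-square
    against ``rhs``, and counts exceedances.  ``min_support`` optionally
    rejects draws whose pattern support falls below the mining threshold.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    k = len(list(lhs))
    groups = {}
    for j, it in enumerate(m.items):
        groups.setdefault(m.item_group(it), []).append(j)
    group_ids = sorted(groups)
    if len(group_ids) < k:
        raise ValueError(
            f"need items from >= {k} SNPs, only {len(group_ids)} available"
        )
    g, g_obs, ph, p_obs = _vectors(m, p, lhs, rhs)
    observed = _chi2(g, g_obs, ph, p_obs)
    rng = np.random.default_rng(seed)
    V = m.values
    Miss = m.missing_mask
    stats = np.empty(n_perm)
    filled = 0
    while filled < n_perm:
        chosen = rng.choice(len(group_ids), size=k, replace=False)
        cols = [
            groups[group_ids[c]][rng.integers(len(groups[group_ids[c]]))]
            for c in chosen
        ]
        rg_obs = ~Miss[:, cols].any(axis=1)
        rg = V[:, cols].all(axis=1) & rg_obs
        if min_support is not None and int(rg.sum()) < min_support:
            continue
        stats[filled] = _chi2(rg, rg_obs, ph, p_obs)
        filled += 1
    return _result(observed, stats, seed, add_one)
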