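"""Contingency tables and per-rule statistics.

Every rule statistic derives from the 2x2 table of a genotype pattern (the
rule antecedent) against a phenotype cluster (the consequent):

    a  pattern present, phenotype present     b  pattern present, phenotype absent
    c  pattern absent,  phenotype present     d  pattern absent,  phenotype absent

The interestingness score is the signed square root of the Pearson chi-square
statistic (1 df, no continuity correction), positive when the pattern
co-occurs with the phenotype more often than independence predicts; z**2
equals chi-square exactly.  Odds ratios are raw cross-products with a Wald
confidence interval on the log scale, with an optional Haldane-Anscombe
correction for zero cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .genio import BinaryItemMatrix, PhenotypeTable

__all__ = [
    "ContingencyTable",
    "RuleStats",
    "contingency",
    "chi2_test",
    "z_score",
    "odds_ratio",
    "compute_rule_stats",
    "trend_test",
    "pattern_group_test",
]


@dataclass(frozen=True)
class ContingencyTable:
    a: int  # pattern present, phenotype present
    b: int  # pattern present, phenotype absent
    c: int  # pattern absent, phenotype present
    d: int  # pattern absent, phenotype absent

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def degenerate(self) -> bool:
        """True when some margin is empty, making the chi-square undefined."""
        return (
            self.a + self.b == 0 or self.c + self.d == 0
            or self.a + self.c == 0 or self.b + self.d == 0
        )


@dataclass(frozen=True)
class RuleStats:
    """Full statistics of one rule on one dataset."""

    z: float
    chi2: float
    p: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    n_effective: int
    table: ContingencyTable
    degenerate: bool = False


def contingency(m: BinaryItemMatrix, p: PhenotypeTable, lhs, rhs) -> ContingencyTable:
    """Cross-tabulate a genotype pattern against a phenotype cluster.

    Complete-case over the union of lhs items and rhs features; the phenotype
    is "present" only when *all* rhs features are true (conjunction, so
    multi-feature clusters are supported).  Individuals are matched
    positionally; ``m`` and ``p`` must describe the same individuals in the
    same order.
    """
    lhs = list(lhs)
    rhs = list(rhs)
    if not lhs or not rhs:
        raise ValueError("lhs and rhs must both be non-empty")
    if m.individuals != p.individuals:
        raise ValueError("genotype and phenotype individuals are not aligned")
    li = [m.item_index(it) for it in lhs]
    ri = [p.feature_index(f) for f in rhs]
    obs = ~m.missing_mask[:, li].any(axis=1) & ~p.missing_mask[:, ri].any(axis=1)
    g = m.values[:, li].all(axis=1) & obs
    ph = p.values[:, ri].all(axis=1) & obs
    a = int((g & ph & obs).sum())
    b = int((g & ~ph & obs).sum())
    c = int((~g & ph & obs).sum())
    d = int((~g & ~ph & obs).sum())
    return ContingencyTable(a, b, c, d)


def chi2_test(t: ContingencyTable) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) and its p-value.

    A degenerate table (an empty margin) returns (0.0, 1.0).
    """
    if t.degenerate:
        return 0.0, 1.0
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    n = a + b + c + d
    chi2 = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def z_score(t: ContingencyTable) -> float:
    """Signed sqrt of the chi-square: standardized deviation of `a` from its
    independence expectation; positive when pattern and phenotype co-occur
    in excess.  Degenerate tables score 0."""
    if t.degenerate:
        return 0.0
    chi2, _ = chi2_test(t)
    expected_a = (t.a + t.b) * (t.a + t.c) / t.n
    return float(math.copysign(math.sqrt(chi2), t.a - expected_a)) if chi2 else 0.0


def odds_ratio(t: ContingencyTable, correction: str = "none") -> tuple[float, float, float]:
    """Cross-product odds ratio ad/(bc) with a 95% Wald CI.

    ``correction="haldane"`` adds 0.5 to every cell when any cell is zero
    (Haldane-Anscombe); without it a zero in b or c yields an infinite OR and
    a zero in a or d yields 0, with CI bounds NaN.
    """
    if correction not in ("none", "haldane"):
        raise ValueError(f"unknown correction {correction!r}")
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    if correction == "haldane" and min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    if b * c == 0:
        return (math.inf if a * d > 0 else math.nan, math.nan, math.nan)
    or_ = (a * d) / (b * c)
    if min(a, b, c, d) == 0:  # a*d == 0 here
        return 0.0, math.nan, math.nan
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = math.exp(math.log(or_) - 1.96 * se)
    hi = math.exp(math.log(or_) + 1.96 * se)
    return or_, lo, hi


def compute_rule_stats(t: ContingencyTable, correction: str = "none") -> RuleStats:
    """Bundle chi-square, z, p and OR/CI for one table."""
    chi2, p = chi2_test(t)
    or_, lo, hi = odds_ratio(t, correction=correction)
    return RuleStats(
        z=z_score(t), chi2=chi2, p=p,
        odds_ratio=or_, ci_low=lo, ci_high=hi,
        n_effective=t.n, table=t, degenerate=t.degenerate,
    )


def trend_test(case_counts, control_counts) -> tuple[float, float]:
    """Cochran-Armitage trend test with dose scores 0/1/2.

    ``case_counts`` and ``control_counts`` are genotype-class counts
    (n0, n1, n2) for carriers of 0, 1 or 2 copies of the counted allele.
    Returns the 1-df trend chi-square and its upper-tail p-value; a
    zero-variance score distribution yields (0.0, 1.0).
    """
    r = np.asarray(case_counts, dtype=float)
    s = np.asarray(control_counts, dtype=float)
    if r.shape != (3,) or s.shape != (3,):
        raise ValueError("counts must be length-3 (n0, n1, n2)")
    if (r < 0).any() or (s < 0).any():
        raise ValueError("counts must be non-negative")
    if r.sum() == 0 or s.sum() == 0:
        raise ValueError("both groups must be non-empty")
    w = np.array([0.0, 1.0, 2.0])
    n_i = r + s
    n = n_i.sum()
    R = r.sum()
    # score statistic of the linear trend in proportions
    num = (w * (r - R * n_i / n)).sum()
    p_bar = R / n
    var = p_bar * (1 - p_bar) * ((w**2 * n_i).sum() - (w * n_i).sum() ** 2 / n)
    if var <= 0:
        return 0.0, 1.0
    chi2 = num**2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def pattern_group_test(m: BinaryItemMatrix, lhs, group_labels) -> RuleStats:
    """Test a genotype pattern for differential frequency between two groups.

    ``group_labels`` is a boolean vector aligned to the individuals of ``m``
    (e.g. case/control or subphenotype/rest); builds the 2x2 of pattern
    carriership against the label and returns full RuleStats.  Individuals
    missing any pattern item are dropped.
    """
    labels = np.asarray(group_labels, dtype=bool)
    if labels.shape != (m.n_individuals,):
        raise ValueError("group_labels must align with individuals")
    li = [m.item_index(it) for it in list(lhs)]
    if not li:
        raise ValueError("empty pattern")
    obs = ~m.missing_mask[:, li].any(axis=1)
    carrier = m.values[:, li].all(axis=1)
    t = ContingencyTable(
        a=int((carrier & labels & obs).sum()),
        b=int((carrier & ~labels & obs).sum()),
        c=int((~carrier & labels & obs).sum()),
        d=int((~carrier & ~labels & obs).sum()),
    )
    return compute_rule_stats(t)
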