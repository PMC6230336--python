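"""Multiple-testing correction over candidate-rule sets.

Two corrections are provided: Bonferroni (family-wise error control;
equivalently a per-test significance level alpha_adj = alpha / n_CR, where
n_CR is the number of candidate rules carried to replication) and the
Benjamini-Hochberg step-up false discovery rate.  Both support adjusting a
top-k list of p-values against a larger total test count, which assumes the
unreported p-values are large enough not to lower the step-up running
minimum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MTCResult", "bonferroni_adjust", "alpha_adjusted", "bh_adjust"]


@dataclass(frozen=True)
class MTCResult:
    """Raw and adjusted p-values of one rule within a family of n_tests."""

    p_raw: float
    p_bonferroni: float
    p_fdr: float
    rank: int
    n_tests: int


def bonferroni_adjust(p: float, n_tests: int) -> float:
    """min(1, p * n_tests)."""
    if not 0 <= p <= 1:
        raise ValueError(f"p-value {p} outside [0, 1]")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return min(1.0, p * n_tests)


def alpha_adjusted(n_cr: int, alpha: float = 0.05) -> float:
    """Bonferroni-adjusted per-test significance level alpha / n_CR."""
    if n_cr < 1:
        raise ValueError("n_cr must be >= 1")
    return alpha / n_cr


def bh_adjust(p_values, n_tests: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    adjusted_(i) = min(1, min_{j >= i} p_(j) * n_tests / j), with global rank
    j assigned by ascending p (ties broken by stable input order).  When the
    input is the top-k of a larger family, pass the family size as
    ``n_tests`` (must be >= k); output order matches input order.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = int(n_tests) if n_tests is not None else p.size
    if m < p.size:
        raise ValueError("n_tests must be >= number of p-values")
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, p.size + 1)
    ratio = p[order] * m / ranks
    adjusted_sorted = np.minimum(1.0, np.minimum.accumulate(ratio[::-1])[::-1])
    out = np.empty_like(p)
    out[order] = adjusted_sorted
    return out
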