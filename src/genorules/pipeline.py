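"""Discovery, replication and reporting of genotype-phenotype rules.

The three-stage procedure:

1. *Discovery* (case-only): mine closed frequent genotype patterns in the
   discovery dataset, cross every pattern with every eligible phenotype
   cluster (single features plus feature pairs meeting a prevalence floor),
   and keep rules whose interestingness z-score meets the threshold.
2. *Replication*: recompute every candidate rule's statistics in an
   independent dataset and correct for the number of candidates n_CR
   (Bonferroni per-test level alpha/n_CR, plus Benjamini-Hochberg FDR).
3. *Reporting*: rules serialized as TSV (one row per rule with counts and
   statistics) and candidate sets as JSON for stand-alone replication runs.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genio import BinaryItemMatrix, PhenotypeTable
from .mining import ItemPattern, MiningConfig, apriori_frequent, closed_filter
from .mtc import MTCResult, alpha_adjusted, bh_adjust, bonferroni_adjust
from .rulestats import ContingencyTable, RuleStats, compute_rule_stats, contingency

logger = logging.getLogger("genorules")

__all__ = [
    "CandidateRule",
    "ReplicatedRule",
    "enumerate_clusters",
    "discover",
    "replicate",
    "combine_and_test",
    "rules_to_dataframe",
    "write_rules_tsv",
    "write_candidates_json",
    "read_candidates_json",
]


@dataclass(frozen=True)
class CandidateRule:
    """A rule "genotype pattern => phenotype cluster" with discovery stats."""

    rule_id: int
    lhs: ItemPattern
    rhs: tuple[str, ...]  # phenotype cluster, conjunction of features
    discovery: RuleStats


@dataclass(frozen=True)
class ReplicatedRule:
    rule: CandidateRule
    replication: RuleStats
    mtc: MTCResult
    significant_bonferroni: bool
    significant_fdr: bool
    testable: bool = True


def enumerate_clusters(p: PhenotypeTable, max_rhs_len: int = 2,
                       min_prevalence: float = 0.05) -> list[tuple[str, ...]]:
    """Phenotype clusters eligible as rule consequents.

    All single features plus all unordered feature combinations up to
    ``max_rhs_len``, each required to reach ``min_prevalence`` joint
    (complete-case) prevalence.  Order is deterministic: by size, then by
    feature order of the table.
    """
    obs = ~p.missing_mask
    val = p.values & obs
    clusters: list[tuple[str, ...]] = []
    for size in range(1, max_rhs_len + 1):
        for combo in itertools.combinations(range(len(p.features)), size):
            ok = obs[:, combo].all(axis=1)
            n_obs = int(ok.sum())
            if n_obs == 0:
                continue
            joint = float((val[:, combo].all(axis=1) & ok).sum() / n_obs)
            if joint >= min_prevalence:
                clusters.append(tuple(p.features[j] for j in combo))
    return clusters


def discover(m: BinaryItemMatrix, p: PhenotypeTable, cfg: MiningConfig,
             min_cluster_prevalence: float = 0.05) -> list[CandidateRule]:
    """Mine candidate rules in the discovery dataset.

    Closed frequent genotype patterns are tested against every eligible
    phenotype cluster; a rule becomes a candidate when its z-score is at
    least ``cfg.z_min`` (positive associations only: rules predict phenotype
    presence).  Rule IDs are deterministic enumeration indices over the
    (pattern, cluster) grid.  Purely a function of inputs and config: no
    randomness.
    """
    if m.individuals != p.individuals:
        raise ValueError("discovery genotype/phenotype individuals not aligned")
    patterns = closed_filter(apriori_frequent(m, cfg))
    clusters = enumerate_clusters(p, cfg.max_rhs_len, min_cluster_prevalence)
    logger.info("discovery: %d closed frequent patterns, %d phenotype clusters",
                len(patterns), len(clusters))
    if not patterns or not clusters:
        return []

    # per-cluster phenotype vectors: observed / observed-and-all-true
    cl_obs = np.stack([
        ~p.missing_mask[:, [p.feature_index(f) for f in cl]].any(axis=1)
        for cl in clusters], axis=1)
    cl_val = np.stack([
        p.values[:, [p.feature_index(f) for f in cl]].all(axis=1)
        for cl in clusters], axis=1) & cl_obs

    # per-pattern cover vectors: observed / observed-and-all-true
    V = m.observed_true
    Vobs = ~m.missing_mask
    n = m.n_individuals
    G = np.empty((len(patterns), n), dtype=np.float32)
    Gobs = np.empty_like(G)
    by_len: dict[int, list[int]] = {}
    for i, pat in enumerate(patterns):
        by_len.setdefault(len(pat.items), []).append(i)
    for k, rows in by_len.items():
        idx = np.array([[m.item_index(it) for it in patterns[i].items]
                        for i in rows])
        obs = Vobs[:, idx].all(axis=2)           # n x len(rows)
        G[rows] = (V[:, idx].all(axis=2) & obs).T
        Gobs[rows] = obs.T

    # counts of the 2x2 for every (pattern, cluster) cell, complete-case over
    # the union of the pattern's items and the cluster's features
    O = cl_obs.astype(np.float32)
    Ph = cl_val.astype(np.float32)
    A = (G @ Ph).astype(np.float64)   # pattern & phenotype
    R1 = (G @ O).astype(np.float64)   # pattern present, case-complete
    C1 = (Gobs @ Ph).astype(np.float64)  # phenotype present, case-complete
    N = (Gobs @ O).astype(np.float64)    # complete cases
    B, C = R1 - A, C1 - A
    D = N - R1 - C1 + A

    # vectorized Pearson chi-square and signed z over the whole grid
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = R1 * (N - R1) * C1 * (N - C1)
        chi2 = N * (A * D - B * C) ** 2 / denom
        chi2 = np.where(denom > 0, chi2, 0.0)
        z = np.sign(A - R1 * C1 / np.where(N > 0, N, 1)) * np.sqrt(chi2)
    hit_i, hit_j = np.nonzero(z >= cfg.z_min)

    rules: list[CandidateRule] = []
    n_clusters = len(clusters)
    for i, j in zip(hit_i.tolist(), hit_j.tolist()):
        t = ContingencyTable(int(A[i, j]), int(B[i, j]),
                             int(C[i, j]), int(D[i, j]))
        rules.append(CandidateRule(
            rule_id=i * n_clusters + j + 1,
            lhs=patterns[i], rhs=clusters[j],
            discovery=compute_rule_stats(t),
        ))
    logger.info("discovery: %d candidate rules (z >= %.2f)",
                len(rules), cfg.z_min)
    return rules


def replicate(rules: list[CandidateRule], m2: BinaryItemMatrix,
              p2: PhenotypeTable, alpha: float = 0.05,
              count_untestable: bool = True) -> list[ReplicatedRule]:
    """Re-test candidate rules in an independent dataset and correct for n_CR.

    Each rule's contingency table and statistics are recomputed on the
    replication data; Bonferroni and BH adjustments use ``n_tests = n_CR``.
    A rule whose items or features are absent from the replication data is
    flagged untestable (p treated as 1); by default untestable rules still
    count toward n_CR (conservative), set ``count_untestable=False`` to
    exclude them.
    """
    reps: list[RuleStats | None] = []
    for rule in rules:
        try:
            t = contingency(m2, p2, rule.lhs.items, rule.rhs)
        except KeyError:
            reps.append(None)
            continue
        reps.append(compute_rule_stats(t))
    n_cr = len(rules) if count_untestable else sum(r is not None for r in reps)
    n_cr = max(n_cr, 1)
    p_raw = np.array([1.0 if r is None else r.p for r in reps])
    p_fdr = np.ones_like(p_raw)
    if count_untestable:
        if len(p_raw):
            p_fdr = bh_adjust(p_raw, n_tests=n_cr)
    else:
        testable_idx = np.flatnonzero([r is not None for r in reps])
        if len(testable_idx):
            p_fdr[testable_idx] = bh_adjust(p_raw[testable_idx], n_tests=n_cr)
    ranks = np.empty(len(p_raw), dtype=int)
    ranks[np.argsort(p_raw, kind="stable")] = np.arange(1, len(p_raw) + 1)
    thr = alpha_adjusted(n_cr, alpha)

    out: list[ReplicatedRule] = []
    for rule, rep, praw, pfdr, rank in zip(rules, reps, p_raw, p_fdr, ranks):
        testable = rep is not None
        if not testable:
            rep = compute_rule_stats(ContingencyTable(0, 0, 0, 0))
        mtc = MTCResult(
            p_raw=float(praw),
            p_bonferroni=bonferroni_adjust(float(praw), n_cr),
            p_fdr=float(pfdr),
            rank=int(rank),
            n_tests=n_cr,
        )
        out.append(ReplicatedRule(
            rule=rule, replication=rep, mtc=mtc,
            significant_bonferroni=testable and float(praw) <= thr,
            significant_fdr=testable and float(pfdr) <= alpha,
            testable=testable,
        ))
    n_bon = sum(r.significant_bonferroni for r in out)
    n_fdr = sum(r.significant_fdr for r in out)
    logger.info("replication: %d rules, n_CR=%d, alpha_adj=%.3e, "
                "%d Bonferroni-significant, %d FDR-significant",
                len(out), n_cr, thr, n_bon, n_fdr)
    return out


def combine_and_test(rule: CandidateRule,
                     datasets: list[tuple[BinaryItemMatrix, PhenotypeTable]]) -> RuleStats:
    """Pool individuals across datasets and re-evaluate one rule.

    Datasets must share the rule's items and features; individual IDs must
    not collide across datasets.
    """
    if not datasets:
        raise ValueError("at least one dataset required")
    seen: set[str] = set()
    a = b = c = d = 0
    for m, p in datasets:
        if m.n_individuals == 0:
            continue
        ids = set(m.individuals)
        if ids & seen:
            clash = sorted(ids & seen)[0]
            raise ValueError(f"individual ID {clash!r} appears in multiple datasets")
        seen |= ids
        t = contingency(m, p, rule.lhs.items, rule.rhs)
        a, b, c, d = a + t.a, b + t.b, c + t.c, d + t.d
    return compute_rule_stats(ContingencyTable(a, b, c, d))


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def rules_to_dataframe(rules) -> pd.DataFrame:
    """Tabulate candidate or replicated rules, one row per rule."""
    rows = []
    for r in rules:
        if isinstance(r, ReplicatedRule):
            cand, st = r.rule, r.replication
        else:
            cand, st = r, r.discovery
        row = {
            "rule_id": cand.rule_id,
            "lhs_items": ",".join(cand.lhs.items),
            "rhs_features": ",".join(cand.rhs),
            "a": st.table.a, "b": st.table.b, "c": st.table.c, "d": st.table.d,
            "z": st.z, "chi2": st.chi2, "p_chisq": st.p,
            "odds_ratio": st.odds_ratio,
            "ci_low": st.ci_low, "ci_high": st.ci_high,
        }
        if isinstance(r, ReplicatedRule):
            row.update({
                "bonferroni": r.mtc.p_bonferroni,
                "fdr": r.mtc.p_fdr,
                "significant_bonferroni": r.significant_bonferroni,
                "significant_fdr": r.significant_fdr,
            })
        rows.append(row)
    return pd.DataFrame(rows)


def _fmt(x: float) -> str:
    """4 significant digits, scientific notation below 1e-4."""
    if not np.isfinite(x):
        return str(x)
    if x != 0 and abs(x) < 1e-4:
        return f"{x:.3e}"
    return f"{x:.4g}"


def write_rules_tsv(rules, path) -> None:
    df = rules_to_dataframe(rules)
    for col in df.columns:
        if df[col].dtype == float:
            df[col] = df[col].map(_fmt)
    df.to_csv(path, sep="\t", index=False)


def write_candidates_json(rules: list[CandidateRule], path) -> None:
    """Persist candidate rules for a stand-alone replication run."""
    payload = [
        {
            "rule_id": r.rule_id,
            "lhs_items": list(r.lhs.items),
            "lhs_support": r.lhs.support,
            "rhs_features": list(r.rhs),
            "discovery": {
                "a": r.discovery.table.a, "b": r.discovery.table.b,
                "c": r.discovery.table.c, "d": r.discovery.table.d,
                "z": r.discovery.z, "chi2": r.discovery.chi2,
                "p": r.discovery.p,
            },
        }
        for r in rules
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_candidates_json(path) -> list[CandidateRule]:
    with open(path) as fh:
        payload = json.load(fh)
    rules = []
    for rec in payload:
        t = ContingencyTable(rec["discovery"]["a"], rec["discovery"]["b"],
                             rec["discovery"]["c"], rec["discovery"]["d"])
        rules.append(CandidateRule(
            rule_id=int(rec["rule_id"]),
            lhs=ItemPattern(tuple(rec["lhs_items"]), int(rec["lhs_support"])),
            rhs=tuple(rec["rhs_features"]),
            discovery=compute_rule_stats(t),
        ))
    return rules
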