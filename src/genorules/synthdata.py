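"""Synthetic genotype/phenotype data with the structure the mining assumes.

The generator emulates a case-only GWAS-derived dataset: independent SNPs in
Hardy-Weinberg equilibrium at minor-allele frequencies drawn uniformly from a
range, and binary clinical features drawn as Bernoulli at configured
prevalences.  Optionally a rule is *planted*: individuals matching a chosen
carrier pattern over up to three SNPs have the odds of one target feature
multiplied by a configured factor, so the planted parameter is directly the
odds ratio the pipeline estimates.  A truth record reports the realized
pattern frequency and feature prevalences for downstream checks.

Defaults mirror the scale of the study this package targets: 1000
individuals (a discovery-sized patient sample; replication samples run to
~1835), 1581 SNPs (3162 binary items after dominant binarization) and 23
binary clinical features with prevalences from 5% to 80%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genio import (
    MISSING,
    BinaryItemMatrix,
    GenotypeMatrix,
    PhenotypeTable,
    SnpMeta,
    binarize_dominant,
)
from .rulestats import ContingencyTable, odds_ratio

__all__ = [
    "PlantedRule",
    "SimConfig",
    "default_prevalences",
    "simulate",
    "estimate_or_recovery",
]


def default_prevalences(n_features: int = 23) -> tuple[float, ...]:
    """Feature prevalences spread evenly on [0.05, 0.80], low to high."""
    return tuple(np.round(np.linspace(0.05, 0.80, n_features), 4))


@dataclass(frozen=True)
class PlantedRule:
    """A genotype-pattern -> feature effect injected into the simulation.

    Individuals whose carrier status matches ``carrier_pattern`` on the SNPs
    at ``snp_indices`` have the odds of feature ``target_feature`` multiplied
    by ``odds_multiplier``.
    """

    snp_indices: tuple[int, ...]
    carrier_pattern: tuple[bool, ...]  # True = carrier (dosage >= 1)
    target_feature: int
    odds_multiplier: float = 4.0
    #: If set, the planted SNPs' MAFs are overridden so the expected pattern
    #: frequency equals this value (each SNP contributes frequency^(1/k)).
    pattern_frequency: float | None = None

    def __post_init__(self) -> None:
        if not 1 <= len(self.snp_indices) <= 3:
            raise ValueError("planted rule uses 1-3 SNPs")
        if len(set(self.snp_indices)) != len(self.snp_indices):
            raise ValueError("snp_indices must be distinct")
        if len(self.carrier_pattern) != len(self.snp_indices):
            raise ValueError("carrier_pattern length must match snp_indices")
        if self.odds_multiplier <= 0:
            raise ValueError("odds_multiplier must be > 0")
        if self.pattern_frequency is not None and not 0 < self.pattern_frequency < 1:
            raise ValueError("pattern_frequency must lie in (0, 1)")


@dataclass(frozen=True)
class SimConfig:
    n_individuals: int = 1000
    n_snps: int = 1581
    maf_range: tuple[float, float] = (0.05, 0.5)
    feature_prevalences: tuple[float, ...] = field(
        default_factory=default_prevalences)
    planted: PlantedRule | None = None
    missing_rate: float = 0.0
    ld_block_size: int = 1  # >1 simulates LD by haplotype copying in blocks
    ld_copy_prob: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        for q in self.feature_prevalences:
            if not 0 < q < 1:
                raise ValueError("feature prevalences must lie in (0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.planted is not None:
            if max(self.planted.snp_indices) >= self.n_snps:
                raise ValueError("planted snp_indices out of range")
            if self.planted.target_feature >= len(self.feature_prevalences):
                raise ValueError("planted target_feature out of range")


def simulate(cfg: SimConfig) -> tuple[GenotypeMatrix, PhenotypeTable, dict]:
    """Draw one dataset under ``cfg``; returns (genotypes, phenotypes, truth).

    Genotypes: per-SNP Hardy-Weinberg draws at a MAF uniform in
    ``maf_range``; with ``ld_block_size > 1`` each non-leading SNP of a block
    copies the previous SNP's genotype with probability ``ld_copy_prob`` per
    individual.  Features: independent Bernoulli at their prevalence, except
    the planted target feature whose odds are multiplied for pattern-matching
    individuals.  Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    n, p = cfg.n_individuals, cfg.n_snps
    mafs = rng.uniform(*cfg.maf_range, size=p)
    if cfg.planted is not None and cfg.planted.pattern_frequency is not None:
        k = len(cfg.planted.snp_indices)
        per_snp = cfg.planted.pattern_frequency ** (1.0 / k)
        for snp_j, want_carrier in zip(cfg.planted.snp_indices,
                                       cfg.planted.carrier_pattern):
            # carrier freq 1-(1-maf)^2 (or its complement) pinned to per_snp
            mafs[snp_j] = (maf_for_carrier_freq(per_snp) if want_carrier
                           else 1.0 - np.sqrt(per_snp))
    # HWE: dosage ~ Binomial(2, maf)
    dosage = rng.binomial(2, mafs[None, :], size=(n, p)).astype(np.int8)
    if cfg.ld_block_size > 1:
        for j in range(1, p):
            if j % cfg.ld_block_size != 0:
                copy = rng.random(n) < cfg.ld_copy_prob
                dosage[copy, j] = dosage[copy, j - 1]
    if cfg.missing_rate > 0:
        dosage[rng.random((n, p)) < cfg.missing_rate] = MISSING

    # allele labels fixed by SNP index so datasets drawn with different seeds
    # share one SNP panel (items line up between discovery and replication)
    snps = [SnpMeta(snp_id=f"rs{j + 1}", counted_allele="ACGT"[j % 4])
            for j in range(p)]
    g = GenotypeMatrix(
        individuals=[f"ind{i + 1}" for i in range(n)], snps=snps, dosage=dosage)

    # pattern membership before drawing features
    match = np.ones(n, dtype=bool)
    if cfg.planted is not None:
        for snp_j, want_carrier in zip(cfg.planted.snp_indices,
                                       cfg.planted.carrier_pattern):
            carrier = dosage[:, snp_j] >= 1
            observed = dosage[:, snp_j] != MISSING
            match &= observed & (carrier == want_carrier)
    else:
        match[:] = False

    q = np.asarray(cfg.feature_prevalences)
    probs = np.broadcast_to(q, (n, len(q))).copy()
    if cfg.planted is not None:
        base = q[cfg.planted.target_feature]
        odds = base / (1 - base) * cfg.planted.odds_multiplier
        probs[match, cfg.planted.target_feature] = odds / (1 + odds)
    if (probs >= 1).any():
        raise ValueError("planted effect implies feature probability >= 1")
    values = rng.random((n, len(q))) < probs
    missing = np.zeros_like(values)
    if cfg.missing_rate > 0:
        missing = rng.random(values.shape) < cfg.missing_rate
    pheno = PhenotypeTable(
        individuals=list(g.individuals),
        features=[f"feat{j + 1}" for j in range(len(q))],
        values=values, missing_mask=missing)

    truth = {
        "seed": cfg.seed,
        "mafs": mafs.tolist(),
        "realized_prevalences": [
            pheno.prevalence(f) for f in pheno.features],
        "planted": None,
    }
    if cfg.planted is not None:
        truth["planted"] = {
            "items": planted_items(g, cfg.planted),
            "target_feature": pheno.features[cfg.planted.target_feature],
            "odds_multiplier": cfg.planted.odds_multiplier,
            "pattern_frequency": float(match.mean()),
            "pattern_count": int(match.sum()),
        }
    return g, pheno, truth


def planted_items(g: GenotypeMatrix, planted: PlantedRule) -> list[str]:
    """Binary item IDs of the planted carrier pattern (sorted)."""
    items = []
    for snp_j, want_carrier in zip(planted.snp_indices, planted.carrier_pattern):
        s = g.snps[snp_j]
        items.append(f"{s.snp_id}_{s.counted_allele}_{int(want_carrier)}")
    return sorted(items)


def maf_for_carrier_freq(freq: float) -> float:
    """MAF at which the dominant carrier frequency 1-(1-maf)^2 equals freq."""
    if not 0 < freq < 1:
        raise ValueError("freq must lie in (0, 1)")
    return 1.0 - np.sqrt(1.0 - freq)


def estimate_or_recovery(cfg: SimConfig, n_reps: int, seed: int) -> dict:
    """Repeatedly simulate and re-estimate the planted odds ratio.

    Each replicate simulates one dataset, builds the 2x2 of planted-pattern
    carriers against the target feature, and records the cross-product odds
    ratio and whether the 95% Wald interval covers the planted value.
    Returns mean/SD of the estimates and the CI coverage.
    """
    if cfg.planted is None:
        raise ValueError("cfg must contain a planted rule")
    rng = np.random.default_rng(seed)
    ors, covered = [], []
    target = cfg.planted.odds_multiplier
    for _ in range(n_reps):
        rep_cfg = SimConfig(**{**cfg.__dict__,
                               "seed": int(rng.integers(2**31 - 1))})
        g, pheno, truth = simulate(rep_cfg)
        m = binarize_dominant(g)
        items = truth["planted"]["items"]
        li = [m.item_index(it) for it in items]
        fi = pheno.feature_index(truth["planted"]["target_feature"])
        obs = ~m.missing_mask[:, li].any(axis=1) & ~pheno.missing_mask[:, fi]
        carrier = m.values[:, li].all(axis=1)
        ph = pheno.values[:, fi]
        t = ContingencyTable(
            a=int((carrier & ph & obs).sum()),
            b=int((carrier & ~ph & obs).sum()),
            c=int((~carrier & ph & obs).sum()),
            d=int((~carrier & ~ph & obs).sum()),
        )
        or_, lo, hi = odds_ratio(t, correction="haldane")
        ors.append(or_)
        covered.append(bool(lo <= target <= hi) if np.isfinite(lo) else False)
    ors = np.asarray(ors, dtype=float)
    return {
        "n_reps": n_reps,
        "target_or": target,
        "mean_or": float(np.mean(ors)),
        "sd_or": float(np.std(ors, ddof=1)) if n_reps > 1 else 0.0,
        "ci_coverage": float(np.mean(covered)),
        "ors": ors.tolist(),
    }
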