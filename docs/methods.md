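# Methods

## Model and procedure

`genorules` treats a patient cohort as a transaction database: each
individual's "basket" contains binary genotype items and binary clinical
features. The analysis has three stages.

**Binarization.** Additive dosages (0/1/2 copies of a counted allele) are
collapsed under a dominant genetic model: each SNP becomes two complementary
items, `<snp>_<allele>_1` (carrier, dosage ≥ 1) and `<snp>_<allele>_0`
(non-carrier, dosage = 0). A missing dosage flags both items missing, and
missingness is handled complete-case everywhere downstream — an individual
contributes to a pattern's support or a rule's 2×2 table only when all the
items and features involved are observed. The dominant collapse is lossless
for carrier status, and item count is exactly twice SNP count. Before
mining, SNPs can be LD-pruned by greedy sliding-window removal of one SNP
from every pair with squared dosage correlation above a threshold (defaults
r² > 0.5, window 50 SNPs, step 5 — the common PLINK convention). r² against
a monomorphic SNP is defined as 0, so a zero-variance SNP never removes a
partner; pruning a pruned panel is a no-op.

**Discovery.** Frequent genotype patterns are enumerated level-wise
(Apriori): candidates of length k+1 come from lexicographic prefix joins of
frequent k-patterns, are pruned when any k-subset is infrequent, and the two
items of one SNP are never joined (their co-support is structurally zero).
Apriori is exact — the output equals exhaustive subset enumeration — and well
suited here because pattern length is capped low. The frequent set is reduced
to *closed* patterns: a pattern is dropped iff a strict superset with
identical support exists within the length-bounded frequent set (a length-3
pattern cannot be un-closed by a length-4 superset, which is never
enumerated). Each closed pattern is tested against every eligible phenotype
cluster — all single features plus all feature pairs whose joint
complete-case prevalence reaches 5%, mirroring the feature-frequency
selection floor. A rule becomes a candidate when its z-score (below) is at
least the threshold; only positive z qualifies, i.e. rules predict phenotype
*presence*. Discovery is case-only and fully deterministic; rule IDs are
enumeration indices over the (pattern, cluster) grid.

**Replication.** Every candidate is re-tested on an independent dataset.
With n_CR candidates, the Bonferroni per-test level is α_adj = α / n_CR and
Benjamini–Hochberg step-up FDR-adjusted p-values are reported alongside
(Bonferroni controls the family-wise error but is conservative when rules
overlap, which mined rules do heavily; FDR trades some type-I control for
power). A rule whose items or features are absent from the replication data
is flagged untestable; by default it still counts toward n_CR
(conservative).

## Statistics

All rule statistics derive from the 2×2 table (a, b, c, d) of pattern ×
phenotype-cluster:

- Pearson χ² with 1 df and no continuity correction,
  χ² = n(ad−bc)²/[(a+b)(c+d)(a+c)(b+d)]; a table with an empty margin is
  flagged degenerate and scored χ² = 0, p = 1.
- Interestingness z = sign(a − (a+b)(a+c)/n) · √χ². This is the standardized
  deviation of the joint count from its independence expectation, so z² = χ²
  identically and a z ≥ 5 cut equals a one-sided χ² ≥ 25 rule. Because small
  subgroups deviate more easily in relative terms, this measure is biased
  toward low-prevalence phenotypes — a property of the approach, visible in
  which rules it promotes.
- Odds ratio as the raw cross-product ad/(bc) with a 95% Wald CI on the log
  scale; optional Haldane–Anscombe correction (+0.5 on all cells) when any
  cell is zero. Without correction, bc = 0 yields an infinite OR flag.
- Cochran–Armitage trend test (scores 0/1/2) for single-SNP dose effects,
  used to check that a rule's association is carried by the SNP combination
  rather than one marker.
- `pattern_group_test` compares pattern-carrier frequency between two labeled
  groups (e.g. subphenotype cases vs controls) with the same machinery.

Multiple-testing helpers support adjusting a top-k list against a larger
family size n_tests ≥ k; this assumes the unreported p-values are large
enough not to lower the BH running minimum — exact whenever the listed
p-values are the k smallest, as in a top-k report.

## Permutation nulls

Scheme (a) shuffles phenotype rows jointly across individuals (whole rows,
preserving inter-feature correlation — the alternative of permuting features
independently would break it); scheme (b) draws random item sets of the same
cardinality as the rule's pattern, uniform with at most one item per SNP,
optionally filtered by minimum support. Both report the empirical p as
n_exceed/n_perm, matching a granularity of 1/n_perm; the positively biased
add-one estimator (n_exceed+1)/(n_perm+1) is available via a flag.

Numerical caveat: under within-dataset permutation the χ² statistic is a
function of the single hypergeometric cell count a (margins are fixed), so
at small sample sizes its distribution is visibly discrete. Ties with the
observed statistic count as exceedances, which makes the empirical p
conservative (super-uniform) at small n. Calibration checks therefore use
samples of ~1000 individuals, where the statistic is near-continuous and
empirical p-values are uniform to Kolmogorov–Smirnov precision; at n ≈ 150
the conservativeness is measurable. This is a property of discrete
permutation tests generally, not of the implementation.

## Synthetic data

The generator emulates the structure the analysis assumes, at the scale of
the motivating study design: defaults of 1000 individuals (a
discovery-sized patient sample; replication cohorts run to ~1835), 1581
independent SNPs in Hardy–Weinberg equilibrium with MAF uniform on
[0.05, 0.5] (3162 items after binarization), and 23 binary features with
prevalences evenly spread over [0.05, 0.80]. A planted rule multiplies the
*odds* of one target feature for individuals matching a chosen carrier
pattern, so the planted parameter is directly the odds ratio the pipeline
estimates; `pattern_frequency` optionally pins the planted SNPs' allele
frequencies so the expected pattern frequency is exact (each SNP contributes
the k-th root). SNPs are independent by default; an optional block-LD mode
copies the previous SNP's genotype with a configurable probability inside
fixed-size blocks, to exercise LD pruning. Missingness is
missing-completely-at-random at a configurable rate.

What the generator does *not* emulate: population structure and relatedness,
imputation uncertainty, realistic LD decay, phenotype correlation structure
(features are independent apart from the planted effect), and
ascertainment. Passing tests on this generator therefore demonstrate the
correctness and calibration of the machinery — exact mining, calibrated
type-I error, unbiased effect recovery — not robustness to those real-data
complications.

Test and calibration runs use scaled-down problem sizes chosen to keep the
statistical targets meaningful: mining-equivalence checks use ≤12 items × ≤40
individuals (where exhaustive enumeration is feasible); power and
recovery use 12 SNPs × 2000 individuals with a 3-SNP rule at 10% pattern
frequency, 10% feature prevalence and OR 4 (predicted z ≈ 8.5, comfortably
above the z ≥ 5 cut, so recovery failures reflect sampling noise only); the
study-scale replication scenario uses n = 1835, 6% pattern frequency, 7%
prevalence, OR 4 against the published multiple-testing burden of 20,882
candidate rules.

## Design choices

- **z as signed √χ².** The interestingness measure is defined as the signed
  root of the Pearson χ²; this is the standard 2×2 standardization, makes
  z² = χ² an identity rather than an approximation, and reproduces the
  published worked examples exactly from their printed counts.
- **Closure within the bounded lattice.** Closedness is evaluated relative
  to the enumerated (length ≤ 3) frequent set; supersets beyond the length
  cap are never considered.
- **Raw cross-product OR.** The published odds ratios for the top rules
  differ slightly from the cross-product of their printed counts (3.566 vs
  3.556 for the strongest rule), suggesting a model-based estimate whose
  exact form is not documented. Rather than guess, the package reports the
  raw cross-product with a Wald interval and treats the OR as descriptive;
  p-values, which do reproduce exactly, carry the inference.
- **Missingness.** No imputation anywhere; complete-case per pattern/rule.
  With MCAR missingness this costs power but not validity.
- **Tie-breaks and determinism.** Items are ordered lexicographically for
  prefix joins; BH rank ties are broken by stable input order; discovery and
  replication contain no randomness, and every random component (simulation,
  permutation) is driven by a single integer seed through one PCG64 stream.
- **LD pruning windows** advance over the surviving SNP list (window 50,
  step 5), removing the later SNP of the worst pair first; with a window
  covering the whole panel this is exact greedy pruning, and on the default
  settings it matches the common PLINK-style behavior of leaving no
  within-window pair above threshold.

## Limitations

- Runtime grows steeply with the number of frequent patterns; the
  implementation is vectorized for the pattern-count × cohort sizes used
  here (10⁴ patterns × 10³–10⁴ individuals), not for genome-wide panels.
- The discovery z-threshold is applied per (pattern, cluster) test without
  a discovery-stage multiplicity correction — by design, since control is
  deferred to replication; discovery output alone is exploratory.
- Closed-set reduction removes only exact-support redundancy; strongly
  correlated (but not identical-support) patterns still inflate n_CR, making
  Bonferroni conservative — the motivation for reporting FDR alongside.
- The BH top-k adjustment against a larger family is exact only when the
  listed p-values are the smallest of the family.
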