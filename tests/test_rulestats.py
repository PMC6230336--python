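"""Contingency statistics: chi-square, z, odds ratio, trend test."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from genorules import (
    ContingencyTable,
    binarize_dominant,
    chi2_test,
    compute_rule_stats,
    contingency,
    odds_ratio,
    pattern_group_test,
    trend_test,
    z_score,
)

from conftest import TABLE1, random_genotypes, random_phenotypes


def random_tables(rng, k, nmax=500):
    for _ in range(k):
        yield ContingencyTable(*(int(x) for x in rng.integers(1, nmax, 4)))


class TestContingency:
    def test_all_present(self, aligned_pair):
        m, p = aligned_pair
        m.values[:, 1] = True  # make one carrier item universal
        p.values[:, 0] = True
        t = contingency(m, p, [m.items[1]], ["f1"])
        assert (t.a, t.b, t.c, t.d) == (t.n, 0, 0, 0)

    def test_counts_equal_row_scan(self, rng):
        m = binarize_dominant(random_genotypes(rng, 20, 3))
        p = random_phenotypes(rng, 20, [("f1", 0.5), ("f2", 0.5)])
        lhs, rhs = [m.items[1], m.items[4]], ["f1", "f2"]
        t = contingency(m, p, lhs, rhs)
        li = [m.items.index(x) for x in lhs]
        a = b = c = d = 0
        for i in range(20):
            g = all(m.values[i, j] for j in li)
            ph = all(p.values[i, p.features.index(f)] for f in rhs)
            a += g and ph
            b += g and not ph
            c += (not g) and ph
            d += (not g) and not ph
        assert (t.a, t.b, t.c, t.d) == (a, b, c, d)

    def test_missing_rhs_value_shrinks_n(self, aligned_pair):
        m, p = aligned_pair
        t0 = contingency(m, p, [m.items[1]], ["f1"])
        p.missing_mask[0, 0] = True
        t1 = contingency(m, p, [m.items[1]], ["f1"])
        assert t1.n == t0.n - 1

    def test_empty_sides_rejected(self, aligned_pair):
        m, p = aligned_pair
        with pytest.raises(ValueError):
            contingency(m, p, [], ["f1"])
        with pytest.raises(ValueError):
            contingency(m, p, [m.items[0]], [])


class TestChi2:
    @pytest.mark.parametrize("pid", sorted(TABLE1))
    def test_published_pvalues_reproduced(self, pid):
        chi2, p = chi2_test(ContingencyTable(*TABLE1[pid]["counts"]))
        assert float(f"{p:.3e}") == pytest.approx(TABLE1[pid]["p"], rel=1e-9)

    def test_independence_gives_zero(self):
        assert chi2_test(ContingencyTable(10, 10, 10, 10)) == (0.0, 1.0)

    def test_zero_margin_degenerate(self):
        t = ContingencyTable(5, 5, 0, 0)
        assert t.degenerate
        assert chi2_test(t) == (0.0, 1.0)

    def test_matches_expected_counts_formula_and_scipy(self, rng):
        for t in random_tables(rng, 200):
            obs = np.array([[t.a, t.b], [t.c, t.d]], dtype=float)
            exp = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
            textbook = ((obs - exp) ** 2 / exp).sum()
            chi2, p = chi2_test(t)
            assert chi2 == pytest.approx(textbook, rel=1e-9)
            sp_chi2, sp_p, _, _ = sps.chi2_contingency(obs, correction=False)
            assert chi2 == pytest.approx(sp_chi2, rel=1e-9)
            assert p == pytest.approx(sp_p, rel=1e-9)

    def test_p_monotone_in_chi2(self, rng):
        pairs = [chi2_test(t) for t in random_tables(rng, 100)]
        pairs.sort()
        ps = [p for _, p in pairs]
        assert all(p1 >= p2 for p1, p2 in zip(ps, ps[1:]))


class TestZScore:
    def test_independence_is_zero(self):
        assert z_score(ContingencyTable(10, 10, 10, 10)) == 0.0

    def test_positive_association_value(self):
        t = ContingencyTable(25, 105, 107, 1598)
        assert z_score(t) == pytest.approx(5.5106, abs=1e-4)
        assert z_score(t) == pytest.approx(math.sqrt(30.3667), abs=1e-4)

    def test_sign_flips_when_association_reverses(self, rng):
        for t in random_tables(rng, 50):
            flipped = ContingencyTable(t.b, t.a, t.d, t.c)
            assert z_score(flipped) == pytest.approx(-z_score(t), rel=1e-9)

    def test_z_squared_equals_chi2(self, rng):
        for t in random_tables(rng, 500):
            chi2, _ = chi2_test(t)
            assert z_score(t) ** 2 == pytest.approx(chi2, rel=1e-9)


class TestOddsRatio:
    def test_uniform_table_is_one(self):
        assert odds_ratio(ContingencyTable(1, 1, 1, 1))[0] == 1.0

    def test_cross_product_value(self):
        or_, lo, hi = odds_ratio(ContingencyTable(25, 105, 107, 1598))
        assert or_ == pytest.approx(3.556, abs=5e-4)
        assert lo < or_ < hi

    def test_haldane_makes_zero_cell_finite(self):
        or_, lo, hi = odds_ratio(ContingencyTable(2, 0, 1, 5),
                                 correction="haldane")
        assert np.isfinite(or_) and np.isfinite(lo) and np.isfinite(hi)

    def test_zero_bc_without_correction_is_infinite(self):
        or_, _, _ = odds_ratio(ContingencyTable(2, 0, 1, 5))
        assert math.isinf(or_)

    def test_wald_ci_brackets_estimate(self, rng):
        for t in random_tables(rng, 50):
            or_, lo, hi = odds_ratio(t)
            assert lo <= or_ <= hi


class TestTrendTest:
    def test_frozen_reference_value(self):
        # reference computed independently with R stats::prop.trend.test,
        # scores 0/1/2
        chi2, p = trend_test((30, 10, 0), (10, 10, 20))
        assert chi2 == pytest.approx(29.0909090909, rel=1e-9)
        assert p == pytest.approx(6.906029e-08, rel=1e-5)

    def test_identical_distributions_are_null(self):
        assert trend_test((10, 20, 5), (10, 20, 5)) == (0.0, 1.0)

    def test_group_swap_preserves_p(self):
        _, p1 = trend_test((30, 10, 0), (10, 10, 20))
        _, p2 = trend_test((10, 10, 20), (30, 10, 0))
        assert p1 == pytest.approx(p2, rel=1e-9)

    def test_zero_variance_flagged_null(self):
        assert trend_test((10, 0, 0), (20, 0, 0)) == (0.0, 1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            trend_test((0, 0, 0), (1, 1, 1))


class TestPatternGroupTest:
    def test_matches_hand_composition(self, rng):
        m = binarize_dominant(random_genotypes(rng, 150, 4))
        labels = rng.random(150) < 0.4
        lhs = [m.items[1], m.items[5]]
        st = pattern_group_test(m, lhs, labels)
        carrier = m.values[:, [1, 5]].all(axis=1)
        t = ContingencyTable(
            int((carrier & labels).sum()), int((carrier & ~labels).sum()),
            int((~carrier & labels).sum()), int((~carrier & ~labels).sum()))
        expected = compute_rule_stats(t)
        assert st == expected

    def test_labels_equal_carrier_status_maximal(self, rng):
        m = binarize_dominant(random_genotypes(rng, 100, 2))
        carrier = m.values[:, 1]
        if carrier.all() or not carrier.any():
            pytest.skip("degenerate draw")
        st = pattern_group_test(m, [m.items[1]], carrier)
        assert st.chi2 == pytest.approx(m.n_individuals)  # perfect 2x2

    def test_joint_permutation_invariance(self, rng):
        m = binarize_dominant(random_genotypes(rng, 120, 3))
        labels = rng.random(120) < 0.5
        perm = rng.permutation(120)
        # permute rows of m jointly with labels
        from genorules import BinaryItemMatrix
        mp = BinaryItemMatrix([m.individuals[i] for i in perm], m.items,
                              m.values[perm], m.missing_mask[perm])
        assert pattern_group_test(m, [m.items[1]], labels) == \
            pattern_group_test(mp, [m.items[1]], labels[perm])
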