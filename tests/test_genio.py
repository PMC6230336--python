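"""Genotype/phenotype I/O, dominant binarization and LD pruning."""

import numpy as np
import pytest

from genorules import (
    MISSING,
    GenotypeMatrix,
    SnpMeta,
    binarize_dominant,
    ld_prune,
    read_phenotypes,
    read_plink_raw,
    subset_snps,
    write_phenotypes,
    write_plink_raw,
)
from genorules.genio import FormatError

from conftest import random_genotypes

RAW_HEADER = "FID IID PAT MAT SEX PHENOTYPE"


def write_raw(tmp_path, body, name="test.raw"):
    path = tmp_path / name
    path.write_text(body)
    return path


class TestReadPlinkRaw:
    def test_parses_dosages_and_counted_allele(self, tmp_path):
        path = write_raw(tmp_path, f"{RAW_HEADER} rs1_A\nf1 i1 0 0 1 2 0\nf2 i2 0 0 1 2 2\n")
        g = read_plink_raw(path)
        assert [s.snp_id for s in g.snps] == ["rs1"]
        assert g.snps[0].counted_allele == "A"
        assert g.dosage.tolist() == [[0], [2]]
        assert g.individuals == ["i1", "i2"]

    def test_na_becomes_missing(self, tmp_path):
        path = write_raw(tmp_path, f"{RAW_HEADER} rs1_A\nf1 i1 0 0 1 2 NA\n")
        g = read_plink_raw(path)
        assert g.dosage[0, 0] == MISSING

    def test_malformed_header_rejected(self, tmp_path):
        path = write_raw(tmp_path, "FID IID SEX rs1_A\nf1 i1 1 0\n")
        with pytest.raises(FormatError):
            read_plink_raw(path)

    def test_bad_dosage_names_row_and_column(self, tmp_path):
        path = write_raw(tmp_path, f"{RAW_HEADER} rs1_A\nf1 i1 0 0 1 2 3\n")
        with pytest.raises(ValueError, match="rs1_A"):
            read_plink_raw(path)

    def test_round_trip(self, tmp_path, rng):
        g = random_genotypes(rng, 10, 5, missing_rate=0.1)
        path = tmp_path / "rt.raw"
        write_plink_raw(g, path)
        g2 = read_plink_raw(path)
        assert g2.individuals == g.individuals
        assert [s.snp_id for s in g2.snps] == [s.snp_id for s in g.snps]
        assert [s.counted_allele for s in g2.snps] == [s.counted_allele for s in g.snps]
        np.testing.assert_array_equal(g2.dosage, g.dosage)


class TestReadPhenotypes:
    def test_prevalence_and_missing_codes(self, tmp_path):
        path = tmp_path / "p.tsv"
        path.write_text("IID\tf1\tf2\ni1\t1\t-9\ni2\t1\t0\n")
        p = read_phenotypes(path, missing_codes={"-9"})
        assert p.prevalence("f1") == 1.0
        assert p.missing_mask[0, 1] and not p.missing_mask[1, 1]

    def test_exact_missing_fraction(self, tmp_path):
        lines = ["IID\tf1"] + [f"i{k}\t{'NA' if k == 0 else 1}" for k in range(10)]
        path = tmp_path / "p.tsv"
        path.write_text("\n".join(lines) + "\n")
        p = read_phenotypes(path)
        assert p.missing_fraction("f1") == pytest.approx(0.10)

    def test_duplicate_ids_rejected(self, tmp_path):
        path = tmp_path / "p.tsv"
        path.write_text("IID\tf1\ni1\t1\ni1\t0\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_phenotypes(path)

    def test_non_binary_value_rejected(self, tmp_path):
        path = tmp_path / "p.tsv"
        path.write_text("IID\tf1\ni1\t2\n")
        with pytest.raises(ValueError, match="non-binary"):
            read_phenotypes(path)

    def test_round_trip(self, tmp_path, rng):
        from conftest import random_phenotypes
        p = random_phenotypes(rng, 12, [("f1", 0.4), ("f2", 0.6)],
                              missing_rate=0.2)
        path = tmp_path / "p.tsv"
        write_phenotypes(p, path)
        p2 = read_phenotypes(path)
        np.testing.assert_array_equal(p2.values & ~p2.missing_mask,
                                      p.values & ~p.missing_mask)
        np.testing.assert_array_equal(p2.missing_mask, p.missing_mask)


class TestBinarizeDominant:
    def test_two_items_per_snp_and_names(self, rng):
        g = random_genotypes(rng, 5, 3)
        m = binarize_dominant(g)
        assert m.n_items == 2 * g.n_snps
        assert m.items[:2] == ["rs0_A_0", "rs0_A_1"]

    @pytest.mark.parametrize("dosage,expect", [(0, (True, False)),
                                               (1, (False, True)),
                                               (2, (False, True))])
    def test_dominant_mapping(self, dosage, expect):
        g = GenotypeMatrix(["i1"], [SnpMeta("rs1", "A")],
                           np.array([[dosage]], dtype=np.int8))
        m = binarize_dominant(g)
        assert (bool(m.values[0, 0]), bool(m.values[0, 1])) == expect

    def test_missing_propagates_to_both_items(self):
        g = GenotypeMatrix(["i1"], [SnpMeta("rs1", "A")],
                           np.array([[MISSING]], dtype=np.int8))
        m = binarize_dominant(g)
        assert m.missing_mask[0].all()
        assert not m.values[0].any()

    def test_complementarity_and_lossless_reconstruction(self, rng):
        g = random_genotypes(rng, 50, 20, missing_rate=0.1)
        m = binarize_dominant(g)
        non_missing = g.dosage != MISSING
        zero = m.values[:, 0::2]
        one = m.values[:, 1::2]
        # exactly one of the two items true wherever the dosage is observed
        assert (zero[non_missing] ^ one[non_missing]).all()
        # carrier status reconstructs exactly from the _1 item
        np.testing.assert_array_equal(one[non_missing],
                                      (g.dosage >= 1)[non_missing])
        # missing dosage flags both items
        np.testing.assert_array_equal(m.missing_mask[:, 0::2], ~non_missing)
        np.testing.assert_array_equal(m.missing_mask[:, 1::2], ~non_missing)


class TestLdPrune:
    def test_duplicated_snp_keeps_exactly_one(self, rng):
        g = random_genotypes(rng, 100, 1)
        dup = GenotypeMatrix(
            g.individuals,
            [SnpMeta("rs0", "A"), SnpMeta("rs0b", "A")],
            np.hstack([g.dosage, g.dosage]),
        )
        kept = ld_prune(dup, r2_max=0.5)
        assert kept == ["rs0"]

    def test_independent_snps_mostly_kept(self):
        kept_frac = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            g = random_genotypes(rng, 500, 30, maf=(0.3, 0.3))
            kept = ld_prune(g, r2_max=0.5)
            kept_frac.append(len(kept) / g.n_snps)
        assert np.mean(kept_frac) >= 0.95

    def test_subset_order_and_idempotence(self, rng):
        g = random_genotypes(rng, 80, 12)
        g.dosage[:, 5] = g.dosage[:, 2]  # force one high-LD pair
        kept = ld_prune(g, r2_max=0.5, window=6, step=2)
        ids = [s.snp_id for s in g.snps]
        assert len(kept) <= g.n_snps
        assert [i for i in ids if i in set(kept)] == kept  # order preserved
        pruned = subset_snps(g, kept)
        assert ld_prune(pruned, r2_max=0.5, window=6, step=2) == kept

    def test_zero_variance_snp_never_removes_others(self, rng):
        g = random_genotypes(rng, 100, 3)
        g.dosage[:, 1] = 1  # monomorphic
        kept = ld_prune(g, r2_max=0.01)  # aggressive threshold
        assert "rs1" in kept  # r^2 with a constant column is defined as 0
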