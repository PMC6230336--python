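"""Shared fixtures: small genotype/phenotype objects built in memory."""

import numpy as np
import pytest

from genorules import (
    BinaryItemMatrix,
    GenotypeMatrix,
    PhenotypeTable,
    SnpMeta,
    binarize_dominant,
)

# Published replication-stage reference: the ten strongest rules' 2x2 counts
# (genotype pattern x phenotype cluster) in a 1835-patient dataset, with the
# reported chi-square p-values and adjusted p-values at 20,882 tests.
TABLE1 = {
    12978: {"counts": (25, 105, 107, 1598), "p": 3.576e-08,
            "bonferroni": 0.00075, "fdr": 0.00075},
    6221: {"counts": (26, 84, 162, 1563), "p": 1.780e-06,
           "bonferroni": 0.03717, "fdr": 0.01859},
    12681: {"counts": (33, 103, 187, 1512), "p": 4.648e-06,
            "bonferroni": 0.09706, "fdr": 0.02771},
    12981: {"counts": (25, 129, 107, 1574), "p": 5.720e-06,
            "bonferroni": 0.11944, "fdr": 0.02771},
    6225: {"counts": (25, 84, 163, 1563), "p": 6.635e-06,
           "bonferroni": 0.13855, "fdr": 0.02771},
    6228: {"counts": (26, 93, 162, 1554), "p": 1.585e-05,
           "bonferroni": 0.33102, "fdr": 0.05517},
    4428: {"counts": (31, 88, 212, 1504), "p": 2.021e-05,
           "bonferroni": 0.42198, "fdr": 0.06028},
    6111: {"counts": (21, 109, 111, 1594), "p": 4.096e-05,
           "bonferroni": 0.85530, "fdr": 0.10654},
    6183: {"counts": (20, 66, 168, 1581), "p": 4.592e-05,
           "bonferroni": 0.95887, "fdr": 0.10654},
    6178: {"counts": (20, 68, 168, 1579), "p": 7.577e-05,
           "bonferroni": 1.0, "fdr": 0.15823},
}
N_CANDIDATE_RULES = 20882


def random_genotypes(rng, n, p, maf=(0.1, 0.5), missing_rate=0.0):
    """Random HWE GenotypeMatrix for structural tests."""
    mafs = rng.uniform(*maf, size=p)
    dosage = rng.binomial(2, mafs, size=(n, p)).astype(np.int8)
    if missing_rate:
        dosage[rng.random((n, p)) < missing_rate] = -1
    snps = [SnpMeta(f"rs{j}", "A") for j in range(p)]
    return GenotypeMatrix([f"i{k}" for k in range(n)], snps, dosage)


def random_phenotypes(rng, n, features, missing_rate=0.0, individuals=None):
    q = np.asarray([f[1] for f in features])
    names = [f[0] for f in features]
    values = rng.random((n, len(q))) < q
    missing = (rng.random(values.shape) < missing_rate if missing_rate
               else np.zeros_like(values))
    ids = individuals or [f"i{k}" for k in range(n)]
    return PhenotypeTable(ids, names, values, missing)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_items():
    """Three single-item 'SNPs' with supports A=4, B=2 (subset of A), C=1."""
    values = np.array([
        [True, True, True],
        [True, True, False],
        [True, False, False],
        [True, False, False],
    ])
    # make C true only on row 0 and B a subset of A
    values[:, 2] = [True, False, False, False]
    return BinaryItemMatrix(
        individuals=["i0", "i1", "i2", "i3"],
        items=["sA_A_1", "sB_A_1", "sC_A_1"],
        values=values,
        missing_mask=np.zeros_like(values),
    )


@pytest.fixture
def aligned_pair(rng):
    """A 200-individual genotype/phenotype pair with no missing data."""
    g = random_genotypes(rng, 200, 6)
    m = binarize_dominant(g)
    p = random_phenotypes(rng, 200, [("f1", 0.3), ("f2", 0.5)],
                          individuals=list(m.individuals))
    return m, p
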