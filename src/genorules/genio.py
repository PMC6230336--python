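"""Genotype/phenotype I/O, dominant-model binarization and LD pruning.

Genotypes are carried as additive dosages (0/1/2 copies of a counted allele)
in the PLINK ``--recode A`` text dialect (".raw"): a whitespace-separated
table whose first six columns are FID IID PAT MAT SEX PHENOTYPE, followed by
one column per SNP named ``<snp_id>_<counted_allele>``.  Rule mining requires
binary items, so each SNP is split into two complementary indicator items
under a dominant genetic model: carrier of at least one counted allele
(suffix ``_1``) versus non-carrier (suffix ``_0``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel for a missing dosage in :class:`GenotypeMatrix.dosage`.
MISSING: int = -1

DEFAULT_MISSING_CODES = frozenset({"NA", "-9", ""})


class FormatError(ValueError):
    """Raised when an input file does not conform to the expected dialect."""


@dataclass(frozen=True)
class SnpMeta:
    """Identity of one SNP: rsID plus the allele whose dosage is counted."""

    snp_id: str
    counted_allele: str
    other_allele: str = "0"
    chromosome: str | None = None
    position: int | None = None

    def __post_init__(self) -> None:
        if not self.snp_id:
            raise ValueError("snp_id must be non-empty")
        if self.counted_allele == self.other_allele:
            raise ValueError(
                f"{self.snp_id}: counted and other allele must differ"
            )


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs additive dosage matrix with missingness sentinel."""

    individuals: list[str]
    snps: list[SnpMeta]
    dosage: np.ndarray  # int8, values in {0, 1, 2, MISSING}

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.individuals), len(self.snps)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.snps)} SNPs"
            )
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid dosage {self.dosage[i, j]} for individual "
                f"{self.individuals[i]!r}, SNP {self.snps[j].snp_id!r}"
            )
        ids = [s.snp_id for s in self.snps]
        if len(set(ids)) != len(ids):
            raise ValueError("SNP IDs must be unique")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def snp_index(self, snp_id: str) -> int:
        try:
            return [s.snp_id for s in self.snps].index(snp_id)
        except ValueError:
            raise KeyError(snp_id) from None


@dataclass
class BinaryItemMatrix:
    """Individuals x binary genotype items, two complementary items per SNP.

    Item IDs follow ``<snp_id>_<counted_allele>_<k>`` with ``k=1`` marking
    carriers (dosage >= 1) and ``k=0`` non-carriers (dosage == 0).  A missing
    dosage flags both items of its SNP as missing.
    """

    individuals: list[str]
    items: list[str]
    values: np.ndarray  # bool, n_individuals x n_items
    missing_mask: np.ndarray  # bool, same shape

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        shape = (len(self.individuals), len(self.items))
        if self.values.shape != shape or self.missing_mask.shape != shape:
            raise ValueError("values/missing_mask shape mismatch")
        if len(set(self.items)) != len(self.items):
            raise ValueError("item IDs must be unique")
        self._index = {it: k for k, it in enumerate(self.items)}

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_items(self) -> int:
        return len(self.items)

    def item_index(self, item: str) -> int:
        try:
            return self._index[item]
        except KeyError:
            raise KeyError(f"unknown item {item!r}") from None

    def item_group(self, item: str) -> str:
        """SNP-level group key of an item (item ID minus its _0/_1 suffix)."""
        return item.rsplit("_", 1)[0]

    @property
    def observed_true(self) -> np.ndarray:
        """Boolean matrix: item is present and not missing."""
        return self.values & ~self.missing_mask


@dataclass
class PhenotypeTable:
    """Individuals x binary clinical features with missingness mask."""

    individuals: list[str]
    features: list[str]
    values: np.ndarray  # bool
    missing_mask: np.ndarray  # bool

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        shape = (len(self.individuals), len(self.features))
        if self.values.shape != shape or self.missing_mask.shape != shape:
            raise ValueError("values/missing_mask shape mismatch")
        if len(set(self.features)) != len(self.features):
            raise ValueError("feature names must be unique")
        self._index = {f: k for k, f in enumerate(self.features)}

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def feature_index(self, feature: str) -> int:
        try:
            return self._index[feature]
        except KeyError:
            raise KeyError(f"unknown feature {feature!r}") from None

    def prevalence(self, feature: str) -> float:
        """Complete-case prevalence of one feature."""
        j = self.feature_index(feature)
        obs = ~self.missing_mask[:, j]
        if not obs.any():
            return float("nan")
        return float(self.values[obs, j].mean())

    def missing_fraction(self, feature: str) -> float:
        j = self.feature_index(feature)
        return float(self.missing_mask[:, j].mean())


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_RAW_META_COLS = ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE")


def read_plink_raw(path, *, sep: str | None = None) -> GenotypeMatrix:
    """Read a PLINK additive-dosage text file (``--recode A`` dialect).

    Parameters
    ----------
    path
        File with header ``FID IID PAT MAT SEX PHENOTYPE`` followed by SNP
        columns named ``<snp_id>_<counted_allele>``; cells are 0/1/2 or NA.
    sep
        Field separator; default splits on any whitespace.

    Returns
    -------
    GenotypeMatrix
        Individuals keyed by IID; counted allele parsed from column suffix.
    """
    df = pd.read_csv(path, sep=sep if sep is not None else r"\s+",
                     dtype=str, engine="python")
    header = list(df.columns)
    if tuple(header[: len(_RAW_META_COLS)]) != _RAW_META_COLS:
        raise FormatError(
            f"{path}: header must start with {' '.join(_RAW_META_COLS)}, "
            f"got {' '.join(header[:6])}"
        )
    snp_cols = header[len(_RAW_META_COLS):]
    if not snp_cols:
        raise FormatError(f"{path}: no SNP columns found")
    snps = []
    for col in snp_cols:
        snp_id, _, allele = col.rpartition("_")
        if not snp_id or len(allele) != 1:
            raise FormatError(
                f"{path}: SNP column {col!r} is not '<snp>_<allele>'"
            )
        snps.append(SnpMeta(snp_id=snp_id, counted_allele=allele))
    individuals = df["IID"].tolist()
    n, p = len(individuals), len(snp_cols)
    dosage = np.full((n, p), MISSING, dtype=np.int8)
    for j, col in enumerate(snp_cols):
        raw = df[col].to_numpy()
        for i, cell in enumerate(raw):
            if cell == "NA" or (isinstance(cell, float) and np.isnan(cell)):
                continue
            if cell not in ("0", "1", "2"):
                raise ValueError(
                    f"{path}: dosage {cell!r} outside {{0,1,2,NA}} at "
                    f"row {i + 1} (IID {individuals[i]!r}), column {col!r}"
                )
            dosage[i, j] = int(cell)
    return GenotypeMatrix(individuals=individuals, snps=snps, dosage=dosage)


def write_plink_raw(g: GenotypeMatrix, path, *, sep: str = " ") -> None:
    """Write a GenotypeMatrix in the PLINK recode-A text dialect."""
    cols = {c: ["0"] * g.n_individuals for c in _RAW_META_COLS}
    cols["FID"] = list(g.individuals)
    cols["IID"] = list(g.individuals)
    cols["PHENOTYPE"] = ["2"] * g.n_individuals  # case-only convention
    df = pd.DataFrame(cols)
    for j, s in enumerate(g.snps):
        col = g.dosage[:, j].astype(object)
        col[col == MISSING] = "NA"
        df[f"{s.snp_id}_{s.counted_allele}"] = col
    df.to_csv(path, sep=sep, index=False)


def read_phenotypes(path, *, missing_codes=DEFAULT_MISSING_CODES,
                    id_column: str | None = None) -> PhenotypeTable:
    """Read a TSV phenotype table of binary clinical features.

    First (or ``id_column``-named) column holds individual IDs; every other
    column is a feature coded 0/1 or one of ``missing_codes``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if id_column is None:
        id_column = df.columns[0]
    ids = df[id_column].tolist()
    if len(set(ids)) != len(ids):
        dup = pd.Series(ids)[pd.Series(ids).duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate individual ID {dup!r}")
    features = [c for c in df.columns if c != id_column]
    n, p = len(ids), len(features)
    values = np.zeros((n, p), dtype=bool)
    missing = np.zeros((n, p), dtype=bool)
    codes = {str(c) for c in missing_codes}
    for j, feat in enumerate(features):
        for i, cell in enumerate(df[feat]):
            cell = "" if (isinstance(cell, float) and np.isnan(cell)) else str(cell)
            if cell in codes:
                missing[i, j] = True
            elif cell == "1":
                values[i, j] = True
            elif cell != "0":
                raise ValueError(
                    f"{path}: non-binary value {cell!r} in feature "
                    f"{feat!r}, row {i + 1} (ID {ids[i]!r})"
                )
    return PhenotypeTable(individuals=ids, features=features,
                          values=values, missing_mask=missing)


def write_phenotypes(p: PhenotypeTable, path, *, missing_code: str = "NA") -> None:
    df = pd.DataFrame({"IID": p.individuals})
    for j, feat in enumerate(p.features):
        col = p.values[:, j].astype(int).astype(object)
        col[p.missing_mask[:, j]] = missing_code
        df[feat] = col
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Binarization and LD pruning
# ---------------------------------------------------------------------------

def binarize_dominant(g: GenotypeMatrix) -> BinaryItemMatrix:
    """Split each SNP into complementary carrier/non-carrier indicator items.

    Under the dominant model, ``<snp>_<allele>_1`` is true iff dosage >= 1
    and ``<snp>_<allele>_0`` iff dosage == 0; a missing dosage marks both
    items missing.  For every non-missing dosage exactly one of the two items
    is true, so binarization is lossless for carrier status.
    """
    n, p = g.dosage.shape
    items: list[str] = []
    for s in g.snps:
        base = f"{s.snp_id}_{s.counted_allele}"
        items.extend((f"{base}_0", f"{base}_1"))
    values = np.zeros((n, 2 * p), dtype=bool)
    missing = np.zeros((n, 2 * p), dtype=bool)
    miss = g.dosage == MISSING
    carrier = g.dosage >= 1
    values[:, 0::2] = ~carrier & ~miss
    values[:, 1::2] = carrier & ~miss
    missing[:, 0::2] = miss
    missing[:, 1::2] = miss
    return BinaryItemMatrix(individuals=list(g.individuals), items=items,
                            values=values, missing_mask=missing)


def _pairwise_r2(dosage: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Pairwise squared Pearson correlation over complete pairs.

    Zero-variance columns (within the complete pairs) yield r^2 = 0 so a
    monomorphic SNP never triggers removal of another SNP.
    """
    k = len(idx)
    r2 = np.zeros((k, k))
    cols = dosage[:, idx].astype(float)
    cols[dosage[:, idx] == MISSING] = np.nan
    for a in range(k):
        for b in range(a + 1, k):
            pair = cols[:, (a, b)]
            ok = ~np.isnan(pair).any(axis=1)
            x, y = pair[ok, 0], pair[ok, 1]
            if len(x) < 2 or x.std() == 0 or y.std() == 0:
                continue
            r = np.corrcoef(x, y)[0, 1]
            r2[a, b] = r2[b, a] = r * r
    return r2


def ld_prune(g: GenotypeMatrix, r2_max: float = 0.5, window: int = 50,
             step: int = 5) -> list[str]:
    """Greedy sliding-window LD pruning on dosage correlation (PLINK-style).

    Within each window of ``window`` SNPs (advanced by ``step``), while any
    surviving pair has r^2 > ``r2_max`` the later SNP of the worst pair is
    dropped.  Returns kept SNP IDs in input order; the kept set contains no
    within-window pair above the threshold.
    """
    if not (0 < r2_max <= 1):
        raise ValueError("r2_max must be in (0, 1]")
    if window < 2:
        raise ValueError("window must be >= 2")
    if step < 1:
        raise ValueError("step must be >= 1")
    n_snps = g.n_snps
    keep = np.ones(n_snps, dtype=bool)
    start = 0
    while True:
        live = np.flatnonzero(keep[start:]) + start
        win = live[:window]
        if len(win) >= 2:
            r2 = _pairwise_r2(g.dosage, win)
            local = np.ones(len(win), dtype=bool)
            while True:
                sub = np.flatnonzero(local)
                if len(sub) < 2:
                    break
                block = r2[np.ix_(sub, sub)]
                worst = block.max()
                if worst <= r2_max:
                    break
                a, b = np.argwhere(block == worst)[0]
                local[sub[max(a, b)]] = False  # drop the later SNP
            keep[win[~local]] = False
        if start + window >= n_snps:
            break
        start += step
    return [g.snps[j].snp_id for j in np.flatnonzero(keep)]


def subset_snps(g: GenotypeMatrix, snp_ids: list[str]) -> GenotypeMatrix:
    """Restrict a GenotypeMatrix to the given SNPs, preserving their order."""
    idx = [g.snp_index(s) for s in snp_ids]
    return GenotypeMatrix(
        individuals=list(g.individuals),
        snps=[g.snps[j] for j in idx],
        dosage=g.dosage[:, idx].copy(),
    )
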