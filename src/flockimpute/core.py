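"""Core containers shared by every stage of the pipeline.

Genotypes are stored as additive dosages of the B allele: 0 (AA), 1 (AB),
2 (BB), with :data:`MISSING` (-1) for no-calls.  A :class:`GenotypeMatrix`
is always bound (by SNP id) to a :class:`MarkerMap` giving chromosome,
position and allele labels; panels are ordered SNP-id subsets of a map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Internal missing-dosage code.
MISSING: int = -1

MARKER_COLUMNS = ("snp_id", "chrom", "pos", "allele_a", "allele_b")


class DataError(ValueError):
    """Raised when input data violate a structural requirement."""


class ParameterError(ValueError):
    """Raised when a caller-supplied parameter is invalid."""


def _chrom_sort_key(chrom) -> tuple:
    """Numeric-aware chromosome ordering: 1 < 2 < ... < 10 < 'X'-style labels."""
    s = str(chrom)
    try:
        return (0, int(s), "")
    except ValueError:
        return (1, 0, s)


@dataclass
class MarkerMap:
    """Per-SNP chromosome, 1-based bp position and (A, B) allele labels.

    The table is kept in canonical (chromosome, position) order; SNPs with
    undefined positions (``pos`` <= 0 or NaN) sort last within chromosome
    and are flagged by QC rather than rejected here.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing_cols = [c for c in MARKER_COLUMNS if c not in self.table.columns]
        if missing_cols:
            raise DataError(f"marker map lacks columns: {missing_cols}")
        if self.table["snp_id"].duplicated().any():
            dups = self.table.loc[self.table["snp_id"].duplicated(), "snp_id"]
            raise DataError(f"duplicated snp_id(s): {sorted(set(dups))[:5]}")
        tab = self.table.copy()
        tab["_ck"] = tab["chrom"].map(_chrom_sort_key)
        tab = tab.sort_values(["_ck", "pos"], kind="stable").drop(columns="_ck")
        self.table = tab.reset_index(drop=True)

    @property
    def snp_ids(self) -> np.ndarray:
        return self.table["snp_id"].to_numpy()

    @property
    def n_snps(self) -> int:
        return len(self.table)

    @property
    def chromosomes(self) -> list:
        seen: list = []
        for c in self.table["chrom"]:
            if c not in seen:
                seen.append(c)
        return seen

    def subset(self, snp_ids) -> "MarkerMap":
        wanted = set(snp_ids)
        sub = self.table[self.table["snp_id"].isin(wanted)].copy()
        return MarkerMap(sub)

    def positions_defined(self) -> np.ndarray:
        pos = self.table["pos"].to_numpy(dtype=float)
        return np.isfinite(pos) & (pos > 0)


@dataclass(frozen=True)
class PanelDef:
    """A named, ordered SNP-id subset defining one panel density."""

    name: str
    snp_ids: tuple

    def __post_init__(self) -> None:
        if len(self.snp_ids) == 0:
            raise DataError(f"panel {self.name!r} is empty")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise DataError(f"panel {self.name!r} has duplicated SNP ids")

    def __len__(self) -> int:
        return len(self.snp_ids)

    def issubset(self, other: "PanelDef") -> bool:
        return set(self.snp_ids) <= set(other.snp_ids)


@dataclass
class GenotypeMatrix:
    """Animals x SNPs dosage matrix with values in {0, 1, 2, MISSING}."""

    animals: np.ndarray
    snps: np.ndarray
    data: np.ndarray

    def __post_init__(self) -> None:
        self.animals = np.asarray(self.animals, dtype=object)
        self.snps = np.asarray(self.snps, dtype=object)
        self.data = np.asarray(self.data)
        if self.data.shape != (len(self.animals), len(self.snps)):
            raise DataError(
                f"dosage matrix shape {self.data.shape} does not match "
                f"{len(self.animals)} animals x {len(self.snps)} SNPs"
            )
        if self.data.dtype != np.int8:
            self.data = self.data.astype(np.int8)
        bad = ~np.isin(self.data, (0, 1, 2, MISSING))
        if bad.any():
            raise DataError("dosages must be 0, 1, 2 or MISSING (-1)")
        if len(set(self.animals)) != len(self.animals):
            raise DataError("duplicated animal ids")
        if len(set(self.snps)) != len(self.snps):
            raise DataError("duplicated SNP ids")

    @property
    def n_animals(self) -> int:
        return len(self.animals)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(self.animals.copy(), self.snps.copy(), self.data.copy())

    def missing_mask(self) -> np.ndarray:
        return self.data == MISSING

    def animal_indices(self, ids) -> np.ndarray:
        lookup = {a: i for i, a in enumerate(self.animals)}
        try:
            return np.array([lookup[a] for a in ids], dtype=np.intp)
        except KeyError as exc:
            raise DataError(f"unknown animal id: {exc.args[0]!r}") from None

    def snp_indices(self, ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.snps)}
        try:
            return np.array([lookup[s] for s in ids], dtype=np.intp)
        except KeyError as exc:
            raise DataError(f"unknown SNP id: {exc.args[0]!r}") from None

    def subset_animals(self, ids) -> "GenotypeMatrix":
        idx = self.animal_indices(ids)
        return GenotypeMatrix(self.animals[idx], self.snps.copy(), self.data[idx])

    def subset_snps(self, ids) -> "GenotypeMatrix":
        idx = self.snp_indices(ids)
        return GenotypeMatrix(self.animals.copy(), self.snps[idx], self.data[:, idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.animals, columns=self.snps)


@dataclass
class Pedigree:
    """Animal, sire, dam, birth year, sex and breed-composition fractions.

    ``table`` columns: animal, sire, dam, year, sex plus one fraction column
    per breed named in ``breeds``.  Founders carry sire = dam = None.
    """

    table: pd.DataFrame
    breeds: tuple

    def __post_init__(self) -> None:
        self.breeds = tuple(self.breeds)
        required = ["animal", "sire", "dam", "year", "sex", *self.breeds]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise DataError(f"pedigree lacks columns: {missing}")
        if self.table["animal"].duplicated().any():
            raise DataError("duplicated animal ids in pedigree")
        frac = self.table[list(self.breeds)].to_numpy(dtype=float)
        if not np.allclose(frac.sum(axis=1), 1.0, atol=1e-8):
            raise DataError("breed fractions must sum to 1 per animal")
        self.table = self.table.reset_index(drop=True)
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        years = dict(zip(self.table["animal"], self.table["year"]))
        for _, row in self.table.iterrows():
            for parent in (row["sire"], row["dam"]):
                if parent is None or (isinstance(parent, float) and np.isnan(parent)):
                    continue
                if parent == row["animal"]:
                    raise DataError(f"animal {row['animal']!r} is its own parent")
                if parent in years and years[parent] >= row["year"]:
                    raise DataError(
                        f"parent {parent!r} not born before offspring {row['animal']!r}"
                    )

    @property
    def animals(self) -> np.ndarray:
        return self.table["animal"].to_numpy(dtype=object)

    def founders(self) -> np.ndarray:
        t = self.table
        mask = t["sire"].isna() & t["dam"].isna()
        return t.loc[mask, "animal"].to_numpy(dtype=object)

    def breed_fractions(self) -> pd.DataFrame:
        return self.table.set_index("animal")[list(self.breeds)]

    def dominant_breed(self) -> pd.Series:
        """Per animal, the breed with the largest composition fraction.

        Ties resolve to the breed listed first in ``breeds``.
        """
        frac = self.breed_fractions()
        return frac.idxmax(axis=1)

    def parent_offspring_pairs(self) -> list:
        pairs = []
        known = set(self.table["animal"])
        for _, row in self.table.iterrows():
            for parent in (row["sire"], row["dam"]):
                if parent in known:
                    pairs.append((parent, row["animal"]))
        return pairs
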