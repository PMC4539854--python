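"""Core in-memory containers: genotype matrices, SNP maps and pedigrees.

Genotypes are coded as the count of the ``a2`` allele (the VCF ALT allele when
read from VCF): 0 = a1/a1, 1 = a1/a2, 2 = a2/a2.  Missing calls are stored as
``MISSING`` (-1) in an int8 matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: sentinel for a missing genotype call
MISSING: int = -1

SNP_COLUMNS = ["id", "chrom", "pos_bp", "pos_cm", "a1", "a2"]


def make_snp_table(
    ids,
    chrom="1",
    pos_bp=None,
    pos_cm=None,
    a1="A",
    a2="B",
) -> pd.DataFrame:
    """Build a SNP map table with the canonical columns.

    ``pos_bp`` defaults to 1-based consecutive positions; ``pos_cm`` may be
    left as NaN when no genetic map is available.
    """
    ids = list(ids)
    n = len(ids)
    tab = pd.DataFrame(
        {
            "id": ids,
            "chrom": chrom if not np.iterable(chrom) or isinstance(chrom, str) else list(chrom),
            "pos_bp": np.arange(1, n + 1, dtype=np.int64) if pos_bp is None else np.asarray(pos_bp, dtype=np.int64),
            "pos_cm": np.full(n, np.nan) if pos_cm is None else np.asarray(pos_cm, dtype=float),
            "a1": a1,
            "a2": a2,
        }
    )
    return tab


@dataclass
class GenotypeMatrix:
    """Animals x SNPs genotype calls plus the SNP map.

    Attributes
    ----------
    animals : list of str
        Ordered animal ids (rows).
    snps : pandas.DataFrame
        SNP map with columns ``id, chrom, pos_bp, pos_cm, a1, a2`` (columns).
    calls : numpy.ndarray of int8
        Genotype calls in {0, 1, 2, MISSING}, shape ``(len(animals), len(snps))``.
    """

    animals: list
    snps: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.animals), len(self.snps)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.animals)} animals x {len(self.snps)} SNPs"
            )
        valid = np.isin(self.calls, [0, 1, 2, MISSING])
        if not valid.all():
            bad = np.unique(self.calls[~valid])
            raise ValueError(f"invalid genotype codes {bad}; expected 0/1/2/{MISSING}")
        if self.snps["id"].duplicated().any():
            dup = self.snps["id"][self.snps["id"].duplicated()].iloc[0]
            raise ValueError(f"duplicate SNP id {dup!r}")
        if len(set(self.animals)) != len(self.animals):
            raise ValueError("duplicate animal ids")

    @property
    def n_animals(self) -> int:
        return len(self.animals)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> list:
        return list(self.snps["id"])

    def animal_index(self, ids) -> np.ndarray:
        lookup = {a: i for i, a in enumerate(self.animals)}
        try:
            return np.array([lookup[a] for a in ids], dtype=np.intp)
        except KeyError as e:
            raise KeyError(f"unknown animal id {e.args[0]!r}") from None

    def snp_index(self, ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.snps["id"])}
        try:
            return np.array([lookup[s] for s in ids], dtype=np.intp)
        except KeyError as e:
            raise KeyError(f"unknown SNP id {e.args[0]!r}") from None

    def subset(self, animals=None, snps=None) -> "GenotypeMatrix":
        """Return a copy restricted to the given animal ids and/or SNP ids."""
        ai = self.animal_index(animals) if animals is not None else np.arange(self.n_animals)
        si = self.snp_index(snps) if snps is not None else np.arange(self.n_snps)
        return GenotypeMatrix(
            animals=[self.animals[i] for i in ai],
            snps=self.snps.iloc[si].reset_index(drop=True),
            calls=self.calls[np.ix_(ai, si)].copy(),
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(list(self.animals), self.snps.copy(), self.calls.copy())


@dataclass
class Pedigree:
    """Per-animal sire/dam/generation records.

    ``table`` has columns ``animal, sire, dam, generation`` and optionally
    ``sex`` and ``genotyped``.  Unknown parents are ``None``/NaN (written as
    "0" on disk).  ``generations`` orders the generation labels from oldest
    to youngest.
    """

    table: pd.DataFrame
    generations: list = field(default_factory=list)

    def __post_init__(self):
        tab = self.table.copy()
        for col in ("sire", "dam"):
            tab[col] = tab[col].where(pd.notna(tab[col]), None)
            tab[col] = tab[col].replace({"0": None, "NA": None, 0: None})
        self.table = tab.reset_index(drop=True)
        if self.table["animal"].duplicated().any():
            raise ValueError("duplicate animal ids in pedigree")
        if not self.generations:
            self.generations = list(pd.unique(self.table["generation"]))
        self._row = {a: i for i, a in enumerate(self.table["animal"])}
        order = {g: i for i, g in enumerate(self.generations)}
        # parents must be placed in strictly earlier generations
        for _, rec in self.table.iterrows():
            g = order.get(rec["generation"])
            for par in (rec["sire"], rec["dam"]):
                if par is not None and par in self._row:
                    gp = order.get(self.table.at[self._row[par], "generation"])
                    if gp is not None and g is not None and gp >= g:
                        raise ValueError(
                            f"parent {par!r} of {rec['animal']!r} is not in an earlier generation"
                        )

    @property
    def animals(self) -> list:
        return list(self.table["animal"])

    def generation_of(self, animal):
        return self.table.at[self._row[animal], "generation"]

    def sire_of(self, animal):
        return self.table.at[self._row[animal], "sire"] if animal in self._row else None

    def dam_of(self, animal):
        return self.table.at[self._row[animal], "dam"] if animal in self._row else None

    def maternal_grandsire_of(self, animal):
        """Sire of the animal's dam, or None when the dam link is missing."""
        dam = self.dam_of(animal)
        if dam is None or dam not in self._row:
            return None
        return self.sire_of(dam)

    def in_generation(self, label) -> list:
        return list(self.table.loc[self.table["generation"] == label, "animal"])

    def parent_offspring_pairs(self) -> list:
        """All (parent, offspring) pairs implied by sire and dam links."""
        pairs = []
        for _, rec in self.table.iterrows():
            for par in (rec["sire"], rec["dam"]):
                if par is not None:
                    pairs.append((par, rec["animal"]))
        return pairs
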