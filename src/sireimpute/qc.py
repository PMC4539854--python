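"""Quality control: allele frequencies, Mendelian checks and marker/animal filters.

The filter thresholds mirror standard SNP-chip QC for pedigreed livestock
data: markers are dropped for low minor allele frequency, low call rate or an
excess of parent-progeny Mendelian inconsistencies, after which animals with
low genotype call rate are dropped.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import MISSING, GenotypeMatrix, Pedigree


def compute_maf(geno: GenotypeMatrix, subset=None) -> np.ndarray:
    """Minor allele frequency per SNP, NaN where no non-missing calls exist.

    MAF = min(p, 1-p) with p the a2-allele frequency over non-missing calls
    of the given animal subset (all animals by default).
    """
    calls = geno.calls if subset is None else geno.calls[geno.animal_index(subset)]
    obs = calls != MISSING
    n_obs = obs.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(obs, calls, 0).sum(axis=0) / (2.0 * n_obs)
    p = np.where(n_obs > 0, p, np.nan)
    return np.minimum(p, 1.0 - p)


def allele_frequency(geno: GenotypeMatrix, subset=None) -> np.ndarray:
    """a2-allele frequency per SNP (not folded to the minor allele)."""
    calls = geno.calls if subset is None else geno.calls[geno.animal_index(subset)]
    obs = calls != MISSING
    n_obs = obs.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(obs, calls, 0).sum(axis=0) / (2.0 * n_obs)
    return np.where(n_obs > 0, p, np.nan)


def _genotyped_pairs(geno: GenotypeMatrix, pedigree: Pedigree):
    """Index pairs (parent_row, child_row) for parent-progeny links where both
    animals are present in the genotype matrix."""
    lookup = {a: i for i, a in enumerate(geno.animals)}
    pairs = []
    for parent, child in pedigree.parent_offspring_pairs():
        if parent in lookup and child in lookup:
            pairs.append((lookup[parent], lookup[child]))
    return pairs


def mendelian_inconsistency_rate(geno: GenotypeMatrix, pedigree: Pedigree, snp=None):
    """Fraction of genotyped parent-progeny pairs with opposite homozygotes.

    A pair is inconsistent at a SNP when parent and child are homozygous for
    different alleles (0 vs 2).  Pairs with a missing call at the SNP are
    excluded from the denominator; a SNP with no complete pair is NaN.

    Returns the rate for one SNP index, or the full per-SNP vector when
    ``snp`` is None.
    """
    pairs = _genotyped_pairs(geno, pedigree)
    sl = slice(None) if snp is None else [snp]
    n_snps = geno.n_snps if snp is None else 1
    n_pairs = np.zeros(n_snps)
    n_bad = np.zeros(n_snps)
    for pi, ci in pairs:
        gp = geno.calls[pi, sl]
        gc = geno.calls[ci, sl]
        ok = (gp != MISSING) & (gc != MISSING)
        n_pairs += ok
        n_bad += ok & (((gp == 0) & (gc == 2)) | ((gp == 2) & (gc == 0)))
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(n_pairs > 0, n_bad / n_pairs, np.nan)
    return float(rate[0]) if snp is not None else rate


def call_rate(geno: GenotypeMatrix, axis="snp") -> np.ndarray:
    obs = geno.calls != MISSING
    return obs.mean(axis=0) if axis == "snp" else obs.mean(axis=1)


class GenotypeQC(TransformerMixin, BaseEstimator):
    """Marker and animal quality-control filter.

    All SNP criteria are evaluated on the unfiltered matrix in a single
    pass, then the animal call-rate filter is applied once to the surviving
    SNPs.  SNPs whose MAF or Mendelian rate is undefined (no informative
    calls/pairs) are dropped with an explicit reason rather than silently
    kept.

    Parameters
    ----------
    maf_min : minimum minor allele frequency (default 0.01).
    call_rate_min : minimum per-SNP call rate (default 0.9).
    mendel_max : maximum parent-progeny Mendelian inconsistency rate (0.10).
    animal_call_rate_min : minimum per-animal call rate (default 0.9).
    """

    def __init__(self, maf_min=0.01, call_rate_min=0.9, mendel_max=0.10,
                 animal_call_rate_min=0.9):
        self.maf_min = maf_min
        self.call_rate_min = call_rate_min
        self.mendel_max = mendel_max
        self.animal_call_rate_min = animal_call_rate_min

    def fit(self, geno: GenotypeMatrix, pedigree: Pedigree = None):
        for name in ("maf_min", "call_rate_min", "mendel_max", "animal_call_rate_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        removals = []

        maf = compute_maf(geno)
        cr = call_rate(geno, axis="snp")
        mendel = (
            mendelian_inconsistency_rate(geno, pedigree, snp=None)
            if pedigree is not None
            else np.full(geno.n_snps, np.nan)
        )
        drop_snp = np.zeros(geno.n_snps, dtype=bool)
        for m in range(geno.n_snps):
            sid = geno.snps["id"].iloc[m]
            if np.isnan(maf[m]):
                drop_snp[m] = True
                removals.append((sid, "snp", "maf_undefined", np.nan))
            elif maf[m] < self.maf_min:
                drop_snp[m] = True
                removals.append((sid, "snp", "low_maf", maf[m]))
            if cr[m] < self.call_rate_min:
                drop_snp[m] = True
                removals.append((sid, "snp", "low_call_rate", cr[m]))
            if not np.isnan(mendel[m]) and mendel[m] > self.mendel_max:
                drop_snp[m] = True
                removals.append((sid, "snp", "mendelian", mendel[m]))
        if drop_snp.all():
            raise ValueError("QC removed every SNP (empty panel)")

        obs = geno.calls[:, ~drop_snp] != MISSING
        acr = obs.mean(axis=1)
        drop_animal = acr < self.animal_call_rate_min
        for i in np.flatnonzero(drop_animal):
            removals.append((geno.animals[i], "animal", "low_call_rate", acr[i]))

        self.keep_snps_ = [geno.snps["id"].iloc[m] for m in np.flatnonzero(~drop_snp)]
        self.keep_animals_ = [geno.animals[i] for i in np.flatnonzero(~drop_animal)]
        self.report_ = pd.DataFrame(
            removals, columns=["item", "kind", "reason", "value"]
        )
        return self

    def transform(self, geno: GenotypeMatrix) -> GenotypeMatrix:
        return geno.subset(animals=self.keep_animals_, snps=self.keep_snps_)


def qc_filter(geno: GenotypeMatrix, pedigree: Pedigree = None, maf_min=0.01,
              call_rate_min=0.9, mendel_max=0.10, animal_call_rate_min=0.9):
    """Apply :class:`GenotypeQC`; returns ``(filtered matrix, removal report)``."""
    qc = GenotypeQC(maf_min, call_rate_min, mendel_max, animal_call_rate_min)
    qc.fit(geno, pedigree)
    return qc.transform(geno), qc.report_
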