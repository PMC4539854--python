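"""Masking designs that turn a complete validation matrix into imputation inputs.

Three designs are provided, mirroring the two study densities:

* per-MAF-class masking (the 48K-to-60K analogue): all SNPs of one MAF class
  are set missing in the validation animals;
* MAF-independent masking: a uniform random ~20% of classed SNPs;
* low-density masking (the 3K-to-60K analogue): all but an evenly spaced
  ~4% of SNPs are masked.

MAF classes span (0.008, 0.5] in five bins; bins are left-open right-closed,
and SNPs with MAF <= 0.008 are unclassed and never masked.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix

MAF_CLASS_EDGES = [0.008, 0.1, 0.2, 0.3, 0.4, 0.5]
UNCLASSED = 0
N_CLASSES = 5


@dataclass
class MAFClassing:
    """Per-SNP MAF class labels: 1..5, or 0 (UNCLASSED) when MAF <= 0.008."""

    snp_ids: list
    maf: np.ndarray
    labels: np.ndarray

    def ids_in_class(self, class_id) -> list:
        return [s for s, c in zip(self.snp_ids, self.labels) if c == class_id]

    def class_of(self) -> pd.Series:
        return pd.Series(self.labels, index=self.snp_ids, name="maf_class")


def assign_maf_classes(maf, snp_ids=None) -> MAFClassing:
    """Bin MAF values into the five study classes.

    Class j covers ``(edge_{j-1}, edge_j]`` — e.g. class 1 is (0.008, 0.1]
    — so a MAF of exactly 0.1 falls in class 1.  NaN or MAF <= 0.008 is
    unclassed.
    """
    maf = np.asarray(maf, dtype=float)
    if np.nanmax(maf, initial=0.0) > 0.5 or np.nanmin(maf, initial=0.0) < 0.0:
        raise ValueError("MAF values must lie in [0, 0.5]")
    labels = np.zeros(len(maf), dtype=int)
    for j in range(1, N_CLASSES + 1):
        lo, hi = MAF_CLASS_EDGES[j - 1], MAF_CLASS_EDGES[j]
        with np.errstate(invalid="ignore"):
            labels[(maf > lo) & (maf <= hi)] = j
    if snp_ids is None:
        snp_ids = list(range(len(maf)))
    return MAFClassing(list(snp_ids), maf, labels)


@dataclass
class MaskingScenario:
    """A set of masked SNP ids plus the design metadata."""

    name: str
    masked_ids: list
    design: str                       # by_maf_class | low_density | maf_independent
    maf_source: str = "reference"     # reference | validation
    params: dict = field(default_factory=dict)

    def retained_ids(self, all_ids) -> list:
        masked = set(self.masked_ids)
        return [s for s in all_ids if s not in masked]


def mask_by_maf_class(classing: MAFClassing, class_id, maf_source="reference",
                      name=None) -> MaskingScenario:
    """Mask every SNP of one MAF class (computed from ``maf_source`` animals)."""
    ids = classing.ids_in_class(class_id)
    if not ids:
        raise ValueError(f"MAF class {class_id} is empty")
    return MaskingScenario(
        name=name or f"maf_class_{class_id}",
        masked_ids=ids,
        design="by_maf_class",
        maf_source=maf_source,
        params={"class_id": class_id},
    )


def low_density_keep_indices(n_snps, keep_fraction) -> np.ndarray:
    """Evenly spaced retained indices: round(i (N-1)/(K-1)), endpoints kept."""
    if not 0.0 < keep_fraction < 1.0:
        raise ValueError("keep_fraction must be in (0, 1)")
    K = int(round(n_snps * keep_fraction))
    if K < 2:
        raise ValueError(f"keep_fraction {keep_fraction} retains {K} < 2 SNPs")
    idx = np.round(np.arange(K) * (n_snps - 1) / (K - 1)).astype(int)
    return np.unique(idx)


def mask_low_density(snp_ids, keep_fraction=0.04, name="low_density") -> MaskingScenario:
    """Mask all but an evenly spaced ``keep_fraction`` of SNPs (by map order)."""
    snp_ids = list(snp_ids)
    keep = set(low_density_keep_indices(len(snp_ids), keep_fraction))
    masked = [s for i, s in enumerate(snp_ids) if i not in keep]
    return MaskingScenario(
        name=name,
        masked_ids=masked,
        design="low_density",
        maf_source="reference",
        params={"keep_fraction": keep_fraction, "n_kept": len(keep)},
    )


def mask_maf_independent(classing: MAFClassing, mask_fraction=0.2, seed=0,
                         name="maf_independent") -> MaskingScenario:
    """Mask a uniform random sample of classed SNPs, irrespective of class."""
    if not 0.0 < mask_fraction < 1.0:
        raise ValueError("mask_fraction must be in (0, 1)")
    classed = [s for s, c in zip(classing.snp_ids, classing.labels) if c != UNCLASSED]
    n_mask = int(round(len(classed) * mask_fraction))
    rng = np.random.default_rng(seed)
    masked = [classed[i] for i in rng.choice(len(classed), size=n_mask, replace=False)]
    label = dict(zip(classing.snp_ids, classing.labels))
    per_class = pd.Series([label[s] for s in masked]).value_counts().sort_index()
    return MaskingScenario(
        name=name,
        masked_ids=masked,
        design="maf_independent",
        maf_source="reference",
        params={
            "mask_fraction": mask_fraction,
            "seed": seed,
            "per_class_masked": per_class.to_dict(),
        },
    )


def random_reference_sets(pool, k=22, n_repeats=10, seed=0) -> list:
    """``n_repeats`` independent uniform k-subsets of the training pool."""
    pool = list(pool)
    if len(pool) < k:
        raise ValueError(f"pool of {len(pool)} animals is smaller than k={k}")
    rng = np.random.default_rng(seed)
    return [
        [pool[i] for i in rng.choice(len(pool), size=k, replace=False)]
        for _ in range(n_repeats)
    ]


def apply_scenario(geno: GenotypeMatrix, scenario: MaskingScenario,
                   validation_animals) -> GenotypeMatrix:
    """Set the scenario's masked SNPs to missing for the validation animals.

    Reference animals keep full density; the returned matrix is a copy, so
    the truth genotypes at masked positions are not reachable from it.
    """
    masked = geno.copy()
    ai = masked.animal_index(validation_animals)
    si = masked.snp_index(scenario.masked_ids)
    masked.calls[np.ix_(ai, si)] = MISSING
    return masked


def scenario_manifest(scenario: MaskingScenario, classing: MAFClassing,
                      maf_reference=None, maf_validation=None) -> pd.DataFrame:
    """Per-SNP manifest: status, class and the MAF in each population."""
    masked = set(scenario.masked_ids)
    label = dict(zip(classing.snp_ids, classing.labels))
    rows = []
    for i, s in enumerate(classing.snp_ids):
        rows.append({
            "snp": s,
            "status": "masked" if s in masked else "retained",
            "maf_class": label[s],
            "maf_reference": None if maf_reference is None else maf_reference[i],
            "maf_validation": None if maf_validation is None else maf_validation[i],
        })
    return pd.DataFrame(rows)
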