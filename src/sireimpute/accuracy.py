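"""Imputation accuracy statistics and stratified summaries.

Two complementary measures:

* animal-specific accuracy ``r_corrected``: the Pearson correlation, across
  an animal's masked SNPs, of the true and imputed genotypes each centered
  by the reference population's mean gene content (the per-SNP mean of the
  0/1/2 codes).  Centering removes the MAF-driven differences in per-SNP
  means so the correlation behaves like one between bivariate-normal scores.
* SNP-specific accuracy: the Pearson correlation across animals of true and
  imputed raw 0/1/2 genotypes at one SNP; its square is the SNP's "true"
  imputation reliability, the quantity the estimated allelic R2 predicts.

Undefined correlations (constant vectors, too few points) are reported as
NaN and excluded from summaries, never coerced to 0.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import MISSING, GenotypeMatrix


def gene_content_means(geno_reference: GenotypeMatrix, snp_ids=None) -> np.ndarray:
    """Per-SNP mean of non-missing 0/1/2 calls among reference animals.

    NaN where every reference call is missing (such SNPs are later excluded
    from r_corrected with a warning by the caller).
    """
    calls = geno_reference.calls
    if snp_ids is not None:
        calls = calls[:, geno_reference.snp_index(snp_ids)]
    obs = calls != MISSING
    n = obs.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(obs, calls, 0).sum(axis=0) / n
    return np.where(n > 0, mean, np.nan)


def _pearson(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def r_corrected(true_calls, imputed_calls, means) -> float:
    """Animal-specific accuracy across the animal's masked SNPs.

    Pearson correlation of (true - mean gene content) with (imputed - mean
    gene content); NaN when fewer than two SNPs have defined means or either
    centered vector is constant.
    """
    true_calls = np.asarray(true_calls, dtype=float)
    imputed_calls = np.asarray(imputed_calls, dtype=float)
    means = np.asarray(means, dtype=float)
    ok = ~np.isnan(means)
    if ok.sum() < 2:
        return np.nan
    return _pearson(true_calls[ok] - means[ok], imputed_calls[ok] - means[ok])


def snp_accuracy(true_calls, imputed_calls):
    """SNP-specific accuracy across animals and its square (reliability).

    Uses raw 0/1/2 coding (no gene-content centering).  Returns
    ``(accuracy, reliability)``; both NaN when either vector is constant.
    """
    r = _pearson(true_calls, imputed_calls)
    return r, (r * r if not np.isnan(r) else np.nan)


def animal_accuracies(truth: GenotypeMatrix, imputed: GenotypeMatrix,
                      reference: GenotypeMatrix, animals, masked_snps) -> pd.Series:
    """r_corrected per validation animal over the masked SNPs."""
    means = gene_content_means(reference, snp_ids=masked_snps)
    ti = truth.calls[np.ix_(truth.animal_index(animals), truth.snp_index(masked_snps))]
    ii = imputed.calls[
        np.ix_(imputed.animal_index(animals), imputed.snp_index(masked_snps))
    ]
    vals = [r_corrected(ti[i], ii[i], means) for i in range(len(animals))]
    return pd.Series(vals, index=list(animals), name="r_corrected")


def snp_accuracies(truth: GenotypeMatrix, imputed: GenotypeMatrix, animals,
                   masked_snps) -> pd.DataFrame:
    """Accuracy and reliability per masked SNP across the given animals."""
    ai_t = truth.animal_index(animals)
    ai_i = imputed.animal_index(animals)
    rows = []
    for s in masked_snps:
        mt = truth.snp_index([s])[0]
        mi = imputed.snp_index([s])[0]
        acc, rel = snp_accuracy(truth.calls[ai_t, mt], imputed.calls[ai_i, mi])
        rows.append({"snp": s, "accuracy": acc, "reliability": rel})
    return pd.DataFrame(rows).set_index("snp")


def reliability_concordance(true_reliability, allelic_r2, strata=None) -> pd.DataFrame:
    """Correlation and regression of true reliability on estimated allelic R2.

    Per stratum (one pooled stratum when ``strata`` is None): Pearson
    correlation, least-squares slope and intercept of reliability on allelic
    R2, over SNPs where both are defined.  Strata with fewer than three such
    SNPs are skipped with a note in the ``n`` column.
    """
    rel = np.asarray(true_reliability, dtype=float)
    ar2 = np.asarray(allelic_r2, dtype=float)
    strata = np.zeros(len(rel), dtype=int) if strata is None else np.asarray(strata)
    rows = []
    for s in pd.unique(strata):
        sel = (strata == s) & ~np.isnan(rel) & ~np.isnan(ar2)
        n = int(sel.sum())
        if n < 3 or np.ptp(ar2[sel]) == 0.0 or np.ptp(rel[sel]) == 0.0:
            rows.append({"stratum": s, "n": n, "correlation": np.nan,
                         "slope": np.nan, "intercept": np.nan})
            continue
        fit = stats.linregress(ar2[sel], rel[sel])
        rows.append({
            "stratum": s, "n": n, "correlation": float(fit.rvalue),
            "slope": float(fit.slope), "intercept": float(fit.intercept),
        })
    return pd.DataFrame(rows).set_index("stratum")


def summarize(values, strata) -> pd.DataFrame:
    """Mean and standard error per stratum.

    ``values`` is a Series/array of per-animal (or per-SNP) statistics,
    ``strata`` an equal-length label array or DataFrame of label columns.
    NaN values are excluded and counted as ``n_undefined``; SE uses the
    sample standard deviation (n-1) over defined values, blank (NaN) for a
    single value.
    """
    vals = np.asarray(values, dtype=float)
    if isinstance(strata, pd.DataFrame):
        keys = [strata[c].to_numpy() for c in strata.columns]
        names = list(strata.columns)
    else:
        keys = [np.asarray(strata)]
        names = ["stratum"]
    df = pd.DataFrame({"value": vals})
    for name, k in zip(names, keys):
        df[name] = k
    rows = []
    for label, grp in df.groupby(names, dropna=False, sort=True):
        if not isinstance(label, tuple):
            label = (label,)
        v = grp["value"].to_numpy()
        defined = v[~np.isnan(v)]
        n = len(defined)
        rows.append(dict(zip(names, label)) | {
            "n": n,
            "n_undefined": int(len(v) - n),
            "mean": defined.mean() if n else np.nan,
            "se": defined.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan,
        })
    return pd.DataFrame(rows).set_index(names)
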