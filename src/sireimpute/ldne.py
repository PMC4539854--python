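"""Linkage disequilibrium statistics and effective population size.

LD between a pair of SNPs is measured as ``r``, the correlation of the two
allele indicator vectors across phased haplotypes (or, as a documented
fallback, of the 0/1/2 genotype vectors across animals).  The expected
squared LD relates to effective population size through Sved's equation::

    r^2 = 1 / (1 + 4 Ne c)

with ``c`` the genetic distance in Morgans, assuming constant population
size.  Two aggregations into a single Ne are provided: the mean of the
per-pair closed-form inversions, and a least-squares fit of the curve
(the default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares


def adjacent_pairs(n_snps) -> list:
    """Neighbouring-SNP index pairs in map order."""
    return [(m, m + 1) for m in range(n_snps - 1)]


def ld_r(data, pairs, pos_bp=None, pos_morgan=None, phased=True) -> pd.DataFrame:
    """Pairwise LD (r and r^2) for the given SNP index pairs.

    ``data`` is haplotypes x SNPs (0/1) when ``phased``, else animals x SNPs
    (0/1/2).  Pairs where either SNP is monomorphic in the sample are
    skipped; the count of skips is attached as ``result.attrs['n_skipped']``.
    """
    data = np.asarray(data, dtype=float)
    rows, n_skipped = [], 0
    for a, b in pairs:
        x, y = data[:, a], data[:, b]
        if np.std(x) == 0.0 or np.std(y) == 0.0:
            n_skipped += 1
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        rows.append({
            "snp_a": a, "snp_b": b, "r": r, "r2": r * r,
            "distance_bp": (abs(int(pos_bp[b] - pos_bp[a])) if pos_bp is not None
                            else np.nan),
            "distance_morgan": (abs(float(pos_morgan[b] - pos_morgan[a]))
                                if pos_morgan is not None else np.nan),
        })
    out = pd.DataFrame(
        rows, columns=["snp_a", "snp_b", "r", "r2", "distance_bp", "distance_morgan"]
    )
    out.attrs["n_skipped"] = n_skipped
    out.attrs["phased"] = phased
    return out


def ld_concordance(pairs_a: pd.DataFrame, pairs_b: pd.DataFrame) -> float:
    """Pearson correlation of r values over the pairs shared by two samples.

    Typically the same adjacent-SNP pairs evaluated in two generations; high
    concordance indicates LD persists across generations.
    """
    merged = pairs_a.merge(pairs_b, on=["snp_a", "snp_b"], suffixes=("_a", "_b"))
    if len(merged) < 3:
        raise ValueError(f"only {len(merged)} shared pairs (need >= 3)")
    return float(np.corrcoef(merged["r_a"], merged["r_b"])[0, 1])


def bp_to_morgan(pos_bp, rate_map) -> np.ndarray:
    """Convert physical positions to genetic positions (Morgans).

    ``rate_map`` is either a constant rate in cM/Mb, or a DataFrame with
    columns ``start_bp, end_bp, cm_per_mb`` covering every queried position
    (half-open intervals [start, end)).  The output is the cumulative
    integral of the rate, hence monotone non-decreasing.
    """
    pos = np.asarray(pos_bp, dtype=float)
    if np.isscalar(rate_map) or isinstance(rate_map, (int, float)):
        return pos * float(rate_map) / 1e6 / 100.0
    rm = rate_map.sort_values("start_bp").reset_index(drop=True)
    if (rm["cm_per_mb"] < 0).any():
        raise ValueError("negative recombination rate")
    starts = rm["start_bp"].to_numpy(dtype=float)
    ends = rm["end_bp"].to_numpy(dtype=float)
    rates = rm["cm_per_mb"].to_numpy(dtype=float)
    # cumulative cM at each segment start
    seg_cm = (ends - starts) * rates / 1e6
    cum = np.concatenate([[0.0], np.cumsum(seg_cm)])
    out = np.empty_like(pos)
    for i, p in enumerate(pos):
        k = np.searchsorted(ends, p, side="right")
        if k >= len(starts) and p == ends[-1]:
            k = len(starts) - 1
            out[i] = (cum[k] + (p - starts[k]) * rates[k] / 1e6) / 100.0
            continue
        if k >= len(starts) or p < starts[k]:
            raise ValueError(f"position {p} outside the rate map")
        out[i] = (cum[k] + (p - starts[k]) * rates[k] / 1e6) / 100.0
    return out


@dataclass
class NeEstimate:
    """Effective population size from pairwise LD."""

    ne: float
    method: str                # per_pair_mean | curve_fit
    n_pairs: int
    distance_range: tuple
    n_excluded: int = 0


def estimate_ne(ld_pairs: pd.DataFrame, method="curve_fit") -> NeEstimate:
    """Estimate Ne from LD pairs via Sved's equation.

    ``per_pair_mean`` averages the closed-form inversion
    ``Ne_i = (1/r2_i - 1) / (4 c_i)`` over pairs; ``curve_fit`` least-squares
    fits ``r2 = 1/(1 + 4 Ne c)`` over Ne > 0.  Pairs with c <= 0 or r2
    outside (0, 1) are excluded (counted).
    """
    c = ld_pairs["distance_morgan"].to_numpy(dtype=float)
    r2 = ld_pairs["r2"].to_numpy(dtype=float)
    ok = (c > 0) & (r2 > 0) & (r2 < 1) & ~np.isnan(c)
    n_excluded = int((~ok).sum())
    c, r2 = c[ok], r2[ok]
    if len(c) == 0:
        raise ValueError("no usable pairs (need distance > 0 and 0 < r2 < 1)")
    per_pair = (1.0 / r2 - 1.0) / (4.0 * c)
    if method == "per_pair_mean":
        ne = float(per_pair.mean())
    elif method == "curve_fit":
        def resid(log_ne):
            return 1.0 / (1.0 + 4.0 * np.exp(log_ne) * c) - r2
        x0 = np.log(max(per_pair.mean(), 1e-6))
        fit = least_squares(resid, x0)
        ne = float(np.exp(fit.x[0]))
    else:
        raise ValueError(f"unknown method {method!r}")
    return NeEstimate(
        ne=ne, method=method, n_pairs=len(c),
        distance_range=(float(c.min()), float(c.max())),
        n_excluded=n_excluded,
    )


def sved_expected_r2(ne, c):
    """Expected r^2 under Sved's equation."""
    return 1.0 / (1.0 + 4.0 * np.asarray(ne, dtype=float) * np.asarray(c, dtype=float))
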