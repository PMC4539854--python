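"""Genomic relationships, the diversity-proportion criterion and panel selection.

The genomic relationship matrix (GRM) follows VanRaden's first method:
``G = Z Z' / (2 sum p_j (1 - p_j))`` with ``Z = M - 2p`` the centered 0/1/2
genotype matrix.  The contribution of a candidate subset of n animals toward
a target population is the solved vector ``P_n = G_n^{-1} c_n``, where
``c_n`` holds each subset animal's mean relationship with the target; the sum
of ``P_n`` is the proportion of the target's genetic variation captured by
the subset.  Reference panels are chosen by greedy forward selection on that
captured proportion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .containers import MISSING, GenotypeMatrix, Pedigree
from .qc import allele_frequency

COND_THRESHOLD = 1e8
DEFAULT_RIDGE = 1e-6


@dataclass
class GRM:
    """Symmetric genomic relationship matrix with its animal ids."""

    animals: list
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.animals)
        if self.values.shape != (n, n):
            raise ValueError("GRM shape does not match number of animals")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("GRM is not symmetric")

    def index(self, ids):
        lookup = {a: i for i, a in enumerate(self.animals)}
        return np.array([lookup[a] for a in ids], dtype=np.intp)

    def block(self, rows, cols=None):
        ri = self.index(rows)
        ci = ri if cols is None else self.index(cols)
        return self.values[np.ix_(ri, ci)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.animals, columns=self.animals)


def compute_grm(geno: GenotypeMatrix, freqs=None) -> GRM:
    """VanRaden method-1 GRM.

    Missing calls are imputed to ``2p`` (i.e. contribute zero after
    centering).  ``freqs`` supplies per-SNP a2-allele frequencies; observed
    frequencies are used by default.  Monomorphic SNPs contribute nothing to
    the numerator; an all-monomorphic panel is an error.
    """
    if geno.n_animals < 2:
        raise ValueError("GRM needs at least two animals")
    p = allele_frequency(geno) if freqs is None else np.asarray(freqs, dtype=float)
    if len(p) != geno.n_snps:
        raise ValueError("frequency vector length does not match SNP count")
    usable = ~np.isnan(p)
    denom = 2.0 * np.sum(p[usable] * (1.0 - p[usable]))
    if denom <= 0.0:
        raise ValueError("all SNPs monomorphic: GRM denominator is zero")
    calls = geno.calls[:, usable].astype(float)
    pu = p[usable]
    Z = np.where(calls == MISSING, 0.0, calls - 2.0 * pu)
    G = (Z @ Z.T) / denom
    G = (G + G.T) / 2.0
    return GRM(list(geno.animals), G)


@dataclass
class DiversityResult:
    """Solved diversity proportions of a candidate subset."""

    subset: list
    proportions: np.ndarray    # P_n, one entry per subset animal
    captured: float            # sum of P_n
    residual: float            # max-norm of G_n P_n - c_n


def _solve_diversity(Gn, cn, ridge=0.0):
    if ridge > 0.0:
        Gn = Gn + ridge * np.eye(len(Gn))
    if np.linalg.cond(Gn) > COND_THRESHOLD:
        raise np.linalg.LinAlgError(
            "subset relationship matrix is near-singular "
            f"(condition number > {COND_THRESHOLD:.0e}); consider ridge="
            f"{DEFAULT_RIDGE}"
        )
    P = np.linalg.solve(Gn, cn)
    return P, float(np.max(np.abs(Gn @ P - cn)))


def diversity_proportion(G: GRM, subset, target, ridge=0.0) -> DiversityResult:
    """Proportion of the target population's diversity captured by ``subset``.

    ``c_n`` is each subset animal's mean genomic relationship with the
    target animals (subset members are excluded from the target average);
    ``P_n`` solves ``G_n P_n = c_n``.
    """
    subset = list(subset)
    target = [t for t in target if t not in set(subset)]
    if not subset:
        raise ValueError("empty subset")
    if not target:
        raise ValueError("empty target after excluding subset animals")
    Gn = G.block(subset)
    cn = G.block(subset, target).mean(axis=1)
    P, resid = _solve_diversity(Gn, cn, ridge=ridge)
    return DiversityResult(subset, P, float(P.sum()), resid)


class GreedyDiversitySelector(BaseEstimator):
    """Greedy forward selection of a reference panel by captured diversity.

    At each step the candidate whose addition maximises the captured
    proportion ``sum(G_n^{-1} c_n)`` of the target population is added.
    Candidates that make the subset relationship matrix near-singular at a
    step are skipped with a warning.

    Attributes (after ``fit``)
    --------------------------
    selected_ : list of chosen animal ids, in selection order.
    trace_ : DataFrame (step, animal, captured) — non-decreasing captured.
    captured_ : captured proportion of the final panel.
    """

    def __init__(self, k=22, ridge=0.0):
        self.k = k
        self.ridge = ridge

    def fit(self, G: GRM, candidates, target):
        candidates = list(candidates)
        if self.k > len(candidates):
            raise ValueError(f"k={self.k} exceeds {len(candidates)} candidates")
        selected, rows = [], []
        captured = 0.0
        remaining = list(candidates)
        for step in range(self.k):
            best, best_cap = None, -np.inf
            for cand in remaining:
                try:
                    res = diversity_proportion(
                        G, selected + [cand], target, ridge=self.ridge
                    )
                except np.linalg.LinAlgError:
                    continue
                if res.captured > best_cap:
                    best, best_cap = cand, res.captured
            if best is None:
                warnings.warn(
                    f"selection stopped at step {step}: every remaining candidate "
                    "makes the subset matrix near-singular"
                )
                break
            selected.append(best)
            remaining.remove(best)
            captured = best_cap
            rows.append((step + 1, best, captured))
        self.selected_ = selected
        self.captured_ = captured
        self.trace_ = pd.DataFrame(rows, columns=["step", "animal", "captured"])
        return self


def select_reference(G: GRM, candidates, target, k, ridge=0.0):
    """Functional wrapper: returns ``(selected ids, trace DataFrame)``."""
    sel = GreedyDiversitySelector(k=k, ridge=ridge).fit(G, candidates, target)
    return sel.selected_, sel.trace_


def top_k_relationship(G: GRM, animal, reference, k=5) -> float:
    """Mean of the k largest relationships of ``animal`` with the reference.

    The animal itself is excluded from the reference (with a warning); if
    fewer than k reference animals remain, all are averaged.
    """
    reference = list(reference)
    if animal in reference:
        warnings.warn(f"{animal!r} is in the reference; excluded from its own top-k")
        reference = [r for r in reference if r != animal]
    if not reference:
        raise ValueError("empty reference")
    rel = G.block([animal], reference).ravel()
    k_eff = min(k, len(rel))
    return float(np.sort(rel)[-k_eff:].mean())


def offspring_counts(pedigree: Pedigree, generation) -> pd.Series:
    """Number of offspring in ``generation`` per sire, most common first."""
    sires = [
        pedigree.sire_of(a)
        for a in pedigree.in_generation(generation)
        if pedigree.sire_of(a) is not None
    ]
    return pd.Series(sires).value_counts()


def sires_and_mgs(pedigree: Pedigree, generation) -> list:
    """Union of sires and maternal grandsires of a generation's animals."""
    out = []
    for a in pedigree.in_generation(generation):
        for anc in (pedigree.sire_of(a), pedigree.maternal_grandsire_of(a)):
            if anc is not None and anc not in out:
                out.append(anc)
    return out


ANCESTOR_GROUPS = ["GR_S", "GR_MGS", "GR_SMGS", "NONE"]


def stratify_by_ancestor(pedigree: Pedigree, validation, reference) -> pd.Series:
    """Label validation animals by which direct ancestors sit in the reference.

    GR_S: only the sire; GR_MGS: only the maternal grandsire; GR_SMGS: both;
    NONE: neither.  An unknown maternal grandsire (missing dam link) counts
    as absent from the reference.
    """
    ref = set(reference)
    labels = {}
    for a in validation:
        s_in = pedigree.sire_of(a) in ref
        m_in = pedigree.maternal_grandsire_of(a) in ref
        labels[a] = (
            "GR_SMGS" if s_in and m_in
            else "GR_S" if s_in
            else "GR_MGS" if m_in
            else "NONE"
        )
    return pd.Series(labels, name="ancestor_group")
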