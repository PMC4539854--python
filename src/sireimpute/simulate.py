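"""Synthetic multi-generation pedigreed SNP data.

The generator emulates a closed commercial layer line: a small founder pool
(low effective population size), four generations of training animals
followed by three generations of selection candidates (G0, G1, G2), a
limited sire pool per generation with strongly skewed usage (so a subset of
"most common sires" exists), ungenotyped dams, one chromosome of biallelic
SNPs with a MAF spectrum spanning 0.008-0.5, and LD that decays with genetic
distance.

Founder linkage disequilibrium comes from a first-order latent-copying
Markov model along the chromosome; descent through the pedigree is simulated
by gene dropping with Haldane (no-interference) recombination.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix, Pedigree, make_snp_table

TRAINING_GENERATIONS = ["T1", "T2", "T3", "T4"]
VALIDATION_GENERATIONS = ["G0", "G1", "G2"]
FOUNDER_GENERATION = "F0"


def _default_generation_sizes():
    # 2140 genotyped animals total: 1230 training + G0/G1/G2 = 367/395/148
    return {
        "T1": 308, "T2": 308, "T3": 307, "T4": 307,
        "G0": 367, "G1": 395, "G2": 148,
    }


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study population.

    Defaults mirror the study conditions: ~4485 post-QC SNPs on one large
    chromosome, validation generations of 367/395/148 animals, a per-
    generation sire pool of 31 (so the union of G0's sires and maternal
    grandsires is ~62), skewed sire usage, and ungenotyped dams.
    """

    n_snps: int = 4485
    chrom_length_bp: int = 195_000_000
    chrom_length_morgan: float = 3.9          # ~2 cM/Mb, macrochromosome-like
    n_founder_haplotypes: int = 104           # 52 founders: small-Ne line
    ld_strength: float = 0.9                  # adjacent-SNP copying persistence
    maf_low: float = 0.008
    maf_high: float = 0.5
    generation_sizes: dict = field(default_factory=_default_generation_sizes)
    n_sires_per_generation: int = 31
    sire_usage_concentration: float = 0.25    # Dirichlet; None = uniform usage
    sire_usage_uniform_fraction: float = 0.5  # planned-mating floor on usage
    n_dams_per_generation: int = 120
    prop_missing: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.n_founder_haplotypes < 2 or self.n_founder_haplotypes % 2:
            raise ValueError("n_founder_haplotypes must be an even number >= 2")
        if not 0.0 <= self.ld_strength < 1.0:
            raise ValueError("ld_strength must be in [0, 1)")
        if any(v <= 0 for v in self.generation_sizes.values()):
            raise ValueError("generation sizes must be positive")
        if not 0.0 <= self.prop_missing < 1.0:
            raise ValueError("prop_missing must be in [0, 1)")
        if self.maf_low <= 0.0 or self.maf_high <= self.maf_low or self.maf_high > 0.5:
            raise ValueError("need 0 < maf_low < maf_high <= 0.5")

    @property
    def generations(self):
        return TRAINING_GENERATIONS + VALIDATION_GENERATIONS


def smoke_config(seed=0) -> SimulationConfig:
    """A reduced-scale configuration with the same population structure.

    Used for desk-scale runs of the full study: fewer SNPs on a shorter
    chromosome and smaller generations, but the same seven-generation
    pedigree, 31-sire pool (62 sires+MGS of G0) and skewed sire usage.
    """
    return SimulationConfig(
        n_snps=400,
        chrom_length_bp=50_000_000,
        chrom_length_morgan=1.0,
        n_founder_haplotypes=104,
        generation_sizes={
            "T1": 110, "T2": 110, "T3": 110, "T4": 110,
            "G0": 100, "G1": 80, "G2": 50,
        },
        n_dams_per_generation=60,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# founder haplotypes
# ---------------------------------------------------------------------------

def _snp_map(config: SimulationConfig, rng) -> pd.DataFrame:
    pos = np.sort(rng.choice(config.chrom_length_bp, size=config.n_snps, replace=False)) + 1
    cm_per_bp = config.chrom_length_morgan * 100.0 / config.chrom_length_bp
    return make_snp_table(
        [f"snp{m:05d}" for m in range(config.n_snps)],
        chrom="1",
        pos_bp=pos,
        pos_cm=pos * cm_per_bp,
    )


def simulate_founder_haplotypes(config: SimulationConfig, rng=None, snp_map=None,
                                freqs=None):
    """Binary founder haplotypes with Markov-copying LD.

    Each haplotype carries a latent uniform variable along the chromosome
    that survives from one SNP to the next with probability
    ``ld_strength ** (d_m / mean_d)`` (``d_m`` = genetic distance of the
    interval); the allele is the indicator ``u < p_m``.  Marginal allele
    frequencies are exactly ``p_m`` and adjacent-SNP r-squared increases
    with ``ld_strength``.

    Returns ``(haplotypes (H, M) uint8, p (M,) float, snp_map)``.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    if snp_map is None:
        snp_map = _snp_map(config, rng)
    M = config.n_snps
    if freqs is None:
        maf = rng.uniform(config.maf_low, config.maf_high, size=M)
        flip = rng.random(M) < 0.5
        freqs = np.where(flip, 1.0 - maf, maf)
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs <= 0.0) or np.any(freqs >= 1.0):
        raise ValueError("degenerate founder allele frequencies (must be in (0, 1))")

    d = np.diff(snp_map["pos_cm"].to_numpy())
    d_mean = d.mean() if len(d) else 1.0
    if config.ld_strength == 0.0 or d_mean == 0.0:
        persist = np.zeros(max(M - 1, 0))
    else:
        persist = config.ld_strength ** (d / d_mean)

    H = config.n_founder_haplotypes
    u = np.empty((H, M))
    u[:, 0] = rng.random(H)
    for m in range(1, M):
        keep = rng.random(H) < persist[m - 1]
        u[:, m] = np.where(keep, u[:, m - 1], rng.random(H))
    haps = (u < freqs[None, :]).astype(np.uint8)
    return haps, freqs, snp_map


# ---------------------------------------------------------------------------
# pedigree
# ---------------------------------------------------------------------------

def build_study_pedigree(config: SimulationConfig, rng=None) -> Pedigree:
    """Founders -> 4 training generations -> G0, G1, G2.

    Each generation holds genotyped selection candidates plus a pool of
    ungenotyped dams; every offspring's sire is drawn from a pool of
    ``n_sires_per_generation`` males of the previous generation with
    Dirichlet-weighted usage (``sire_usage_concentration``; None = uniform),
    and its dam uniformly from the previous generation's dam pool.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    records = []  # animal, sire, dam, generation, sex, genotyped

    n_founders = config.n_founder_haplotypes // 2
    founders = [f"F0_{i:04d}" for i in range(n_founders)]
    sexes = np.array(["M", "F"] * (n_founders // 2 + 1))[:n_founders]
    for a, s in zip(founders, sexes):
        records.append((a, None, None, FOUNDER_GENERATION, s, False))
    prev_males = [a for a, s in zip(founders, sexes) if s == "M"]
    prev_dams = [a for a, s in zip(founders, sexes) if s == "F"]

    for gen in config.generations:
        n_cand = config.generation_sizes[gen]
        is_last = gen == config.generations[-1]
        n_dams = 0 if is_last else config.n_dams_per_generation

        pool = list(prev_males)
        if len(pool) > config.n_sires_per_generation:
            pool = list(rng.choice(pool, size=config.n_sires_per_generation,
                                   replace=False))
        if not pool:
            raise ValueError(f"empty sire pool for generation {gen}")
        if config.sire_usage_concentration is None:
            weights = np.full(len(pool), 1.0 / len(pool))
        else:
            # skewed usage with a uniform floor: every pool sire gets some
            # planned matings, but a minority fathers most offspring
            u = config.sire_usage_uniform_fraction
            weights = (1.0 - u) * rng.dirichlet(
                np.full(len(pool), config.sire_usage_concentration)
            ) + u / len(pool)
        if not prev_dams:
            raise ValueError(f"empty dam pool for generation {gen}")

        males, dams_next = [], []
        for kind, n in (("cand", n_cand), ("dam", n_dams)):
            for i in range(n):
                a = f"{gen}_{i:04d}" if kind == "cand" else f"{gen}d_{i:04d}"
                sire = pool[rng.choice(len(pool), p=weights)]
                dam = prev_dams[rng.integers(len(prev_dams))]
                if kind == "cand":
                    sex = "M" if rng.random() < 0.5 else "F"
                    records.append((a, sire, dam, gen, sex, True))
                    if sex == "M":
                        males.append(a)
                else:
                    records.append((a, sire, dam, gen, "F", False))
                    dams_next.append(a)
        prev_males, prev_dams = males, dams_next

    tab = pd.DataFrame(
        records, columns=["animal", "sire", "dam", "generation", "sex", "genotyped"]
    )
    return Pedigree(tab, generations=[FOUNDER_GENERATION] + config.generations)


# ---------------------------------------------------------------------------
# gene dropping
# ---------------------------------------------------------------------------

@dataclass
class TruthSet:
    """Complete simulated truth: genotypes, phased haplotypes and pedigree."""

    genotypes: GenotypeMatrix           # genotyped animals only, no missing
    haplotypes: dict                    # animal id -> (2, M) uint8, all animals
    pedigree: Pedigree
    snp_map: pd.DataFrame
    founder_freqs: np.ndarray
    maf_by_generation: pd.DataFrame     # rows = SNPs, columns = generations

    def haplotype_matrix(self, animals) -> np.ndarray:
        """Stack phased haplotypes for the given animals: (n, 2, M)."""
        return np.stack([self.haplotypes[a] for a in animals])


def _gamete(hap_pair, pos_morgan, length_morgan, rng):
    """One recombinant gamete under Haldane's model (Poisson crossovers)."""
    n_x = rng.poisson(length_morgan)
    if n_x == 0:
        return hap_pair[rng.integers(2)].copy()
    breaks = np.sort(rng.uniform(0.0, length_morgan, size=n_x))
    seg = np.searchsorted(breaks, pos_morgan, side="right")
    which = (seg + rng.integers(2)) % 2
    return np.where(which == 0, hap_pair[0], hap_pair[1]).astype(np.uint8)


def gene_drop(founder_haps, pedigree: Pedigree, snp_map, length_morgan, rng,
              genotyped=None, founder_freqs=None) -> TruthSet:
    """Drop founder haplotypes through the pedigree.

    Each non-founder inherits one recombinant haplotype per parent; crossover
    counts are Poisson with mean ``length_morgan`` and positions uniform on
    the genetic map (no interference).  Genotype = sum of the two haplotypes,
    so the output is Mendelian-consistent by construction.
    """
    pos_morgan = snp_map["pos_cm"].to_numpy() / 100.0
    if np.any(np.diff(pos_morgan) < 0):
        raise ValueError("genetic map positions must be monotone")
    if pos_morgan[-1] > length_morgan + 1e-9:
        raise ValueError("genetic map extends beyond the chromosome length")

    haplotypes = {}
    next_founder_hap = 0
    tab = pedigree.table
    for _, rec in tab.iterrows():
        a, sire, dam = rec["animal"], rec["sire"], rec["dam"]
        if sire is None and dam is None:
            haplotypes[a] = founder_haps[next_founder_hap:next_founder_hap + 2].copy()
            next_founder_hap += 2
        else:
            haplotypes[a] = np.stack([
                _gamete(haplotypes[sire], pos_morgan, length_morgan, rng),
                _gamete(haplotypes[dam], pos_morgan, length_morgan, rng),
            ])

    if genotyped is None:
        genotyped = (
            list(tab.loc[tab["genotyped"], "animal"])
            if "genotyped" in tab.columns else list(tab["animal"])
        )
    calls = np.stack([haplotypes[a].sum(axis=0) for a in genotyped]).astype(np.int8)
    geno = GenotypeMatrix(genotyped, snp_map.copy(), calls)

    maf_cols = {}
    for gen in pedigree.generations:
        anim = [a for a in pedigree.in_generation(gen) if a in haplotypes]
        if not anim:
            continue
        p = np.stack([haplotypes[a] for a in anim]).mean(axis=(0, 1))
        maf_cols[gen] = np.minimum(p, 1.0 - p)
    maf_by_gen = pd.DataFrame(maf_cols, index=snp_map["id"])

    return TruthSet(
        genotypes=geno,
        haplotypes=haplotypes,
        pedigree=pedigree,
        snp_map=snp_map,
        founder_freqs=founder_freqs,
        maf_by_generation=maf_by_gen,
    )


def apply_missingness(truth: TruthSet, prop_missing, seed) -> GenotypeMatrix:
    """Return a copy of the truth genotypes with random calls set missing."""
    if not 0.0 <= prop_missing < 1.0:
        raise ValueError("prop_missing must be in [0, 1)")
    geno = truth.genotypes.copy()
    if prop_missing > 0.0:
        rng = np.random.default_rng(seed)
        mask = rng.random(geno.calls.shape) < prop_missing
        geno.calls[mask] = MISSING
    return geno


MAF_CLASS_COVERAGE_MIN = 0.05


def check_maf_coverage(truth: TruthSet, min_fraction=MAF_CLASS_COVERAGE_MIN):
    """Require every study MAF class to hold at least ``min_fraction`` of SNPs.

    Evaluated on the realized MAF over all genotyped animals; raises
    ``ValueError`` when the configuration produced a spectrum too narrow for
    MAF-stratified masking.
    """
    from .masking import MAF_CLASS_EDGES

    p = truth.genotypes.calls.mean(axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    n = len(maf)
    for lo, hi in zip(MAF_CLASS_EDGES[:-1], MAF_CLASS_EDGES[1:]):
        frac = np.mean((maf > lo) & (maf <= hi))
        if frac < min_fraction:
            raise ValueError(
                f"MAF class ({lo}, {hi}] holds {frac:.1%} of {n} SNPs "
                f"(< {min_fraction:.0%}); widen the simulated MAF spectrum"
            )


def simulate_study(config: SimulationConfig, validate=True):
    """Full generator: founders, pedigree, gene drop and missingness.

    Returns ``(truth, observed)`` where ``observed`` is the truth genotype
    matrix with ``config.prop_missing`` of calls masked.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_hap, rng_ped, rng_drop, rng_miss = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    haps, freqs, snp_map = simulate_founder_haplotypes(config, rng=rng_hap)
    ped = build_study_pedigree(config, rng=rng_ped)
    truth = gene_drop(
        haps, ped, snp_map, config.chrom_length_morgan, rng_drop,
        founder_freqs=freqs,
    )
    if validate:
        check_maf_coverage(truth)
    observed = apply_missingness(
        truth, config.prop_missing, seed=rng_miss.integers(2**31)
    )
    return truth, observed
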