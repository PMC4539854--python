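# Methods

`sireimpute` evaluates genotype imputation in a small closed breeding line
where the reference panel is a handful of influential sires. This note
documents the models, the defaults and the numerical choices, and what the
synthetic validation does and does not demonstrate.

## The simulated study population

The generator emulates a commercial layer-type line with seven genotyped
generations: four training generations followed by three generations of
selection candidates (G0, G1, G2). Defaults mirror that setting: ~4485 SNPs
on one macrochromosome (195 Mb, 3.9 Morgan, i.e. ~2 cM/Mb constant rate),
generation sizes 308/308/307/307 and 367/395/148 (2140 genotyped animals in
total), 52 founders (104 haplotypes, matching the low effective population
size such lines show), a pool of 31 sires per generation so that the union
of G0's sires and maternal grandsires is ~62 animals, and ungenotyped dams
(so the maternal grandsire is the closest genotyped maternal ancestor).

*Founder LD.* Haplotypes follow a first-order latent-copying Markov model:
each haplotype carries a latent uniform variate along the chromosome that
survives an interval with probability `ld_strength ** (d/mean_d)` (default
`ld_strength = 0.9`); the allele is the indicator `u < p_m`. Marginals are
exactly the target frequencies (drawn uniformly on (0.008, 0.5] and
randomly oriented) and adjacent-SNP r² increases monotonically with
`ld_strength` and decays with genetic distance. This model is
parameter-transparent and desk-scale; it is **not** a coalescent: its
r²-vs-distance profile does not follow Sved's curve shape (tightly linked
pairs plateau near `ld_strength²` instead of approaching 1), so the Ne
diagnostic computed *on simulated data* overestimates the nominal founder
Ne. The Sved machinery itself is validated separately on pairs generated
exactly on the curve. `gene_drop` accepts any externally produced founder
haplotype panel if a coalescent source is preferred.

*Sire usage.* Offspring sires are drawn from the generation's pool with
weights `(1-u)·Dirichlet(α) + u/pool` (defaults `α = 0.25`, `u = 0.5`): the
Dirichlet term creates the strongly skewed family sizes that make a "most
common sires" subset meaningful, while the uniform floor reflects planned
matings in which every pool sire is used at least occasionally (and keeps
the sires+MGS union near its target size). `α = None` gives exactly uniform
usage for calibration tests.

*Gene dropping.* Each meiosis draws a Poisson number of crossovers (mean =
map length in Morgans) placed uniformly on the genetic map — Haldane's
model, no interference — and transmits the recombinant haplotype. Genotypes
are haplotype sums, so the truth set is Mendelian-consistent by
construction; ~2 % of calls are then masked at random to exercise QC.

The simulator does **not** model selection on phenotypes (the real
populations are under genomic selection), mutation, genotyping batch
effects, or sex chromosomes. Passing the ordering tests on this data shows
the pipeline reproduces the *mechanisms* (reference size, relatedness, MAF
class, density) — not that any particular accuracy value transfers to a
real line.

## Quality control

SNPs are removed for MAF < 0.01, call rate < 0.9, or > 10 % parent-progeny
Mendelian inconsistencies (opposite homozygotes among complete genotyped
pairs); animals with call rate < 0.9 are then removed. All SNP criteria are
evaluated on the unfiltered matrix in one pass, then the animal filter is
applied once — deterministic, and idempotent in practice. SNPs whose MAF or
Mendelian rate is undefined are dropped with an explicit reason, never
silently kept; Mendelian-conflicting *calls* are left intact (only whole
SNPs are dropped).

## Diversity-based reference selection

The GRM is VanRaden's method 1 with observed allele frequencies; missing
calls are imputed to `2p` (zero after centering). The captured-diversity
criterion solves `G_n P_n = c_n` with `c_n` the candidates' mean
relationship to the target generation, candidates excluded from the target
average. Solves are rejected when the subset block's condition number
exceeds 1e8 (an optional ridge `λI`, default `λ = 1e-6`, is available);
accepted solves satisfy `‖G_n P_n − c_n‖∞ < 1e-8`.

Greedy forward selection adds, at each step, the candidate that maximises
the captured sum. Two caveats discovered during validation:

* the captured trace is non-decreasing while additions help, but **can
  decrease past saturation** — `P_n` entries may be negative, so forcing
  `k` close to the full candidate set can reduce the sum below an interior
  maximum. In the intended regime (k well below the pool, pedigree-
  structured GRM) the trace is monotone.
* with observed-frequency centering, the mean relationship of *random*
  training animals to the target is near zero, so random panels capture a
  small, often slightly negative, proportion. The selected-vs-random
  contrast (the design's point) is unaffected.

Both an offspring-count ranking (`offspring_counts`) and the diversity
criterion are available; the pipeline default is the diversity criterion.

## The copying-HMM imputation engine

The engine is a diploid Li & Stephens model: the target's two chromosomes
are mosaics of the `H` reference haplotypes, the hidden state the ordered
pair of copied templates. Per haplotype and interval, the switch
probability is `θ_m = 1 − exp(−4·ne_scale·d_m/H)` spread uniformly over the
H templates (`d_m` in Morgans; `ne_scale` default 52, the effective size
the simulated line mirrors). Emissions compare observed genotype with the
state pair's dosage under independent per-allele error `ε` (default 0.001).
It is a transparent stand-in for localized-haplotype-cluster imputation
software, honouring the same contract — posterior genotype probabilities,
most-likely genotypes, estimated allelic R² — with no claim of
call-for-call agreement with any external program.

*State space.* Ordered pairs (H²) with the standard row/column-sum
factorisation, so one site costs O(H²); collapsing to unordered pairs would
halve constants but complicate exactness checks, and the factorised kernel
is verified to 1e-10 against a dense H²×H² transition-matrix
forward–backward and literal path enumeration on small instances.

*Numerics.* Forward–backward uses per-site renormalisation (scale factors
accumulate the log-likelihood); Viterbi runs in log space with per-site
re-centering. Zero genetic distances give switch probability 0 and are
legal. Posterior triples sum to 1 within 1e-9; no NaN/Inf for valid input.
Forward quantities are stored only at missing sites, so memory is
O(missing × H²).

*Phasing.* Reference phasing is iterated conditional maximisation: random
initial heterozygote orientation (seeded), then each animal's haplotype
pair is re-derived from the diploid Viterbi path against all other animals'
current haplotypes, iterating up to `n_phasing_iterations` (default 50,
early-stopped at convergence). Copied alleles at heterozygous sites set the
phase; sites the path cannot phase keep their previous orientation; missing
reference calls are filled from the copied templates. Pairs always sum to
the observed genotype. A single-animal reference is returned random-phased
with a warning.

*Hard calls.* Argmax of the posterior triple; ties break toward the
heterozygote, then toward the homozygote of the panel's major allele.

*Estimated allelic R².* With best-guess dosage `b_i`, expected dosage
`e_i = P(het) + 2·P(hom₂)` and `s_i = P(het) + 4·P(hom₂)`:

    R² = [Σb·e − Σb·Σe/n]² / ([Σb² − (Σb)²/n]·[Σs − (Σe)²/n])

clamped to [0, 1], defined as 0 when either variance term is non-positive,
undefined (NaN) for fewer than two imputed animals. Degenerate correct
posteriors give exactly 1.

## Accuracy statistics

* `r_corrected` (per animal): Pearson correlation across the animal's
  masked SNPs of true and imputed genotypes, each centered by the reference
  panel's mean gene content. Centering removes MAF-driven differences in
  per-SNP means.
* SNP-specific accuracy (per SNP): Pearson correlation across animals of
  raw 0/1/2 codes — deliberately uncentered, as the two statistics are
  defined differently; its square is the "true" reliability that the
  estimated allelic R² predicts.
* Undefined correlations (constant vectors, too few points) are NaN and are
  excluded from stratum means — coercing them to 0 would bias low-MAF
  strata. Standard errors use the sample SD (n−1) over animals within a
  stratum.
* Concordance tables regress true reliability on allelic R² per stratum;
  strata with fewer than three defined points are skipped.

## Masking designs

MAF classes are (0.008, 0.1], (0.1, 0.2], (0.2, 0.3], (0.3, 0.4],
(0.4, 0.5] — left-open right-closed (a convention had to be fixed for the
shared boundaries), with MAF ≤ 0.008 unclassed and never masked. The class
MAF is computed in the *reference* panel by default (the validation
population is the documented alternative). The low-density design retains
`round(i·(N−1)/(K−1))` for `i = 0..K−1`, `K = round(N·keep_fraction)`
(default 4 %): evenly spaced by map index, endpoints kept, duplicate-free.
The MAF-independent design samples `round(0.2·N)` classed SNPs uniformly.
Masking applies to validation animals only; the imputer receives a copy
with masked calls set missing, so truth is unreachable by construction.

## LD and effective population size

LD is the correlation `r` of allele indicators across phased haplotypes
(genotype-vector correlation is the documented unphased fallback);
adjacent pairs follow map order after QC. Cross-generation concordance is
the Pearson correlation of `r` over shared pairs. Ne inverts Sved's
`r² = 1/(1 + 4·Ne·c)` either per pair (closed form, averaged) or by least
squares over `Ne > 0` (default; optimised in log Ne). The small-sample
correction of r² is deliberately omitted (exposed later if needed); pairs
with `c ≤ 0` or `r² ∉ (0, 1)` are excluded and counted.

## Problem sizes used by the test suite

The ordering checks run a reduced ("smoke") configuration chosen as the
smallest population that preserves the study's structure: 400 SNPs on a
1-Morgan chromosome, generations 110×4 and 100/80/50, the same 31-sire
pool (sires+MGS union ~50), phasing capped at 20 sweeps, G0 as the scored
validation generation, five seeds. At this scale the qualitative contrasts
(reference size, MAF class, density, selected-vs-random, concordance
ordering) are stable across seeds while a full five-seed evaluation stays
within a few minutes per seed on one core. `scripts/acceptance.py` runs one
replicate end to end plus the Sved recovery check.

## Known limitations

* ICM phasing converges to a local optimum; with very small panels its
  switch-error rate is well above what long-range phasing tools achieve,
  which depresses absolute accuracies (orderings are unaffected).
* The founder LD model's r²-distance profile is not coalescent-shaped (see
  above); Ne estimated from simulated LD is a diagnostic, not a recovery
  of the founder count.
* O(H²) per site per animal means large reference panels (hundreds of
  animals) become expensive; no windowed/chunked mode is provided.
* Multi-chromosome analyses run per chromosome; there is no liftover, no
  pedigree-aware imputation, and no tag-SNP optimisation for the
  low-density design.
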