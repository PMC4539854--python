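# sireimpute

Genotype imputation evaluation for small, closed, pedigreed populations —
the situation of a commercial breeding line where a handful of influential
sires can serve as the entire imputation reference panel.

In such populations, selection candidates are genotyped at low density and
imputed up to a dense panel from a few carefully chosen reference animals.
`sireimpute` provides the full evaluation machinery for that design:

* **Reference-panel selection by captured genomic diversity.** From the
  VanRaden genomic relationship matrix `G = ZZ' / (2 Σ pⱼ(1−pⱼ))`, the
  contribution of a candidate subset of *n* animals toward a target
  population is the solved vector **P**ₙ = **G**ₙ⁻¹**c**ₙ, where **c**ₙ holds
  each candidate's mean relationship with the target; Σ**P**ₙ is the
  proportion of the target's genetic variation the subset captures. Panels
  are chosen by greedy forward selection on this criterion
  (`GreedyDiversitySelector`), typically picking the "most common sires".
* **MAF-stratified masking designs.** Five minor-allele-frequency classes
  spanning (0.008, 0.5] are masked one at a time (the dense-to-dense,
  "48K→60K"-style design), a random ~20 % is masked independent of MAF, or
  ~96 % is masked leaving an evenly spaced low-density panel ("3K→60K").
* **A diploid Li & Stephens haplotype-copying HMM imputer**
  (`LiStephensImputer`, scikit-learn estimator conventions): `fit` phases
  the reference by iterated conditional maximisation, `predict_proba` runs
  forward–backward over ordered pairs of reference haplotypes (switch rate
  `1 − exp(−4·Ne·d/H)` per Morgan interval, per-allele error ε) and returns
  posterior genotype probabilities at masked sites.
* **Accuracy statistics.** Animal-specific accuracy `r_corrected` (Pearson
  correlation of true and imputed 0/1/2 genotypes, each centered by the
  reference panel's mean gene content), SNP-specific accuracy and its square
  (true imputation reliability), and the truth-free estimated allelic R²
  computed from the posterior probabilities, with concordance diagnostics
  between the two.
* **LD and effective population size.** Adjacent-SNP LD (r), its
  persistence across generations, and Ne from Sved's equation
  `r² = 1/(1 + 4·Ne·c)`.
* **A pedigreed population simulator** that generates the whole study
  system: founders with Markov-copying LD, four training generations plus
  three validation generations (G0/G1/G2), a limited sire pool with skewed
  usage, ungenotyped dams, and gene dropping with Haldane recombination —
  so every stage above is testable without any external data.

## Worked example

```python
import numpy as np
from sireimpute import (
    smoke_config, simulate_study, qc_filter, compute_grm, select_reference,
)
from sireimpute.grm import sires_and_mgs, diversity_proportion
from sireimpute.masking import assign_maf_classes, mask_by_maf_class, apply_scenario
from sireimpute.qc import compute_maf
from sireimpute.hmm import LiStephensImputer
from sireimpute.accuracy import animal_accuracies

# 1. simulate a reduced-scale closed line and apply QC
truth, observed = simulate_study(smoke_config(seed=1))
geno, report = qc_filter(observed, truth.pedigree)
truth.genotypes = truth.genotypes.subset(snps=geno.snp_ids)

# 2. pick the 22 most influential sires by captured genomic diversity
ped = truth.pedigree
genotyped = set(geno.animals)
candidates = [a for a in sires_and_mgs(ped, "G0") if a in genotyped]
g0 = [a for a in ped.in_generation("G0") if a in genotyped]
G = compute_grm(geno)
ref22, trace = select_reference(G, candidates, g0, k=22)

# 3. mask the rarest MAF class in G0 and impute it back
maf_ref = compute_maf(geno, subset=ref22)
classing = assign_maf_classes(maf_ref, snp_ids=geno.snp_ids)
scenario = mask_by_maf_class(classing, class_id=1)
masked = apply_scenario(geno.subset(animals=g0), scenario, g0)

imputer = LiStephensImputer(n_phasing_iterations=20).fit(geno.subset(animals=ref22))
imputed = imputer.predict(masked)
acc = animal_accuracies(truth.genotypes, imputed, geno.subset(animals=ref22),
                        g0, scenario.masked_ids)
```

Output:

```
post-QC: 670 animals x 385 SNPs (15 removals)
selected 22 of 54 sires/MGS, captured diversity = 60.1%
full candidate set captures 43.7%
masked 74 SNPs with MAF in (0.008, 0.1]; mean r_corrected = 0.667 over 100 G0 animals
```

The 22 diversity-selected sires capture 60 % of the G0 generation's genetic
variation (the full 54-candidate set yields less once saturated additions
start contributing negative proportions — see `docs/methods.md`), and the
rarest SNPs are imputed at a mean gene-content-corrected accuracy of 0.67
from just those 22 animals. Larger panels, higher-MAF classes and denser
validation panels all raise this number; `sireimpute run-all --smoke
--seed 1 --out study/` produces the full stratified report tables.

## Command-line interface

`sireimpute` exposes thin subcommands over the library: `simulate`, `qc`,
`grm`, `select-ref`, `mask`, `impute`, `evaluate`, `ld-ne` and `run-all`
(the full orchestrated study from one YAML config, with seeded, byte-
reproducible outputs). See `sireimpute --help`.
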