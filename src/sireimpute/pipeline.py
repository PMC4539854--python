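"""End-to-end study orchestration: simulate -> QC -> select -> mask -> impute -> score.

``run_study`` executes the full evaluation from one :class:`StudyConfig` and
writes tab-separated report tables (accuracy by MAF class and reference
size, low-density accuracy, random-reference comparison, ancestor groups,
reliability/allelic-R2 concordance, LD and Ne diagnostics) plus a manifest
sufficient to reproduce the run.  The intermediate helpers are public so
tests and scripts can run individual cells of the design.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .accuracy import (
    animal_accuracies,
    gene_content_means,
    reliability_concordance,
    snp_accuracies,
    summarize,
)
from .containers import GenotypeMatrix
from .grm import (
    compute_grm,
    diversity_proportion,
    select_reference,
    sires_and_mgs,
    stratify_by_ancestor,
    top_k_relationship,
)
from .hmm import (
    estimated_allelic_r2,
    impute,
    most_likely_genotype,
    phase_reference,
)
from .ldne import adjacent_pairs, estimate_ne, ld_concordance, ld_r
from .masking import (
    apply_scenario,
    assign_maf_classes,
    mask_by_maf_class,
    mask_low_density,
    mask_maf_independent,
    random_reference_sets,
)
from .qc import compute_maf, qc_filter
from .simulate import (
    TRAINING_GENERATIONS,
    VALIDATION_GENERATIONS,
    SimulationConfig,
    simulate_study,
    smoke_config,
)

log = logging.getLogger("sireimpute")


@dataclass
class HMMConfig:
    error_rate: float = 0.001
    ne_scale: float = 52.0
    n_phasing_iterations: int = 50


@dataclass
class QCConfig:
    maf_min: float = 0.01
    call_rate_min: float = 0.9
    mendel_max: float = 0.10
    animal_call_rate_min: float = 0.9


@dataclass
class StudyConfig:
    """Configuration of the full imputation evaluation study."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    qc: QCConfig = field(default_factory=QCConfig)
    hmm: HMMConfig = field(default_factory=HMMConfig)
    reference_k: int = 22                     # small diversity-selected panel
    random_reference_repeats: int = 10
    scenarios: list = field(
        default_factory=lambda: ["by_maf_class", "low_density", "maf_independent"]
    )
    validation_generations: list = field(
        default_factory=lambda: list(VALIDATION_GENERATIONS)
    )
    seed: int = 0

    def __post_init__(self):
        known = {"by_maf_class", "low_density", "maf_independent"}
        bad = set(self.scenarios) - known
        if bad:
            raise ValueError(f"unknown scenarios {sorted(bad)}; choose from {sorted(known)}")


def smoke_study_config(seed=0, **overrides) -> StudyConfig:
    """Reduced-scale study used for desk runs; see :func:`smoke_config`."""
    cfg = StudyConfig(
        simulation=smoke_config(seed=seed),
        hmm=HMMConfig(n_phasing_iterations=20),
        seed=seed,
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


def load_config(path) -> StudyConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return StudyConfig(
        simulation=SimulationConfig(**raw.get("simulation", {})),
        qc=QCConfig(**raw.get("qc", {})),
        hmm=HMMConfig(**raw.get("hmm", {})),
        **{k: v for k, v in raw.items() if k not in ("simulation", "qc", "hmm")},
    )


def save_config(config: StudyConfig, path):
    Path(path).write_text(yaml.safe_dump(asdict(config), sort_keys=False))


# ---------------------------------------------------------------------------
# study stages
# ---------------------------------------------------------------------------

@dataclass
class ReferenceSets:
    """The evaluated reference panels and their captured diversity."""

    all_sires_mgs: list            # the ~62 sires + maternal grandsires of G0
    selected: list                 # diversity-selected k-subset
    random: list                   # list of random k-subsets
    captured_all: float
    captured_selected: float
    captured_random: list
    selection_trace: pd.DataFrame
    top5: pd.DataFrame             # mean top-5 relationship per generation/ref


def build_reference_sets(geno: GenotypeMatrix, pedigree, config: StudyConfig,
                         rng) -> ReferenceSets:
    """GRM, diversity proportions and reference panels for the study."""
    G = compute_grm(geno)
    genotyped = set(geno.animals)
    candidates = [a for a in sires_and_mgs(pedigree, "G0") if a in genotyped]
    target = [a for a in pedigree.in_generation("G0") if a in genotyped]
    captured_all = diversity_proportion(G, candidates, target).captured
    selected, trace = select_reference(G, candidates, target, k=config.reference_k)
    captured_sel = float(trace["captured"].iloc[-1])

    training = [
        a for g in TRAINING_GENERATIONS for a in pedigree.in_generation(g)
        if a in genotyped
    ]
    random_sets = random_reference_sets(
        training, k=config.reference_k,
        n_repeats=config.random_reference_repeats,
        seed=int(rng.integers(2**31)),
    ) if config.random_reference_repeats else []
    captured_rand = [
        diversity_proportion(G, s, target).captured for s in random_sets
    ]

    rows = []
    for gen in config.validation_generations:
        val = [a for a in pedigree.in_generation(gen) if a in genotyped]
        for name, ref in (("selected", selected), ("all_sires_mgs", candidates)):
            t5 = np.mean([top_k_relationship(G, a, ref, k=5) for a in val])
            rows.append({"generation": gen, "reference": name, "mean_top5": t5})
    return ReferenceSets(
        all_sires_mgs=candidates, selected=selected, random=random_sets,
        captured_all=captured_all, captured_selected=captured_sel,
        captured_random=captured_rand, selection_trace=trace,
        top5=pd.DataFrame(rows),
    )


@dataclass
class CellResult:
    """One scenario x reference x generation cell of the design."""

    reference_name: str
    scenario_name: str
    generation: str
    animal_r: pd.Series            # r_corrected per validation animal
    snp_table: pd.DataFrame        # accuracy, reliability, allelic_r2, maf_class


def impute_cell(truth, geno, panel, reference_ids, validation_ids, scenario,
                hmm_cfg: HMMConfig, classing, reference_name, generation) -> CellResult:
    """Mask, impute and score one cell of the design."""
    val = geno.subset(animals=validation_ids)
    masked = apply_scenario(val, scenario, validation_ids)
    post = impute(masked, panel, error_rate=hmm_cfg.error_rate,
                  ne_scale=hmm_cfg.ne_scale)
    hard = most_likely_genotype(post)
    imputed = masked.copy()
    imputed.calls = hard

    ref_geno = geno.subset(animals=reference_ids)
    animal_r = animal_accuracies(
        truth.genotypes, imputed, ref_geno, validation_ids, scenario.masked_ids
    )
    snp_tab = snp_accuracies(truth.genotypes, imputed, validation_ids,
                             scenario.masked_ids)
    ar2 = estimated_allelic_r2(post)
    ar2_by_id = dict(zip(post.snp_ids, ar2))
    snp_tab["allelic_r2"] = [ar2_by_id[s] for s in snp_tab.index]
    cls = classing.class_of()
    snp_tab["maf_class"] = [cls.get(s, 0) for s in snp_tab.index]
    return CellResult(reference_name, scenario.name, generation, animal_r, snp_tab)


def run_reference(truth, geno, reference_name, reference_ids, config: StudyConfig,
                  generations=None, scenario_names=None, seed=0) -> list:
    """Phase one reference panel and run its scenario x generation cells."""
    generations = generations or config.validation_generations
    scenario_names = scenario_names or config.scenarios
    ref_geno = geno.subset(animals=reference_ids)
    panel = phase_reference(
        ref_geno, error_rate=config.hmm.error_rate, ne_scale=config.hmm.ne_scale,
        n_iterations=config.hmm.n_phasing_iterations, random_state=seed,
    )
    maf_ref = compute_maf(geno, subset=reference_ids)
    classing = assign_maf_classes(maf_ref, snp_ids=geno.snp_ids)

    scenarios = []
    if "by_maf_class" in scenario_names:
        for j in range(1, 6):
            try:
                scenarios.append(mask_by_maf_class(classing, j))
            except ValueError:
                log.warning("reference %s: MAF class %d empty, skipped",
                            reference_name, j)
    if "low_density" in scenario_names:
        scenarios.append(mask_low_density(geno.snp_ids, keep_fraction=0.04))
    if "maf_independent" in scenario_names:
        scenarios.append(mask_maf_independent(classing, mask_fraction=0.2, seed=seed))

    results = []
    genotyped = set(geno.animals)
    for gen in generations:
        val = [a for a in truth.pedigree.in_generation(gen) if a in genotyped]
        for sc in scenarios:
            results.append(impute_cell(
                truth, geno, panel, reference_ids, val, sc, config.hmm,
                classing, reference_name, gen,
            ))
    return results


# ---------------------------------------------------------------------------
# report tables
# ---------------------------------------------------------------------------

def table_by_maf_class(cells) -> pd.DataFrame:
    """Mean r_corrected per generation x reference x MAF class (per-class
    masking scenarios)."""
    rows = []
    for c in cells:
        if not c.scenario_name.startswith("maf_class_"):
            continue
        class_id = int(c.scenario_name.rsplit("_", 1)[1])
        for a, v in c.animal_r.items():
            rows.append({
                "generation": c.generation, "reference": c.reference_name,
                "maf_class": class_id, "animal": a, "r_corrected": v,
            })
    df = pd.DataFrame(rows)
    return summarize(
        df["r_corrected"], df[["generation", "reference", "maf_class"]]
    ).reset_index()


def table_scenario_means(cells, scenario_name) -> pd.DataFrame:
    """Mean r_corrected per generation x reference for one scenario."""
    rows = [
        {"generation": c.generation, "reference": c.reference_name,
         "animal": a, "r_corrected": v}
        for c in cells if c.scenario_name == scenario_name
        for a, v in c.animal_r.items()
    ]
    df = pd.DataFrame(rows)
    return summarize(df["r_corrected"], df[["generation", "reference"]]).reset_index()


def table_maf_independent(cells) -> pd.DataFrame:
    """Per-MAF-class r_corrected when masking ignored the MAF class.

    Each animal's masked SNPs are split by class and the per-animal
    correlation is computed within class, mirroring evaluation-within-class
    of a class-blind design.  Requires the per-SNP table, so this reports
    SNP-level reliability summaries per class alongside masked counts.
    """
    rows = []
    for c in cells:
        if c.scenario_name != "maf_independent":
            continue
        for snp, rec in c.snp_table.iterrows():
            rows.append({
                "generation": c.generation, "reference": c.reference_name,
                "maf_class": int(rec["maf_class"]), "snp": snp,
                "accuracy": rec["accuracy"], "reliability": rec["reliability"],
            })
    df = pd.DataFrame(rows)
    out = summarize(df["accuracy"], df[["generation", "reference", "maf_class"]])
    counts = df.groupby(["generation", "reference", "maf_class"])["snp"].count()
    out["n_masked_snps"] = counts
    return out.reset_index()


def table_concordance(cells) -> pd.DataFrame:
    """Correlation of true reliability with allelic R2 per cell x MAF class."""
    rows = []
    for c in cells:
        conc = reliability_concordance(
            c.snp_table["reliability"], c.snp_table["allelic_r2"],
            strata=c.snp_table["maf_class"].to_numpy(),
        )
        for stratum, rec in conc.iterrows():
            rows.append({
                "generation": c.generation, "reference": c.reference_name,
                "scenario": c.scenario_name, "maf_class": stratum,
                "n": rec["n"], "correlation": rec["correlation"],
                "slope": rec["slope"], "intercept": rec["intercept"],
            })
    return pd.DataFrame(rows)


def table_reliability_vs_ar2(cells) -> pd.DataFrame:
    """Mean true reliability and mean allelic R2 per reference x MAF class."""
    rows = [
        {"reference": c.reference_name, "scenario": c.scenario_name,
         "maf_class": int(rec["maf_class"]), "reliability": rec["reliability"],
         "allelic_r2": rec["allelic_r2"]}
        for c in cells for _, rec in c.snp_table.iterrows()
    ]
    df = pd.DataFrame(rows)
    return (
        df.groupby(["reference", "scenario", "maf_class"])[["reliability", "allelic_r2"]]
        .mean()
        .reset_index()
    )


def ld_ne_report(truth, generations=("G0", "G2")) -> dict:
    """Adjacent-SNP LD per generation, cross-generation concordance and Ne."""
    pos_m = truth.snp_map["pos_cm"].to_numpy() / 100.0
    pos_bp = truth.snp_map["pos_bp"].to_numpy()
    pairs = adjacent_pairs(len(pos_m))
    ld = {}
    for gen in generations:
        anim = truth.pedigree.in_generation(gen)
        haps = truth.haplotype_matrix(anim).reshape(len(anim) * 2, -1)
        ld[gen] = ld_r(haps, pairs, pos_bp=pos_bp, pos_morgan=pos_m, phased=True)
    first, last = generations[0], generations[-1]
    conc = ld_concordance(ld[first], ld[last])
    ne = estimate_ne(ld[first], method="curve_fit")
    return {"ld": ld, "concordance": conc, "ne": ne}


def run_seed_experiment(seed, config: StudyConfig = None) -> dict:
    """One replicate of the core accuracy experiment (G0 validation).

    Simulates the population, applies QC, builds the diversity-selected and
    random reference panels, imputes the per-MAF-class and low-density
    masking designs, and returns the headline metrics: captured diversity,
    mean r_corrected per MAF class for the small and large panels, random-
    panel class-1 accuracy, reliability/allelic-R2 concordance and LD/Ne
    diagnostics.
    """
    config = config or smoke_study_config(seed=seed)
    sim = SimulationConfig(**{**asdict(config.simulation), "seed": seed})
    truth, observed = simulate_study(sim)
    ped = truth.pedigree
    geno, _ = qc_filter(
        observed, ped, maf_min=config.qc.maf_min,
        call_rate_min=config.qc.call_rate_min, mendel_max=config.qc.mendel_max,
        animal_call_rate_min=config.qc.animal_call_rate_min,
    )
    truth.genotypes = truth.genotypes.subset(snps=geno.snp_ids)
    truth.snp_map = truth.genotypes.snps
    refs = build_reference_sets(geno, ped, config, np.random.default_rng(seed + 1))

    def class_means(cells):
        out = {}
        for c in cells:
            if c.scenario_name.startswith("maf_class_"):
                out[int(c.scenario_name.rsplit("_", 1)[1])] = float(
                    c.animal_r.mean(skipna=True))
        return out

    def pooled_concordance(cells, scenario_prefix):
        tabs = [c.snp_table for c in cells if c.scenario_name.startswith(scenario_prefix)]
        if not tabs:
            return np.nan
        tab = pd.concat(tabs)
        conc = reliability_concordance(tab["reliability"], tab["allelic_r2"])
        return float(conc["correlation"].iloc[0])

    cells_small = run_reference(
        truth, geno, "small", refs.selected, config, generations=["G0"],
        scenario_names=["by_maf_class", "low_density"], seed=seed + 2,
    )
    cells_large = run_reference(
        truth, geno, "large", refs.all_sires_mgs, config, generations=["G0"],
        scenario_names=["by_maf_class", "low_density"], seed=seed + 2,
    )
    rand_class1 = []
    for i, rnd in enumerate(refs.random):
        cells_r = run_reference(
            truth, geno, f"rand{i}", rnd, config, generations=["G0"],
            scenario_names=["by_maf_class"], seed=seed + 2,
        )
        cm = class_means(cells_r)
        if 1 in cm:
            rand_class1.append(cm[1])

    def low_density_mean(cells):
        for c in cells:
            if c.scenario_name == "low_density":
                return float(c.animal_r.mean(skipna=True))
        return np.nan

    ldne = ld_ne_report(truth)
    return {
        "n_snps": geno.n_snps,
        "n_g0": len([a for a in ped.in_generation("G0") if a in set(geno.animals)]),
        "n_reference_all": len(refs.all_sires_mgs),
        "n_reference_small": len(refs.selected),
        "captured_all": refs.captured_all,
        "captured_selected": refs.captured_selected,
        "captured_random_mean": (float(np.mean(refs.captured_random))
                                 if refs.captured_random else np.nan),
        "r_by_class_small": class_means(cells_small),
        "r_by_class_large": class_means(cells_large),
        "r_low_density_small": low_density_mean(cells_small),
        "r_low_density_large": low_density_mean(cells_large),
        "r_class1_random": rand_class1,
        "concordance_by_class_small": pooled_concordance(cells_small, "maf_class"),
        "concordance_low_density_small": pooled_concordance(cells_small, "low_density"),
        "mean_reliability_small": float(pd.concat(
            [c.snp_table for c in cells_small if c.scenario_name.startswith("maf_class")]
        )["reliability"].mean(skipna=True)),
        "mean_allelic_r2_small": float(pd.concat(
            [c.snp_table for c in cells_small if c.scenario_name.startswith("maf_class")]
        )["allelic_r2"].mean(skipna=True)),
        "ld_concordance_g0_g2": float(ldne["concordance"]),
        "ne_estimate": float(ldne["ne"].ne),
    }


# ---------------------------------------------------------------------------
# full study
# ---------------------------------------------------------------------------

def run_study(config: StudyConfig, outdir) -> dict:
    """Run the complete study and write report tables under ``outdir``.

    Returns a manifest dict (also written as ``manifest.yaml``).  Stage
    seeds derive from the master seed through a seed sequence, so adding a
    scenario never perturbs another stage's randomness.
    """
    outdir = Path(outdir)
    tables = outdir / "tables"
    tables.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    ss = np.random.SeedSequence(config.seed)
    seed_sim, seed_ref, seed_phase = (int(s.generate_state(1)[0] % 2**31)
                                      for s in ss.spawn(3))

    sim = SimulationConfig(**{**asdict(config.simulation), "seed": seed_sim})
    log.info("simulating population (%d SNPs)", sim.n_snps)
    truth, observed = simulate_study(sim)
    ped = truth.pedigree

    log.info("quality control")
    geno, qc_report = qc_filter(
        observed, ped, maf_min=config.qc.maf_min,
        call_rate_min=config.qc.call_rate_min, mendel_max=config.qc.mendel_max,
        animal_call_rate_min=config.qc.animal_call_rate_min,
    )
    truth_qc = truth
    truth_qc.genotypes = truth.genotypes.subset(snps=geno.snp_ids)
    truth_qc.snp_map = truth_qc.genotypes.snps
    qc_report.to_csv(tables / "qc_removals.tsv", sep="\t", index=False)

    if not config.scenarios:
        log.warning("no scenarios configured: writing manifest only")
        manifest = {
            "version": __version__, "config": asdict(config),
            "warnings": ["no scenarios configured"], "tables": [],
        }
        (outdir / "manifest.yaml").write_text(
            yaml.safe_dump(manifest, sort_keys=False))
        return manifest

    log.info("reference selection")
    refs = build_reference_sets(geno, ped, config, np.random.default_rng(seed_ref))
    refs.selection_trace.to_csv(tables / "selection_trace.tsv", sep="\t", index=False)
    refs.top5.to_csv(tables / "top5_relationships.tsv", sep="\t", index=False)

    cells = []
    named_refs = [
        (f"ref_{config.reference_k}", refs.selected),
        (f"ref_{len(refs.all_sires_mgs)}", refs.all_sires_mgs),
    ]
    for i, rnd in enumerate(refs.random):
        named_refs.append((f"ref_{config.reference_k}rand_{i}", rnd))
    for name, ids in named_refs:
        log.info("imputation with reference %s (%d animals)", name, len(ids))
        scen = config.scenarios
        gens = config.validation_generations
        if name.startswith(f"ref_{config.reference_k}rand"):
            # random panels are evaluated on G0 only, per the study design
            gens = [g for g in gens if g == "G0"] or gens[:1]
        cells.extend(run_reference(
            truth_qc, geno, name, ids, config, generations=gens,
            scenario_names=scen, seed=seed_phase,
        ))

    log.info("writing report tables")
    if "by_maf_class" in config.scenarios:
        table_by_maf_class(cells).to_csv(
            tables / "r_corrected_by_maf_class.tsv", sep="\t", index=False)
    if "low_density" in config.scenarios:
        table_scenario_means(cells, "low_density").to_csv(
            tables / "r_corrected_low_density.tsv", sep="\t", index=False)
    if "maf_independent" in config.scenarios:
        table_maf_independent(cells).to_csv(
            tables / "r_corrected_maf_independent.tsv", sep="\t", index=False)
    table_concordance(cells).to_csv(
        tables / "reliability_concordance.tsv", sep="\t", index=False)
    table_reliability_vs_ar2(cells).to_csv(
        tables / "reliability_vs_allelic_r2.tsv", sep="\t", index=False)

    grp = stratify_by_ancestor(
        ped, [a for a in ped.in_generation("G0") if a in set(geno.animals)],
        refs.all_sires_mgs,
    )
    rows = []
    for c in cells:
        if c.generation != "G0" or not c.reference_name.startswith("ref_"):
            continue
        for a, v in c.animal_r.items():
            rows.append({"reference": c.reference_name, "scenario": c.scenario_name,
                         "group": grp.get(a, "NONE"), "r_corrected": v})
    anc = pd.DataFrame(rows)
    if len(anc):
        summarize(anc["r_corrected"], anc[["reference", "scenario", "group"]]) \
            .reset_index().to_csv(tables / "ancestor_groups.tsv", sep="\t", index=False)

    ldne = ld_ne_report(truth_qc)
    pd.DataFrame([{
        "ld_concordance_g0_g2": ldne["concordance"],
        "ne_estimate": ldne["ne"].ne, "ne_method": ldne["ne"].method,
        "n_pairs": ldne["ne"].n_pairs,
    }]).to_csv(tables / "ld_ne.tsv", sep="\t", index=False)

    manifest = {
        "version": __version__,
        "python": platform.python_version(),
        "config": asdict(config),
        "stage_seeds": {"simulation": seed_sim, "reference": seed_ref,
                        "phasing": seed_phase},
        "captured_diversity": {
            "all_sires_mgs": refs.captured_all,
            "selected": refs.captured_selected,
            "random_mean": (float(np.mean(refs.captured_random))
                            if refs.captured_random else None),
        },
        "n_snps_post_qc": len(geno.snp_ids),
        "n_animals_post_qc": len(geno.animals),
        "tables": sorted(p.name for p in tables.glob("*.tsv")),
    }
    (outdir / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
    return manifest
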