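"""End-to-end orchestration: simulate -> traits -> normalize -> gwas ->
enrich -> rsa -> rhythm, with a single global seed, per-stage TSV
outputs and a machine-readable run report (counts + SHA-256 digests).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import enrichment, gwas, io, normalize, rhythm, rnai, synthetic, traces

log = logging.getLogger("circaqtl")

STAGES = ("simulate", "traits", "normalize", "gwas", "enrich", "rsa", "rhythm")

_DEPENDS = {
    "traits": ["simulate"],
    "normalize": ["traits"],
    "gwas": ["normalize"],
    "enrich": ["gwas"],
}


@dataclass
class PipelineConfig:
    out_dir: str = "pipeline_out"
    seed: int = 0
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    #: default study design: a 159-line cohort, 2000 SNPs in 5-SNP LD
    #: blocks, sparse causal loci on the cellular traits, and mild
    #: passage/date confounding.
    simulation: dict = field(
        default_factory=lambda: {
            "n_samples": 159,
            "n_snps": 2000,
            "ld_block_size": 5,
            "causal_spec": [
                [100, "period", 0.8], [500, "period", -0.7],
                [900, "amplitude", 0.8], [1300, "phase", 0.7],
                [1700, "PER2", 0.8],
            ],
            "confounder_spec": {"passage_beta": 0.1, "n_dates": 4, "date_sd": 0.3},
        }
    )
    chronotype: dict = field(
        default_factory=lambda: {"population_size": 600, "n_larks": 11, "n_owls": 17,
                                 "noise_sd": 1.0}
    )
    gwas_trait: str = "period"
    thresholds: list = field(default_factory=lambda: list(enrichment.DEFAULT_THRESHOLDS))
    rnai: dict = field(
        default_factory=lambda: {"genome_size": 1000, "hairpins_per_gene": 4,
                                 "genelist_size": 30,
                                 "effect_spec": {"period": -2.0, "amplitude": -2.0}}
    )
    timecourses: dict = field(
        default_factory=lambda: {"n_series": 200, "frac_rhythmic": 0.3,
                                 "times": [0, 3, 6, 9, 12, 15, 18, 21],
                                 "amp_range": [1.0, 2.0], "noise_sd": 0.3, "fdr": 0.05}
    )

    _KNOWN = {"out_dir", "seed", "stages", "simulation", "chronotype",
              "gwas_trait", "thresholds", "rnai", "timecourses"}


def _sim_config(simulation: dict, seed: int) -> synthetic.SimulationConfig:
    kwargs = dict(simulation)
    for key, cls in (("confounder_spec", synthetic.ConfounderSpec),
                     ("replicate_spec", synthetic.ReplicateSpec),
                     ("trace_spec", synthetic.TraceSpec)):
        if key in kwargs and isinstance(kwargs[key], dict):
            kwargs[key] = cls(**kwargs[key])
    if "causal_spec" in kwargs:
        kwargs["causal_spec"] = [tuple(c) for c in kwargs["causal_spec"]]
    kwargs.pop("seed", None)
    return synthetic.SimulationConfig(seed=seed, **kwargs)


def validate_config(path) -> PipelineConfig:
    """Parse, default and range-check a YAML pipeline config; unknown keys
    are rejected with their key path."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> PipelineConfig:
    unknown = set(raw) - PipelineConfig._KNOWN
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = PipelineConfig(**raw)
    bad_stages = set(cfg.stages) - set(STAGES)
    if bad_stages:
        raise ValueError(f"stages: unknown stage names {sorted(bad_stages)}")
    _sim_config(cfg.simulation, cfg.seed)  # raises on bad values
    for name in ("population_size", "n_larks", "n_owls"):
        if cfg.chronotype.get(name, 1) < 0:
            raise ValueError(f"chronotype.{name} must be >= 0")
    return cfg


def config_to_dict(cfg: PipelineConfig) -> dict:
    sim = dict(cfg.simulation)
    for key in ("confounder_spec", "replicate_spec", "trace_spec"):
        if key in sim and not isinstance(sim[key], dict):
            sim[key] = vars(sim[key]).copy()
    if "causal_spec" in sim:
        sim["causal_spec"] = [list(c) for c in sim["causal_spec"]]
    return {
        "out_dir": cfg.out_dir, "seed": cfg.seed, "stages": dict(cfg.stages),
        "simulation": sim, "chronotype": dict(cfg.chronotype),
        "gwas_trait": cfg.gwas_trait, "thresholds": list(cfg.thresholds),
        "rnai": dict(cfg.rnai), "timecourses": dict(cfg.timecourses),
    }


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages in dependency order.

    Returns the run report (also written as ``report.json``): per-stage
    output digests, headline counts, version and elapsed wall time.
    Rerunning with the same config and seed reproduces identical digests.
    """
    from . import __version__

    enabled = [s for s in STAGES if config.stages.get(s, True)]
    for stage in enabled:
        for dep in _DEPENDS.get(stage, []):
            if dep not in enabled:
                raise ValueError(f"stage {stage!r} requires {dep!r} to be enabled")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    report: dict = {"stages": {}, "counts": {}, "version": __version__, "seed": config.seed}

    sim_cfg = _sim_config(config.simulation, config.seed)
    genotypes = phen = truth = None
    trait_table = None
    phen_final = None
    gwas_res = None

    if "simulate" in enabled:
        log.info("simulate: %d samples x %d SNPs", sim_cfg.n_samples, sim_cfg.n_snps)
        genotypes = synthetic.simulate_genotypes(sim_cfg)
        phen, truth = synthetic.simulate_phenotypes(genotypes, sim_cfg)
        trace_list = synthetic.simulate_traces(phen, sim_cfg)
        io.write_vcf(genotypes, out / "genotypes.vcf")
        io.write_dosage_tsv(genotypes, out / "genotypes_dosage.tsv")
        io.write_tsv(phen, out / "phenotypes.tsv")
        io.write_traces_tsv(trace_list, out / "traces.tsv")
        truth_frame = truth.latent.reset_index()
        io.write_tsv(truth_frame, out / "truth_latent.tsv")
        io.write_tsv(genotypes.variants, out / "variants.tsv")
        io.write_tsv(
            pd.DataFrame(
                sorted(truth.chronotype_weights.items()), columns=["snp_index", "weight"]
            ),
            out / "truth_chronotype_weights.tsv",
        )
        report["counts"]["samples"] = genotypes.n_samples
        report["counts"]["variants_simulated"] = genotypes.n_snps
        report["stages"]["simulate"] = {
            f.name: _digest(f)
            for f in (out / n for n in ("genotypes.vcf", "phenotypes.tsv", "traces.tsv"))
        }

    if "traits" in enabled:
        trace_list = io.read_traces_tsv(out / "traces.tsv")
        log.info("traits: fitting %d traces", len(trace_list))
        fits = [
            traces.analyze_trace(tr)
            for tr in trace_list
        ]
        trait_table = traces.extract_traits(fits)
        trait_table.reset_index().to_csv(out / "circadian_traits.tsv", sep="\t", index=False)
        report["counts"]["lines_with_traits"] = int(trait_table["n_converged"].gt(0).sum())
        report["stages"]["traits"] = {"circadian_traits.tsv": _digest(out / "circadian_traits.tsv")}

    if "normalize" in enabled:
        phen = io.read_tsv(out / "phenotypes.tsv")
        log.info("normalize: %d phenotype rows", len(phen))
        phen_final, res = normalize.normalize_phenotypes(phen)
        io.write_tsv(phen_final, out / "phenotypes_normalized.tsv")
        io.write_tsv(res.report, out / "normalization_report.tsv")
        report["counts"]["normalized_rows"] = len(phen_final)
        report["stages"]["normalize"] = {
            "phenotypes_normalized.tsv": _digest(out / "phenotypes_normalized.tsv")
        }

    if "gwas" in enabled:
        if genotypes is None:
            variants = io.read_tsv(out / "variants.tsv")
            genotypes = io.read_dosage_tsv(out / "genotypes_dosage.tsv", variants=variants)
        phen_final = phen_final if phen_final is not None else io.read_tsv(
            out / "phenotypes_normalized.tsv"
        )
        filtered, qc_report = gwas.qc_filter_variants(genotypes)
        io.write_tsv(qc_report, out / "variant_qc.tsv")
        trait = config.gwas_trait
        pheno = phen_final[phen_final["trait"] == trait].set_index("line_id")["value"]
        log.info("gwas: %d variants after QC, trait %s", filtered.n_snps, trait)
        gwas_res = gwas.spearman_gwas(filtered, pheno, trait=trait)
        io.write_tsv(gwas_res, out / "gwas_results.tsv")
        summary = gwas.gwas_summary(gwas_res)
        io.write_tsv(summary["manhattan"], out / "gwas_manhattan.tsv")
        io.write_tsv(summary["qq"], out / "gwas_qq.tsv")
        report["counts"]["variants_retained"] = filtered.n_snps
        report["counts"]["gwas_lambda"] = round(summary["lambda"], 4)
        report["stages"]["gwas"] = {"gwas_results.tsv": _digest(out / "gwas_results.tsv")}

    if "enrich" in enabled:
        ct = config.chronotype
        pop_cfg = _sim_config(
            {**config.simulation, "n_samples": ct["population_size"]}, sim_cfg.seed + 101
        )
        population = synthetic.simulate_genotypes(pop_cfg)
        if truth is None:
            weights_file = out / "truth_chronotype_weights.tsv"
            weights = {}
            if weights_file.exists():
                wf = io.read_tsv(weights_file)
                weights = dict(zip(wf["snp_index"].astype(int), wf["weight"]))
            truth = synthetic.CohortTruth({}, pd.DataFrame(), weights)
        if gwas_res is None:
            gwas_res = io.read_tsv(out / "gwas_results.tsv")
        cohort = synthetic.simulate_chronotype_cohorts(
            population, truth, ct["n_larks"], ct["n_owls"],
            seed=sim_cfg.seed + 202, noise_sd=ct.get("noise_sd", 1.0),
        )
        profile = enrichment.enrichment_profile(gwas_res, cohort, config.thresholds)
        io.write_tsv(profile.per_snp, out / "enrichment_per_snp.tsv")
        io.write_tsv(profile.summary, out / "enrichment_summary.tsv")
        io.write_tsv(profile.density, out / "enrichment_density.tsv")
        report["counts"]["snps_below_thresholds"] = {
            str(r["threshold"]): int(r["n_snps"]) for _, r in profile.summary.iterrows()
        }
        report["stages"]["enrich"] = {
            "enrichment_summary.tsv": _digest(out / "enrichment_summary.tsv")
        }

    if "rsa" in enabled:
        rn = config.rnai
        genome = rn["genome_size"]
        genelist = [f"GENE{g:05d}" for g in range(rn["genelist_size"])]
        screen = synthetic.simulate_rnai_screen(
            genelist, genome, rn["hairpins_per_gene"], rn.get("effect_spec"),
            seed=config.seed,
        )
        log.info("rsa: %d hairpins", len(screen))
        scores = rnai.rsa_gene_scores(rnai.zscore_hairpins(screen))
        dists = rnai.compare_genelist_distributions(scores, genelist, seed=config.seed)
        io.write_tsv(scores, out / "rsa_gene_scores.tsv")
        io.write_tsv(dists.tests, out / "rsa_tests.tsv")
        io.write_tsv(dists.combined_cdf, out / "rsa_combined_cdf.tsv")
        report["counts"]["rsa_genes"] = int(scores["gene_id"].nunique())
        report["stages"]["rsa"] = {"rsa_gene_scores.tsv": _digest(out / "rsa_gene_scores.tsv")}

    if "rhythm" in enabled:
        tc = config.timecourses
        matrix, labels = synthetic.simulate_timecourses(
            tc["n_series"], tc["frac_rhythmic"], tc["times"],
            tuple(tc["amp_range"]), tc["noise_sd"], seed=config.seed,
        )
        fits = rhythm.detect_rhythmic(matrix, fdr=tc.get("fdr", 0.05))
        fits["truth_rhythmic"] = labels
        io.write_tsv(fits, out / "rhythmicity.tsv")
        report["counts"]["rhythmic_series"] = int(fits["rhythmic"].fillna(False).sum())
        report["stages"]["rhythm"] = {"rhythmicity.tsv": _digest(out / "rhythmicity.tsv")}

    report["elapsed_s"] = round(time.time() - t0, 2)
    (out / "report.json").write_text(json.dumps(report, indent=2) + "\n")
    return report
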