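"""Extreme-chronotype allele-frequency enrichment.

If loci that shift the cellular clock also shift behavioral chronotype,
then SNPs passing ever-stricter GWAS thresholds should show growing
allele-frequency differences between behavioral extremes ("larks" vs
"owls").  This example plants that situation and computes the profile,
including the tag-SNP (one per LD block) variant.
"""

import pandas as pd

from circaqtl import (
    ReplicateSpec,
    SimulationConfig,
    enrichment_profile,
    simulate_chronotype_cohorts,
    simulate_genotypes,
    simulate_phenotypes,
    spearman_gwas,
    tag_snps,
)
from circaqtl.synthetic import CohortTruth

causal = [(100, "period", 1.3), (300, "period", 1.3), (500, "period", 1.3)]
config = SimulationConfig(
    n_samples=150, n_snps=1000, ld_block_size=5, maf_range=(0.1, 0.5),
    causal_spec=causal, replicate_spec=ReplicateSpec(1, 1, 1.0, 0.0), seed=5,
)
genotypes = simulate_genotypes(config)
phenotypes, truth = simulate_phenotypes(genotypes, config)
period = phenotypes[phenotypes["trait"] == "period"].set_index("line_id")["value"]
results = spearman_gwas(genotypes, period, trait="period")

# A fresh behavioral population on the same panel; chronotype score is
# driven by the same causal loci (shared genetics), and the 11 earliest /
# 17 latest individuals form the extreme cohorts.
population = simulate_genotypes(
    SimulationConfig(n_samples=600, n_snps=1000, ld_block_size=5,
                     maf_range=(0.1, 0.5), seed=55)
)
cohort = simulate_chronotype_cohorts(
    population, CohortTruth({}, pd.DataFrame(), truth.chronotype_weights),
    n_larks=11, n_owls=17, seed=6,
)

profile = enrichment_profile(results, cohort)
cols = ["threshold", "n_snps", "mean", "median"]
print("|delta allele frequency| by GWAS p-value threshold:")
print(profile.summary[cols].to_string(index=False))
print("\nHigh mean |delta f| at strict thresholds indicates the cellular "
      "associations carry over to behavior (at this small panel size all "
      "suggestive SNPs come from the causal LD blocks, so the profile is "
      "uniformly elevated; a genome-scale panel dilutes the relaxed "
      "thresholds with background SNPs).")

strict = profile.per_snp.loc[profile.per_snp["threshold"] == 1e-5, "snp_id"]
if len(strict):
    tags = tag_snps(strict, genotypes, gwas_results=results, r2_threshold=0.6)
    print(f"\ntag SNPs at p<1e-5 (r^2 >= 0.6): {int(tags['is_tag'].sum())} of "
          f"{len(tags)} — one representative per LD block, so large blocks "
          "do not dominate the profile")
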