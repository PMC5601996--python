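"""RSA statistics for a genome-wide RNAi screen.

Simulates a hairpin screen in which 30 genelist genes shorten the
circadian period by ~2 screen SDs, concatenates each gene's hairpins
into directional RSA p-values, and compares the genelist score
distribution against the whole-screen background with KS and
Kruskal-Wallis tests.
"""

from circaqtl import (
    compare_genelist_distributions,
    rsa_gene_scores,
    rsa_score,
    simulate_rnai_screen,
    zscore_hairpins,
)

# The RSA primitive: a gene with hairpins ranked 1 and 2 out of 10
print(f"rsa_score(ranks=[1,2], N=10) = {rsa_score([1, 2], 10):.4f} "
      "(probability both hairpins land in the top 2 by chance = 1/45)")

genelist = [f"GENE{i:05d}" for i in range(30)]
screen = simulate_rnai_screen(
    genelist, genome_size=2000, hairpins_per_gene=4,
    effect_spec={"period": -2.0}, seed=11,
)
scores = rsa_gene_scores(zscore_hairpins(screen))
out = compare_genelist_distributions(scores, genelist, seed=11)

print("\ngenelist vs transcriptome background:")
print(out.tests[["trait", "direction", "ks_p", "kruskal_p"]].round(4).to_string(index=False))
print("\nThe period distributions differ strongly from background in both "
      "directions: genelist genes crowd the top of the decrease ranking "
      "(strong RSA scores) and the bottom of the increase ranking (uniformly "
      "weak scores).  Amplitude, which received no planted effect, stays at "
      "background levels.")
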