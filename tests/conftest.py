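import numpy as np
import pandas as pd
import pytest

from circaqtl.synthetic import (
    ConfounderSpec,
    ReplicateSpec,
    SimulationConfig,
    simulate_genotypes,
    simulate_phenotypes,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A small cohort with one planted period locus and confounders."""
    config = SimulationConfig(
        n_samples=80,
        n_snps=60,
        maf_range=(0.2, 0.4),
        ld_block_size=3,
        causal_spec=[(9, "period", 1.0)],
        confounder_spec=ConfounderSpec(passage_beta=0.3, n_dates=3, date_sd=0.5),
        replicate_spec=ReplicateSpec(2, 2),
        seed=11,
    )
    genotypes = simulate_genotypes(config)
    phenotypes, truth = simulate_phenotypes(genotypes, config)
    return config, genotypes, phenotypes, truth


def spearman_permutation_p(g, y):
    """Exact two-sided permutation p-value for the Spearman correlation,
    enumerating all n! orderings of the phenotype (n <= 8)."""
    from itertools import permutations

    from scipy import stats

    rho_obs = stats.spearmanr(g, y).statistic
    count = total = 0
    for perm in permutations(y):
        rho = stats.spearmanr(g, perm).statistic
        total += 1
        if abs(rho) >= abs(rho_obs) - 1e-12:
            count += 1
    return rho_obs, count / total


def rsa_enumeration_oracle(ranks, n_total):
    """RSA p-value by brute force: for each j, count the C(N, k)
    placements of k hairpins with at least j of them inside the top r_j
    positions, divided by C(N, k); return the minimum over j."""
    from itertools import combinations

    ranks = sorted(ranks)
    k = len(ranks)
    best = 1.0
    placements = list(combinations(range(1, n_total + 1), k))
    for j, r in enumerate(ranks, start=1):
        hits = sum(1 for pl in placements if sum(x <= r for x in pl) >= j)
        best = min(best, hits / len(placements))
    return best


def hwe_enumeration_oracle(n_AA, n_Aa, n_aa):
    """Exact conditional HWE p by direct evaluation of the heterozygote
    probability mass function (log factorial form)."""
    from math import exp, lgamma, log

    n = n_AA + n_Aa + n_aa
    n_A = 2 * n_AA + n_Aa
    n_a = 2 * n_aa + n_Aa
    if n_A == 0 or n_a == 0:
        return 1.0
    rare = min(n_A, n_a)

    def logprob(het):
        hom_rare = (rare - het) // 2
        hom_common = n - het - hom_rare
        return (
            lgamma(n + 1) - lgamma(het + 1) - lgamma(hom_rare + 1) - lgamma(hom_common + 1)
            + het * log(2) + lgamma(n_A + 1) + lgamma(n_a + 1) - lgamma(2 * n + 1)
        )

    hets = range(rare % 2, rare + 1, 2)
    probs = {h: exp(logprob(h)) for h in hets}
    total = sum(probs.values())
    p_obs = probs[n_Aa] / total
    return sum(p for p in probs.values() if p / total <= p_obs * (1 + 1e-12)) / total
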