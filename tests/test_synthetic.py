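"""Generator properties: HWE, LD, effect injection, determinism."""

import numpy as np
import pandas as pd
import pytest

from circaqtl.gwas import hwe_exact_test
from circaqtl.synthetic import (
    BioluminescenceTrace,
    ConfounderSpec,
    ReplicateSpec,
    SimulationConfig,
    damped_oscillation,
    simulate_chronotype_cohorts,
    simulate_genotypes,
    simulate_phenotypes,
    simulate_rnai_screen,
    simulate_timecourses,
    simulate_traces,
)


class TestGenotypes:
    def test_dosage_domain(self):
        config = SimulationConfig(n_samples=100, n_snps=50, maf_range=(0.2, 0.3), seed=1)
        g = simulate_genotypes(config)
        assert g.dosages.shape == (100, 50)
        assert set(np.unique(g.dosages)) <= {0.0, 1.0, 2.0}

    def test_empty_panel(self):
        g = simulate_genotypes(SimulationConfig(n_samples=10, n_snps=0, seed=1))
        assert g.dosages.shape == (10, 0)
        assert len(g.variants) == 0

    def test_sample_maf_concentrates(self):
        # binomial sampling: Var(f_hat) = f(1-f)/2n, so +-0.05 covers
        # many SDs at n=2000 even after the LD flip shift
        config = SimulationConfig(
            n_samples=2000, n_snps=200, maf_range=(0.3, 0.3), ld_block_size=1, seed=7
        )
        g = simulate_genotypes(config)
        freq = g.dosages.mean(axis=0) / 2
        maf = np.minimum(freq, 1 - freq)
        assert np.mean(np.abs(maf - 0.3) <= 0.05) >= 0.95

    def test_invalid_maf_range_rejected(self):
        with pytest.raises(ValueError, match="maf_range"):
            SimulationConfig(maf_range=(0.6, 0.7))
        with pytest.raises(ValueError, match="maf_range"):
            SimulationConfig(maf_range=(0.0, 0.3))

    def test_determinism(self):
        config = SimulationConfig(n_samples=50, n_snps=30, seed=5, missing_rate=0.02)
        a = simulate_genotypes(config)
        b = simulate_genotypes(config)
        np.testing.assert_array_equal(a.dosages, b.dosages)
        pd.testing.assert_frame_equal(a.variants, b.variants)

    def test_missing_rate(self):
        config = SimulationConfig(n_samples=500, n_snps=50, missing_rate=0.1, seed=2)
        g = simulate_genotypes(config)
        frac = np.isnan(g.dosages).mean()
        assert 0.07 < frac < 0.13

    def test_hwe_holds_across_seeds(self):
        # haplotype-level sampling means genotypes are Binomial(2, f):
        # the exact test should essentially never reject at 1e-6
        n_pass = n_total = 0
        for seed in range(5):
            g = simulate_genotypes(
                SimulationConfig(n_samples=300, n_snps=100, ld_block_size=1, seed=seed)
            )
            for j in range(g.n_snps):
                col = g.dosages[:, j].astype(int)
                p = hwe_exact_test(
                    int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum())
                )
                n_total += 1
                n_pass += p > 1e-6
        assert n_pass / n_total >= 0.99

    def test_ld_blocks_correlated(self):
        config = SimulationConfig(
            n_samples=800, n_snps=20, ld_block_size=5, ld_flip_rate=0.02, seed=3
        )
        g = simulate_genotypes(config)
        within = np.corrcoef(g.dosages[:, 0], g.dosages[:, 1])[0, 1] ** 2
        across = np.corrcoef(g.dosages[:, 0], g.dosages[:, 7])[0, 1] ** 2
        # two flip-rate-0.02 copies of one ancestor: r^2 well above 0.5,
        # while SNPs of different blocks are independent
        assert within > 0.6
        assert across < 0.1


class TestPhenotypes:
    def test_null_model_variance(self):
        config = SimulationConfig(
            n_samples=2000, n_snps=5, seed=4,
            replicate_spec=ReplicateSpec(1, 1, bio_noise_sd=1.0, tech_noise_sd=0.0),
        )
        g = simulate_genotypes(config)
        table, _ = simulate_phenotypes(g, config)
        sub = table[table["trait"] == "phase"]
        from circaqtl.synthetic import TRAIT_SCALES
        sd_unit = TRAIT_SCALES["phase"][1]
        assert sub["value"].var() == pytest.approx(sd_unit**2, rel=0.15)

    def test_additive_genotype_ordering(self):
        config = SimulationConfig(
            n_samples=500, n_snps=10, causal_spec=[(2, "period", 1.0)], seed=6,
            replicate_spec=ReplicateSpec(1, 1, 1.0, 0.0),
        )
        g = simulate_genotypes(config)
        table, truth = simulate_phenotypes(g, config)
        sub = table[table["trait"] == "period"].set_index("line_id")["value"]
        dosage = pd.Series(g.dosages[:, 2], index=g.samples)
        means = sub.groupby(dosage).mean()
        assert means.loc[0] < means.loc[1] < means.loc[2]

    def test_passage_slope_recovered(self):
        config = SimulationConfig(
            n_samples=300, n_snps=5, seed=8,
            confounder_spec=ConfounderSpec(passage_beta=0.5, n_dates=1, date_sd=0.0),
            replicate_spec=ReplicateSpec(2, 1, 1.0, 0.0),
        )
        g = simulate_genotypes(config)
        table, _ = simulate_phenotypes(g, config)
        sub = table[table["trait"] == "phase"]
        from circaqtl.synthetic import TRAIT_SCALES
        sd_unit = TRAIT_SCALES["phase"][1]
        slope = np.polyfit(sub["passage"], sub["value"] / sd_unit, 1)[0]
        assert slope == pytest.approx(0.5, abs=0.1)

    def test_causal_index_out_of_range(self):
        with pytest.raises(ValueError, match="out of range"):
            SimulationConfig(n_snps=10, causal_spec=[(10, "period", 1.0)])

    def test_variance_conservation(self):
        # Var(trait) ~ sum beta^2 2f(1-f) + confounder + noise, in SD units
        beta, passage_beta, date_sd = 0.8, 0.2, 0.4
        config = SimulationConfig(
            n_samples=5000, n_snps=4, ld_block_size=1, maf_range=(0.3, 0.3), seed=9,
            causal_spec=[(0, "period", beta)],
            confounder_spec=ConfounderSpec(passage_beta=passage_beta, n_dates=40,
                                           date_sd=date_sd),
            replicate_spec=ReplicateSpec(1, 1, bio_noise_sd=1.0, tech_noise_sd=0.5),
        )
        g = simulate_genotypes(config)
        table, _ = simulate_phenotypes(g, config)
        sub = table[table["trait"] == "period"]
        from circaqtl.synthetic import TRAIT_SCALES
        sd_unit = TRAIT_SCALES["period"][1]
        observed = sub["value"].var() / sd_unit**2
        f = g.dosages[:, 0].mean() / 2
        passage_var = np.var(np.arange(3, 13))  # discrete uniform passage draw
        expected = beta**2 * 2 * f * (1 - f) + passage_beta**2 * passage_var \
            + date_sd**2 + 1.0 + 0.25
        assert observed == pytest.approx(expected, rel=0.10)


class TestTraces:
    def test_pure_cosine_closed_form(self):
        t = np.arange(0, 96, 0.5)
        y = damped_oscillation(t, 24.0, 0.0, 1.0)
        np.testing.assert_allclose(y, np.cos(2 * np.pi * t / 24), atol=1e-12)

    def test_zero_amplitude_flat_baseline(self):
        t = np.arange(0, 96, 1.0)
        y = damped_oscillation(t, 24.0, 0.0, 0.0, baseline_mu=100.0, baseline_tau_h=48.0)
        np.testing.assert_allclose(y, 100.0 * np.exp(-t / 48.0))

    def test_non_positive_period_rejected(self):
        with pytest.raises(ValueError, match="period"):
            damped_oscillation(np.arange(10.0), -24.0, 0.0, 1.0)

    def test_trace_count_and_determinism(self, small_cohort):
        config, _, phenotypes, _ = small_cohort
        a = simulate_traces(phenotypes, config)
        b = simulate_traces(phenotypes, config)
        assert len(a) == 80 * 2 * 2
        np.testing.assert_array_equal(a[0].signal, b[0].signal)


class TestChronotypeCohorts:
    def _population(self, seed=1, weights=None, n=400):
        config = SimulationConfig(n_samples=n, n_snps=30, ld_block_size=1,
                                  maf_range=(0.3, 0.3), seed=seed)
        g = simulate_genotypes(config)
        from circaqtl.synthetic import CohortTruth
        truth = CohortTruth({}, pd.DataFrame(), weights or {})
        return g, truth

    def test_planted_direction(self):
        g, truth = self._population(weights={4: 3.0})
        cohort = simulate_chronotype_cohorts(g, truth, 30, 30, seed=2, noise_sd=0.5)
        f_lark = cohort.larks.dosages[:, 4].mean() / 2
        f_owl = cohort.owls.dosages[:, 4].mean() / 2
        assert f_owl - f_lark > 0.2

    def test_null_weights_small_delta(self):
        g, truth = self._population(weights={})
        cohort = simulate_chronotype_cohorts(g, truth, 50, 50, seed=3)
        delta = np.abs(
            cohort.larks.dosages.mean(axis=0) - cohort.owls.dosages.mean(axis=0)
        ) / 2
        # binomial null: SD of delta f ~ sqrt(2 * f(1-f) / (2*50)) ~ 0.065
        assert delta.mean() < 0.12

    def test_empty_cohort_rejected(self):
        g, truth = self._population()
        with pytest.raises(ValueError, match="n_larks"):
            simulate_chronotype_cohorts(g, truth, 0, 10, seed=1)

    def test_oversized_request_rejected(self):
        g, truth = self._population(n=20)
        with pytest.raises(ValueError, match="population"):
            simulate_chronotype_cohorts(g, truth, 15, 15, seed=1)


class TestRnaiScreen:
    def test_shapes_and_columns(self):
        t = simulate_rnai_screen(["GENE00000"], 50, 4, {"period": -3.0}, seed=1)
        assert len(t) == 50 * 4 * 2
        assert set(t["trait"]) == {"period", "amplitude"}

    def test_planted_shift_visible(self):
        genelist = [f"GENE{i:05d}" for i in range(10)]
        t = simulate_rnai_screen(genelist, 300, 4, {"period": -3.0}, seed=2)
        sub = t[t["trait"] == "period"]
        in_list = sub["gene_id"].isin(genelist)
        assert sub.loc[in_list, "value"].mean() < sub.loc[~in_list, "value"].mean() - 2
        amp = t[t["trait"] == "amplitude"]
        assert abs(amp.loc[amp["gene_id"].isin(genelist), "value"].mean()) < 0.5

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError, match="hairpins_per_gene"):
            simulate_rnai_screen(["g"], 10, 0, None, seed=1)
        with pytest.raises(ValueError, match="genome_size"):
            simulate_rnai_screen([f"g{i}" for i in range(20)], 10, 2, None, seed=1)


class TestTimecourses:
    def test_exact_sinusoid_rows(self):
        times = [0, 4, 8, 12, 16, 20]
        m, labels = simulate_timecourses(5, 1.0, times, (2.0, 2.0), 0.0, seed=4)
        assert labels.all()
        t = np.asarray(times, dtype=float)
        for _, row in m.iterrows():
            y = row.to_numpy()
            X = np.column_stack([np.ones(6), np.sin(2 * np.pi * t / 24),
                                 np.cos(2 * np.pi * t / 24)])
            coef, *_ = np.linalg.lstsq(X, y, rcond=None)
            assert np.hypot(coef[1], coef[2]) == pytest.approx(2.0, abs=1e-9)
            np.testing.assert_allclose(X @ coef, y, atol=1e-9)

    def test_flat_rows_when_none_rhythmic(self):
        m, labels = simulate_timecourses(10, 0.0, [0, 6, 12, 18], noise_sd=0.0, seed=5)
        assert not labels.any()
        assert (m.std(axis=1) < 1e-12).all()

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="time grid"):
            simulate_timecourses(5, 0.5, [], seed=1)
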