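"""Variant QC, Spearman association, gene assignment, overlap testing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from circaqtl.gwas import (
    assign_genes,
    gwas_summary,
    hwe_exact_test,
    qc_filter_variants,
    read_bed6,
    spearman_gwas,
    trait_overlap_test,
)
from circaqtl.synthetic import GenotypeMatrix

from conftest import hwe_enumeration_oracle, spearman_permutation_p


def make_matrix(dosages, info=None, pos=None):
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    variants = pd.DataFrame(
        {
            "chrom": ["1"] * m,
            "pos": pos if pos is not None else np.arange(1, m + 1) * 100,
            "snp_id": [f"snp{j}" for j in range(m)],
            "ref": ["A"] * m, "alt": ["G"] * m,
            "info_score": info if info is not None else np.ones(m),
        }
    )
    return GenotypeMatrix([f"S{i}" for i in range(n)], variants, dosages)


class TestHweExactTest:
    def test_monomorphic_is_one(self):
        assert hwe_exact_test(50, 0, 0) == 1.0
        assert hwe_exact_test(0, 0, 50) == 1.0

    @pytest.mark.parametrize(
        "counts",
        [(57, 14, 4), (21, 27, 52), (10, 5, 2), (3, 1, 1), (100, 50, 10), (0, 3, 5)],
    )
    def test_matches_enumeration_oracle(self, counts):
        assert hwe_exact_test(*counts) == pytest.approx(
            hwe_enumeration_oracle(*counts), rel=1e-9
        )

    def test_extreme_heterozygote_excess_filtered(self):
        assert hwe_exact_test(0, 200, 0) < 1e-6

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_test(0, 0, 0)

    @given(st.integers(0, 40), st.integers(0, 40), st.integers(0, 40))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_valid_probability_everywhere(self, a, b, c):
        if a + b + c == 0:
            return
        p = hwe_exact_test(a, b, c)
        assert 0.0 < p <= 1.0
        assert p == pytest.approx(hwe_enumeration_oracle(a, b, c), rel=1e-9)


class TestQcFilter:
    def test_clean_variant_retained(self):
        g = make_matrix(np.array([[0, 1], [1, 1], [2, 1], [1, 0], [0, 2], [2, 0]]))
        filtered, report = qc_filter_variants(g, callrate_min=0.9)
        assert report["retained"].iloc[0]

    def test_low_maf_removed_with_reason(self):
        dos = np.zeros((100, 1))
        dos[0, 0] = 1  # MAF 0.005
        _, report = qc_filter_variants(make_matrix(dos))
        assert not report["retained"].iloc[0]
        assert report["reason"].iloc[0] == "MAF"

    def test_toy_panel_matches_hand_evaluation(self):
        rng = np.random.default_rng(0)
        n = 200
        good = rng.binomial(2, 0.3, n).astype(float)
        low_maf = np.zeros(n); low_maf[:4] = 1          # maf 0.01
        het_excess = np.ones(n)                          # all heterozygous
        low_call = rng.binomial(2, 0.3, n).astype(float)
        low_call[: n // 2] = np.nan                      # call rate 0.5
        low_info = rng.binomial(2, 0.4, n).astype(float)
        dos = np.column_stack([good, low_maf, het_excess, low_call, low_info])
        g = make_matrix(dos, info=[1.0, 1.0, 1.0, 1.0, 0.2])
        filtered, report = qc_filter_variants(g)
        assert list(report["retained"]) == [True, False, False, False, False]
        assert list(report.loc[~report["retained"], "reason"]) == [
            "MAF", "HWE", "call_rate", "info"
        ]
        assert filtered.n_snps == 1

    def test_retained_set_is_criterion_order_independent(self):
        rng = np.random.default_rng(1)
        dos = rng.binomial(2, rng.uniform(0.02, 0.5, 30), size=(150, 30)).astype(float)
        g = make_matrix(dos, info=rng.uniform(0.2, 1.0, 30))
        _, report = qc_filter_variants(g)
        masks = {
            "MAF": report["maf"] >= 0.05,
            "HWE": report["hwe_p"] >= 1e-6,
            "call_rate": report["call_rate"] >= 0.975,
            "info": report["info_score"] >= 0.4,
        }
        expected = np.logical_and.reduce(list(masks.values()))
        np.testing.assert_array_equal(report["retained"].to_numpy(), expected)


class TestSpearman:
    def test_perfect_monotone(self):
        # phenotype equal to the dosage itself (matching tie structure)
        dos = np.array([[0, 0, 1, 1, 2, 2]]).T.repeat(2, axis=1).astype(float)
        g = make_matrix(dos)
        y = pd.Series([0, 0, 1, 1, 2, 2], index=g.samples, dtype=float)
        res = spearman_gwas(g, y, min_n=5)
        assert res["rho"].iloc[0] == pytest.approx(1.0)
        assert res["p"].iloc[0] < 1e-3

    def test_antitone(self):
        g = make_matrix(np.array([[0, 0, 1, 1, 2, 2]], dtype=float).T)
        y = pd.Series([2, 2, 1, 1, 0, 0], index=g.samples, dtype=float)
        res = spearman_gwas(g, y, min_n=5)
        assert res["rho"].iloc[0] == pytest.approx(-1.0)

    def test_example_matches_permutation_oracle_rho(self):
        gvec = [0, 0, 1, 1, 2, 2]
        yvec = [1.2, 0.8, 1.5, 2.0, 2.6, 2.4]
        g = make_matrix(np.array([gvec], dtype=float).T)
        res = spearman_gwas(g, pd.Series(yvec, index=g.samples), min_n=5)
        rho_oracle, p_exact = spearman_permutation_p(gvec, yvec)
        assert res["rho"].iloc[0] == pytest.approx(rho_oracle, abs=1e-12)
        # the t approximation must agree with the exact permutation null
        # to within its known small-n error
        assert res["p"].iloc[0] == pytest.approx(p_exact, abs=0.05)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(2)
        dos = rng.binomial(2, 0.4, size=(40, 3)).astype(float)
        g = make_matrix(dos)
        y = pd.Series(rng.normal(size=40), index=g.samples)
        base = spearman_gwas(g, y)
        transformed = spearman_gwas(g, np.exp(y) + 5)
        np.testing.assert_allclose(base["rho"], transformed["rho"], atol=1e-12)

    def test_missing_dosages_pairwise_complete(self):
        dos = np.array([[0, 1, 2, np.nan, 1, 0, 2, 1, 0, 2, 1, 0]], dtype=float).T
        g = make_matrix(dos)
        y = pd.Series(np.arange(12, dtype=float), index=g.samples)
        res = spearman_gwas(g, y, min_n=5)
        assert res["n"].iloc[0] == 11

    def test_monomorphic_is_na_with_reason(self):
        g = make_matrix(np.ones((12, 1)))
        y = pd.Series(np.arange(12, dtype=float), index=g.samples)
        res = spearman_gwas(g, y)
        assert np.isnan(res["rho"].iloc[0])
        assert res["reason"].iloc[0] == "monomorphic"

    def test_sample_mismatch_rejected(self):
        g = make_matrix(np.zeros((4, 1)))
        with pytest.raises(ValueError, match="sample"):
            spearman_gwas(g, pd.Series([1.0], index=["X"]))


class TestGeneAssignment:
    def write_bed(self, tmp_path, lines):
        path = tmp_path / "genes.bed"
        path.write_text("\n".join(lines) + "\n")
        return path

    def test_snp_at_tss_distance_zero(self, tmp_path):
        bed = read_bed6(self.write_bed(tmp_path, ["1\t999\t2000\tGENE_A\t0\t+"]))
        snps = pd.DataFrame({"chrom": ["1"], "pos": [1000], "snp_id": ["rs1"]})
        out = assign_genes(snps, bed)
        assert len(out) == 1 and out["distance_bp"].iloc[0] == 0

    def test_window_boundary_inclusive(self, tmp_path):
        bed = read_bed6(self.write_bed(tmp_path, ["1\t0\t500\tGENE_A\t0\t+"]))
        at_limit = pd.DataFrame({"chrom": ["1"], "pos": [100_001], "snp_id": ["rs1"]})
        beyond = pd.DataFrame({"chrom": ["1"], "pos": [100_002], "snp_id": ["rs2"]})
        assert len(assign_genes(at_limit, bed)) == 1
        assert len(assign_genes(beyond, bed)) == 0

    def test_minus_strand_tss_is_end(self, tmp_path):
        bed = read_bed6(self.write_bed(tmp_path, ["1\t100\t500\tGENE_A\t0\t-"]))
        assert bed["tss_1based"].iloc[0] == 500

    def test_matches_brute_force_all_pairs(self, tmp_path):
        bed = read_bed6(self.write_bed(tmp_path, [
            "1\t0\t1000\tGENE_A\t0\t+",
            "1\t150000\t160000\tGENE_B\t0\t-",
            "2\t100\t200\tGENE_C\t0\t+",
        ]))
        snps = pd.DataFrame({"chrom": ["1", "1"], "pos": [50_000, 120_000],
                             "snp_id": ["rs1", "rs2"]})
        out = assign_genes(snps, bed, window_bp=100_000)
        expected = set()
        for _, s in snps.iterrows():
            for _, g in bed.iterrows():
                if s["chrom"] == g["chrom"] and abs(s["pos"] - g["tss_1based"]) <= 100_000:
                    expected.add((s["snp_id"], g["gene_id"]))
        assert set(zip(out["snp_id"], out["gene_id"])) == expected

    def test_malformed_bed_reports_line_number(self, tmp_path):
        path = self.write_bed(tmp_path, ["1\t0\t500\tGENE_A\t0\t+", "1\t10\t20"])
        with pytest.raises(ValueError, match="line 2"):
            read_bed6(path)


class TestTraitOverlap:
    def test_disjoint_sets_p_near_one(self):
        k, p = trait_overlap_test({"a", "b"}, {"c", "d"}, universe=100)
        assert k == 0 and p == pytest.approx(1.0)

    def test_subset_gives_minimal_p(self):
        k, p = trait_overlap_test({"a", "b"}, {"a", "b", "c"}, universe=100)
        from scipy.stats import hypergeom
        assert k == 2
        assert p == pytest.approx(hypergeom.sf(1, 100, 3, 2))

    def test_matches_direct_summation(self):
        from math import comb
        universe, na, nb, k = 1000, 50, 40, 10
        tail = sum(
            comb(nb, i) * comb(universe - nb, na - i) for i in range(k, min(na, nb) + 1)
        ) / comb(universe, na)
        _, p = trait_overlap_test(
            {f"s{i}" for i in range(na)},
            {f"s{i}" for i in range(na - k, na - k + nb)},
            universe,
        )
        assert p == pytest.approx(tail, rel=1e-9)

    def test_universe_too_small_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            trait_overlap_test({"a"}, {"b"}, universe=1)


class TestSummary:
    def test_single_median_p_gives_unit_lambda(self):
        res = pd.DataFrame({"chrom": ["1"], "pos": [1], "snp_id": ["rs1"], "p": [0.5]})
        out = gwas_summary(res)
        assert out["lambda"] == pytest.approx(1.0)
        assert out["qq"]["observed"].iloc[0] == pytest.approx(
            out["qq"]["expected"].iloc[0]
        )

    def test_empty_results_rejected(self):
        res = pd.DataFrame({"chrom": [], "pos": [], "snp_id": [], "p": []})
        with pytest.raises(ValueError):
            gwas_summary(res)

    def test_uniform_p_lambda_near_one(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=5000)
        res = pd.DataFrame({"chrom": "1", "pos": np.arange(5000),
                            "snp_id": [f"s{i}" for i in range(5000)], "p": p})
        assert gwas_summary(res)["lambda"] == pytest.approx(1.0, abs=0.05)
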