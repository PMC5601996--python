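"""Variant QC, Spearman rank-correlation GWAS, SNP-to-gene assignment
and trait-pair overlap statistics.

QC mirrors a standard imputed-array filter: variants are removed when
MAF < 5%, Hardy-Weinberg exact p < 1e-6, call rate < 97.5% or imputation
info score < 0.4.  Association is the Spearman correlation between per
SNP dosage and the residualized per-line phenotype, with the two-sided
p-value from the t approximation on n-2 degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .synthetic import GenotypeMatrix

__all__ = [
    "hwe_exact_test",
    "qc_filter_variants",
    "spearman_gwas",
    "assign_genes",
    "trait_overlap_test",
    "gwas_summary",
    "read_bed6",
]


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional Hardy-Weinberg test.

    Conditional on the observed allele counts, the p-value is the sum of
    the probabilities of all heterozygote counts (same parity as the
    observed one) whose probability does not exceed that of the observed
    count.  Monomorphic sites have a single attainable configuration and
    return p = 1.
    """
    counts = (int(n_AA), int(n_Aa), int(n_aa))
    if any(c < 0 for c in counts):
        raise ValueError("genotype counts must be non-negative")
    n = sum(counts)
    if n == 0:
        raise ValueError("all genotype counts are zero")
    n_A = 2 * counts[0] + counts[1]
    n_a = 2 * counts[2] + counts[1]
    if n_A == 0 or n_a == 0:
        return 1.0
    rare = min(n_A, n_a)
    hets = np.arange(rare % 2, rare + 1, 2)
    homs_rare = (rare - hets) // 2
    homs_common = n - hets - homs_rare
    # log P(het = h | allele counts) up to a shared constant
    logp = (
        hets * np.log(2)
        - gammaln(hets + 1)
        - gammaln(homs_rare + 1)
        - gammaln(homs_common + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs = counts[1]
    p_obs = probs[np.searchsorted(hets, obs)]
    return float(min(probs[probs <= p_obs * (1 + 1e-12)].sum(), 1.0))


def _variant_stats(dosages: np.ndarray) -> pd.DataFrame:
    """Per-variant ALT frequency, folded MAF, call rate and HWE p."""
    n, m = dosages.shape
    stats_rows = np.empty((m, 4))
    for j in range(m):
        col = dosages[:, j]
        ok = ~np.isnan(col)
        n_called = int(ok.sum())
        call_rate = n_called / n if n else 0.0
        if n_called == 0:
            stats_rows[j] = (np.nan, np.nan, call_rate, np.nan)
            continue
        g = np.rint(col[ok]).astype(int)
        alt = g.sum() / (2 * n_called)
        maf = min(alt, 1 - alt)
        hwe = hwe_exact_test(int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum()))
        stats_rows[j] = (alt, maf, call_rate, hwe)
    return pd.DataFrame(stats_rows, columns=["alt_freq", "maf", "call_rate", "hwe_p"])


def qc_filter_variants(
    genotypes: GenotypeMatrix,
    maf_min: float = 0.05,
    hwe_min: float = 1e-6,
    callrate_min: float = 0.975,
    info_min: float = 0.4,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Apply the four variant filters; returns the retained matrix and a
    QC report listing every variant with its statistics and, for removed
    variants, the first failing criterion (MAF, HWE, call rate, info —
    checked in that order)."""
    for name, value, lo, hi in (
        ("maf_min", maf_min, 0.0, 0.5),
        ("hwe_min", hwe_min, 0.0, 1.0),
        ("callrate_min", callrate_min, 0.0, 1.0),
    ):
        if not lo <= value <= hi:
            raise ValueError(f"{name}={value} outside [{lo}, {hi}]")
    vstats = _variant_stats(genotypes.dosages)
    info = genotypes.variants.get("info_score", pd.Series(np.ones(genotypes.n_snps)))
    info = np.asarray(info, dtype=float)
    reasons = []
    keep = np.ones(genotypes.n_snps, dtype=bool)
    for j in range(genotypes.n_snps):
        reason = ""
        if not vstats.loc[j, "maf"] >= maf_min:
            reason = "MAF"
        elif not vstats.loc[j, "hwe_p"] >= hwe_min:
            reason = "HWE"
        elif not vstats.loc[j, "call_rate"] >= callrate_min:
            reason = "call_rate"
        elif not info[j] >= info_min:
            reason = "info"
        reasons.append(reason)
        keep[j] = reason == ""
    report = pd.concat(
        [genotypes.variants[["snp_id"]].reset_index(drop=True), vstats], axis=1
    )
    report["info_score"] = info
    report["retained"] = keep
    report["reason"] = reasons
    return genotypes.subset_variants(keep), report


@dataclass
class SpearmanResult:
    table: pd.DataFrame  # snp_id, trait, rho, p, n, reason


def _spearman_p(rho: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Two-sided p by the t approximation with n-2 df."""
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2 * stats.t.sf(np.abs(t), df=np.maximum(n - 2, 1))
    p[np.isinf(t)] = np.nextafter(0.0, 1.0)
    return np.minimum(p, 1.0)


def spearman_gwas(
    genotypes: GenotypeMatrix,
    phenotype: pd.Series,
    trait: str = "trait",
    min_n: int = 10,
) -> pd.DataFrame:
    """Per-SNP Spearman correlation between dosage and phenotype.

    ``phenotype`` is indexed by line/sample id.  Missing dosages are
    handled by pairwise-complete deletion; SNPs monomorphic after
    deletion, or with fewer than ``min_n`` complete pairs, yield NaN with
    a reason.  Average ranks are used for ties (the norm for dosage data,
    where ties are ubiquitous).
    """
    common = [s for s in genotypes.samples if s in phenotype.index]
    missing_pheno = [s for s in genotypes.samples if s not in phenotype.index]
    if not common:
        raise ValueError("no overlapping samples between genotypes and phenotype")
    if len(missing_pheno) == len(genotypes.samples):
        raise ValueError(f"unmatched sample ids: {missing_pheno[:5]}")
    sub = genotypes.subset_samples(common)
    y = phenotype.loc[common].to_numpy(dtype=float)
    dos = sub.dosages
    n_total, m = dos.shape

    rho = np.full(m, np.nan)
    pval = np.full(m, np.nan)
    n_used = np.zeros(m, dtype=int)
    reason = np.array([""] * m, dtype=object)

    complete = ~np.isnan(dos).any(axis=0)
    y_rank = stats.rankdata(y)
    if complete.any():
        cols = dos[:, complete]
        ranks = np.apply_along_axis(stats.rankdata, 0, cols)
        rc = ranks - ranks.mean(axis=0)
        yc = y_rank - y_rank.mean()
        denom = np.sqrt((rc**2).sum(axis=0) * (yc**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (rc * yc[:, None]).sum(axis=0) / denom
        mono = np.ptp(cols, axis=0) == 0
        r[mono] = np.nan
        idx = np.flatnonzero(complete)
        rho[idx] = r
        n_used[idx] = n_total
        pval[idx] = _spearman_p(np.nan_to_num(r), np.full(idx.size, n_total))
        pval[idx[mono]] = np.nan
        reason[idx[mono]] = "monomorphic"
        if n_total < min_n:
            rho[idx] = np.nan
            pval[idx] = np.nan
            reason[idx] = "too_few_pairs"
    for j in np.flatnonzero(~complete):
        ok = ~np.isnan(dos[:, j])
        nj = int(ok.sum())
        n_used[j] = nj
        if nj < min_n:
            reason[j] = "too_few_pairs"
            continue
        g = dos[ok, j]
        if np.ptp(g) == 0:
            reason[j] = "monomorphic"
            continue
        r, _ = stats.spearmanr(g, y[ok])
        rho[j] = r
        pval[j] = _spearman_p(np.array([r]), np.array([nj]))[0]

    out = sub.variants[["chrom", "pos", "snp_id"]].copy()
    out["trait"] = trait
    out["rho"] = rho
    out["p"] = pval
    out["n"] = n_used
    out["reason"] = reason
    return out


def read_bed6(path) -> pd.DataFrame:
    """Read a BED6 annotation (0-based half-open) of gene bodies.

    Returns chrom, start, end, gene_id, score, strand with the TSS in
    1-based coordinates (start+1 for + strand, end for - strand)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"malformed BED line {lineno}: expected 6 fields")
            chrom, start, end, name, score, strand = parts[:6]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"malformed BED line {lineno}: non-integer coordinate") from exc
            if strand not in "+-" or end_i < start_i:
                raise ValueError(f"malformed BED line {lineno}")
            rows.append((chrom, start_i, end_i, name, score, strand))
    bed = pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id", "score", "strand"])
    bed["tss_1based"] = np.where(bed["strand"] == "+", bed["start"] + 1, bed["end"])
    return bed


def assign_genes(
    results: pd.DataFrame, tss: pd.DataFrame, window_bp: int = 100_000
) -> pd.DataFrame:
    """All (SNP, gene) pairs whose transcription start site lies within
    ``window_bp`` of the SNP (inclusive boundary, same chromosome).

    ``results`` needs chrom/pos/snp_id columns (1-based positions);
    ``tss`` is the frame from :func:`read_bed6`.
    """
    out = []
    for chrom, snps in results.groupby("chrom"):
        genes = tss[tss["chrom"] == chrom]
        if genes.empty:
            continue
        pos = snps["pos"].to_numpy()[:, None]
        tpos = genes["tss_1based"].to_numpy()[None, :]
        dist = pos - tpos  # signed: positive = SNP downstream of TSS
        hit_i, hit_j = np.nonzero(np.abs(dist) <= window_bp)
        for i, j in zip(hit_i, hit_j):
            out.append(
                (
                    snps["snp_id"].iloc[i],
                    genes["gene_id"].iloc[j],
                    int(dist[i, j]),
                )
            )
    return pd.DataFrame(out, columns=["snp_id", "gene_id", "distance_bp"])


def trait_overlap_test(set_a, set_b, universe: int) -> tuple[int, float]:
    """Hypergeometric upper-tail test of SNP-set overlap between two
    traits: p = P(overlap >= observed) for |A| draws from a universe
    containing |B| successes."""
    a, b = set(set_a), set(set_b)
    if universe < len(a | b):
        raise ValueError("universe smaller than the union of the two sets")
    k = len(a & b)
    p = float(stats.hypergeom.sf(k - 1, universe, len(b), len(a)))
    return k, min(p, 1.0)


def gwas_summary(results: pd.DataFrame) -> dict:
    """Manhattan/QQ export and genomic-inflation lambda.

    Returns {'manhattan': frame(chrom, pos, snp_id, minus_log10_p),
    'qq': frame(expected, observed) in -log10 units, 'lambda': float}
    with lambda = median observed chi2(1) / median expected chi2(1).
    """
    p = results["p"].to_numpy(dtype=float)
    ok = np.isfinite(p)
    if not ok.any():
        raise ValueError("no finite p-values to summarize")
    p = np.clip(p[ok], np.nextafter(0.0, 1.0), 1.0)
    manhattan = results.loc[ok, ["chrom", "pos", "snp_id"]].copy()
    manhattan["minus_log10_p"] = -np.log10(p)
    order = np.sort(p)
    m = order.size
    expected = (np.arange(1, m + 1) - 0.5) / m
    qq = pd.DataFrame(
        {"expected": -np.log10(expected), "observed": -np.log10(order)}
    )
    chi_obs = stats.chi2.isf(order, df=1)
    lam = float(np.median(chi_obs) / stats.chi2.isf(0.5, df=1))
    return {"manhattan": manhattan, "qq": qq, "lambda": lam}
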