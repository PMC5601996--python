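"""Extreme-chronotype allele-frequency enrichment.

For every SNP the statistic is |f_larks - f_owls|, the absolute
difference of the designated (ALT) allele frequency between the early
and late extreme-chronotype cohorts.  The profile reports the
distribution of this difference over the SNPs passing each of a ladder
of GWAS p-value thresholds: if cellular-trait associations carry over to
behavior, the mean difference rises as the threshold tightens.
A tag-SNP variant keeps one SNP per LD block (greedy r^2 pruning in
ascending-p order) so large blocks do not dominate the profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import ChronotypeCohort, GenotypeMatrix

DEFAULT_THRESHOLDS = (1e-3, 1e-4, 1e-5, 1e-6)

__all__ = [
    "allele_frequency",
    "delta_frequencies",
    "enrichment_profile",
    "tag_snps",
    "EnrichmentProfile",
]


def allele_frequency(genotypes: GenotypeMatrix, snp_id: str) -> float:
    """Designated (ALT) allele frequency: sum of dosages over twice the
    number of non-missing genotypes."""
    ids = genotypes.variants["snp_id"]
    hits = np.flatnonzero(ids.to_numpy() == snp_id)
    if hits.size == 0:
        raise KeyError(f"unknown snp_id {snp_id!r}")
    col = genotypes.dosages[:, hits[0]]
    ok = ~np.isnan(col)
    if not ok.any():
        raise ValueError(f"all genotypes missing for {snp_id}")
    return float(col[ok].sum() / (2 * ok.sum()))


def _frequencies(genotypes: GenotypeMatrix) -> pd.Series:
    dos = genotypes.dosages
    ok = ~np.isnan(dos)
    counts = np.where(ok, dos, 0.0).sum(axis=0)
    n_called = ok.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = counts / (2 * n_called)
    return pd.Series(freq, index=genotypes.variants["snp_id"].to_numpy())


def delta_frequencies(cohort: ChronotypeCohort) -> pd.Series:
    """|f_larks - f_owls| per SNP of the shared panel, in [0, 1]."""
    return (_frequencies(cohort.larks) - _frequencies(cohort.owls)).abs()


def _tukey_summary(values: np.ndarray) -> dict:
    q1, q2, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = values[(values >= lo_fence) & (values <= hi_fence)]
    return {
        "q1": float(q1),
        "median": float(q2),
        "q3": float(q3),
        "whisker_low": float(inside.min()),
        "whisker_high": float(inside.max()),
        "mean": float(values.mean()),
    }


@dataclass
class EnrichmentProfile:
    per_snp: pd.DataFrame    # threshold, snp_id, delta_f
    summary: pd.DataFrame    # threshold, n_snps, mean, Tukey five numbers
    density: pd.DataFrame    # threshold, grid, density (per-threshold KDE)


def enrichment_profile(
    gwas_results: pd.DataFrame,
    cohort: ChronotypeCohort,
    thresholds=DEFAULT_THRESHOLDS,
    density_grid: int = 101,
) -> EnrichmentProfile:
    """Per-threshold |delta f| distributions with Tukey box summaries and
    kernel-density exports.

    SNP sets are nested by construction (p < tau); thresholds with no
    SNP are recorded with n = 0 and no summary row values.
    """
    delta = delta_frequencies(cohort)
    shared = gwas_results[gwas_results["snp_id"].isin(delta.index)]
    per_rows, sum_rows, dens_rows = [], [], []
    grid = np.linspace(0.0, 1.0, density_grid)
    for tau in sorted(thresholds, reverse=True):
        snps = shared.loc[shared["p"] < tau, "snp_id"].unique()
        vals = delta.loc[snps].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        for sid, v in zip(snps, delta.loc[snps]):
            per_rows.append((tau, sid, float(v)))
        if vals.size == 0:
            sum_rows.append({"threshold": tau, "n_snps": 0})
            continue
        row = {"threshold": tau, "n_snps": int(vals.size)}
        row.update(_tukey_summary(vals))
        sum_rows.append(row)
        if vals.size >= 2 and np.ptp(vals) > 0:
            kde = stats.gaussian_kde(vals)
            dens = kde(grid)
        else:  # degenerate sample: a spike at the single value
            dens = np.zeros_like(grid)
            dens[np.argmin(np.abs(grid - vals[0]))] = 1.0 / (grid[1] - grid[0])
        for g, d in zip(grid, dens):
            dens_rows.append((tau, float(g), float(d)))
    return EnrichmentProfile(
        per_snp=pd.DataFrame(per_rows, columns=["threshold", "snp_id", "delta_f"]),
        summary=pd.DataFrame(sum_rows),
        density=pd.DataFrame(dens_rows, columns=["threshold", "delta_f", "density"]),
    )


def tag_snps(
    snp_ids,
    genotypes: GenotypeMatrix,
    gwas_results: pd.DataFrame | None = None,
    r2_threshold: float = 0.8,
) -> pd.DataFrame:
    """Greedy tag-SNP selection: one SNP per LD block.

    SNPs are visited in ascending GWAS p order (or input order when no
    results are given; ties broken by snp_id); a SNP founds a new block
    unless its dosage r^2 with an existing tag reaches ``r2_threshold``.
    Returns snp_id, tag_id, is_tag.
    """
    snp_ids = list(snp_ids)
    panel = genotypes.variants["snp_id"].tolist()
    missing = sorted(set(snp_ids) - set(panel))
    if missing:
        raise KeyError(f"snp ids absent from genotype panel: {missing[:5]}")
    if gwas_results is not None:
        pmap = gwas_results.set_index("snp_id")["p"].to_dict()
        order = sorted(snp_ids, key=lambda s: (pmap.get(s, np.inf), s))
    else:
        order = snp_ids
    col = {s: panel.index(s) for s in snp_ids}
    tags: list[str] = []
    assignment = {}
    for sid in order:
        x = genotypes.dosages[:, col[sid]]
        best_tag, best_r2 = None, 0.0
        for tag in tags:
            yv = genotypes.dosages[:, col[tag]]
            ok = ~(np.isnan(x) | np.isnan(yv))
            if ok.sum() < 3 or np.ptp(x[ok]) == 0 or np.ptp(yv[ok]) == 0:
                continue
            r = np.corrcoef(x[ok], yv[ok])[0, 1]
            if r * r >= r2_threshold and r * r > best_r2:
                best_tag, best_r2 = tag, r * r
        if best_tag is None:
            tags.append(sid)
            assignment[sid] = sid
        else:
            assignment[sid] = best_tag
    return pd.DataFrame(
        {
            "snp_id": list(assignment),
            "tag_id": [assignment[s] for s in assignment],
            "is_tag": [s == assignment[s] for s in assignment],
        }
    )
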