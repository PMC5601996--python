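"""Genome-wide RNAi screen statistics: hairpin Z-scores, redundant
siRNA activity (RSA) gene scores, and genelist-versus-background
distribution comparisons.

RSA concatenates the ranks of a gene's hairpins in the screen-wide
ranking into one p-value per effect direction: for a gene with k
hairpins at ascending ranks r_1 < ... < r_k among N hairpins, the score
is the minimum over j of the hypergeometric upper tail
P(>= j of k hairpins fall in the top r_j positions) under uniform random
placement.  Scores are computed separately on the most-negative-first
ranking ("decrease") and the most-positive-first ranking ("increase"),
so a gene with discordant hairpins can score in both directions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "zscore_hairpins",
    "rsa_score",
    "rsa_gene_scores",
    "compare_genelist_distributions",
    "RsaDistributions",
]


def zscore_hairpins(raw: pd.DataFrame) -> pd.DataFrame:
    """Z-score raw hairpin values per trait over the entire screen.

    z = (value - mean) / sd with the sample (n-1) standard deviation.
    """
    for col in ("hairpin_id", "gene_id", "trait", "value"):
        if col not in raw.columns:
            raise ValueError(f"hairpin table lacks column {col!r}")
    out = raw.reset_index(drop=True).copy()
    zs = np.empty(len(out))
    for trait, sub in out.groupby("trait", sort=False):
        v = sub["value"].to_numpy(dtype=float)
        if v.size < 2 or np.ptp(v) == 0:
            raise ValueError(f"trait {trait!r}: zero variance, cannot Z-score")
        zs[sub.index] = (v - v.mean()) / v.std(ddof=1)
    out["z"] = zs
    return out


def rsa_score(gene_ranks, n_total: int) -> float:
    """RSA p-value for one gene from its hairpin ranks.

    ``gene_ranks``: distinct ascending ranks in [1, N] of the gene's k
    hairpins within the full screen ranking of ``n_total`` hairpins.
    p = min_j P(X >= j), X ~ Hypergeometric(N, k, r_j).
    """
    ranks = np.asarray(sorted(int(r) for r in gene_ranks))
    k = ranks.size
    if k == 0:
        raise ValueError("gene has no hairpins")
    if len(set(ranks)) != k:
        raise ValueError("hairpin ranks must be distinct")
    if ranks[0] < 1 or ranks[-1] > n_total:
        raise ValueError(f"ranks must lie in [1, {n_total}]")
    j = np.arange(1, k + 1)
    tails = stats.hypergeom.sf(j - 1, n_total, k, ranks)
    return float(min(tails.min(), 1.0))


def _direction_ranks(z: np.ndarray, hairpin_ids: np.ndarray, direction: str) -> np.ndarray:
    """1-based screen-wide ranks; 'decrease' ranks most-negative first,
    'increase' most-positive first.  Ties broken by hairpin id."""
    key = z if direction == "decrease" else -z
    order = np.lexsort((hairpin_ids, key))
    ranks = np.empty(len(z), dtype=int)
    ranks[order] = np.arange(1, len(z) + 1)
    return ranks


def rsa_gene_scores(hairpins: pd.DataFrame) -> pd.DataFrame:
    """Directional RSA scores for every gene and trait in a Z-scored
    hairpin table.

    Returns gene_id, trait, direction ('increase'|'decrease'), p,
    log10_p (<= 0) and the contributing hairpin ranks.
    """
    if "z" not in hairpins.columns:
        hairpins = zscore_hairpins(hairpins)
    frames = []
    for trait, sub in hairpins.groupby("trait", sort=False):
        sub = sub.reset_index(drop=True)
        z = sub["z"].to_numpy(dtype=float)
        hp = sub["hairpin_id"].to_numpy()
        genes = sub["gene_id"].to_numpy()
        n_total = len(sub)
        for direction in ("decrease", "increase"):
            ranks = _direction_ranks(z, hp, direction)
            # segment by gene, rank-sorted within gene, and evaluate every
            # hypergeometric tail in one vectorized call
            order = np.lexsort((ranks, genes))
            g_sorted = genes[order]
            r_sorted = ranks[order]
            starts = np.flatnonzero(np.r_[True, g_sorted[1:] != g_sorted[:-1]])
            sizes = np.diff(np.r_[starts, len(g_sorted)])
            k_per_row = np.repeat(sizes, sizes)
            j_per_row = np.arange(len(g_sorted)) - np.repeat(starts, sizes) + 1
            tails = stats.hypergeom.sf(j_per_row - 1, n_total, k_per_row, r_sorted)
            p_gene = np.minimum(np.minimum.reduceat(tails, starts), 1.0)
            rank_strings = [
                ",".join(map(str, r_sorted[s:s + n])) for s, n in zip(starts, sizes)
            ]
            frames.append(pd.DataFrame({
                "gene_id": g_sorted[starts], "trait": trait, "direction": direction,
                "p": p_gene, "log10_p": np.log10(p_gene),
                "hairpin_ranks": rank_strings,
            }))
    return pd.concat(frames, ignore_index=True)


@dataclass
class RsaDistributions:
    tests: pd.DataFrame       # trait, direction, ks_stat, ks_p, kruskal_p, n_genelist, n_background
    combined_cdf: pd.DataFrame  # trait, signed_log10_p, genelist_cdf, background_cdf
    subsample: pd.DataFrame   # seeded size-matched random background draw for display
    genelist_scores: pd.DataFrame
    background_scores: pd.DataFrame


def compare_genelist_distributions(
    scores: pd.DataFrame,
    genelist,
    subsample_size: int = 50,
    seed: int = 0,
) -> RsaDistributions:
    """Compare genelist RSA score distributions to the whole-screen
    background.

    Per trait and direction: two-sample Kolmogorov-Smirnov and
    Kruskal-Wallis tests between genelist log10 scores and the full
    background (the genelist is not excluded from the background,
    mirroring a genome-wide reference).  The combined display pools the
    decrease-direction log-scores with the sign-inverted
    increase-direction log-scores into one cumulative distribution.
    A size-matched random background subsample (default 50 genes per
    direction, seeded) is exported for scatter display.
    """
    genelist = sorted(set(genelist))
    if not genelist:
        raise ValueError("empty genelist")
    in_list = scores["gene_id"].isin(genelist)
    if not in_list.any():
        raise ValueError("no genelist gene present in the score table")
    gl = scores[in_list]
    bg = scores
    rng = np.random.default_rng(seed)

    test_rows, cdf_rows, sub_rows = [], [], []
    for trait, strait in scores.groupby("trait", sort=False):
        signed_gl, signed_bg = [], []
        for direction in ("decrease", "increase"):
            sign = -1.0 if direction == "increase" else 1.0
            b = strait.loc[strait["direction"] == direction, "log10_p"].to_numpy()
            g = gl.loc[
                (gl["trait"] == trait) & (gl["direction"] == direction), "log10_p"
            ].to_numpy()
            if g.size == 0 or b.size == 0:
                continue
            ks = stats.ks_2samp(g, b, method="asymp")
            try:
                kw_p = float(stats.kruskal(g, b).pvalue)
            except ValueError:  # all values identical
                kw_p = 1.0
            test_rows.append(
                (trait, direction, float(ks.statistic), float(ks.pvalue), kw_p,
                 g.size, b.size)
            )
            signed_gl.append(sign * g)
            signed_bg.append(sign * b)
            take = min(subsample_size, b.size)
            draw = rng.choice(b, size=take, replace=False)
            for v in draw:
                sub_rows.append((trait, direction, float(sign * v)))
        if signed_gl:
            gl_all = np.sort(np.concatenate(signed_gl))
            bg_all = np.sort(np.concatenate(signed_bg))
            grid = np.unique(np.concatenate([gl_all, bg_all]))
            gcdf = np.searchsorted(gl_all, grid, side="right") / gl_all.size
            bcdf = np.searchsorted(bg_all, grid, side="right") / bg_all.size
            for x, gc, bc in zip(grid, gcdf, bcdf):
                cdf_rows.append((trait, float(x), float(gc), float(bc)))

    return RsaDistributions(
        tests=pd.DataFrame(
            test_rows,
            columns=["trait", "direction", "ks_stat", "ks_p", "kruskal_p",
                     "n_genelist", "n_background"],
        ),
        combined_cdf=pd.DataFrame(
            cdf_rows, columns=["trait", "signed_log10_p", "genelist_cdf", "background_cdf"]
        ),
        subsample=pd.DataFrame(sub_rows, columns=["trait", "direction", "signed_log10_p"]),
        genelist_scores=gl.reset_index(drop=True),
        background_scores=bg.reset_index(drop=True),
    )
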