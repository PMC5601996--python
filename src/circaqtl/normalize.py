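"""Three-step phenotype normalization before association testing.

1. Average technical replicates within each biological replicate.
2. Residualize confounders (cell passage as a numeric covariate,
   experiment date as a factor) by backward elimination on a linear
   mixed model with a random intercept per cell line: starting from all
   covariates, the least significant one is dropped until every retained
   covariate is nominally significant (p < alpha).  The factor is tested
   and dropped as a block (joint Wald chi-square on its dummy columns).
3. Average the residuals of the biological replicates into one value per
   cell line.

Residuals are observed minus the *fixed-effect* prediction: the random
line intercept is deliberately not subtracted, because the line-level
signal is the phenotype carried into the GWAS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

ALPHA_DEFAULT = 0.05

REQUIRED_COLUMNS = [
    "line_id", "biological_replicate", "technical_replicate",
    "trait", "value", "passage", "date",
]


def _check_columns(table: pd.DataFrame, columns) -> None:
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise ValueError(f"phenotype table lacks columns: {missing}")


def average_technical_replicates(table: pd.DataFrame) -> pd.DataFrame:
    """Mean over technical replicates: one row per (line, bio-rep, trait).

    Covariates must be constant within each averaged group; a conflict is
    an error naming the offending group.
    """
    _check_columns(table, REQUIRED_COLUMNS)
    keys = ["line_id", "biological_replicate", "trait"]
    for cov in ("passage", "date"):
        nunique = table.groupby(keys, sort=False)[cov].nunique()
        bad = nunique[nunique > 1]
        if len(bad):
            group = bad.index[0]
            raise ValueError(
                f"covariate {cov!r} varies within technical replicates of group {group}"
            )
    out = (
        table.groupby(keys, sort=False)
        .agg(value=("value", "mean"), passage=("passage", "first"), date=("date", "first"))
        .reset_index()
    )
    return out


@dataclass
class EliminationStep:
    trait: str
    step: int
    covariate: str
    p_value: float
    action: str  # "drop" | "retain" | "degenerate"


@dataclass
class ResidualizationResult:
    residuals: pd.DataFrame  # line_id, biological_replicate, trait, residual
    report: pd.DataFrame     # trait, step, covariate, p, action
    retained: dict[str, list[str]] = field(default_factory=dict)


def _fit_mixed(y, groups, passage, date_dummies, include):
    """Fit value ~ 1 (+ passage) (+ date dummies) with a random intercept
    per line, by REML.

    The response is standardized and the passage covariate centered and
    scaled internally (an affine reparameterization: Wald tests and the
    returned original-scale residuals are unaffected) to keep the REML
    optimization well conditioned on arbitrarily scaled traits.
    Returns (fe params, fe covariance, column names, design, residual fn).
    """
    y_mean, y_sd = float(np.mean(y)), float(np.std(y))
    y_sd = y_sd if y_sd > 0 else 1.0
    ys = (y - y_mean) / y_sd
    cols = [np.ones_like(y)]
    names = ["const"]
    if "passage" in include:
        p_mean, p_sd = float(np.mean(passage)), float(np.std(passage))
        p_sd = p_sd if p_sd > 0 else 1.0
        cols.append((passage - p_mean) / p_sd)
        names.append("passage")
    if "date" in include:
        for c in date_dummies.columns:
            cols.append(date_dummies[c].to_numpy(dtype=float))
            names.append(c)
    X = np.column_stack(cols)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(ys, X, groups=groups)
        res = None
        for method in ("lbfgs", "bfgs", "powell"):
            try:
                res = model.fit(reml=True, method=method, maxiter=300)
                break
            except (np.linalg.LinAlgError, ValueError):
                continue
        if res is None:
            raise np.linalg.LinAlgError("mixed-model fit failed for all optimizers")
    k = X.shape[1]
    fe = np.asarray(res.fe_params)
    cov = np.asarray(res.cov_params())[:k, :k]
    resid = y_sd * (ys - X @ fe)
    return fe, cov, names, resid


def _wald_block_p(fe, cov, names, block: list[str]) -> float:
    idx = [names.index(n) for n in block]
    beta = fe[idx]
    V = cov[np.ix_(idx, idx)]
    try:
        stat = float(beta @ np.linalg.solve(V, beta))
    except np.linalg.LinAlgError:
        return 1.0
    return float(stats.chi2.sf(stat, df=len(idx)))


def backward_residualize(
    table: pd.DataFrame, alpha: float = ALPHA_DEFAULT
) -> ResidualizationResult:
    """Backward-eliminated mixed-model residualization, per trait.

    Candidate covariates are passage (numeric, z-test on its coefficient)
    and date (factor, joint Wald test on its dummy block).  At each step
    the candidate with the largest p >= alpha is dropped (ties broken by
    covariate name) and the model refitted; degenerate covariates (a
    single level / zero variance) are dropped with a warning before
    fitting.  Residual = observed - fixed-effect prediction.
    """
    _check_columns(table, ["line_id", "biological_replicate", "trait", "value", "passage", "date"])
    steps: list[EliminationStep] = []
    retained: dict[str, list[str]] = {}
    frames = []
    for trait, sub in table.groupby("trait", sort=False):
        sub = sub.reset_index(drop=True)
        y = sub["value"].to_numpy(dtype=float)
        groups = sub["line_id"].to_numpy()
        passage = sub["passage"].to_numpy(dtype=float)
        include = []
        step_no = 0
        if np.ptp(passage) > 0:
            include.append("passage")
        else:
            warnings.warn(f"{trait}: passage has no variance; dropped from the model")
            step_no += 1
            steps.append(EliminationStep(trait, step_no, "passage", np.nan, "degenerate"))
        if sub["date"].nunique() > 1:
            include.append("date")
            date_dummies = pd.get_dummies(sub["date"], prefix="date", drop_first=True)
        else:
            date_dummies = pd.DataFrame(index=sub.index)
            warnings.warn(f"{trait}: a single date level; date dropped from the model")
            step_no += 1
            steps.append(EliminationStep(trait, step_no, "date", np.nan, "degenerate"))

        while True:
            fe, cov, names, resid = _fit_mixed(y, groups, passage, date_dummies, include)
            pvals: dict[str, float] = {}
            if "passage" in include:
                j = names.index("passage")
                se = np.sqrt(max(cov[j, j], 0.0))
                z = fe[j] / se if se > 0 else 0.0
                pvals["passage"] = float(2 * stats.norm.sf(abs(z)))
            if "date" in include:
                block = [n for n in names if n.startswith("date_")]
                pvals["date"] = _wald_block_p(fe, cov, names, block)
            worst = [c for c, p in pvals.items() if p >= alpha or not np.isfinite(p)]
            if not worst:
                for c, p in sorted(pvals.items()):
                    step_no += 1
                    steps.append(EliminationStep(trait, step_no, c, p, "retain"))
                break
            # drop the largest p; deterministic tie-break by name
            drop = sorted(worst, key=lambda c: (-(pvals[c] if np.isfinite(pvals[c]) else 2.0), c))[0]
            step_no += 1
            steps.append(EliminationStep(trait, step_no, drop, pvals[drop], "drop"))
            include.remove(drop)

        frames.append(
            pd.DataFrame(
                {
                    "line_id": sub["line_id"],
                    "biological_replicate": sub["biological_replicate"],
                    "trait": trait,
                    "residual": resid,
                }
            )
        )
        retained[trait] = list(include)
    report = pd.DataFrame(
        [(s.trait, s.step, s.covariate, s.p_value, s.action) for s in steps],
        columns=["trait", "step", "covariate", "p", "action"],
    )
    return ResidualizationResult(pd.concat(frames, ignore_index=True), report, retained)


def aggregate_by_line(residuals: pd.DataFrame) -> pd.DataFrame:
    """Final per-line phenotype: mean of biological-replicate residuals.

    Returns a table with one row per (line_id, trait)."""
    _check_columns(residuals, ["line_id", "trait", "residual"])
    out = (
        residuals.groupby(["line_id", "trait"], sort=True)["residual"]
        .mean()
        .rename("value")
        .reset_index()
    )
    return out


def normalize_phenotypes(
    table: pd.DataFrame, alpha: float = ALPHA_DEFAULT
) -> tuple[pd.DataFrame, ResidualizationResult]:
    """Full three-step chain; returns (per-line phenotypes, model report)."""
    averaged = average_technical_replicates(table)
    result = backward_residualize(averaged, alpha=alpha)
    return aggregate_by_line(result.residuals), result
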