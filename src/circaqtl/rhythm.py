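"""Harmonic (cosinor) regression at a fixed 24 h period, batch
rhythmicity detection with Benjamini-Hochberg FDR, and pulse-chase
exponential half-life estimation.

The regression model for a (log2-transformed) timecourse y(t) is

    y(t) = mu + a sin(2 pi t / P) + b cos(2 pi t / P) + noise,  P = 24 h

fitted by ordinary least squares; rhythmicity is the F test of
(a, b) = (0, 0) against the mean-only model on (2, n-3) degrees of
freedom.  Amplitude = sqrt(a^2 + b^2); acrophase = hour of the fitted
maximum in [0, 24).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["HarmonicFit", "harmonic_fit", "bh_fdr", "detect_rhythmic",
           "DecayFit", "fit_decay_halflife"]

_PERFECT_RTOL = 1e-12


@dataclass
class HarmonicFit:
    series_id: str
    mu: float
    a: float  # sine coefficient
    b: float  # cosine coefficient
    amplitude: float
    acrophase_h: float
    p: float
    perfect_fit: bool
    q: float | None = None
    rhythmic: bool | None = None


def harmonic_fit(times, values, period_h: float = 24.0, series_id: str = "") -> HarmonicFit:
    """OLS cosinor fit of one series on a fixed period.

    Requires >= 4 timepoints and a non-collinear design (timepoints must
    not all share the same phase mod period).  Perfect fits (machine-zero
    residual) are flagged and reported with the smallest positive p
    rather than a silent 0.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.ndim != 1 or t.shape != y.shape:
        raise ValueError("times and values must be matching 1-D arrays")
    n = t.size
    if n < 4:
        raise ValueError("need at least 4 timepoints for the cosinor fit")
    w = 2 * np.pi / period_h
    X = np.column_stack([np.ones(n), np.sin(w * t), np.cos(w * t)])
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError("collinear design: timepoints cover a single phase mod period")
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ coef
    rss = float(np.sum((y - fitted) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    mu, a, b = (float(c) for c in coef)
    amp = float(np.hypot(a, b))
    # y peaks where sin(wt)=a/amp, cos(wt)=b/amp  ->  t = atan2(a, b)/w
    acro = float((np.arctan2(a, b) / w) % period_h) if amp > 0 else 0.0
    scale = max(tss, np.sum(y**2), 1.0)
    perfect = (rss <= _PERFECT_RTOL * scale) and tss > rss
    if perfect:
        p = float(np.finfo(float).tiny)
    elif tss <= rss * (1 + 1e-12):
        p = 1.0
    else:
        f = ((tss - rss) / 2) / (rss / (n - 3))
        p = float(stats.f.sf(f, 2, n - 3))
    return HarmonicFit(series_id, mu, a, b, amp, acro, p, perfect)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment.

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1, returned in the
    input order.  All p must lie in (0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def detect_rhythmic(
    matrix: pd.DataFrame, fdr: float = 0.05, period_h: float = 24.0
) -> pd.DataFrame:
    """Cosinor fit per row of a wide timecourse matrix (columns = hours),
    BH adjustment across all successfully fitted series, rhythmic iff
    q < fdr.  Series whose fit fails are flagged and excluded from the
    BH family."""
    times = np.asarray(matrix.columns, dtype=float)
    fits: list[HarmonicFit] = []
    failures: list[tuple[str, str]] = []
    for sid, row in matrix.iterrows():
        try:
            fits.append(harmonic_fit(times, row.to_numpy(dtype=float), period_h, str(sid)))
        except ValueError as exc:
            failures.append((str(sid), str(exc)))
    if fits:
        q = bh_fdr([f.p for f in fits])
        for f, qi in zip(fits, q):
            f.q = float(qi)
            f.rhythmic = bool(qi < fdr)
    rows = [
        {
            "series_id": f.series_id, "mu": f.mu, "a": f.a, "b": f.b,
            "amplitude": f.amplitude, "acrophase_h": f.acrophase_h,
            "p": f.p, "q": f.q, "rhythmic": f.rhythmic,
            "perfect_fit": f.perfect_fit, "error": "",
        }
        for f in fits
    ]
    rows += [
        {"series_id": sid, "mu": np.nan, "a": np.nan, "b": np.nan,
         "amplitude": np.nan, "acrophase_h": np.nan, "p": np.nan, "q": np.nan,
         "rhythmic": False, "perfect_fit": False, "error": msg}
        for sid, msg in failures
    ]
    return pd.DataFrame(rows)


@dataclass
class DecayFit:
    rate_per_h: float
    half_life_h: float
    r_squared: float
    stable: bool


def fit_decay_halflife(times, fractions) -> DecayFit:
    """Exponential half-life from pulse-chase labeled fractions.

    ``fractions`` are percentages of the t = 0 signal (the first value
    should be 100).  Least squares on log(fraction) versus time gives the
    decay rate k = -slope and half-life ln 2 / k; when the fitted k is
    non-positive the protein is flagged stable.
    """
    t = np.asarray(times, dtype=float)
    f = np.asarray(fractions, dtype=float)
    if t.shape != f.shape or t.ndim != 1:
        raise ValueError("times and fractions must be matching 1-D arrays")
    if t.size < 3:
        raise ValueError("need at least 3 timepoints")
    if np.any(f <= 0):
        raise ValueError("fractions must be positive")
    logf = np.log(f)
    slope, intercept = np.polyfit(t, logf, 1)
    fitted = slope * t + intercept
    tss = float(np.sum((logf - logf.mean()) ** 2))
    rss = float(np.sum((logf - fitted) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    k = -float(slope)
    if k <= 1e-12:  # no measurable decay at double precision
        return DecayFit(rate_per_h=k, half_life_h=np.inf, r_squared=r2, stable=True)
    return DecayFit(rate_per_h=k, half_life_h=float(np.log(2) / k), r_squared=r2, stable=False)
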