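"""Design-weighted prevalence estimation and self-report validity.

Point estimates are Hájek ratio estimators p̂ = Σwᵢyᵢ / Σwᵢ.  Interval
estimates use a logit-scale Wald construction with a Taylor-linearised
(ratio) variance, which keeps the interval inside [0, 1]; at p̂ ∈ {0, 1}
the logit transform degenerates and a one-sided exact-style (Clopper–
Pearson on the effective sample size) bound is substituted and flagged.
Missing outcomes are dropped pairwise with their weights (complete case);
no imputation anywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from cvdmap.spatial_graph import AdjacencyGraph


class EstimationError(ValueError):
    """Raised when an estimate is requested from an empty/degenerate sample."""


@dataclass(frozen=True)
class PrevalenceEstimate:
    p_hat: float
    ci_low: float
    ci_high: float
    n: int
    degenerate_ci: bool = False


@dataclass(frozen=True)
class ValidityStats:
    """2×2 agreement of self-report against the measured gold standard."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def sensitivity(self) -> float:
        if self.tp + self.fn == 0:
            return float("nan")
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        if self.tn + self.fp == 0:
            return float("nan")
        return self.tn / (self.tn + self.fp)


def _clean(y, weights) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float)
    w = np.asarray(weights, dtype=float)
    if y.shape != w.shape:
        raise EstimationError(f"y ({y.shape}) and weights ({w.shape}) misaligned")
    keep = ~np.isnan(y) & ~np.isnan(w)
    y, w = y[keep], w[keep]
    if y.size == 0 or w.sum() <= 0:
        raise EstimationError("no observed outcomes with positive weight")
    if (w <= 0).any():
        raise EstimationError("weights must be positive")
    return y, w


def weighted_prevalence(y, weights, level: float = 0.95) -> PrevalenceEstimate:
    """Hájek-weighted prevalence with a logit-Wald linearised CI."""
    y, w = _clean(y, weights)
    n = y.size
    wsum = w.sum()
    p = float(np.dot(w, y) / wsum)
    z = stats.norm.ppf(0.5 + level / 2)
    # effective sample size for degenerate fallback
    n_eff = wsum**2 / np.dot(w, w)
    if p <= 0.0 or p >= 1.0:
        # one-sided exact-style bound on the effective n
        if p >= 1.0:
            lo = float(stats.beta.ppf((1 - level), n_eff, 1)) if n_eff > 0 else 0.0
            return PrevalenceEstimate(p, lo, 1.0, n, degenerate_ci=True)
        hi = float(stats.beta.ppf(level, 1, n_eff)) if n_eff > 0 else 1.0
        return PrevalenceEstimate(p, 0.0, hi, n, degenerate_ci=True)
    # Taylor-linearised ratio variance with finite-sample correction n/(n-1)
    resid = w * (y - p) / wsum
    var = n / max(n - 1, 1) * np.sum(resid**2)
    se_logit = np.sqrt(var) / (p * (1 - p))
    logit = np.log(p / (1 - p))
    lo = 1 / (1 + np.exp(-(logit - z * se_logit)))
    hi = 1 / (1 + np.exp(-(logit + z * se_logit)))
    return PrevalenceEstimate(p, float(lo), float(hi), n)


def stratified_prevalence(
    y, weights, strata, level: float = 0.95
) -> pd.DataFrame:
    """Per-stratum weighted prevalence plus each level's weighted share.

    Mirrors the layout of a survey prevalence table: one row per stratum
    level with columns p_hat, ci_low, ci_high, n, weighted_share (the
    level's share of the total weight among observed outcomes).
    """
    y = np.asarray(y, dtype=float)
    w = np.asarray(weights, dtype=float)
    s = pd.Series(strata).reset_index(drop=True)
    keep = ~np.isnan(y) & ~np.isnan(w)
    total_w = w[keep].sum()
    rows = []
    for lev in s.dropna().unique():
        m = (s == lev).to_numpy() & keep
        row = {"level": lev, "weighted_share": float(w[m].sum() / total_w)}
        try:
            est = weighted_prevalence(y[m], w[m], level=level)
            row.update(
                p_hat=est.p_hat, ci_low=est.ci_low, ci_high=est.ci_high,
                n=est.n, available=True,
            )
        except EstimationError:
            row.update(p_hat=np.nan, ci_low=np.nan, ci_high=np.nan, n=0, available=False)
        rows.append(row)
    return pd.DataFrame(rows)


def sensitivity_specificity(self_report, measured) -> ValidityStats:
    """2×2 validity of self-report vs measurement on pairwise-complete pairs."""
    sr = np.asarray(self_report, dtype=float)
    gold = np.asarray(measured, dtype=float)
    keep = ~np.isnan(sr) & ~np.isnan(gold)
    sr, gold = sr[keep].astype(int), gold[keep].astype(int)
    return ValidityStats(
        tp=int(((sr == 1) & (gold == 1)).sum()),
        fp=int(((sr == 1) & (gold == 0)).sum()),
        fn=int(((sr == 0) & (gold == 1)).sum()),
        tn=int(((sr == 0) & (gold == 0)).sum()),
    )


def district_prevalence(
    y, weights, district, graph: AdjacencyGraph, level: float = 0.95
) -> tuple[pd.DataFrame, dict]:
    """Per-district weighted prevalence and cross-district summary.

    *district* carries 1-based indices into *graph*.  Districts with no
    observed outcome are marked unavailable and excluded from the summary;
    per-district n is reported so small-sample instability is visible.
    """
    y = np.asarray(y, dtype=float)
    w = np.asarray(weights, dtype=float)
    d = np.asarray(district, dtype=int)
    if d.size and (d.min() < 1 or d.max() > graph.n_areas):
        raise EstimationError(
            f"district indices must lie in 1..{graph.n_areas}"
        )
    rows = []
    for j in range(1, graph.n_areas + 1):
        m = d == j
        row = {"district": j, "code": graph.codes[j - 1], "n": int((m & ~np.isnan(y)).sum())}
        try:
            est = weighted_prevalence(y[m], w[m], level=level)
            row.update(
                p_hat=est.p_hat, ci_low=est.ci_low, ci_high=est.ci_high, available=True
            )
        except EstimationError:
            row.update(p_hat=np.nan, ci_low=np.nan, ci_high=np.nan, available=False)
        rows.append(row)
    table = pd.DataFrame(rows)
    avail = table[table["available"]]
    if len(avail) < len(table):
        warnings.warn(
            f"{len(table) - len(avail)} district(s) had no observed outcomes; "
            "excluded from the summary",
            stacklevel=2,
        )
    p = avail["p_hat"]
    summary = {
        "mean": float(p.mean()),
        "median": float(p.median()),
        "min": float(p.min()),
        "max": float(p.max()),
        "n_districts": int(len(avail)),
        "sample_size_mean": float(avail["n"].mean()),
        "sample_size_median": float(avail["n"].median()),
        "sample_size_min": int(avail["n"].min()),
        "sample_size_max": int(avail["n"].max()),
    }
    return table, summary
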