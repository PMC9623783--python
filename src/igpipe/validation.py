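"""Validation statistics for indirect predictions.

The standard diagnostics of genomic-prediction bias and accuracy: the
regression GEBV = b0 + b1 * IGP per trait and sex group (b0 = level bias,
b1 = dispersion, R^2 = squared correlation = accuracy proxy), mean and
maximum absolute GEBV-IGP differences, the standardized genetic trend
(cohort-mean slope per year in genetic-SD units), and the cross-trait
correlations of the trend with each diagnostic. b0, MEAN, MAX and the trend
are reported in genetic-SD units; b1 and R^2 are scale-free and never
standardized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import linregress, pearsonr

__all__ = [
    "ValidationReport",
    "regress_gebv_on_igp",
    "abs_diff_stats",
    "genetic_trend",
    "correlate_with_trend",
    "build_report",
]

STATISTICS = ["b0", "b1", "r2", "mean", "max"]


@dataclass
class ValidationReport:
    """Per trait x sex-group diagnostics plus trend correlations.

    ``per_trait`` columns: trait, group, b0 (genetic-SD units), b1, r2,
    mean, max (genetic-SD units), dg. ``trend_correlations``: per group,
    Pearson correlation of dg across traits with each statistic (2 dp).
    """

    per_trait: pd.DataFrame
    trend_correlations: pd.DataFrame | None = None

    def rounded(self) -> pd.DataFrame:
        out = self.per_trait.copy()
        for c in ("b0", "b1", "dg", "mean", "max"):
            if c in out:
                out[c] = out[c].round(2)
        if "r2" in out:
            out["r2"] = out["r2"].round(3)
        return out


def _paired(gebv, igp):
    g = np.atleast_2d(np.asarray(gebv, dtype=float))
    v = np.atleast_2d(np.asarray(igp, dtype=float))
    if g.shape[0] == 1:
        g = g.T
    if v.shape[0] == 1:
        v = v.T
    if g.shape != v.shape:
        raise ValueError("GEBV and IGP are not paired")
    return g, v


def regress_gebv_on_igp(gebv, igp, groups=None, genetic_sd=None) -> pd.DataFrame:
    """OLS of GEBV on IGP per trait (and sex group if ``groups`` given).

    Returns a frame with b0, b1, r2 and a ``degenerate`` flag for groups with
    zero IGP variance (slope undefined). ``genetic_sd`` (per trait) divides
    b0 only. At least 3 paired animals per group are required.
    """
    g, v = _paired(gebv, igp)
    n, t = g.shape
    groups = np.asarray(groups) if groups is not None else np.full(n, "all")
    sd = np.ones(t) if genetic_sd is None else np.asarray(genetic_sd, dtype=float)
    rows = []
    for grp in np.unique(groups):
        sel = groups == grp
        if sel.sum() < 3:
            raise ValueError(f"group {grp!r} has fewer than 3 paired animals")
        for tdx in range(t):
            x, y = v[sel, tdx], g[sel, tdx]
            if np.ptp(x) == 0.0:
                rows.append((tdx, grp, np.nan, np.nan, np.nan, True))
                continue
            fit = linregress(x, y)
            rows.append((tdx, grp, fit.intercept / sd[tdx], fit.slope, fit.rvalue**2, False))
    return pd.DataFrame(rows, columns=["trait", "group", "b0", "b1", "r2", "degenerate"])


def abs_diff_stats(gebv, igp, genetic_sd, groups=None) -> pd.DataFrame:
    """MEAN and MAX of |GEBV - IGP| per trait (and group), in genetic-SD units."""
    g, v = _paired(gebv, igp)
    n, t = g.shape
    groups = np.asarray(groups) if groups is not None else np.full(n, "all")
    sd = np.asarray(genetic_sd, dtype=float)
    rows = []
    for grp in np.unique(groups):
        d = np.abs(g[groups == grp] - v[groups == grp]) / sd
        for tdx in range(t):
            rows.append((tdx, grp, d[:, tdx].mean(), d[:, tdx].max()))
    return pd.DataFrame(rows, columns=["trait", "group", "mean", "max"])


def genetic_trend(values, birth_years, genetic_sd, window=None) -> np.ndarray:
    """Standardized genetic trend: slope of cohort means on birth year / sd.

    ``values`` is (n_animals, n_traits) of breeding values (true or
    estimated); ``window`` optionally restricts to (first_year, last_year)
    inclusive. Requires at least two cohorts.
    """
    vals = np.atleast_2d(np.asarray(values, dtype=float))
    if vals.shape[0] == 1:
        vals = vals.T
    years = np.asarray(birth_years)
    if window is not None:
        keep = (years >= window[0]) & (years <= window[1])
        vals, years = vals[keep], years[keep]
    uniq = np.unique(years)
    if uniq.size < 2:
        raise ValueError("genetic trend needs at least two birth-year cohorts")
    sd = np.asarray(genetic_sd, dtype=float)
    means = np.array([vals[years == y].mean(axis=0) for y in uniq])
    return np.array([linregress(uniq, means[:, tdx]).slope / sd[tdx] for tdx in range(vals.shape[1])])


def correlate_with_trend(report: pd.DataFrame, statistics=STATISTICS, decimals: int = 2) -> pd.DataFrame:
    """Pearson correlations, across traits, of the genetic trend with each
    diagnostic, per group (reported at ``decimals`` places).

    Requires >= 3 traits; a statistic with zero variance across traits gives
    NaN and is flagged.
    """
    rows = []
    for grp, sub in report.groupby("group"):
        if len(sub) < 3:
            raise ValueError("trend correlations need at least 3 traits")
        dg = sub["dg"].to_numpy(dtype=float)
        for stat in statistics:
            s = sub[stat].to_numpy(dtype=float)
            if np.ptp(s) == 0.0 or np.ptp(dg) == 0.0:
                rows.append((grp, stat, np.nan, True))
                continue
            rows.append((grp, stat, round(float(pearsonr(dg, s)[0]), decimals), False))
    return pd.DataFrame(rows, columns=["group", "statistic", "correlation", "degenerate"])


def build_report(gebv, igp, groups, genetic_sd, dg) -> ValidationReport:
    """Assemble the full per-trait report and (with >= 3 traits) the trend
    correlations. ``dg`` is the per-trait standardized genetic trend."""
    reg = regress_gebv_on_igp(gebv, igp, groups, genetic_sd)
    ad = abs_diff_stats(gebv, igp, genetic_sd, groups)
    per_trait = reg.merge(ad, on=["trait", "group"])
    dg = np.asarray(dg, dtype=float)
    per_trait["dg"] = dg[per_trait["trait"].to_numpy()]
    corr = None
    if dg.size >= 3:
        corr = correlate_with_trend(per_trait)
    return ValidationReport(per_trait, corr)
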