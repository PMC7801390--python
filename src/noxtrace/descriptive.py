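"""Descriptive statistics: spatial group comparisons and temporal trends.

Comparisons operate on site means (replicates are averaged per site first):
one-way ANOVA across regions within each site class, and Welch two-sample
tests between urban and non-urban sites within each region.  Temporal trends
are ordinary least-squares fits of site-year mean delta15N on year with a
Pearson correlation and a pointwise 95% confidence band for the mean
response.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = ["GroupComparison", "TrendFit", "compare_groups", "fit_trend",
           "site_means", "site_year_means"]


@dataclass(frozen=True)
class GroupComparison:
    test: str                     # "anova_regions" | "urban_vs_non_urban"
    groups: tuple[str, ...]
    means: tuple[float, ...]
    sds: tuple[float, ...]
    n: tuple[int, ...]
    statistic: float
    p_value: float
    significant: bool
    alpha: float


@dataclass(frozen=True)
class TrendFit:
    slope: float                  # permil per year
    intercept: float
    pearson_r: float
    p_value: float
    ci95_band: pd.DataFrame = field(repr=False)  # year, fit, lo, hi


def site_means(observations: pd.DataFrame) -> pd.DataFrame:
    """Mean delta15N per site (replicates and years pooled)."""
    return (
        observations.groupby(["region", "site_class", "site_id"], as_index=False)
        ["delta15n_permil"].mean()
    )


def site_year_means(observations: pd.DataFrame) -> pd.DataFrame:
    """Mean delta15N per site and year."""
    return (
        observations.groupby(
            ["region", "site_class", "site_id", "year"], as_index=False
        )["delta15n_permil"].mean()
    )


def _group_summary(values: list[np.ndarray]) -> tuple[tuple, tuple, tuple]:
    means = tuple(float(v.mean()) for v in values)
    sds = tuple(float(v.std(ddof=1)) if v.size > 1 else 0.0 for v in values)
    ns = tuple(int(v.size) for v in values)
    return means, sds, ns


def compare_groups(
    observations: pd.DataFrame, alpha: float = 0.1
) -> list[GroupComparison]:
    """Region and urban/non-urban comparisons of site-mean delta15N.

    Groups with fewer than two sites are skipped with a warning.  The
    default significance level is 0.1, appropriate for the high natural
    variability of precipitation-nitrate delta15N.
    """
    sites = site_means(observations)
    results: list[GroupComparison] = []

    for site_class, sub in sites.groupby("site_class"):
        groups = {r: g["delta15n_permil"].to_numpy()
                  for r, g in sub.groupby("region")}
        usable = {r: v for r, v in groups.items() if v.size >= 2}
        if len(usable) < len(groups):
            warnings.warn(
                f"skipping degenerate region groups in {site_class} comparison",
                stacklevel=2,
            )
        if len(usable) >= 2:
            values = list(usable.values())
            stat, p = stats.f_oneway(*values)
            if not np.isfinite(p):
                # identical groups: round-off can drive F epsilon-negative
                stat, p = max(float(stat), 0.0), 1.0
            means, sds, ns = _group_summary(values)
            results.append(GroupComparison(
                test=f"anova_regions[{site_class}]",
                groups=tuple(usable), means=means, sds=sds, n=ns,
                statistic=float(stat), p_value=float(p),
                significant=bool(p < alpha), alpha=alpha,
            ))

    for region, sub in sites.groupby("region"):
        groups = {c: g["delta15n_permil"].to_numpy()
                  for c, g in sub.groupby("site_class")}
        if not all(v.size >= 2 for v in groups.values()) or len(groups) < 2:
            warnings.warn(
                f"skipping urban/non-urban comparison for {region}: "
                "fewer than two sites in a class",
                stacklevel=2,
            )
            continue
        a, b = (groups[c] for c in sorted(groups))
        stat, p = stats.ttest_ind(a, b, equal_var=False)
        means, sds, ns = _group_summary([a, b])
        results.append(GroupComparison(
            test=f"urban_vs_non_urban[{region}]",
            groups=tuple(sorted(groups)), means=means, sds=sds, n=ns,
            statistic=float(stat), p_value=float(p),
            significant=bool(p < alpha), alpha=alpha,
        ))
    return results


def fit_trend(site_year_mean_table: pd.DataFrame | list[tuple[int, float]]) -> TrendFit:
    """Linear trend of annual mean delta15N with a 95% confidence band.

    Accepts ``(year, delta15N)`` pairs or a frame with ``year`` and
    ``delta15n_permil`` columns; requires at least three distinct years.
    """
    if isinstance(site_year_mean_table, pd.DataFrame):
        years = site_year_mean_table["year"].to_numpy(dtype=float)
        deltas = site_year_mean_table["delta15n_permil"].to_numpy(dtype=float)
    else:
        arr = np.asarray(site_year_mean_table, dtype=float)
        years, deltas = arr[:, 0], arr[:, 1]
    if np.unique(years).size < 3:
        raise ValueError("trend fitting requires at least 3 distinct years")

    model = sm.OLS(deltas, sm.add_constant(years)).fit()
    r, p = stats.pearsonr(years, deltas)
    grid = np.unique(years)
    pred = model.get_prediction(sm.add_constant(grid))
    ci = pred.conf_int(alpha=0.05)
    band = pd.DataFrame({
        "year": grid.astype(int),
        "fit": pred.predicted_mean,
        "lo": ci[:, 0],
        "hi": ci[:, 1],
    })
    return TrendFit(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        pearson_r=float(r),
        p_value=float(p),
        ci95_band=band,
    )
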