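"""Whole-domain annual aggregation indicators.

Presence area, concentration curves, the space selectivity index (a Gini-type
concentration measure: twice the area between the concentration curve and the
diagonal), per-year summaries, and stock OLS regressions of indicators on the
annual log-biomass index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .survey import LogTransformSpec, SurveyDataset


@dataclass
class ConcentrationCurve:
    """Maximum proportion of biomass as a function of proportion of samples.

    Vertices start at (0, 0) and end at (1, 1); a homogeneously distributed
    population gives the first diagonal, and the further the curve lies above
    the diagonal the more spatially concentrated the population.
    """

    sample_fraction: np.ndarray
    biomass_fraction: np.ndarray

    def __post_init__(self) -> None:
        sf, bf = self.sample_fraction, self.biomass_fraction
        if sf[0] != 0 or bf[0] != 0:
            raise ValueError("curve must start at (0, 0)")
        if abs(sf[-1] - 1) > 1e-12 or abs(bf[-1] - 1) > 1e-12:
            raise ValueError("curve must end at (1, 1)")
        if np.any(np.diff(sf) < 0) or np.any(np.diff(bf) < -1e-12):
            raise ValueError("curve fractions must be non-decreasing")


def presence_area(values) -> float:
    """Percentage of sampled points where the species is present (> 0)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty input")
    return 100.0 * float((v > 0).sum()) / v.size


def concentration_curve(values) -> ConcentrationCurve:
    """Concentration curve: values ranked in decreasing order, cumulative
    biomass fraction against cumulative sample fraction."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty input")
    total = v.sum()
    if total <= 0:
        raise ValueError("total biomass must be > 0")
    ranked = np.sort(v)[::-1]
    n = v.size
    sf = np.concatenate([[0.0], np.arange(1, n + 1) / n])
    bf = np.concatenate([[0.0], np.cumsum(ranked) / total])
    return ConcentrationCurve(sf, bf)


def space_selectivity_index(values) -> float:
    """Twice the area between the concentration curve and the first diagonal.

    0 for a homogeneous distribution, approaching 1 for extreme spatial
    concentration (exactly 1 - 1/n when a single EDSU holds all biomass).
    Equals the Gini coefficient of the biomass distribution.
    """
    curve = concentration_curve(values)
    area = float(np.trapezoid(curve.biomass_fraction, curve.sample_fraction))
    return 2.0 * (area - 0.5)


def annual_summaries(
    dataset: SurveyDataset, spec: LogTransformSpec = LogTransformSpec()
) -> pd.DataFrame:
    """One row per year x species with the global aggregation indicators.

    Columns: presence_area_pct, total_biomass, log_biomass (ln of the total,
    NaN for an empty year), mean_density_presence (tons per occupied EDSU),
    cv_biomass (sample SD / mean over all EDSUs), selectivity.
    """
    rows = []
    for year in dataset.years:
        for sp in dataset.species:
            v = dataset.values(sp, year)
            total = float(v.sum())
            present = v > 0
            rows.append(
                {
                    "year": year,
                    "species": sp,
                    "presence_area_pct": presence_area(v),
                    "total_biomass": total,
                    "log_biomass": float(np.log(total)) if total > 0 else np.nan,
                    "mean_density_presence": float(v[present].mean()) if present.any() else np.nan,
                    "cv_biomass": float(v.std(ddof=1) / v.mean()) if v.mean() > 0 else np.nan,
                    "selectivity": space_selectivity_index(v) if total > 0 else np.nan,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class RegressionSummary:
    """Simple OLS of an annual indicator on the log-biomass index.

    A stock statsmodels fit, reported for completeness; not bespoke method
    content.
    """

    slope: float
    intercept: float
    r2_adj: float
    p_value: float
    n: int


def metric_vs_logbiomass(metric, logbiomass) -> RegressionSummary:
    """OLS regression metric ~ log-biomass with adjusted R-squared and the
    two-sided p-value of the slope."""
    y = np.asarray(metric, dtype=float)
    x = np.asarray(logbiomass, dtype=float)
    if y.shape != x.shape:
        raise ValueError("metric and logbiomass must have equal length")
    if y.size < 3:
        raise ValueError("need at least 3 years")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionSummary(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r2_adj=float(fit.rsquared_adj),
        p_value=float(fit.pvalues[1]),
        n=int(y.size),
    )
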