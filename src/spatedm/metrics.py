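"""Survey-derived population statistics.

From a long-format CPUE table this module computes, per biquarterly step:

* population spatial variability — the coefficient of variation (CV) of
  total CPUE over subareas, ``CV_q = sigma_q / mu_q``,
* age diversity — the Shannon entropy of the age-class CPUE composition,
* total abundance — CPUE summed over subareas and classes,

plus the filtering rules applied before any of them (drop subareas that
are zero throughout the survey; drop quarters surveyed in fewer than
``min_grids`` subareas), the detrend/normalise preprocessing used before
any state-space analysis, yearly averaging, and the Taylor's-power-law fit
``log V = log a + b log M`` whose exponent ``b`` measures aggregation
tendency (under ``V = a M^b`` the spatial CV scales as ``M^(b/2 - 1)``, so
``b = 2`` is the neutral point of the CV-abundance relationship).

Conventions fixed here for reproducibility: sample standard deviation
(denominator n-1) throughout, natural logarithms for Shannon and Taylor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import QuarterSeries, SurveyTable
from .errors import (
    DegenerateSeriesError,
    EmptyDataError,
    InsufficientDataError,
)

__all__ = [
    "TaylorFit",
    "filter_survey",
    "spatial_cv",
    "age_diversity",
    "total_abundance",
    "preprocess",
    "to_yearly",
    "fit_taylor",
    "cv_abundance_direction",
]

logger = logging.getLogger(__name__)

#: minimum series length for empirical dynamic modeling to be viable
EDM_MIN_LENGTH = 30


def filter_survey(table: SurveyTable, min_grids: int = 10) -> SurveyTable:
    """Apply the survey retention rules, grids first then time points.

    1. Remove subareas whose CPUE is zero at every time step they were
       surveyed (the species never inhabited them).
    2. Remove quarter steps surveyed in fewer than ``min_grids`` distinct
       subareas (spatial statistics would be biased).
    """
    df = table.records
    if not len(df):
        raise EmptyDataError("survey table has no records")

    sub_tot = df.groupby("subarea")["cpue"].sum()
    dead = sub_tot.index[sub_tot == 0]
    if len(dead):
        logger.info(
            "filter_survey[always_zero_subarea]: removed %d subareas: %s",
            len(dead), ", ".join(map(str, dead)),
        )
        df = df[~df["subarea"].isin(dead)]

    n_sub = df.groupby("quarter_step")["subarea"].nunique()
    thin = n_sub.index[n_sub < min_grids]
    if len(thin):
        logger.info(
            "filter_survey[too_few_grids]: removed %d quarter steps (<%d subareas): %s",
            len(thin), min_grids, ", ".join(map(str, thin)),
        )
        df = df[~df["quarter_step"].isin(thin)]

    if not len(df):
        raise EmptyDataError("no records remain after filtering")
    n_steps = df["quarter_step"].nunique()
    if n_steps < EDM_MIN_LENGTH:
        logger.warning(
            "filter_survey[short_series]: %d retained time steps (< %d); "
            "empirical dynamic modeling may be unreliable",
            n_steps, EDM_MIN_LENGTH,
        )
    return table.replace_records(df)


def _grid_series(table: SurveyTable, name: str, per_step: pd.Series, **extra) -> QuarterSeries:
    values = np.full(table.n_steps, np.nan)
    values[per_step.index.to_numpy()] = per_step.to_numpy()
    arrays = {}
    for key, series in extra.items():
        arr = np.full(table.n_steps, np.nan)
        arr[series.index.to_numpy()] = series.to_numpy()
        arrays[key] = arr
    return QuarterSeries(
        name=name,
        values=values,
        years=table.grid["year"].to_numpy(),
        quarters=table.grid["quarter"].to_numpy(),
        **arrays,
    )


def spatial_cv(table: SurveyTable) -> QuarterSeries:
    """Spatial CV of total CPUE over subareas, per quarter step.

    Total CPUE per subarea sums over classes; the CV uses the sample SD.
    Quarters with zero mean CPUE (CV undefined) or a single surveyed
    subarea are excluded (NaN) with a log entry.
    """
    totals = table.totals_by_subarea()
    g = totals.groupby("quarter_step")["cpue"]
    mu = g.mean()
    sigma = g.std(ddof=1)
    n = g.size()
    cv = sigma / mu
    undefined = mu.index[(mu == 0) | (n < 2)]
    if len(undefined):
        logger.info(
            "spatial_cv[undefined]: excluded %d quarter steps (zero mean or <2 subareas): %s",
            len(undefined), ", ".join(map(str, undefined)),
        )
        cv.loc[undefined] = np.nan
    return _grid_series(table, "spatial_cv", cv, mu=mu, sigma=sigma)


def age_diversity(table: SurveyTable) -> QuarterSeries:
    """Shannon entropy of the age-class CPUE distribution, per quarter step.

    ``Shannon_q = -sum_a p_qa ln p_qa`` with ``p_qa`` the share of age
    class ``a`` in the quarter's total CPUE (summed over subareas); zero
    shares contribute nothing.  All-zero quarters are undefined.
    """
    if table.class_kind != "age":
        raise ValueError("age_diversity needs an age-classed table")
    by_age = table.records.groupby(["quarter_step", "class_id"])["cpue"].sum()

    def entropy(g: pd.Series) -> float:
        tot = g.sum()
        if tot == 0:
            return np.nan
        p = (g / tot).to_numpy()
        p = p[p > 0]
        return float(-(p * np.log(p)).sum())

    sh = by_age.groupby(level="quarter_step").agg(entropy)
    bad = sh.index[sh.isna()]
    if len(bad):
        logger.info(
            "age_diversity[all_zero]: excluded %d quarter steps: %s",
            len(bad), ", ".join(map(str, bad)),
        )
    return _grid_series(table, "age_diversity", sh)


def total_abundance(table: SurveyTable) -> QuarterSeries:
    """Total CPUE per quarter step (sum over subareas and classes)."""
    tot = table.records.groupby("quarter_step")["cpue"].sum()
    return _grid_series(table, "abundance", tot)


def preprocess(series: QuarterSeries, alpha_trend: float = 0.05) -> QuarterSeries:
    """Remove a significant linear trend, then z-score.

    An ordinary least-squares regression of the values on the time index is
    fitted; if the slope is significant (two-sided p < ``alpha_trend``) the
    residuals replace the values.  The series is then normalised to sample
    mean 0 and sample SD 1.  NaN steps are carried through untouched.
    """
    v = series.values.astype(float).copy()
    ok = np.isfinite(v)
    if ok.sum() < 5:
        raise InsufficientDataError("preprocess needs >= 5 finite values")
    t = np.nonzero(ok)[0].astype(float)
    x = v[ok]
    detrended = False
    fit = stats.linregress(t, x)
    if fit.pvalue < alpha_trend:
        x = x - (fit.intercept + fit.slope * t)
        detrended = True
        logger.info(
            "preprocess[detrended]: %s slope=%.4g p=%.3g", series.name, fit.slope, fit.pvalue
        )
    sd = x.std(ddof=1)
    if not np.isfinite(sd) or sd < 1e-12:
        raise DegenerateSeriesError(f"{series.name}: zero variance after detrending")
    x = (x - x.mean()) / sd
    v[ok] = x
    return series.with_values(
        v,
        normalized=True,
        detrended=detrended,
        detrend_slope=float(fit.slope),
        detrend_pvalue=float(fit.pvalue),
    )


def to_yearly(series: QuarterSeries) -> QuarterSeries:
    """Average the Q1/Q3 values within each year (yearly-grid series).

    Years with no finite value get NaN on the (consecutive) yearly grid.
    """
    if series.grid != "biquarterly":
        raise ValueError("to_yearly expects a biquarterly series")
    years = np.arange(series.years.min(), series.years.max() + 1)
    values = np.full(years.size, np.nan)
    for i, yr in enumerate(years):
        vals = series.values[(series.years == yr) & np.isfinite(series.values)]
        if vals.size:
            values[i] = vals.mean()
    return QuarterSeries(name=series.name, values=values, years=years, quarters=None)


@dataclass
class TaylorFit:
    """Taylor's power law ``V = a M^b`` fitted in log-log space.

    ``points`` holds one (log M, log V) pair per usable quarter, with M and
    V the spatial mean and sample variance of total CPUE over subareas.
    """

    a: float
    b: float
    r_squared: float
    points: pd.DataFrame  # columns quarter_step, log_M, log_V

    @property
    def n_points(self) -> int:
        return len(self.points)


def fit_taylor(table: SurveyTable) -> TaylorFit:
    """Fit ``log V = log a + b log M`` over quarters.

    Quarters need a positive spatial mean, positive sample variance and at
    least 3 surveyed subareas; fewer than 3 usable quarters is an error.
    """
    totals = table.totals_by_subarea()
    g = totals.groupby("quarter_step")["cpue"]
    M = g.mean()
    V = g.var(ddof=1)
    n = g.size()
    usable = (M > 0) & (V > 0) & (n >= 3)
    dropped = int((~usable).sum())
    if dropped:
        logger.info("fit_taylor[unusable_quarters]: excluded %d quarter steps", dropped)
    M, V = M[usable], V[usable]
    if len(M) < 3:
        raise InsufficientDataError(f"Taylor fit needs >= 3 usable quarters, got {len(M)}")
    logM, logV = np.log(M.to_numpy()), np.log(V.to_numpy())
    fit = stats.linregress(logM, logV)
    points = pd.DataFrame(
        {"quarter_step": M.index.to_numpy(), "log_M": logM, "log_V": logV}
    )
    return TaylorFit(
        a=float(np.exp(fit.intercept)),
        b=float(fit.slope),
        r_squared=float(fit.rvalue**2),
        points=points,
    )


def cv_abundance_direction(fit: TaylorFit, tol: float = 1e-6) -> str:
    """Sign of the CV-abundance relationship implied by the Taylor exponent.

    Under ``V = a M^b`` the spatial CV is ``a' M^(b/2 - 1)``: it falls with
    abundance for ``b < 2`` ("negative"), rises for ``b > 2`` ("positive"),
    and is abundance-independent at ``b = 2`` ("neutral").
    """
    if abs(fit.b - 2.0) < tol:
        return "neutral"
    return "negative" if fit.b < 2.0 else "positive"
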