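"""Step-change detection and step/trend decomposition of annual series.

The Pettitt test locates a single step change in a series through the
Mann–Whitney-type statistic

    U_t = sum_{i<=t} sum_{j>t} sign(x_j - x_i),   t = 1..n-1,

with K = max_t |U_t| and the approximate two-sided significance
p = 2·exp(-6 K² / (n³ + n²)).  Significant series are then split at the
detected change year and ordinary least squares is fitted to each side;
the *step offset* is the gap between the two segment fits evaluated at
the change year, and the post-change slope carries the gradual trend.

DIF is the series' end-minus-start change (2010 value − 1850 value by
default) and ABS its end value; together with the step/trend split they
summarize how much of a site's isotopic shift is attributable to an
abrupt event (e.g. harbor-inlet construction in 1946) versus a gradual
driver (e.g. rising fertilizer use, 1940–1980).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .core import WaterQualityRecord, annual_mean_water_quality


@dataclass(frozen=True)
class PettittResult:
    """Outcome of the Pettitt single change-point test.

    ``change_index`` is the number of points before the change (the split
    is between 0-based indices change_index−1 and change_index);
    ``change_year`` is the last year of the pre-change regime — the change
    occurs immediately *after* it, matching the usual reporting convention
    of the test.  Both are None for a constant series (K = 0).
    """

    n: int
    k_stat: float
    u_trace: np.ndarray
    p_value: float
    change_index: int | None
    change_year: float | None

    @property
    def significant(self) -> bool:
        return self.change_year is not None and self.p_value < 0.05


def pettitt(series: pd.Series) -> PettittResult:
    """Pettitt test on an annual series (index = years, values = variable).

    Requires n ≥ 10 with no missing values; ties in |U_t| resolve to the
    earliest candidate index.
    """
    x = np.asarray(series.values, dtype=float)
    years = np.asarray(series.index, dtype=float)
    n = len(x)
    if n < 10:
        raise ValueError(f"need at least 10 points, got {n}")
    if np.isnan(x).any():
        raise ValueError("series contains missing values; interpolate or drop first")

    sgn = np.sign(x[None, :] - x[:, None])  # sgn[i, j] = sign(x_j - x_i)
    csum = np.cumsum(np.cumsum(sgn, axis=0), axis=1)
    # U_t = sum of sgn[0:t, t:n]  (t = number of points before the change)
    t_idx = np.arange(1, n)
    u = csum[t_idx - 1, n - 1] - np.where(t_idx - 1 >= 0, csum[t_idx - 1, t_idx - 1], 0.0)
    k = float(np.max(np.abs(u)))
    p = min(1.0, 2.0 * math.exp(-6.0 * k**2 / (n**3 + n**2)))
    if k == 0:
        return PettittResult(n, 0.0, u, 1.0, None, None)
    t = int(np.argmax(np.abs(u))) + 1  # earliest argmax, 1-based count before
    return PettittResult(n, k, u, p, t, float(years[t - 1]))


def pettitt_brute_force(series: pd.Series) -> PettittResult:
    """O(n²) double-loop reference implementation of the Pettitt statistic.

    Kept deliberately naive as an independent oracle for the vectorized
    :func:`pettitt`.
    """
    x = np.asarray(series.values, dtype=float)
    years = np.asarray(series.index, dtype=float)
    n = len(x)
    u = np.zeros(n - 1)
    for t in range(1, n):
        total = 0.0
        for i in range(t):
            for j in range(t, n):
                d = x[j] - x[i]
                total += int(d > 0) - int(d < 0)
        u[t - 1] = total
    k = float(np.max(np.abs(u)))
    p = min(1.0, 2.0 * math.exp(-6.0 * k**2 / (n**3 + n**2)))
    if k == 0:
        return PettittResult(n, 0.0, u, 1.0, None, None)
    t = int(np.argmax(np.abs(u))) + 1
    return PettittResult(n, k, u, p, t, float(years[t - 1]))


# ---------------------------------------------------------------------------
# split regression


@dataclass
class Decomposition:
    """Step + trend decomposition of one site's annual series.

    ``step_offset`` is (after-fit prediction − before-fit prediction) at
    the change year; slopes are per-year with OLS standard errors.  DIF is
    value(end) − value(start); ABS is value(end).  ``fraction_before_year``
    evaluates the fitted piecewise-linear model to report the proportion of
    the total fitted change realized before a given year.
    """

    change_year: float | None
    step_offset: float | None
    slope_before: float | None
    slope_after: float | None
    se_slope_before: float | None
    se_slope_after: float | None
    intercept_before: float | None  # fit evaluated at the change year
    intercept_after: float | None
    n_before: int
    n_after: int
    start_year: float
    end_year: float
    dif: float
    abs_value: float
    flags: dict = field(default_factory=dict)

    def fitted(self, year: float) -> float:
        """Fitted piecewise value at ``year`` (segment fits, change at change_year)."""
        if self.change_year is None:
            if self.slope_after is None or self.intercept_after is None:
                raise ValueError("no fitted model available")
            return self.intercept_after + self.slope_after * (year - self.end_year)
        if year <= self.change_year:
            if self.slope_before is None:
                raise ValueError("before-side fit unavailable")
            return self.intercept_before + self.slope_before * (year - self.change_year)
        if self.slope_after is None:
            raise ValueError("after-side fit unavailable")
        return self.intercept_after + self.slope_after * (year - self.change_year)

    @property
    def fitted_total_change(self) -> float:
        return self.fitted(self.end_year) - self.fitted(self.start_year)

    def fraction_before_year(self, year: float = 1988.0) -> float:
        """Proportion of the fitted total change realized before ``year``."""
        total = self.fitted_total_change
        if total == 0:
            raise ValueError("zero fitted total change; fraction undefined")
        frac = (self.fitted(year) - self.fitted(self.start_year)) / total
        return float(np.clip(frac, 0.0, 1.0))


def _ols_line(years: np.ndarray, values: np.ndarray, at_year: float):
    """OLS of value on year; returns (slope, se_slope, prediction at at_year)."""
    res = stats.linregress(years, values)
    pred = res.intercept + res.slope * at_year
    return float(res.slope), float(res.stderr), float(pred)


def split_regression(series: pd.Series, change_year: float) -> Decomposition:
    """Fit OLS separately before (≤ change_year) and after (> change_year).

    The change year is the last pre-change year, so the before side is
    inclusive of it.  Either side with fewer than 3 points leaves that
    side's slope (and the step offset) undefined rather than extrapolating.
    """
    years = np.asarray(series.index, dtype=float)
    vals = np.asarray(series.values, dtype=float)
    before = years <= change_year
    after = ~before
    flags: dict = {}

    sb = seb = pb = None
    sa = sea = pa = None
    if before.sum() >= 3:
        sb, seb, pb = _ols_line(years[before], vals[before], change_year)
    else:
        flags["before_side_too_short"] = int(before.sum())
    if after.sum() >= 3:
        sa, sea, pa = _ols_line(years[after], vals[after], change_year)
    else:
        flags["after_side_too_short"] = int(after.sum())

    offset = (pa - pb) if (pa is not None and pb is not None) else None
    dif, abs_value = dif_abs(series, start_year=years[0], end_year=years[-1])
    return Decomposition(
        change_year=float(change_year),
        step_offset=offset,
        slope_before=sb,
        slope_after=sa,
        se_slope_before=seb,
        se_slope_after=sea,
        intercept_before=pb,
        intercept_after=pa,
        n_before=int(before.sum()),
        n_after=int(after.sum()),
        start_year=float(years[0]),
        end_year=float(years[-1]),
        dif=dif,
        abs_value=abs_value,
        flags=flags,
    )


def decompose(
    series: pd.Series,
    harbor_year: float = 1946.0,
    harbor_tolerance: float = 10.0,
    alpha: float = 0.05,
) -> Decomposition:
    """Pettitt test followed by split regression at the detected change year.

    When the change point is significant at ``alpha`` the result carries
    ``step_attributed_to_inlet`` (change year within harbor_year ±
    harbor_tolerance) and the step/trend contributions to total change
    (step_offset, and slope_after × (end_year − change_year)).  An
    insignificant test returns a trend-only decomposition over the full
    series, flagged accordingly.
    """
    pt = pettitt(series)
    years = np.asarray(series.index, dtype=float)
    vals = np.asarray(series.values, dtype=float)
    if not (pt.change_year is not None and pt.p_value < alpha):
        slope, se, pred_end = _ols_line(years, vals, years[-1])
        dif, abs_value = dif_abs(series, start_year=years[0], end_year=years[-1])
        d = Decomposition(
            change_year=None,
            step_offset=None,
            slope_before=None,
            slope_after=slope,
            se_slope_before=None,
            se_slope_after=se,
            intercept_before=None,
            intercept_after=pred_end,
            n_before=0,
            n_after=len(series),
            start_year=float(years[0]),
            end_year=float(years[-1]),
            dif=dif,
            abs_value=abs_value,
            flags={
                "change_significant": False,
                "pettitt_p": pt.p_value,
                "step_attributed_to_inlet": False,
            },
        )
        return d
    d = split_regression(series, pt.change_year)
    d.flags["change_significant"] = True
    d.flags["pettitt_p"] = pt.p_value
    d.flags["pettitt_k"] = pt.k_stat
    d.flags["step_attributed_to_inlet"] = abs(pt.change_year - harbor_year) <= harbor_tolerance
    if d.step_offset is not None and d.slope_after is not None:
        d.flags["step_component"] = d.step_offset
        d.flags["trend_component"] = d.slope_after * (d.end_year - d.change_year)
    return d


# ---------------------------------------------------------------------------
# summaries


def dif_abs(
    series: pd.Series,
    start_year: float = 1850.0,
    end_year: float = 2010.0,
    tolerance: float = 5.0,
) -> tuple[float, float]:
    """(DIF, ABS): end-minus-start change and absolute end value.

    Uses the nearest observed year within ``tolerance`` of each endpoint
    (exact years preferred); raises if an endpoint has no year within
    tolerance.
    """
    years = np.asarray(series.index, dtype=float)

    def nearest(y: float) -> float:
        d = np.abs(years - y)
        i = int(np.argmin(d))
        if d[i] > tolerance:
            raise ValueError(f"no observation within {tolerance} yr of {y}")
        return float(series.iloc[i])

    v_end = nearest(end_year)
    v_start = nearest(start_year)
    return v_end - v_start, v_end


def interpolate_missing(series: pd.Series) -> pd.Series:
    """Linear interpolation of missing annual values (flag upstream)."""
    return series.interpolate(method="index", limit_direction="both")


# ---------------------------------------------------------------------------
# water-quality pairing


@dataclass
class WaterQualityPairing:
    table: pd.DataFrame  # year, sediment, no3, salinity, n_months
    r_no3: float  # Pearson correlation, sediment vs NO3
    p_no3: float
    n: int
    flags: dict = field(default_factory=dict)


def pair_with_water_quality(
    sediment_series: pd.Series,
    wq_records: Iterable[WaterQualityRecord],
    station: str,
    start_year: int = 1990,
    end_year: int = 2010,
) -> WaterQualityPairing:
    """Join annual-mean water quality with same-year sediment values.

    Reports the Pearson correlation between sediment values and annual
    mean NO3 over the overlapping years (≥3 required for a correlation;
    constant inputs leave it undefined and flagged).
    """
    records = list(wq_records)
    rows = []
    for year in range(start_year, end_year + 1):
        if year not in sediment_series.index:
            continue
        wq = annual_mean_water_quality(records, station, year)
        if wq.n_months == 0:
            continue
        rows.append(
            {
                "year": year,
                "sediment": float(sediment_series.loc[year]),
                "no3": wq.no3,
                "salinity": wq.salinity,
                "n_months": wq.n_months,
            }
        )
    table = pd.DataFrame(rows, columns=["year", "sediment", "no3", "salinity", "n_months"])
    flags: dict = {}
    r = p = math.nan
    if len(table) < 3:
        flags["too_few_overlapping_years"] = len(table)
    elif np.std(table["no3"]) == 0 or np.std(table["sediment"]) == 0:
        flags["constant_input"] = True
    else:
        r, p = stats.pearsonr(table["sediment"], table["no3"])
    return WaterQualityPairing(table, float(r), float(p), len(table), flags)
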