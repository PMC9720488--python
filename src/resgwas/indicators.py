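"""Resilience indicators from longitudinal egg production.

Weekly egg counts are the interval collection records aggregated into age
weeks (week ``w`` covers days of age ``7(w-1) .. 7w-1``). Each hen's weekly
deviation is her observed count minus the batch mean for that week, and the
three resilience indicators summarise the deviation series per period:

* ``LNvar`` — natural log of the sample variance (n-1 denominator),
* ``Skew``  — moment skewness m3 / m2^(3/2) (central moments, n denominator),
* ``Rauto`` — lag-one serial autocorrelation (single mean, full-sum
  denominator), bounded in [-1, 1].

Indicators are computed for two laying periods, weeks [25, 83) and week 83
to end of life, and set to missing for any hen laying fewer than
``min_eggs`` (default 20) eggs in a period.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import EggLogSet

__all__ = [
    "InputError",
    "weekly_counts",
    "weekly_production",
    "batch_mean",
    "deviations",
    "ln_variance",
    "skewness",
    "lag1_autocorrelation",
    "resilience_indicators",
    "DEFAULT_PERIODS",
    "MIN_EGGS",
]

DEFAULT_PERIODS: tuple[tuple[int, int | None], ...] = ((25, 83), (83, None))
MIN_EGGS = 20


class InputError(ValueError):
    """Raised for malformed egg-log input."""


def _period_label(start: int, stop: int | None) -> str:
    return f"{start}-{stop if stop is not None else 'end'}"


# ---------------------------------------------------------------------------
# weekly aggregation
# ---------------------------------------------------------------------------


def weekly_counts(
    days: np.ndarray, eggs: np.ndarray, coverage_start: int = 0
) -> pd.Series:
    """Aggregate one hen's collection records into weekly counts.

    Each record's eggs are assigned to the age week containing its
    collection day (no proration across week boundaries). Weeks only
    partially covered by the registration window — the week containing
    ``coverage_start`` if it starts mid-week, and the final week if the
    last collection precedes its end — are dropped.
    """
    days = np.asarray(days, dtype=int)
    eggs = np.asarray(eggs, dtype=int)
    if days.size == 0:
        return pd.Series(dtype=int, name="eggs")
    if np.any(np.diff(days) <= 0):
        raise InputError("collection days must be strictly increasing")
    if np.any(eggs < 0):
        raise InputError("egg counts must be non-negative")
    week = days // 7 + 1
    sums = pd.Series(eggs).groupby(pd.Series(week)).sum()
    last_day = days[-1]
    first_full = coverage_start // 7 + (1 if coverage_start % 7 == 0 else 2)
    keep = sums.index[(sums.index >= first_full) & (sums.index * 7 - 1 <= last_day)]
    out = sums.loc[keep]
    if len(out):
        out = out.reindex(np.arange(out.index.min(), out.index.max() + 1), fill_value=0)
    out.index.name = "week"
    out.name = "eggs"
    return out


def weekly_production(logs: EggLogSet, coverage_start: int = 0) -> pd.DataFrame:
    """Vectorised weekly aggregation for a whole batch.

    Returns a wide frame (hens x weeks of age) of integer counts with NaN
    for unobserved weeks (before full coverage or after death).
    """
    rec = logs.records
    if len(rec) == 0:
        return pd.DataFrame()
    if (rec["eggs"] < 0).any():
        raise InputError("egg counts must be non-negative")
    week = rec["day"] // 7 + 1
    sums = rec.groupby(["hen", week.rename("week")])["eggs"].sum()
    wide = sums.unstack("week")
    # coverage: drop a hen's final partial week(s); fill interior gaps with 0
    last_day = rec.groupby("hen")["day"].max()
    wide = wide.reindex(logs.last_day.index.intersection(wide.index, sort=False))
    weeks = wide.columns.to_numpy()
    week_end = weeks * 7 - 1
    covered = week_end[None, :] <= last_day.reindex(wide.index).to_numpy()[:, None]
    first_full = coverage_start // 7 + (1 if coverage_start % 7 == 0 else 2)
    covered &= weeks[None, :] >= first_full
    out = wide.where(covered)
    out = out.where(~covered, out.fillna(0.0))
    return out


def batch_mean(weekly: pd.DataFrame) -> pd.Series:
    """Batch mean curve: per week, the mean count over hens observed that
    week; weeks with no observed hen are excluded."""
    curve = weekly.mean(axis=0, skipna=True)
    return curve.dropna()


def deviations(weekly: pd.DataFrame, curve: pd.Series) -> pd.DataFrame:
    """Observed minus expected (batch mean) per hen-week, observed weeks only."""
    obs_weeks = weekly.columns[weekly.notna().any(axis=0)]
    missing = obs_weeks.difference(curve.index)
    if len(missing):
        raise InputError(f"batch curve undefined for observed weeks {list(missing)}")
    return weekly.sub(curve, axis=1)[curve.index.intersection(weekly.columns)]


# ---------------------------------------------------------------------------
# per-series indicators
# ---------------------------------------------------------------------------


def ln_variance(values: np.ndarray) -> float:
    """ln of the sample variance (n-1 denominator); NaN if fewer than two
    values or zero variance."""
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 2:
        return np.nan
    v = x.var(ddof=1)
    if v <= 0:
        return np.nan
    return float(np.log(v))


def skewness(values: np.ndarray) -> float:
    """Unadjusted Fisher-Pearson moment skewness m3 / m2^(3/2) (central
    moments with n denominator); NaN if fewer than three values or zero
    variance."""
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 3:
        return np.nan
    d = x - x.mean()
    m2 = np.mean(d**2)
    if m2 <= 0:
        return np.nan
    return float(np.mean(d**3) / m2**1.5)


def lag1_autocorrelation(
    values: np.ndarray,
    weeks: np.ndarray | None = None,
    method: str = "serial",
) -> float:
    """Lag-one autocorrelation of a deviation series.

    ``serial`` (default) is the standard time-series estimator
    ``r1 = sum (d_t - dbar)(d_{t+1} - dbar) / sum (d_t - dbar)^2``; it is
    bounded in [-1, 1]. ``pearson`` computes the Pearson correlation of
    lagged pairs instead. When ``weeks`` is given, only pairs of
    consecutive weeks contribute to the numerator (gaps are skipped);
    the denominator uses all present values.
    """
    x = np.asarray(values, dtype=float)
    ok = ~np.isnan(x)
    if weeks is None:
        weeks = np.arange(x.size)
    weeks = np.asarray(weeks)[ok]
    x = x[ok]
    if x.size < 3:
        return np.nan
    adjacent = np.diff(weeks) == 1
    if not adjacent.any():
        return np.nan
    if method == "pearson":
        a, b = x[:-1][adjacent], x[1:][adjacent]
        if a.size < 2 or a.std() == 0 or b.std() == 0:
            return np.nan
        return float(np.corrcoef(a, b)[0, 1])
    if method != "serial":
        raise ValueError(f"unknown Rauto method {method!r}")
    d = x - x.mean()
    denom = np.sum(d**2)
    if denom <= 0:
        return np.nan
    num = np.sum(d[:-1][adjacent] * d[1:][adjacent])
    return float(num / denom)


# ---------------------------------------------------------------------------
# per-period records
# ---------------------------------------------------------------------------


@dataclass
class FilterCounts:
    """Per-period bookkeeping of the <min_eggs filter."""

    period: str
    n_hens: int
    n_filtered_low_eggs: int
    n_no_data: int


def resilience_indicators(
    dev: pd.DataFrame,
    weekly: pd.DataFrame,
    periods: tuple[tuple[int, int | None], ...] = DEFAULT_PERIODS,
    min_eggs: int = MIN_EGGS,
    rauto_method: str = "serial",
) -> tuple[pd.DataFrame, list[FilterCounts]]:
    """One record per hen per period: LNvar, Skew, Rauto plus week and egg
    totals; all three indicators are missing for hens laying fewer than
    ``min_eggs`` eggs in the period (or with no observed weeks)."""
    rows = []
    counts: list[FilterCounts] = []
    for start, stop in periods:
        label = _period_label(start, stop)
        cols = dev.columns[(dev.columns >= start) & ((stop is None) | (dev.columns < stop))]
        n_filtered = n_no_data = 0
        for hen in dev.index:
            d = dev.loc[hen, cols].to_numpy(dtype=float)
            e = weekly.loc[hen, cols].to_numpy(dtype=float)
            obs = ~np.isnan(d)
            n_weeks = int(obs.sum())
            total = int(np.nansum(e))
            if n_weeks == 0:
                n_no_data += 1
                ln_v = sk = ra = np.nan
            elif total < min_eggs:
                n_filtered += 1
                ln_v = sk = ra = np.nan
            else:
                w = cols.to_numpy()[obs]
                ln_v = ln_variance(d[obs])
                sk = skewness(d[obs])
                ra = lag1_autocorrelation(d[obs], weeks=w, method=rauto_method)
            rows.append((hen, label, ln_v, sk, ra, n_weeks, total))
        counts.append(FilterCounts(label, len(dev.index), n_filtered, n_no_data))
    table = pd.DataFrame(
        rows,
        columns=["hen", "period", "ln_var", "skew", "r_auto", "n_weeks", "total_eggs"],
    )
    return table, counts
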