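"""Smoothed time trends of the small and large newborn composites.

Per-country annual prevalences (%) are smoothed with a centred 3-year moving
average, defined only where all three consecutive calendar years are
present.  A year is flagged as a trend change when consecutive smoothed
values differ by more than a threshold — 0.5 percentage points by default,
interpreted as absolute prevalence points, not a relative change.  Trend
series are produced only for countries with at least four country-years of
data.  Uncertainty on the raw annual percentages is a binomial standard
error under the normal approximation; this is a labelled convention, not a
replication of any particular published band.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

TREND_MIN_YEARS = 4
CHANGE_THRESHOLD_PP = 0.5
PERIODS = ((2000, 2009), (2010, 2021))

COMPOSITES = ("small", "large")


def moving_average_3(series: pd.Series) -> pd.Series:
    """Centred 3-year moving average over a year-indexed series.

    ``smoothed(t) = mean(raw(t-1), raw(t), raw(t+1))`` only where all three
    consecutive calendar years exist; endpoints and years adjacent to gaps
    are left undefined (NaN), on the original year index.
    """
    if len(series) == 0:
        return series.astype("float64")
    years = series.index.astype(int)
    full = pd.RangeIndex(years.min(), years.max() + 1)
    dense = series.reindex(full).astype("float64")
    smoothed = dense.rolling(window=3, center=True, min_periods=3).mean()
    return smoothed.reindex(years)


def eligible_for_trends(
    years_by_country: dict[str, set] | pd.Series,
    min_years: int = TREND_MIN_YEARS,
) -> dict[str, bool]:
    """Countries with at least ``min_years`` country-years of data."""
    if isinstance(years_by_country, pd.Series):
        years_by_country = years_by_country.to_dict()
    return {
        country: len(set(years)) >= min_years
        for country, years in years_by_country.items()
    }


def change_flags(
    smoothed: pd.Series, threshold_pp: float = CHANGE_THRESHOLD_PP
) -> pd.Series:
    """Flag years where the smoothed trend moved by more than the threshold.

    A year ``t`` is flagged iff ``|smoothed(t) - smoothed(t-1)|`` is strictly
    greater than ``threshold_pp`` with both values defined in consecutive
    calendar years; a change of exactly the threshold is not a flag.
    """
    years = np.asarray(smoothed.index, dtype=int)
    vals = smoothed.to_numpy(dtype="float64")
    flags = np.zeros(len(smoothed), dtype=bool)
    for i in range(1, len(smoothed)):
        if years[i] - years[i - 1] != 1:
            continue
        if np.isnan(vals[i]) or np.isnan(vals[i - 1]):
            continue
        flags[i] = abs(vals[i] - vals[i - 1]) > threshold_pp
    return pd.Series(flags, index=smoothed.index)


def binomial_se_pct(pct: pd.Series | np.ndarray, n: pd.Series | np.ndarray):
    """Binomial standard error (in percentage points) of an annual rate."""
    p = np.asarray(pct, dtype="float64") / 100.0
    n = np.asarray(n, dtype="float64")
    with np.errstate(invalid="ignore", divide="ignore"):
        return 100.0 * np.sqrt(p * (1.0 - p) / n)


def period_summary(
    smoothed: pd.Series,
    periods: tuple[tuple[int, int], ...] = PERIODS,
) -> pd.DataFrame:
    """Net change in the smoothed series over fixed calendar periods.

    Per period: last defined smoothed value minus first defined smoothed
    value within the period, with the years actually used; periods with
    fewer than two defined values report an undefined (NaN) change.
    """
    defined = smoothed.dropna()
    years = np.asarray(defined.index, dtype=int)
    rows = []
    for start, end in periods:
        inside = (years >= start) & (years <= end)
        sub = defined.iloc[np.flatnonzero(inside)]
        if len(sub) < 2:
            rows.append(
                {
                    "period_start": start,
                    "period_end": end,
                    "first_year": None,
                    "last_year": None,
                    "net_change_pp": float("nan"),
                }
            )
        else:
            rows.append(
                {
                    "period_start": start,
                    "period_end": end,
                    "first_year": int(sub.index[0]),
                    "last_year": int(sub.index[-1]),
                    "net_change_pp": float(sub.iloc[-1] - sub.iloc[0]),
                }
            )
    return pd.DataFrame(rows)


def trend_table(
    prevalence_country_year: pd.DataFrame,
    min_years: int = TREND_MIN_YEARS,
    threshold_pp: float = CHANGE_THRESHOLD_PP,
) -> pd.DataFrame:
    """Full trend output: one row per eligible country, composite and year.

    Columns: ``country``, ``composite`` (small/large), ``year``, ``raw_pct``,
    ``smoothed_pct`` (NaN where the 3-year window is incomplete), ``se_pct``
    (binomial SE of the raw annual percentage) and ``change_flag``.
    """
    prev = prevalence_country_year
    eligibility = eligible_for_trends(
        prev.groupby("country")["year"].apply(set), min_years=min_years
    )
    rows = []
    for country, block in prev.groupby("country", sort=True):
        if not eligibility[country]:
            continue
        block = block.sort_values("year")
        for composite, col in (("small", "small_composite"), ("large", "T_LGA")):
            raw = pd.Series(
                100.0 * block[col].to_numpy(), index=block["year"].astype(int)
            )
            smoothed = moving_average_3(raw)
            flags = change_flags(smoothed, threshold_pp=threshold_pp)
            se = binomial_se_pct(raw.to_numpy(), block["n"].to_numpy())
            for i, year in enumerate(raw.index):
                rows.append(
                    {
                        "country": country,
                        "composite": composite,
                        "year": int(year),
                        "raw_pct": float(raw.iloc[i]),
                        "smoothed_pct": float(smoothed.iloc[i]),
                        "se_pct": float(se[i]),
                        "change_flag": bool(flags.iloc[i]),
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "country",
            "composite",
            "year",
            "raw_pct",
            "smoothed_pct",
            "se_pct",
            "change_flag",
        ],
    )
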