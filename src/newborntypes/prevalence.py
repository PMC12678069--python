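"""Prevalence tables and cross-country median/IQR summaries.

Country-year proportions come straight from the type counts; national
prevalences pool each country's counts across years (count-weighted, not a
mean of annual rates); the headline summary is the median and interquartile
range of the national prevalences across countries, overall and within each
Sustainable Development Goal region.  Quantiles use linear interpolation
between order statistics; the rule is recorded in output metadata.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .io import SdgRegionMap
from .types import SMALL_TYPE6, TYPE6

logger = logging.getLogger(__name__)

QUANTILE_RULE = "linear"  # linear interpolation between order statistics


@dataclasses.dataclass(frozen=True)
class SummaryStat:
    """Median and interquartile range over a set of national prevalences."""

    median: float
    q1: float
    q3: float

    def __post_init__(self) -> None:
        if not (self.q1 <= self.median <= self.q3):
            raise ValueError(
                f"inconsistent quantiles q1={self.q1} median={self.median} q3={self.q3}"
            )


def _proportions(counts: pd.DataFrame, keys: list[str]) -> pd.DataFrame:
    zero = counts["n"] == 0
    if zero.any():
        dropped = counts.loc[zero, keys].to_dict("records")
        logger.info("dropping %d zero-count rows: %s", zero.sum(), dropped)
        counts = counts.loc[~zero]
    out = counts[keys].copy()
    extra = [c for c in counts.columns if c not in keys + list(TYPE6) + ["n"]]
    for t6 in TYPE6:
        out[t6] = counts[t6] / counts["n"]
    for c in extra:  # e.g. ten-type columns carried through as proportions
        out[c] = counts[c] / counts["n"]
    out["small_composite"] = out[list(SMALL_TYPE6)].sum(axis=1)
    out["n"] = counts["n"].to_numpy()
    return out.reset_index(drop=True)


def country_year_prevalence(counts: pd.DataFrame) -> pd.DataFrame:
    """Six-type proportions per country-year from a type-count table."""
    return _proportions(counts, ["country", "year"])


def national_prevalence(counts: pd.DataFrame) -> pd.DataFrame:
    """National proportions pooling each country's counts across years.

    Pooling is count-weighted: counts are summed over years before dividing,
    so large years carry proportionally more weight than small ones.
    """
    value_cols = [c for c in counts.columns if c not in ("country", "year")]
    pooled = counts.groupby("country", sort=True)[value_cols].sum().reset_index()
    return _proportions(pooled, ["country"])


def median_iqr(values) -> SummaryStat:
    """Median and quartiles by linear interpolation between order statistics."""
    arr = np.asarray(pd.Series(values).dropna(), dtype="float64")
    if arr.size == 0:
        raise ValueError("median_iqr needs at least one value")
    q1, med, q3 = np.percentile(arr, [25.0, 50.0, 75.0], method=QUANTILE_RULE)
    return SummaryStat(median=float(med), q1=float(q1), q3=float(q3))


def regional_summary(
    national: pd.DataFrame,
    region_map: SdgRegionMap,
    columns: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Median/IQR of national prevalences, overall and per region.

    One row per (region | "overall") x prevalence column, with the median
    and quartiles across that group's countries and the number of national
    datasets summarised.  Raises if any country has no region assigned.
    """
    unmapped = region_map.unmapped(national["country"])
    if unmapped:
        raise ValueError(
            f"countries without a region assignment: {unmapped}"
        )
    if columns is None:
        columns = tuple(TYPE6) + ("small_composite",)
    national = national.copy()
    national["region"] = [region_map.region(c) for c in national["country"]]

    rows = []

    def summarise(label: str, block: pd.DataFrame) -> None:
        for col in columns:
            stat = median_iqr(block[col])
            rows.append(
                {
                    "region": label,
                    "variable": col,
                    "median": stat.median,
                    "q1": stat.q1,
                    "q3": stat.q3,
                    "n_countries": len(block),
                }
            )

    summarise("overall", national)
    for region, block in national.groupby("region", sort=True):
        summarise(str(region), block)
    return pd.DataFrame(rows)
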