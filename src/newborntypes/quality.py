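"""Registry quality battery: heaping, tail shares, completeness, eligibility.

Missingness is measured on all records received (before the exclusion
cascade); the tail proportions and heaping index describe the cleaned
analysis set.  Both denominators are carried in the per-country-year quality
table for transparency.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: birthweight window around the 2500 g heap used by the heaping index
HEAP_VALUE_G = 2500
HEAP_FLANK_LO_G = 2250
HEAP_FLANK_HI_G = 2750

#: day-resolution cut for the "up to and including 28+6 weeks" tail
GA_TAIL_MAX_DAYS = 202


def heaping_index(bw_grams) -> float:
    """Digit-preference index for birthweight heaping at 2500 g.

    Number of births reported at exactly 2500 g divided by the number
    reported 249 g below (2250–2499 g) or 249 g above (2501–2750 g).
    Low values indicate better reporting practice.  Returns a proportion;
    NaN (undefined, not zero) when the flank denominator is empty.
    """
    bw = pd.Series(bw_grams).dropna().astype("float64").to_numpy()
    at_heap = int(np.sum(bw == HEAP_VALUE_G))
    flanks = int(
        np.sum((bw >= HEAP_FLANK_LO_G) & (bw <= HEAP_FLANK_HI_G) & (bw != HEAP_VALUE_G))
    )
    if flanks == 0:
        return float("nan")
    return at_heap / flanks


def tail_proportions(records: pd.DataFrame) -> dict[str, float]:
    """Shares (%) of extremely small births in the analysis set.

    Birthweight below 500 g, below 1000 g (strict inequalities) and
    gestational age up to and including 28+6 weeks (≤ 202 days).
    Denominators are the records with the relevant variable non-missing;
    an empty denominator yields NaN.
    """
    bw = records["bw_grams"].dropna().astype("float64").to_numpy()
    ga = records["ga_days"].dropna().astype("float64").to_numpy()

    def share(mask: np.ndarray, n: int) -> float:
        return 100.0 * float(mask.sum()) / n if n else float("nan")

    return {
        "pct_bw_lt_500": share(bw < 500, bw.size),
        "pct_bw_lt_1000": share(bw < 1000, bw.size),
        "pct_ga_le_28w6d": share(ga <= GA_TAIL_MAX_DAYS, ga.size),
    }


def completeness(records: pd.DataFrame) -> dict[str, float]:
    """Per-variable missingness (%) over all records received."""
    n = len(records)
    if n == 0:
        raise ValueError("completeness undefined for zero records")
    return {
        "pct_missing_bw": 100.0 * records["bw_grams"].isna().sum() / n,
        "pct_missing_ga": 100.0 * records["ga_days"].isna().sum() / n,
        "pct_missing_sex": 100.0 * pd.isna(records["sex"]).sum() / n,
    }


def inclusion_check(
    coverage_pct: float | None,
    facility_pct: float | None,
    completeness_pct: dict[str, float] | None,
    threshold_pct: float = 80.0,
) -> tuple[bool, list[str]]:
    """Country-level eligibility: high coverage, facility births, completeness.

    Passes iff coverage ≥ 80%, facility births ≥ 80% and completeness for
    each of birthweight, gestational age and sex ≥ 80%.  Coverage against
    the UN reference population and the facility-birth share are metadata
    inputs, not computed here.  Returns (passed, reasons-for-failure).
    """
    reasons: list[str] = []
    if coverage_pct is None or facility_pct is None or completeness_pct is None:
        return False, ["insufficient metadata"]
    for key in ("bw", "ga", "sex"):
        if key not in completeness_pct or completeness_pct[key] is None:
            return False, ["insufficient metadata"]
    if coverage_pct < threshold_pct:
        reasons.append(f"coverage {coverage_pct:.1f}% < {threshold_pct:g}%")
    if facility_pct < threshold_pct:
        reasons.append(
            f"facility births {facility_pct:.1f}% < {threshold_pct:g}%"
        )
    for key, label in (
        ("bw", "birthweight"),
        ("ga", "gestational age"),
        ("sex", "sex"),
    ):
        if completeness_pct[key] < threshold_pct:
            reasons.append(
                f"{label} completeness {completeness_pct[key]:.1f}% "
                f"< {threshold_pct:g}%"
            )
    return len(reasons) == 0, reasons


def sensitivity_filter(
    quality: pd.DataFrame, threshold_pct: float = 20.0
) -> pd.DataFrame:
    """Country-years whose missingness exceeds the sensitivity threshold.

    Flags rows of a per-country-year quality table where any of the three
    missingness percentages is strictly greater than ``threshold_pct``
    (default 20%).  Downstream prevalences can be recomputed without the
    flagged country-years.
    """
    cols = ["pct_missing_bw", "pct_missing_ga", "pct_missing_sex"]
    mask = (quality[cols] > threshold_pct).any(axis=1)
    return quality.loc[mask, ["country", "year"]].reset_index(drop=True)


def _battery(pre: pd.DataFrame, included: pd.DataFrame, excluded: pd.DataFrame) -> dict:
    n_total = len(pre)
    out: dict[str, float] = {"n_total": n_total, "n_included": len(included)}
    out.update(completeness(pre))
    out.update(tail_proportions(included))
    n_combo = (
        int((excluded["exclusion_reason"] == "implausible_combo").sum())
        if len(excluded)
        else 0
    )
    out["pct_implausible_combo"] = 100.0 * n_combo / n_total if n_total else float("nan")
    hi = heaping_index(included["bw_grams"])
    out["heaping_index_pct"] = 100.0 * hi if hi == hi else float("nan")
    return out


def quality_table(
    records: pd.DataFrame,
    included: pd.DataFrame,
    excluded: pd.DataFrame,
    per_year: bool = True,
) -> pd.DataFrame:
    """Quality battery per country-year and per country overall.

    ``records`` is the pre-exclusion dataset; ``included``/``excluded`` the
    cascade outputs (``excluded`` carries ``exclusion_reason``).  The
    per-country rows (year = ``"all"``) pool that country's records.
    """
    rows = []
    keys = [("country", "year")] if per_year else []
    for country, pre_c in records.groupby("country", sort=True):
        inc_c = included[included["country"] == country]
        exc_c = excluded[excluded["country"] == country]
        row = {"country": country, "year": "all"}
        row.update(_battery(pre_c, inc_c, exc_c))
        rows.append(row)
        if keys:
            for year, pre_cy in pre_c.groupby("year", sort=True):
                inc_cy = inc_c[inc_c["year"] == year]
                exc_cy = exc_c[exc_c["year"] == year]
                row = {"country": country, "year": year}
                row.update(_battery(pre_cy, inc_cy, exc_cy))
                rows.append(row)
    return pd.DataFrame(rows)
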