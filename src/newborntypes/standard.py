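"""Sex- and gestational-age-specific birthweight centile standards.

A :class:`GrowthStandard` holds 10th and 90th centile birthweight knots per
sex on a gestational-age grid (in days), interpolates them at day resolution,
extends the covered range by extrapolation or clamping, and classifies
birthweights as small (SGA), appropriate (AGA) or large (LGA) for
gestational age.  The engine consumes any table honouring the file contract
— published standards such as INTERGROWTH-21st can be plugged in as delimited
files; the repository itself ships only synthetic/toy standards.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

SIZE_CLASSES = ("SGA", "AGA", "LGA")
SEXES = ("male", "female")

EXTENSION_METHODS = ("linear_extrapolate", "clamp")


class StandardError(ValueError):
    """Invalid standard table (crossing centiles, bad grid, …)."""


class OutOfRangeError(ValueError):
    """Gestational age outside the standard's covered range."""


class GrowthStandard:
    """Birthweight centile standard with day-resolution interpolation.

    Parameters
    ----------
    knots
        Frame with columns ``sex`` (``male``/``female``), ``ga_days`` (int),
        ``p10_g``, ``p90_g``.  Knots must be strictly increasing in
        ``ga_days`` within sex, with ``p10_g < p90_g`` everywhere, and both
        sexes covered.
    provenance
        Free-text label recorded in output metadata (e.g. the source table
        and any extension applied).
    day_interpolation
        When True (default), centile limits between knots are linear in
        gestational days.  When False, gestational age is floored to the
        completed week before lookup — for registries reporting weeks only.
    """

    def __init__(
        self,
        knots: pd.DataFrame,
        provenance: str = "unspecified",
        day_interpolation: bool = True,
    ):
        knots = knots.copy()
        required = {"sex", "ga_days", "p10_g", "p90_g"}
        missing = required - set(knots.columns)
        if missing:
            raise StandardError(f"standard table missing columns {sorted(missing)}")
        knots["ga_days"] = knots["ga_days"].astype(int)
        knots = knots.sort_values(["sex", "ga_days"]).reset_index(drop=True)

        for sex in SEXES:
            sub = knots[knots["sex"] == sex]
            if sub.empty:
                raise StandardError(f"standard covers no knots for sex {sex!r}")
            if sub["ga_days"].duplicated().any():
                dupes = sub.loc[sub["ga_days"].duplicated(), "ga_days"].tolist()
                raise StandardError(f"duplicate knots for {sex} at ga_days {dupes}")
            gaps = np.diff(sub["ga_days"].to_numpy())
            if (gaps > 7).any():
                warnings.warn(
                    f"standard has gestational-age gaps > 1 week for {sex}; "
                    "interpolation will bridge them linearly",
                    stacklevel=2,
                )
        bad = knots["p10_g"] >= knots["p90_g"]
        if bad.any():
            rows = knots.loc[bad, ["sex", "ga_days", "p10_g", "p90_g"]]
            raise StandardError(
                f"crossing centiles (p10 >= p90) at:\n{rows.to_string(index=False)}"
            )
        if (knots["p10_g"] <= 0).any():
            raise StandardError("non-positive 10th-centile weights in standard")
        unknown = set(knots["sex"]) - set(SEXES)
        if unknown:
            raise StandardError(f"unknown sex labels in standard: {sorted(unknown)}")

        self.knots = knots
        self.provenance = provenance
        self.day_interpolation = day_interpolation
        self._grid = {
            sex: (
                knots.loc[knots["sex"] == sex, "ga_days"].to_numpy(dtype="int64"),
                knots.loc[knots["sex"] == sex, "p10_g"].to_numpy(dtype="float64"),
                knots.loc[knots["sex"] == sex, "p90_g"].to_numpy(dtype="float64"),
            )
            for sex in SEXES
        }

    # -- range ---------------------------------------------------------

    def native_range(self, sex: str) -> tuple[int, int]:
        days = self._grid[sex][0]
        return int(days[0]), int(days[-1])

    # -- lookup --------------------------------------------------------

    def centile_limits(self, sex, ga_days):
        """10th/90th centile weights at given sex and gestational age.

        Scalar or array arguments; limits at knots equal the knot values
        exactly, between knots they are interpolated linearly and
        independently per centile.  Raises :class:`OutOfRangeError` for
        gestational ages outside the covered range (extend the standard
        first).
        """
        scalar = np.isscalar(sex) or isinstance(sex, str)
        sex_arr = np.atleast_1d(np.asarray(sex, dtype=object))
        ga_arr = np.atleast_1d(np.asarray(ga_days, dtype="float64"))
        if sex_arr.size == 1 and ga_arr.size > 1:
            sex_arr = np.repeat(sex_arr, ga_arr.size)
        if not self.day_interpolation:
            ga_arr = (ga_arr // 7) * 7
        p10 = np.empty_like(ga_arr)
        p90 = np.empty_like(ga_arr)
        for s in SEXES:
            mask = sex_arr == s
            if not mask.any():
                continue
            days, k10, k90 = self._grid[s]
            lo, hi = days[0], days[-1]
            bad = (ga_arr[mask] < lo) | (ga_arr[mask] > hi)
            if bad.any():
                offending = sorted(set(ga_arr[mask][bad].astype(int).tolist()))
                raise OutOfRangeError(
                    f"gestational age(s) {offending[:5]} outside the standard's "
                    f"{s} range [{lo}, {hi}] days; extend the standard first"
                )
            p10[mask] = np.interp(ga_arr[mask], days, k10)
            p90[mask] = np.interp(ga_arr[mask], days, k90)
        unknown = ~np.isin(sex_arr, SEXES)
        if unknown.any():
            raise ValueError(
                f"cannot look up centiles for sex {set(sex_arr[unknown])}"
            )
        if scalar and np.ndim(ga_days) == 0:
            return float(p10[0]), float(p90[0])
        return p10, p90

    # -- extension -----------------------------------------------------

    def extend(
        self,
        target_min_days: int,
        target_max_days: int,
        method: str = "linear_extrapolate",
    ) -> "GrowthStandard":
        """Extend the covered gestational-age range per sex.

        ``linear_extrapolate`` continues the slope of the two outermost
        knots per sex and centile; ``clamp`` holds the boundary values
        constant.  The target range must contain the native range, and the
        extended table must still satisfy every standard invariant (positive
        weights, non-crossing centiles) or an error is raised.
        """
        if method not in EXTENSION_METHODS:
            raise ValueError(
                f"unknown extension method {method!r}; expected {EXTENSION_METHODS}"
            )
        frames = []
        for sex in SEXES:
            days, k10, k90 = self._grid[sex]
            if target_min_days > days[0] or target_max_days < days[-1]:
                raise ValueError(
                    "target range must contain the native range "
                    f"[{days[0]}, {days[-1]}] for {sex}"
                )
            new_days = list(days)
            new10 = list(k10)
            new90 = list(k90)

            def edge(value_at, side):
                if method == "clamp":
                    return value_at[0] if side == "low" else value_at[-1]
                if side == "low":
                    slope10 = (value_at[1] - value_at[0]) / (days[1] - days[0])
                    return value_at[0] + slope10 * (target_min_days - days[0])
                slope10 = (value_at[-1] - value_at[-2]) / (days[-1] - days[-2])
                return value_at[-1] + slope10 * (target_max_days - days[-1])

            if target_min_days < days[0]:
                new_days.insert(0, target_min_days)
                new10.insert(0, edge(k10, "low"))
                new90.insert(0, edge(k90, "low"))
            if target_max_days > days[-1]:
                new_days.append(target_max_days)
                new10.append(edge(k10, "high"))
                new90.append(edge(k90, "high"))
            frames.append(
                pd.DataFrame(
                    {
                        "sex": sex,
                        "ga_days": new_days,
                        "p10_g": new10,
                        "p90_g": new90,
                    }
                )
            )
        knots = pd.concat(frames, ignore_index=True)
        if (knots["p10_g"] <= 0).any():
            raise StandardError(
                "extension produced non-positive 10th-centile weights"
            )
        return GrowthStandard(
            knots,
            provenance=(
                f"{self.provenance}; extended to "
                f"[{target_min_days}, {target_max_days}] days by {method}"
            ),
            day_interpolation=self.day_interpolation,
        )

    # -- classification ------------------------------------------------

    def classify(self, bw_grams, sex, ga_days):
        """Size-for-gestational-age class per record.

        SGA below the 10th centile, LGA above the 90th; weights exactly on
        either centile are appropriate for gestational age (AGA).
        """
        p10, p90 = self.centile_limits(sex, ga_days)
        bw = np.atleast_1d(np.asarray(bw_grams, dtype="float64"))
        out = np.where(bw < p10, "SGA", np.where(bw > p90, "LGA", "AGA"))
        if np.ndim(bw_grams) == 0:
            return str(out[0])
        return out

    def to_frame(self) -> pd.DataFrame:
        return self.knots.copy()


def load_standard(path: str | Path, **kwargs) -> GrowthStandard:
    """Load a centile standard from a delimited text file.

    Expected columns: ``sex``, ``p10_g``, ``p90_g`` and either ``ga_days``
    or ``ga_weeks`` (optionally plus ``ga_extra_days``); week-indexed files
    are converted to days.  Invariant violations are hard errors carrying
    the offending rows.
    """
    path = Path(path)
    df = pd.read_csv(path, encoding="utf-8")
    df.columns = [c.lower() for c in df.columns]
    if "ga_days" not in df.columns:
        if "ga_weeks" not in df.columns:
            raise StandardError(
                f"{path}: need a ga_days or ga_weeks column"
            )
        extra = (
            df["ga_extra_days"].astype(int) if "ga_extra_days" in df.columns else 0
        )
        df["ga_days"] = 7 * df["ga_weeks"].astype(int) + extra
    return GrowthStandard(
        df[["sex", "ga_days", "p10_g", "p90_g"]],
        provenance=str(path.name),
        **kwargs,
    )
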