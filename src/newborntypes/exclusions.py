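"""Exclusion cascade with full flow accounting.

Records are removed, in a fixed order, for missing gestational age,
birthweight or sex, and for implausible values: birthweight outside
[250, 6500) g, gestational age outside 154–314 days (22+0 to 44+6 weeks), or
a birthweight further than a configurable number of standard deviations from
the mean birthweight at that completed week of gestation.  Each excluded
record carries exactly one reason — the first matching rule — and the flow
accounting reconciles input to output as an exact integer identity.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

#: exclusion reasons in cascade order
REASONS = (
    "missing_ga",
    "missing_bw",
    "missing_both",
    "missing_sex",
    "implausible_bw",
    "implausible_ga",
    "implausible_combo",
)


@dataclasses.dataclass(frozen=True)
class PlausibilityLimits:
    """Hard plausibility window and envelope settings.

    Birthweight is plausible in ``[bw_min_g, bw_max_g)`` — 250 g is plausible,
    6500 g is not.  Gestational age is plausible in
    ``[ga_min_days, ga_max_days]`` inclusive (22+0 to 44+6 weeks).  The
    birthweight-given-gestational-age envelope spans
    ``mean ± combo_sd_multiplier · SD`` per completed week, computed only for
    weeks with at least ``envelope_min_cell`` records.
    """

    bw_min_g: int = 250
    bw_max_g: int = 6500
    ga_min_days: int = 154
    ga_max_days: int = 314
    combo_sd_multiplier: float = 5.0
    envelope_min_cell: int = 10

    def __post_init__(self) -> None:
        if not self.bw_min_g < self.bw_max_g:
            raise ValueError("bw_min_g must be < bw_max_g")
        if not self.ga_min_days < self.ga_max_days:
            raise ValueError("ga_min_days must be < ga_max_days")
        if not self.combo_sd_multiplier > 0:
            raise ValueError("combo_sd_multiplier must be positive")


@dataclasses.dataclass
class FlowAccounting:
    """Ordered exclusion counts reconciling input to analysis dataset."""

    n_input: int
    counts: dict[str, int]
    n_included: int

    def check(self) -> None:
        total = self.n_included + sum(self.counts.values())
        if total != self.n_input:
            raise AssertionError(
                f"flow identity broken: {self.n_input} input != "
                f"{self.n_included} included + {sum(self.counts.values())} excluded"
            )

    @property
    def n_excluded(self) -> int:
        return sum(self.counts.values())


@dataclasses.dataclass
class ExclusionResult:
    included: pd.DataFrame
    excluded: pd.DataFrame  # carries an ``exclusion_reason`` column
    flow: FlowAccounting
    envelope: pd.DataFrame


def build_envelope(
    records: pd.DataFrame,
    multiplier: float = 5.0,
    min_cell: int = 10,
) -> pd.DataFrame:
    """Per-completed-week birthweight mean, sample SD and plausibility bounds.

    Input records must already have plausible, non-missing gestational age
    and birthweight.  Weeks with fewer than ``min_cell`` records (or an
    undefined sample SD) get no bounds and therefore produce no combination
    exclusions.  Returns a frame indexed by completed week with columns
    ``n``, ``mean_g``, ``sd_g``, ``lower_g``, ``upper_g``.
    """
    if len(records) == 0:
        return pd.DataFrame(
            columns=["n", "mean_g", "sd_g", "lower_g", "upper_g"]
        ).rename_axis("week")
    week = (records["ga_days"].astype("int64") // 7).rename("week")
    bw = records["bw_grams"].astype("float64")
    grouped = bw.groupby(week)
    env = pd.DataFrame(
        {
            "n": grouped.size(),
            "mean_g": grouped.mean(),
            "sd_g": grouped.std(ddof=1),
        }
    )
    defined = (env["n"] >= min_cell) & env["sd_g"].notna()
    env["lower_g"] = np.where(
        defined, env["mean_g"] - multiplier * env["sd_g"], np.nan
    )
    env["upper_g"] = np.where(
        defined, env["mean_g"] + multiplier * env["sd_g"], np.nan
    )
    return env


def apply_exclusions(
    records: pd.DataFrame,
    limits: PlausibilityLimits | None = None,
    envelope: pd.DataFrame | None = None,
) -> ExclusionResult:
    """Run the exclusion cascade and account for every record exactly once.

    Cascade order: missing gestational age (birthweight present), missing
    birthweight (gestational age present), missing both, missing sex,
    implausible birthweight, implausible gestational age, implausible
    birthweight/gestational-age combination.  The envelope for the last step
    is built from the survivors of the first six unless one is passed in
    (pass the previous run's envelope to check idempotence).
    """
    limits = limits or PlausibilityLimits()
    ga = records["ga_days"]
    bw = records["bw_grams"]
    sex = records["sex"]

    ga_missing = ga.isna().to_numpy()
    bw_missing = bw.isna().to_numpy()
    sex_missing = pd.isna(sex).to_numpy()
    ga_f = ga.astype("float64").to_numpy()
    bw_f = bw.astype("float64").to_numpy()

    with np.errstate(invalid="ignore"):
        implausible_bw = (~bw_missing) & (
            (bw_f < limits.bw_min_g) | (bw_f >= limits.bw_max_g)
        )
        implausible_ga = (~ga_missing) & (
            (ga_f < limits.ga_min_days) | (ga_f > limits.ga_max_days)
        )

    reason = np.full(len(records), "", dtype=object)
    conds = [
        ("missing_ga", ga_missing & ~bw_missing),
        ("missing_bw", bw_missing & ~ga_missing),
        ("missing_both", ga_missing & bw_missing),
        ("missing_sex", sex_missing),
        ("implausible_bw", implausible_bw),
        ("implausible_ga", implausible_ga),
    ]
    taken = np.zeros(len(records), dtype=bool)
    for name, mask in conds:
        new = mask & ~taken
        reason[new] = name
        taken |= new

    survivors = records.loc[~taken]
    if envelope is None:
        envelope = build_envelope(
            survivors,
            multiplier=limits.combo_sd_multiplier,
            min_cell=limits.envelope_min_cell,
        )
    if len(survivors) and len(envelope):
        week = survivors["ga_days"].astype("int64") // 7
        lower = week.map(envelope["lower_g"]).to_numpy(dtype="float64")
        upper = week.map(envelope["upper_g"]).to_numpy(dtype="float64")
        sbw = survivors["bw_grams"].astype("float64").to_numpy()
        with np.errstate(invalid="ignore"):
            combo = (sbw < lower) | (sbw > upper)  # NaN bounds → no exclusion
        idx = survivors.index[combo]
        reason[records.index.get_indexer(idx)] = "implausible_combo"
        taken[records.index.get_indexer(idx)] = True

    included = records.loc[~taken].copy()
    excluded = records.loc[taken].copy()
    excluded["exclusion_reason"] = reason[taken]

    counts = {r: 0 for r in REASONS}
    if len(excluded):
        for r, n in excluded["exclusion_reason"].value_counts().items():
            counts[r] = int(n)
    flow = FlowAccounting(
        n_input=len(records), counts=counts, n_included=len(included)
    )
    flow.check()
    return ExclusionResult(
        included=included, excluded=excluded, flow=flow, envelope=envelope
    )


def flow_summary(flow: FlowAccounting) -> pd.DataFrame:
    """Flow-chart table: counts and percentages of the input total.

    Percentages are ``100 · count / n_input`` reported at one decimal.
    Rows: the input total, each exclusion reason in cascade order, the
    excluded subtotal, and the included analysis set.
    """
    if flow.n_input == 0:
        raise ValueError("flow summary undefined for zero input records")
    flow.check()

    def pct(n: int) -> float:
        return round(100.0 * n / flow.n_input, 1)

    rows = [("input", "", flow.n_input, 100.0)]
    rows += [
        ("excluded", reason, n, pct(n)) for reason, n in flow.counts.items()
    ]
    rows.append(("excluded_total", "", flow.n_excluded, pct(flow.n_excluded)))
    rows.append(("included", "", flow.n_included, pct(flow.n_included)))
    return pd.DataFrame(rows, columns=["stage", "reason", "n", "pct_of_input"])
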