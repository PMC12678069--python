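"""The analysis model: registry data in, fitted prevalence results out.

:class:`NewbornTypeAnalysis` bundles a registry, a centile standard and the
analysis settings; :meth:`NewbornTypeAnalysis.fit` runs the full pipeline —
quality audit, exclusion cascade, six/ten-type classification, prevalence
aggregation, sensitivity re-analysis and trend smoothing — and returns a
:class:`NewbornTypeResults` carrying every output table, a text ``summary()``
and a manifest of the decisions (quantile rule, extension method, limits)
that make the run reproducible.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from ._version import __version__ as _pkg_version
from .exclusions import ExclusionResult, PlausibilityLimits, apply_exclusions, flow_summary
from .io import RegistrySchema, SdgRegionMap, read_registry, write_table
from .prevalence import (
    QUANTILE_RULE,
    country_year_prevalence,
    national_prevalence,
    regional_summary,
)
from .quality import inclusion_check, quality_table, sensitivity_filter
from .standard import GrowthStandard, load_standard
from .trends import CHANGE_THRESHOLD_PP, PERIODS, TREND_MIN_YEARS, period_summary, trend_table
from .types import classify_records, collapse_type10, type_counts


class NewbornTypeAnalysis:
    """Vulnerable-newborn-type analysis of an individual-level registry.

    Parameters
    ----------
    records
        Canonical birth records (see :mod:`newborntypes.io`), pooled over
        countries and years.
    standard
        A :class:`~newborntypes.standard.GrowthStandard`; it must cover the
        plausible gestational-age window (extend it first if needed).
    limits
        Plausibility limits for the exclusion cascade.
    region_map
        Country → SDG-region lookup for the regional summary; without one,
        only the overall summary row is produced.
    country_metadata
        Optional mapping country → dict with ``coverage_pct`` and
        ``facility_pct`` for the eligibility check.
    sensitivity_threshold_pct
        Country-years with any variable's missingness strictly above this
        are flagged and removed in the sensitivity re-analysis.
    """

    def __init__(
        self,
        records: pd.DataFrame,
        standard: GrowthStandard,
        limits: PlausibilityLimits | None = None,
        region_map: SdgRegionMap | None = None,
        country_metadata: dict | None = None,
        sensitivity_threshold_pct: float = 20.0,
        trend_threshold_pp: float = CHANGE_THRESHOLD_PP,
        trend_min_years: int = TREND_MIN_YEARS,
        keep_typed_records: bool = False,
        suppress_small_cells: bool = False,
    ):
        self.records = records
        self.standard = standard
        self.limits = limits or PlausibilityLimits()
        self.region_map = region_map
        self.country_metadata = country_metadata or {}
        self.sensitivity_threshold_pct = sensitivity_threshold_pct
        self.trend_threshold_pp = trend_threshold_pp
        self.trend_min_years = trend_min_years
        self.keep_typed_records = keep_typed_records
        self.suppress_small_cells = suppress_small_cells

    @classmethod
    def from_files(
        cls,
        registries: list[tuple[str, RegistrySchema]],
        standard_path: str,
        extend_to: tuple[int, int] | None = None,
        extension_method: str = "linear_extrapolate",
        region_map_path: str | None = None,
        **kwargs,
    ) -> "NewbornTypeAnalysis":
        """Build the model from registry files and a standard-table file."""
        frames, reports = [], []
        for path, schema in registries:
            recs, report = read_registry(path, schema)
            frames.append(recs)
            reports.append((str(path), report))
        records = pd.concat(frames, ignore_index=True)
        standard = load_standard(standard_path)
        if extend_to is not None:
            standard = standard.extend(*extend_to, method=extension_method)
        region_map = (
            SdgRegionMap.from_file(region_map_path) if region_map_path else None
        )
        model = cls(records, standard, region_map=region_map, **kwargs)
        model.parse_reports = reports
        return model

    def fit(self) -> "NewbornTypeResults":
        """Run the full pipeline and return the fitted results."""
        exclusion = apply_exclusions(self.records, self.limits)
        quality = quality_table(
            self.records, exclusion.included, exclusion.excluded
        )
        typed = classify_records(exclusion.included, self.standard)

        counts6 = type_counts(typed, which="type6")
        counts10 = type_counts(typed, which="type10")
        prev_cy = country_year_prevalence(counts6)
        prev_nat = national_prevalence(counts6)
        summary = self._summarise(prev_nat)

        cy_quality = quality[quality["year"] != "all"]
        flagged = sensitivity_filter(
            cy_quality, threshold_pct=self.sensitivity_threshold_pct
        )
        prev_nat_sens = None
        if len(flagged):
            keep = ~pd.MultiIndex.from_frame(
                counts6[["country", "year"]].astype(str)
            ).isin(pd.MultiIndex.from_frame(flagged.astype(str)))
            prev_nat_sens = national_prevalence(counts6[keep])

        trends = trend_table(
            prev_cy,
            min_years=self.trend_min_years,
            threshold_pp=self.trend_threshold_pp,
        )
        period_changes = self._period_changes(trends)
        eligibility = self._eligibility()

        return NewbornTypeResults(
            model=self,
            exclusion=exclusion,
            quality=quality,
            counts6=counts6,
            counts10=counts10,
            prevalence_country_year=prev_cy,
            prevalence_national=prev_nat,
            summary_table=summary,
            sensitivity_flagged=flagged,
            prevalence_national_sensitivity=prev_nat_sens,
            trends=trends,
            period_changes=period_changes,
            eligibility=eligibility,
            typed=typed if self.keep_typed_records else None,
        )

    # -- helpers -------------------------------------------------------

    def _summarise(self, prev_nat: pd.DataFrame) -> pd.DataFrame:
        if self.region_map is not None:
            return regional_summary(prev_nat, self.region_map)
        every = SdgRegionMap({c: "all" for c in prev_nat["country"]})
        table = regional_summary(prev_nat, every)
        return table[table["region"] == "overall"].reset_index(drop=True)

    def _period_changes(self, trends: pd.DataFrame) -> pd.DataFrame:
        rows = []
        for (country, composite), block in trends.groupby(
            ["country", "composite"], sort=True
        ):
            smoothed = pd.Series(
                block["smoothed_pct"].to_numpy(), index=block["year"].to_numpy()
            )
            per = period_summary(smoothed, periods=PERIODS)
            per.insert(0, "country", country)
            per.insert(1, "composite", composite)
            rows.append(per)
        if not rows:
            return pd.DataFrame(
                columns=[
                    "country",
                    "composite",
                    "period_start",
                    "period_end",
                    "first_year",
                    "last_year",
                    "net_change_pp",
                ]
            )
        return pd.concat(rows, ignore_index=True)

    def _eligibility(self) -> pd.DataFrame:
        rows = []
        from .quality import completeness

        for country, block in self.records.groupby("country", sort=True):
            meta = self.country_metadata.get(country, {})
            comp = completeness(block)
            passed, reasons = inclusion_check(
                meta.get("coverage_pct"),
                meta.get("facility_pct"),
                {
                    "bw": 100.0 - comp["pct_missing_bw"],
                    "ga": 100.0 - comp["pct_missing_ga"],
                    "sex": 100.0 - comp["pct_missing_sex"],
                },
            )
            rows.append(
                {"country": country, "eligible": passed, "reasons": "; ".join(reasons)}
            )
        return pd.DataFrame(rows)

    def manifest(self) -> dict:
        """Decision record sufficient to re-run the analysis identically."""
        return {
            "package": "newborntypes",
            "version": _pkg_version,
            "n_input_records": int(len(self.records)),
            "limits": {
                "bw_min_g": self.limits.bw_min_g,
                "bw_max_g": self.limits.bw_max_g,
                "ga_min_days": self.limits.ga_min_days,
                "ga_max_days": self.limits.ga_max_days,
                "combo_sd_multiplier": self.limits.combo_sd_multiplier,
                "envelope_min_cell": self.limits.envelope_min_cell,
            },
            "standard_provenance": self.standard.provenance,
            "standard_day_interpolation": self.standard.day_interpolation,
            "quantile_rule": QUANTILE_RULE,
            "sensitivity_threshold_pct": self.sensitivity_threshold_pct,
            "trend_threshold_pp": self.trend_threshold_pp,
            "trend_min_years": self.trend_min_years,
            "trend_periods": [list(p) for p in PERIODS],
        }


class NewbornTypeResults:
    """Fitted outputs of a :class:`NewbornTypeAnalysis` run."""

    def __init__(
        self,
        model: NewbornTypeAnalysis,
        exclusion: ExclusionResult,
        quality: pd.DataFrame,
        counts6: pd.DataFrame,
        counts10: pd.DataFrame,
        prevalence_country_year: pd.DataFrame,
        prevalence_national: pd.DataFrame,
        summary_table: pd.DataFrame,
        sensitivity_flagged: pd.DataFrame,
        prevalence_national_sensitivity: pd.DataFrame | None,
        trends: pd.DataFrame,
        period_changes: pd.DataFrame,
        eligibility: pd.DataFrame,
        typed: pd.DataFrame | None,
    ):
        self.model = model
        self.exclusion = exclusion
        self.flow = exclusion.flow
        self.flow_table = flow_summary(exclusion.flow)
        self.quality = quality
        self.counts6 = counts6
        self.counts10 = counts10
        self.prevalence_country_year = prevalence_country_year
        self.prevalence_national = prevalence_national
        self.summary_table = summary_table
        self.sensitivity_flagged = sensitivity_flagged
        self.prevalence_national_sensitivity = prevalence_national_sensitivity
        self.trends = trends
        self.period_changes = period_changes
        self.eligibility = eligibility
        self.typed = typed

    def summary(self) -> str:
        """Human-readable run summary, Table-3-shaped at one decimal."""
        flow = self.flow
        lines = [
            "Vulnerable newborn type analysis",
            "=" * 60,
            f"records received          {flow.n_input:>14,d}",
            f"records excluded          {flow.n_excluded:>14,d} "
            f"({100 * flow.n_excluded / flow.n_input:.1f}%)",
            f"analysis data set         {flow.n_included:>14,d} "
            f"({100 * flow.n_included / flow.n_input:.1f}%)",
            "",
            "Median (IQR) national prevalence, % of live births",
            "-" * 60,
        ]
        overall = self.summary_table[self.summary_table["region"] == "overall"]
        for _, row in overall.iterrows():
            lines.append(
                f"{row['variable']:<16} {100 * row['median']:5.1f} "
                f"({100 * row['q1']:.1f}-{100 * row['q3']:.1f})  "
                f"across {int(row['n_countries'])} national datasets"
            )
        if len(self.sensitivity_flagged):
            lines.append("")
            lines.append(
                f"sensitivity: {len(self.sensitivity_flagged)} country-years "
                f"above {self.model.sensitivity_threshold_pct:g}% missingness"
            )
        n_trend = self.trends["country"].nunique() if len(self.trends) else 0
        n_flags = int(self.trends["change_flag"].sum()) if len(self.trends) else 0
        lines.append("")
        lines.append(
            f"trends: {n_trend} countries with >= "
            f"{self.model.trend_min_years} years; {n_flags} year-to-year "
            f"changes beyond {self.model.trend_threshold_pp:g} pp"
        )
        return "\n".join(lines)

    def save_tables(self, outdir: str | Path) -> list[Path]:
        """Write every output table (and the manifest) as delimited text.

        By default only aggregate tables are written; per-record typed output
        requires the model's ``keep_typed_records`` flag — the
        aggregate-only default mirrors the disclosure-control design of
        multi-country collaborations.
        """
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written: list[Path] = []

        def emit(name: str, table: pd.DataFrame) -> None:
            path = outdir / name
            if self.suppressed_counts and name.startswith("counts"):
                table = table.copy()
                num = table.select_dtypes("number").columns
                table[num] = table[num].mask(
                    (table[num] > 0) & (table[num] < 5)
                )
            write_table(table, path)
            written.append(path)

        emit("flow.csv", self.flow_table)
        emit("quality.csv", self.quality)
        emit("counts_type6.csv", self.counts6)
        emit("counts_type10.csv", self.counts10)
        emit("prevalence_country_year.csv", self.prevalence_country_year)
        emit("prevalence_national.csv", self.prevalence_national)
        emit("summary_median_iqr.csv", self.summary_table)
        emit("trends.csv", self.trends)
        emit("period_changes.csv", self.period_changes)
        emit("eligibility.csv", self.eligibility)
        emit("sensitivity_flagged.csv", self.sensitivity_flagged)
        if self.prevalence_national_sensitivity is not None:
            emit(
                "prevalence_national_sensitivity.csv",
                self.prevalence_national_sensitivity,
            )
        if self.typed is not None:
            emit("typed_records.csv", self.typed)
        manifest_path = outdir / "manifest.json"
        manifest_path.write_text(
            json.dumps(self.model.manifest(), indent=2, sort_keys=True) + "\n"
        )
        written.append(manifest_path)
        return written

    @property
    def suppressed_counts(self) -> bool:
        return self.model.suppress_small_cells

    @property
    def collapse_check(self) -> bool:
        """True when the ten-type counts collapse exactly to the six-type."""
        collapsed = collapse_type10(self.counts10)
        merged = collapsed.merge(
            self.counts6, on=["country", "year"], suffixes=("_c", "_6")
        )
        from .types import TYPE6

        return all(
            (merged[f"{t}_c"] == merged[f"{t}_6"]).all() for t in TYPE6
        )
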