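"""Registry input/output: schema-driven parsing into canonical birth records.

The canonical in-memory container is a :class:`pandas.DataFrame` with one row
per live birth and columns

``country``    registry/country identifier (string)
``year``       calendar year of birth (int)
``ga_days``    gestational age in days since last menstrual period (nullable Int64)
``bw_grams``   birthweight in grams (nullable Int64)
``sex``        ``"male"`` / ``"female"`` / missing (NaN)
``plurality``  ``"singleton"`` / ``"multiple"`` / missing — pass-through
``ga_week_resolution``  True when the source reported completed weeks only

plus any extra pass-through covariates the schema names.  Gestational age is
held in days throughout so that week-boundary rules (``36+6`` vs ``37+0``)
are unambiguous integer comparisons.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from collections.abc import Mapping, Sequence
from pathlib import Path

import numpy as np
import pandas as pd

GA_ENCODINGS = ("completed_weeks", "weeks_plus_days", "days")

#: canonical record columns, in output order
RECORD_COLUMNS = (
    "country",
    "year",
    "ga_days",
    "bw_grams",
    "sex",
    "plurality",
    "ga_week_resolution",
)

DEFAULT_SENTINELS = ("", "NA", "N/A", "NaN", "nan", ".", "-", "NULL")

DEFAULT_SEX_CODES = {
    "male": "male",
    "m": "male",
    "1": "male",
    "boy": "male",
    "female": "female",
    "f": "female",
    "2": "female",
    "girl": "female",
}

DEFAULT_PLURALITY_CODES = {
    "singleton": "singleton",
    "single": "singleton",
    "1": "singleton",
    "multiple": "multiple",
    "twin": "multiple",
    "2": "multiple",
    "3": "multiple",
}


class ConfigurationError(ValueError):
    """A schema or config problem that prevents reading a file at all."""


class MalformedRecordError(ValueError):
    """A single record violates a parse-level precondition."""


@dataclasses.dataclass(frozen=True)
class RegistrySchema:
    """Column mapping and dialect for one registry file.

    ``columns`` maps canonical names to source column names.  Required keys:
    ``country``, ``year``, ``bw_grams``, ``sex`` and, depending on
    ``ga_encoding``, either ``ga_days`` (encoding ``"days"``) or ``ga_weeks``
    (other encodings; ``ga_extra_days`` additionally for
    ``"weeks_plus_days"``).  Any keys beyond the canonical set are carried
    through unparsed.
    """

    columns: Mapping[str, str]
    ga_encoding: str = "weeks_plus_days"
    sentinels: Sequence[str] = DEFAULT_SENTINELS
    delimiter: str = ","
    sex_codes: Mapping[str, str] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_SEX_CODES)
    )
    plurality_codes: Mapping[str, str] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_PLURALITY_CODES)
    )

    def __post_init__(self) -> None:
        if self.ga_encoding not in GA_ENCODINGS:
            raise ConfigurationError(
                f"unknown gestational-age encoding {self.ga_encoding!r}; "
                f"expected one of {GA_ENCODINGS}"
            )
        required = {"country", "year", "bw_grams", "sex"}
        if self.ga_encoding == "days":
            required.add("ga_days")
        else:
            required.add("ga_weeks")
        if self.ga_encoding == "weeks_plus_days":
            required.add("ga_extra_days")
        missing = required - set(self.columns)
        if missing:
            raise ConfigurationError(
                f"schema is missing mappings for {sorted(missing)}"
            )

    @property
    def extra_keys(self) -> list[str]:
        known = {
            "country",
            "year",
            "bw_grams",
            "sex",
            "plurality",
            "ga_days",
            "ga_weeks",
            "ga_extra_days",
        }
        return [k for k in self.columns if k not in known]


@dataclasses.dataclass
class ParseReport:
    """Reconciliation of rows read to records produced."""

    n_rows: int
    n_records: int
    n_malformed: int
    malformed_reasons: Counter = dataclasses.field(default_factory=Counter)

    def check(self) -> None:
        if self.n_rows != self.n_records + self.n_malformed:
            raise AssertionError(
                f"parse accounting broken: {self.n_rows} rows != "
                f"{self.n_records} records + {self.n_malformed} malformed"
            )


def normalize_gestational_age(
    weeks: int, days: int | None, encoding: str = "weeks_plus_days"
) -> int:
    """Convert a (completed weeks, extra days) gestational age to days.

    With encoding ``"completed_weeks"`` the day component is taken as 0, so
    week-based thresholds reduce to completed-week comparisons.  ``days``
    outside 0–6 is a malformed record, not an exclusion-cascade event.
    """
    if encoding not in GA_ENCODINGS:
        raise ConfigurationError(f"unknown encoding {encoding!r}")
    weeks = int(weeks)
    if weeks < 0:
        raise MalformedRecordError(f"negative gestational weeks: {weeks}")
    if encoding == "completed_weeks" or days is None:
        return 7 * weeks
    days = int(days)
    if not 0 <= days <= 6:
        raise MalformedRecordError(
            f"gestational-age day component {days} outside 0-6"
        )
    return 7 * weeks + days


def _to_numeric(raw: pd.Series, sentinels: Sequence[str]) -> pd.Series:
    """Parse a string column to float with NaN for sentinels and junk.

    Returns (values, junk_mask): sentinel strings become NaN quietly; any
    other unparseable token is NaN *and* flagged as malformed by the caller
    via the companion mask.
    """
    s = raw.astype("string").str.strip()
    is_sentinel = s.isin(list(sentinels)) | s.isna()
    parsed = pd.to_numeric(s, errors="coerce")
    return parsed, (~is_sentinel) & parsed.isna()


def read_registry(
    path: str | Path, schema: RegistrySchema
) -> tuple[pd.DataFrame, ParseReport]:
    """Read one delimited registry file into canonical birth records.

    Every well-formed row yields exactly one record, in file order.  Rows
    with unparseable values (non-numeric weights, day-of-week components
    outside 0–6, unrecognised non-missing sex codes, …) are dropped and
    counted in the :class:`ParseReport`, separately from the downstream
    exclusion cascade, which only handles missing and implausible values.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"registry file not found: {path}")
    raw = pd.read_csv(
        path,
        sep=schema.delimiter,
        dtype=str,
        keep_default_na=False,
        encoding="utf-8",
    )
    missing_cols = [c for c in schema.columns.values() if c not in raw.columns]
    if missing_cols:
        raise ConfigurationError(
            f"{path}: mapped source columns absent from file: {missing_cols}"
        )

    n_rows = len(raw)
    sentinels = list(schema.sentinels)
    reasons: Counter = Counter()
    bad = pd.Series(False, index=raw.index)

    def flag(mask: pd.Series, reason: str) -> None:
        new = mask & ~bad
        if new.any():
            reasons[reason] += int(new.sum())
        bad.loc[mask] = True

    # year: required, integer
    year, junk = _to_numeric(raw[schema.columns["year"]], sentinels)
    flag(junk | year.isna() | (year % 1 != 0), "bad_year")
    # birthweight: optional, positive integer when present
    bw, junk = _to_numeric(raw[schema.columns["bw_grams"]], sentinels)
    flag(junk | (bw % 1 != 0) | (bw <= 0), "bad_birthweight")

    # gestational age per encoding
    if schema.ga_encoding == "days":
        ga_days, junk = _to_numeric(raw[schema.columns["ga_days"]], sentinels)
        flag(junk | (ga_days % 1 != 0) | (ga_days < 0), "bad_gestational_age")
        week_resolution = pd.Series(False, index=raw.index)
    else:
        weeks, junk = _to_numeric(raw[schema.columns["ga_weeks"]], sentinels)
        flag(junk | (weeks % 1 != 0) | (weeks < 0), "bad_gestational_age")
        if schema.ga_encoding == "weeks_plus_days":
            extra, junk = _to_numeric(
                raw[schema.columns["ga_extra_days"]], sentinels
            )
            flag(
                junk | (extra % 1 != 0) | (extra < 0) | (extra > 6),
                "bad_gestational_age_days",
            )
            # missing day component degrades gracefully to week resolution
            week_resolution = weeks.notna() & extra.isna()
            ga_days = 7 * weeks + extra.fillna(0)
        else:
            week_resolution = weeks.notna()
            ga_days = 7 * weeks

    # sex: optional; unrecognised non-missing codes are malformed
    sex_raw = raw[schema.columns["sex"]].astype("string").str.strip()
    sex_missing = sex_raw.isin(sentinels) | sex_raw.isna()
    sex = sex_raw.str.lower().map(dict(schema.sex_codes))
    flag(~sex_missing & sex.isna(), "bad_sex_code")
    sex = sex.where(~sex_missing)

    if "plurality" in schema.columns:
        pl_raw = raw[schema.columns["plurality"]].astype("string").str.strip()
        pl_missing = pl_raw.isin(sentinels) | pl_raw.isna()
        plurality = pl_raw.str.lower().map(dict(schema.plurality_codes))
        plurality = plurality.where(~pl_missing)
    else:
        plurality = pd.Series(pd.NA, index=raw.index, dtype="string")

    country = raw[schema.columns["country"]].astype("string").str.strip()
    flag(country.isin(sentinels) | country.isna(), "missing_country")

    records = pd.DataFrame(
        {
            "country": country,
            "year": year,
            "ga_days": ga_days,
            "bw_grams": bw,
            "sex": sex,
            "plurality": plurality,
            "ga_week_resolution": week_resolution.astype(bool),
        }
    )
    for key in schema.extra_keys:
        records[key] = raw[schema.columns[key]]

    records = records.loc[~bad].reset_index(drop=True)
    records["year"] = records["year"].astype(int)
    records["ga_days"] = records["ga_days"].astype("Int64")
    records["bw_grams"] = records["bw_grams"].astype("Int64")
    records["sex"] = records["sex"].astype(object).where(records["sex"].notna(), np.nan)
    records["plurality"] = (
        records["plurality"].astype(object).where(records["plurality"].notna(), np.nan)
    )

    report = ParseReport(
        n_rows=n_rows,
        n_records=len(records),
        n_malformed=int(bad.sum()),
        malformed_reasons=reasons,
    )
    report.check()
    return records, report


def write_table(rows: pd.DataFrame, path: str | Path) -> None:
    """Write any output table as UTF-8 comma-delimited text with a header.

    Values are written at full precision (no pre-rounding) so that reading
    the file back yields a value-identical table.
    """
    rows.to_csv(path, index=False, encoding="utf-8")


def read_table(path: str | Path) -> pd.DataFrame:
    """Read back a table written by :func:`write_table`."""
    return pd.read_csv(path, encoding="utf-8")


class SdgRegionMap:
    """Country → Sustainable Development Goal region lookup.

    The lookup is total: countries absent from the mapping resolve to the
    explicit ``"unassigned"`` label rather than raising, so that downstream
    aggregation can decide how to treat them.
    """

    UNASSIGNED = "unassigned"

    def __init__(self, mapping: Mapping[str, str]):
        self._map = {str(k): str(v) for k, v in mapping.items()}

    def region(self, country: str) -> str:
        return self._map.get(str(country), self.UNASSIGNED)

    def regions(self, countries: Sequence[str]) -> pd.Series:
        return pd.Series(
            [self.region(c) for c in countries], index=None, dtype=object
        )

    def unmapped(self, countries: Sequence[str]) -> list[str]:
        return sorted({str(c) for c in countries} - set(self._map))

    def __len__(self) -> int:
        return len(self._map)

    @classmethod
    def from_file(cls, path: str | Path) -> "SdgRegionMap":
        """Load from a two-column delimited file (country, region)."""
        df = pd.read_csv(path, encoding="utf-8")
        cols = [c.lower() for c in df.columns]
        df.columns = cols
        if not {"country", "region"} <= set(cols):
            raise ConfigurationError(
                f"region map {path} needs 'country' and 'region' columns"
            )
        return cls(dict(zip(df["country"].astype(str), df["region"].astype(str))))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self._map.items()), columns=["country", "region"]
        )
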