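"""Synthetic multi-country birth registries with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes: a gestational-age distribution mixing a Gaussian term component
with a skewed preterm tail, a Gaussian birthweight-given-gestational-age
law whose location/scale can be shifted and scaled to hit target SGA/LGA
rates, and realistic data defects injected after truth labelling — heaping
of flank-range weights onto exactly 2500 g, rounding to the nearest 100 g,
per-variable missingness, and implausible values in each exclusion category.

Truth labels are computed against the same toy standard the pipeline uses,
so with all corruption rates at zero the pipeline must recover the truth
exactly; any disagreement is a pipeline defect, not a standard mismatch.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import SdgRegionMap
from .standard import GrowthStandard
from .types import SMALL_TYPE6, assign_type6, assign_type10

Z10 = stats.norm.ppf(0.10)
Z90 = stats.norm.ppf(0.90)

#: weekly mean birthweight anchors (female), grams — a smooth, realistic
#: fetal-growth curve over the plausible 22+0 to 44+6 week window
_ANCHOR_WEEKS = np.array([22, 24, 26, 28, 30, 32, 34, 36, 38, 40, 42, 44, 45])
_ANCHOR_MEANS = np.array(
    [500, 680, 900, 1150, 1500, 1900, 2350, 2800, 3150, 3450, 3650, 3750, 3790],
    dtype="float64",
)

GA_MIN_DAYS = 154
GA_MAX_DAYS = 314

IMPLAUSIBLE_KINDS = ("bw_low", "bw_high", "ga_low", "ga_high", "combo")

DEFECT_TAGS = (
    "heaped",
    "rounded",
    "missing_bw",
    "missing_ga",
    "missing_sex",
    "implausible_bw_low",
    "implausible_bw_high",
    "implausible_ga_low",
    "implausible_ga_high",
    "implausible_combo",
)


@dataclasses.dataclass(frozen=True)
class ToyWeightFamily:
    """Gaussian-by-week birthweight law shared by generator and standard.

    The female mean is piecewise-linear between weekly knots; males are
    offset by a constant.  The scale is either a fixed coefficient of
    variation of the mean (default 12%) or a constant SD in grams.  Because
    the toy standard's centile knots are built from the same knots and the
    standard interpolates linearly, quantile relationships hold exactly at
    every gestational day, not only at knots.
    """

    knot_days: tuple = tuple(range(GA_MIN_DAYS, 309, 7)) + (GA_MAX_DAYS,)
    mean_female: tuple = ()
    male_offset_g: float = 100.0
    cv: float = 0.12
    sd_constant_g: float | None = None

    def __post_init__(self) -> None:
        if not self.mean_female:
            means = np.interp(
                np.asarray(self.knot_days) / 7.0, _ANCHOR_WEEKS, _ANCHOR_MEANS
            )
            object.__setattr__(self, "mean_female", tuple(means))
        if len(self.mean_female) != len(self.knot_days):
            raise ValueError("mean_female must align with knot_days")
        if self.sd_constant_g is not None and self.sd_constant_g <= 0:
            raise ValueError("sd_constant_g must be positive")
        if self.sd_constant_g is None and self.cv <= 0:
            raise ValueError("cv must be positive")

    def mean(self, ga_days, sex) -> np.ndarray:
        ga = np.asarray(ga_days, dtype="float64")
        base = np.interp(ga, np.asarray(self.knot_days), np.asarray(self.mean_female))
        offset = np.where(np.asarray(sex, dtype=object) == "male", self.male_offset_g, 0.0)
        return base + offset

    def sd(self, ga_days, sex) -> np.ndarray:
        if self.sd_constant_g is not None:
            return np.full(np.shape(np.asarray(ga_days)), float(self.sd_constant_g))
        return self.cv * self.mean(ga_days, sex)

    def standard(self) -> GrowthStandard:
        """Toy centile standard: 10%/90% normal quantiles at every knot."""
        frames = []
        for sex in ("male", "female"):
            days = np.asarray(self.knot_days)
            mean = self.mean(days, np.repeat(sex, days.size))
            sd = self.sd(days, np.repeat(sex, days.size))
            if np.any(mean + Z10 * sd <= 0):
                raise ValueError("toy standard would have non-positive p10")
            frames.append(
                pd.DataFrame(
                    {
                        "sex": sex,
                        "ga_days": days,
                        "p10_g": mean + Z10 * sd,
                        "p90_g": mean + Z90 * sd,
                    }
                )
            )
        return GrowthStandard(
            pd.concat(frames, ignore_index=True),
            provenance="synthetic gaussian_by_week toy standard",
        )


def make_toy_standard(
    family: str = "gaussian_by_week", params: dict | None = None
) -> GrowthStandard:
    """Build a synthetic centile standard from a named distribution family."""
    if family != "gaussian_by_week":
        raise ValueError(f"unknown toy-standard family {family!r}")
    return ToyWeightFamily(**(params or {})).standard()


def _rates_field():
    return dataclasses.field(default_factory=dict)


@dataclasses.dataclass
class CountryConfig:
    """Per-country generating conditions.

    ``sga_target``/``lga_target`` are the marginal probabilities of falling
    below the 10th / above the 90th centile of the toy standard; they are
    achieved analytically by a location shift and scale factor on the
    Gaussian weight law, so they hold at every gestational age.
    ``implausible_rates`` maps any of ``bw_low``, ``bw_high``, ``ga_low``,
    ``ga_high``, ``combo`` to injection rates.  ``coverage_pct`` and
    ``facility_pct`` are metadata consumed by the eligibility check.
    """

    country: str
    years: Sequence[int]
    births_per_year: int
    preterm_rate: float = 0.065
    sga_target: float = 0.10
    lga_target: float = 0.10
    sex_ratio_male: float = 0.515
    multiple_rate: float = 0.03
    term_mean_days: float = 280.0
    term_sd_days: float = 9.0
    preterm_shape: float = 2.0
    preterm_scale_days: float = 14.0
    missing_bw_rate: float = 0.0
    missing_ga_rate: float = 0.0
    missing_sex_rate: float = 0.0
    heaping_fraction: float = 0.0
    round100_fraction: float = 0.0
    implausible_rates: dict = _rates_field()
    coverage_pct: float = 98.0
    facility_pct: float = 97.0

    def validate(self) -> None:
        rates = {
            "preterm_rate": self.preterm_rate,
            "sga_target": self.sga_target,
            "lga_target": self.lga_target,
            "sex_ratio_male": self.sex_ratio_male,
            "multiple_rate": self.multiple_rate,
            "missing_bw_rate": self.missing_bw_rate,
            "missing_ga_rate": self.missing_ga_rate,
            "missing_sex_rate": self.missing_sex_rate,
            "heaping_fraction": self.heaping_fraction,
            "round100_fraction": self.round100_fraction,
            **{f"implausible_{k}": v for k, v in self.implausible_rates.items()},
        }
        for name, value in rates.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{self.country}: rate {name}={value} outside [0, 1]")
        unknown = set(self.implausible_rates) - set(IMPLAUSIBLE_KINDS)
        if unknown:
            raise ValueError(f"{self.country}: unknown implausible kinds {unknown}")
        if not 0.0 < self.sga_target < 1.0 or not 0.0 < self.lga_target < 1.0:
            raise ValueError(f"{self.country}: SGA/LGA targets must be in (0, 1)")
        if self.sga_target + self.lga_target >= 1.0:
            raise ValueError(
                f"{self.country}: sga_target + lga_target must be < 1 "
                "(the AGA band would be empty)"
            )
        if len(self.years) == 0 or self.births_per_year <= 0:
            raise ValueError(f"{self.country}: needs years and a positive size")

    @property
    def small_composite_target(self) -> float:
        """Expected small-composite prevalence implied by the targets."""
        return self.preterm_rate + (1.0 - self.preterm_rate) * self.sga_target

    @property
    def large_composite_target(self) -> float:
        """Expected large-composite (term + LGA) prevalence."""
        return (1.0 - self.preterm_rate) * self.lga_target


@dataclasses.dataclass
class GeneratorConfig:
    """Full multi-country scenario; the seed is mandatory."""

    countries: list[CountryConfig]
    seed: int
    family: ToyWeightFamily = dataclasses.field(default_factory=ToyWeightFamily)

    def validate(self) -> None:
        if not self.countries:
            raise ValueError("scenario has no countries")
        for c in self.countries:
            c.validate()

    def standard(self) -> GrowthStandard:
        return self.family.standard()


def _shift_scale(sga: float, lga: float) -> tuple[float, float]:
    """Location shift and scale (in SD units) hitting the target tail rates.

    Solves P(Z' < z10) = sga and P(Z' > z90) = lga for Z' = s + k·Z with
    Z standard normal; exact because the toy standard's centiles are the
    10%/90% quantiles of the unshifted law.
    """
    a = stats.norm.ppf(sga)
    b = stats.norm.ppf(1.0 - lga)
    k = (Z90 - Z10) / (b - a)
    s = Z10 - k * a
    return s, k


def _sample_ga(rng: np.random.Generator, cfg: CountryConfig, n: int) -> np.ndarray:
    """Gestational ages in days: term Gaussian + bounded skewed preterm tail."""
    preterm = rng.random(n) < cfg.preterm_rate
    ga = np.empty(n, dtype="float64")
    n_term = int((~preterm).sum())
    term = rng.normal(cfg.term_mean_days, cfg.term_sd_days, size=n_term)
    ga[~preterm] = np.clip(term, 259.0, float(GA_MAX_DAYS))
    n_pt = int(preterm.sum())
    tail = rng.gamma(cfg.preterm_shape, cfg.preterm_scale_days, size=n_pt)
    ga[preterm] = np.clip(258.0 - tail, float(GA_MIN_DAYS), 258.0)
    return np.floor(ga).astype("int64")


def _sample_bw(
    rng: np.random.Generator,
    family: ToyWeightFamily,
    cfg: CountryConfig,
    ga: np.ndarray,
    sex: np.ndarray,
) -> np.ndarray:
    mean = family.mean(ga, sex)
    sd = family.sd(ga, sex)
    s, k = _shift_scale(cfg.sga_target, cfg.lga_target)
    z = np.clip(rng.standard_normal(ga.size), -4.0, 4.0)
    bw = mean + sd * (s + k * z)
    # keep genuine records inside the hard-plausibility window
    bw = np.clip(bw, 260.0, 6400.0)
    return np.round(bw).astype("int64")


def _inject(
    rng: np.random.Generator,
    records: pd.DataFrame,
    truth: pd.DataFrame,
    cfg: CountryConfig,
    family: ToyWeightFamily,
) -> None:
    """Apply corruption in order: heaping, rounding, missingness, implausible.

    Missingness and implausible injections target disjoint record sets, so
    each injected defect maps to exactly one intended exclusion reason.
    """
    n = len(records)
    bw = records["bw_grams"].to_numpy(dtype="float64")

    # 1. heaping: relocate a fraction of flank-range weights to exactly 2500 g
    eligible = np.flatnonzero((bw >= 2250) & (bw <= 2750) & (bw != 2500))
    if cfg.heaping_fraction > 0 and eligible.size:
        k = int(round(cfg.heaping_fraction * eligible.size))
        chosen = rng.choice(eligible, size=k, replace=False)
        bw[chosen] = 2500
        truth.loc[truth.index[chosen], "heaped"] = True

    # 2. rounding to the nearest 100 g (separate digit-preference defect)
    if cfg.round100_fraction > 0:
        pool = np.flatnonzero(~truth["heaped"].to_numpy())
        k = int(round(cfg.round100_fraction * pool.size))
        chosen = rng.choice(pool, size=k, replace=False)
        bw[chosen] = np.round(bw[chosen] / 100.0) * 100.0
        truth.loc[truth.index[chosen], "rounded"] = True
    records["bw_grams"] = bw.astype("int64")

    # 3. missingness per variable (independent draws)
    for var, col, rate in (
        ("missing_bw", "bw_grams", cfg.missing_bw_rate),
        ("missing_ga", "ga_days", cfg.missing_ga_rate),
        ("missing_sex", "sex", cfg.missing_sex_rate),
    ):
        if rate <= 0:
            continue
        hit = rng.random(n) < rate
        records.loc[records.index[hit], col] = (
            pd.NA if col != "sex" else np.nan
        )
        truth.loc[truth.index[hit], var] = True

    # 4. implausible injection, on records untouched by missingness so each
    #    defect maps to one intended exclusion reason
    clean = ~truth[["missing_bw", "missing_ga", "missing_sex"]].any(axis=1).to_numpy()
    pool = np.flatnonzero(clean)
    rng.shuffle(pool)
    cursor = 0
    for kind in IMPLAUSIBLE_KINDS:
        rate = cfg.implausible_rates.get(kind, 0.0)
        if rate <= 0:
            continue
        k = min(int(round(rate * n)), pool.size - cursor)
        chosen = pool[cursor : cursor + k]
        cursor += k
        idx = records.index[chosen]
        if kind == "bw_low":
            records.loc[idx, "bw_grams"] = rng.integers(50, 250, size=k)
        elif kind == "bw_high":
            records.loc[idx, "bw_grams"] = rng.integers(6500, 8000, size=k)
        elif kind == "ga_low":
            records.loc[idx, "ga_days"] = rng.integers(100, GA_MIN_DAYS, size=k)
        elif kind == "ga_high":
            records.loc[idx, "ga_days"] = rng.integers(GA_MAX_DAYS + 1, 340, size=k)
        else:  # combo: far outside the weight envelope, inside hard limits
            ga = records.loc[idx, "ga_days"].to_numpy(dtype="float64")
            sex = records.loc[idx, "sex"].to_numpy(dtype=object)
            s, scale_k = _shift_scale(cfg.sga_target, cfg.lga_target)
            mean_eff = family.mean(ga, sex) + s * family.sd(ga, sex)
            sd_eff = scale_k * family.sd(ga, sex)
            high = np.minimum(mean_eff + 8.0 * sd_eff, 6499.0)
            records.loc[idx, "bw_grams"] = np.round(high).astype("int64")
        truth.loc[idx, f"implausible_{kind}"] = True


def generate(config: GeneratorConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a registry and its ground-truth sidecar.

    Returns ``(records, truth)`` sharing a common index.  ``records`` is in
    the canonical column layout; ``truth`` carries the pre-corruption type
    labels (``true_type6``, ``true_type10``, ``true_small``, ``true_large``)
    computed against the toy standard, plus one boolean tag per injected
    defect.  Deterministic given the config's seed.
    """
    config.validate()
    standard = config.standard()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))

    rec_frames, truth_frames = [], []
    for cfg in config.countries:
        for year in cfg.years:
            n = cfg.births_per_year
            sex = np.where(rng.random(n) < cfg.sex_ratio_male, "male", "female")
            ga = _sample_ga(rng, cfg, n)
            bw = _sample_bw(rng, config.family, cfg, ga, sex)
            plurality = np.where(
                rng.random(n) < cfg.multiple_rate, "multiple", "singleton"
            )

            size_class = standard.classify(bw, sex, ga)
            type6 = assign_type6(ga, size_class)
            bw_class = np.where(bw < 2500, "LBW", "nonLBW")
            type10 = assign_type10(type6, bw_class)

            records = pd.DataFrame(
                {
                    "country": cfg.country,
                    "year": int(year),
                    "ga_days": pd.array(ga, dtype="Int64"),
                    "bw_grams": pd.array(bw, dtype="Int64"),
                    "sex": sex.astype(object),
                    "plurality": plurality.astype(object),
                    "ga_week_resolution": False,
                }
            )
            truth = pd.DataFrame(
                {
                    "country": cfg.country,
                    "year": int(year),
                    "true_type6": type6,
                    "true_type10": type10,
                    "true_small": np.isin(type6, SMALL_TYPE6),
                    "true_large": type6 == "T_LGA",
                }
            )
            for tag in DEFECT_TAGS:
                truth[tag] = False
            _inject(rng, records, truth, cfg, config.family)
            rec_frames.append(records)
            truth_frames.append(truth)

    records = pd.concat(rec_frames, ignore_index=True)
    truth = pd.concat(truth_frames, ignore_index=True)
    return records, truth


# -- packaged 23-country demonstration scenario -------------------------

#: per-country target prevalences (%) for the packaged scenario: the small
#: composite spans ~7.6-26% with median 11.7 and the large composite spans
#: ~5.6-28.8% with median 18.1, negatively paired so countries with many
#: small newborns have few large ones.  Targets are scenario inputs, not
#: claims about any real country.
_SCENARIO_SMALL_PCT = (
    7.6, 8.4, 9.2, 9.7, 9.9, 10.3, 10.7, 11.0, 11.2, 11.4, 11.6, 11.7,
    12.1, 12.6, 13.3, 14.2, 14.8, 15.7, 16.5, 18.6, 20.5, 23.0, 26.0,
)
_SCENARIO_LARGE_PCT = (
    28.8, 27.5, 25.9, 24.8, 23.5, 22.1, 21.2, 21.0, 20.4, 19.4, 18.7, 18.1,
    17.6, 17.0, 16.3, 15.5, 14.6, 13.5, 12.6, 11.9, 10.2, 8.0, 5.6,
)

_SCENARIO_REGIONS = (
    "Eastern and South-Eastern Asia and Oceania",
    "Latin America and the Caribbean",
    "Northern America, Australia and New Zealand, Central Asia and Europe",
    "Western Asia and Northern Africa",
)


def scenario_region_map() -> SdgRegionMap:
    """Region assignment for the packaged scenario's 23 synthetic countries."""
    return SdgRegionMap(
        {
            f"country_{i + 1:02d}": _SCENARIO_REGIONS[i % len(_SCENARIO_REGIONS)]
            for i in range(23)
        }
    )


def scenario_paperlike(
    seed: int = 20230508,
    births_per_year: int = 5000,
    n_years: int = 10,
    first_year: int = 2008,
) -> GeneratorConfig:
    """Packaged 23-country scenario for demonstration and integration tests.

    Twenty countries carry ``n_years`` years of data; three carry fewer than
    four years, so exactly 20 series survive the trend-eligibility rule.
    Mild realistic defects (light missingness and heaping, sparse
    implausible records) are on everywhere, but below every quality
    threshold, so all countries pass the eligibility check by construction.
    """
    countries = []
    for i, (small, large) in enumerate(
        zip(_SCENARIO_SMALL_PCT, _SCENARIO_LARGE_PCT)
    ):
        small_p = small / 100.0
        large_p = large / 100.0
        preterm = float(np.clip(0.65 * small_p, 0.045, 0.12))
        sga = (small_p - preterm) / (1.0 - preterm)
        lga = large_p / (1.0 - preterm)
        short = i >= 20  # last three countries: too few years for trends
        years = (
            range(first_year, first_year + (2 if i == 20 else 3))
            if short
            else range(first_year, first_year + n_years)
        )
        countries.append(
            CountryConfig(
                country=f"country_{i + 1:02d}",
                years=list(years),
                births_per_year=births_per_year,
                preterm_rate=preterm,
                sga_target=sga,
                lga_target=lga,
                missing_bw_rate=0.004,
                missing_ga_rate=0.006,
                missing_sex_rate=0.001,
                heaping_fraction=0.05,
                round100_fraction=0.02,
                implausible_rates={
                    "bw_low": 0.0005,
                    "bw_high": 0.0002,
                    "ga_low": 0.0005,
                    "ga_high": 0.0003,
                    "combo": 0.001,
                },
            )
        )
    return GeneratorConfig(countries=countries, seed=seed)
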