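# Methods

## The classification model

Every live birth with complete, plausible data is placed in exactly one of
six newborn types, the cross of

- **gestational-age class**: preterm (PT) up to 36 weeks + 6 days,
  term (T) from 37 weeks + 0 days. Gestational age is carried internally
  as integer days since last menstrual period, so the split is `ga ≤ 258`
  vs `ga ≥ 259` with no week/day ambiguity. Sources reporting completed
  weeks only are normalised with a day component of 0 and flagged
  (`ga_week_resolution`); week-based thresholds then reduce to
  completed-week comparisons.
- **size-for-gestational-age class**: SGA strictly below the 10th centile,
  LGA strictly above the 90th, AGA otherwise — weights exactly on either
  centile are AGA. Centiles come from a sex- and gestational-age-specific
  standard supplied as a table of knots.

The *small* composite is any type involving PT and/or SGA (PT+SGA, PT+AGA,
PT+LGA, T+SGA); *large* is T+LGA; T+AGA is the reference. The secondary
ten-type classification refines the six types by low birthweight
(LBW < 2500 g; exactly 2500 g is nonLBW). Two refinements, PT+SGA+nonLBW
and T+LGA+LBW, are essentially impossible anatomically given how the
centile curves sit relative to 2500 g; rather than silently merging them we
emit explicit `unexpected_*` buckets, so the ten-type table always collapses
to the six-type table exactly and conservation checks cannot be fooled.

## Data cleaning

The exclusion cascade removes records in a fixed order, each with exactly
one reason (first matching rule): missing gestational age (weight present),
missing birthweight (gestational age present), missing both, missing sex,
implausible birthweight (<250 g or ≥6500 g, boundaries read literally),
implausible gestational age (<154 or >314 days, i.e. outside 22⁺⁰–44⁺⁶
weeks), and implausible birthweight/gestational-age combinations. Flow
accounting is an exact integer identity (`n_input = n_included + Σ
exclusions`) checked on every run.

The combination rule uses an **envelope**: mean ± 5 sample standard
deviations (n−1) of birthweight per completed week, computed from the
records that survive the first six rules — a self-referential envelope
requiring no external reference population. It is pooled over sexes and
countries within a run; the multiplier is configurable. Weeks with fewer
than 10 records (configurable) get no bounds and produce no combination
exclusions, which avoids degenerate bounds in sparse extreme-week cells.
Missing-reason precedence (gestational age before birthweight before both
before sex) is a bookkeeping choice: a record missing both gestational age
and sex counts once, under missing gestational age.

Rows that fail to *parse* (non-numeric weights, a day-of-week component
outside 0–6, unrecognised sex codes) are counted in a separate parse
report, not in the cascade: the cascade accounts only for missing and
implausible values, and mixing the two would corrupt the flow chart.

## Quality battery

Per country-year and per country: missingness of birthweight, gestational
age and sex computed over **all records received** (pre-exclusion); shares
of births <500 g, <1000 g and at ≤28⁺⁶ weeks (≤202 days — the
day-resolution reading of "up to and including 28⁺⁶") and the heaping
index computed over the **cleaned analysis set**; implausible-combination
share over the received total. Both denominators are carried in the output.
The heaping index is n(bw = 2500 g) / n(bw ∈ [2250, 2499] ∪ [2501, 2750]),
undefined (not zero) when the flank window is empty. Country eligibility
(coverage ≥80% of the reference population, ≥80% facility births, ≥80%
completeness per variable) consumes the first two as metadata — they are
external population figures, not computable from a registry. Country-years
with any variable's missingness strictly above 20% are flagged, and the
national prevalences are recomputed without them as a sensitivity analysis.

## The centile standard engine

A standard is a table of (sex, ga_days, p10_g, p90_g) knots, validated for
strictly increasing knots per sex, non-crossing centiles and positive
weights. Between knots each centile is interpolated linearly in days (a
week-floor mode exists for week-resolution registries). The range can be
extended either by continuing the slope of the two outermost knots
(`linear_extrapolate`, the default, used to reach 154–314 days from a
narrower native range) or by holding boundary values constant (`clamp`);
the method is recorded in the standard's provenance and the extension
fails hard if it would produce non-positive or crossing centiles. Published
standards (e.g. INTERGROWTH-21st newborn size standards) are consumed as
user-supplied tables under this contract; the repository ships only
synthetic standards, and neither extension method claims to replicate any
particular published extrapolation.

## Aggregation

Country-year prevalences are type counts over the country-year's analysis
records. National prevalence pools a country's counts across years before
dividing (count-weighted), so multi-year national figures reflect record
volume, not a mean of annual rates; a year-level table is always emitted
alongside for sensitivity. Cross-country summaries are the median and
quartiles of the national prevalences with equal weight per national
dataset, overall and within each SDG region; quartiles use linear
interpolation between order statistics, and the rule is recorded in the run
manifest. Proportions are kept at full precision in machine-readable
output; the text summary prints one decimal.

## Trends

Annual composite prevalences (small, large; in %) are smoothed with a
centred 3-year moving average defined only where all three consecutive
calendar years exist — endpoints and gap-adjacent years stay undefined. A
year is flagged as a trend change when consecutive smoothed values differ
by strictly more than 0.5 **percentage points** (absolute, matching the
scale of the prevalences; not a relative 0.5%). Series are computed only
for countries with at least four country-years. Net change per decade
(2000–2009, 2010–2021) is last-defined minus first-defined smoothed value
within the period, with the years used recorded. Uncertainty on the raw
annual percentages is the binomial standard error under the normal
approximation, `100·√(p(1−p)/n)` — a labelled convention chosen because
annual prevalences are simple binomial proportions; no changepoint or
loess model is fitted.

## Synthetic registries

The generator draws, per country-year: sex (P(male) = 0.515 by default);
gestational age from a mixture of a term Gaussian (mean 280 d, SD 9 d,
truncated to 259–314 d) and a preterm tail (258 − Gamma(shape 2, scale
14 d), truncated to 154–258 d) whose weight is the preterm rate, so preterm
and SGA rates tune independently; and birthweight from a Gaussian whose
mean is piecewise-linear between weekly knots of a realistic fetal-growth
curve (500 g at 22 weeks to ≈3790 g post-term, females; males +100 g) with
SD proportional to the mean (CV 12%) by default. Target SGA/LGA rates are
hit *analytically* by solving for the location shift and scale factor on
the Gaussian that put exactly the target mass below the standard's 10th and
above its 90th centile; because the toy standard's knots are the 10%/90%
quantiles of the same family and both sides interpolate linearly, the
targets hold at every gestational day. Draws are clipped at ±4 SD and
weights to 260–6400 g so that uncorrupted records never trip the
plausibility rules.

Ground-truth type labels are computed **against the toy standard, before
corruption**, so with all corruption rates at zero the pipeline must
reproduce the truth labels record-for-record; tests of agreement therefore
isolate pipeline defects rather than standard mismatch. Corruption is then
applied in a fixed order — heaping (a fraction of weights in 2250–2750 g
moved to exactly 2500 g, targeting the heaping index's definition),
rounding to the nearest 100 g, per-variable missingness, implausible
injection — with every defect tagged in a truth sidecar. Implausible
injections target records untouched by missingness so each maps to one
intended exclusion reason; combination injections sit 8 SD above the
(shifted) conditional mean, capped at 6499 g, hence inside the hard limits
but far outside any ±5 SD envelope.

The packaged 23-country scenario assigns per-country small-composite
targets spanning 7.6–26% with median 11.7% and large-composite targets
with median 18.1% (negatively paired, so countries with many small
newborns have few large ones), preterm rates at 0.65× the small target
clamped to 4.5–12%, mild defects everywhere (0.4–0.6% missingness, 5%
heaping fraction, ≈0.25% implausible records), ten years of 5,000 births
for twenty countries and two or three years for the last three — so
exactly 20 countries clear the four-year trend rule. Default problem sizes
(~50,000 births per country, ~1.04 million records in total) keep a full
end-to-end run around ten seconds on one CPU while leaving binomial
standard errors small enough for meaningful recovery checks.

**What the generator does not emulate:** secular trends within a country
(annual targets are constant, so trend tests inject steps explicitly),
gestational-age measurement error and last-menstrual-period dating bias,
digit preference at values other than 2500 g and round hundreds,
missingness that is correlated with outcomes (all injections are completely
at random), birth-order/plurality structure in weights, and any real
country's joint (ga, bw) distribution. Passing recovery tests therefore
demonstrates that the pipeline's arithmetic and accounting are correct
under the stated statistical structure — not that any real registry meets
that structure.

## Numerical and degenerate-input choices

- Envelope cells need n ≥ 10 and a defined sample SD; single-record cells
  produce no bounds.
- An empty heaping-flank denominator yields NaN, reported as missing.
- Zero-count country-year rows are dropped from prevalence tables with a
  log notice rather than emitting 0/0.
- The moving average and change flags require consecutive calendar years;
  gaps never bridge.
- Quantiles: NumPy's `linear` method throughout.
- Re-running the cascade on its own output with the envelope held fixed
  excludes nothing (idempotence, under test).

## Known limitations

- The self-referential ±5 SD envelope estimates its mean and SD from data
  that may include the very outliers it is meant to catch; with heavy
  contamination the bounds inflate. Injected 8 SD outliers at realistic
  rates are still caught ≥95% of the time (under test).
- Disclosure control is minimal: a small-cell suppression option (<5)
  masks count tables only, and per-record output is off by default.
- No imputation: records with missing key variables are excluded, matching
  the analysis design this package implements.
- The trend machinery flags moving-average changes; it is not a formal
  changepoint model and carries no multiplicity control.
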