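# Methods

## Model and assumptions

The package models a food system as an annual mass balance per crop,
followed by a crop–nutrient network per year and region.

**Supply-chain balance.** For each production identifier (23 crops plus a
vegetable aggregate), annual production passes fractional losses at the
production, postharvest-handling and storage stages; net trade (imports −
exports − stock increase) is added and non-food use (feed, seed, other)
subtracted; the remainder passes the processing, distribution, retail and
consumption loss stages, is converted to grams/day (×10⁶/365) and reduced
to its edible fraction.  Assumptions baked into this accounting:

- Loss fractions are constant over the study years.
- Non-food use is diverted at the post-storage point, i.e. before the
  four consumer-side loss stages.
- A negative balance (net exports plus non-food use exceeding
  loss-adjusted availability) cannot be consumed: it is clamped to zero
  and logged as a diagnostic rather than raised, since it is a data
  inconsistency, not a programming error.

**Vegetables.** Production statistics carry vegetables only as an
aggregate.  The aggregate balance (stages 1–3, trade, uses) is computed
once, then split into seven subgroups by consumption shares; each
subgroup has its own consumer-side losses and edible proportion.  The
resulting diversity estimates are lower bounds: subgroups hide
species-level variety.

**Processing.** Rice and wheat are partitioned into whole-grain and
refined streams by a whole-grain fraction; both streams share the grain's
milling yield but differ in nutrient content.  Consumer-side (stage 4–7)
losses are applied to the combined grain stream before the split — the
alternative (stream-specific processing losses) would need data that
supply statistics do not provide.  Soybean, groundnut and sesame are
split between direct seed consumption and vegetable oil by a food/oil
fraction; sunflower seed, linseed and rapeseed go entirely to oil.  Oil
mass is seed mass × shelling rate × extraction rate; the groundnut
shelling rate is 0.7, and on the direct-consumption stream the shell is
captured by the form's edible proportion instead.  Mass is never created:
outputs are bounded by the input stream.

**Requirements.** Population requirements are age- and sex-weighted means
of per-capita reference intakes times total population.  EAR and RNI are
carried in parallel for 16 nutrients; potassium uses an adequate intake
and energy an estimated energy requirement (moderate physical activity).
Pregnancy/lactation increments are not part of the weighted average.
Age-group granularity is data-driven: whatever strata the DRI and
population tables share.

**Network statistics.** Coverage is the sum of supply/requirement ratios
over sources; source diversity is the exponential of the Shannon entropy
(natural log) of proportional contributions, with 0·ln 0 := 0.  Diversity
is invariant to which reference defines the requirement, since the
requirement cancels in the shares; it is reported as NaN (missing, not an
error) when a nutrient has no supply at all.  Band boundaries follow the
printed wording literally: supply exactly at the RNI is high; for AI/EER
nutrients, exactly 100% is medium ("above" is strict) and exactly 80% is
medium (the 80–100% band is inclusive).

**Scenarios.** The five scenario presets are switch sets over the same
pipeline.  Choices where the design was genuinely open:

- Whole-grain replacement is a transfer of 10% of the *refined* stream to
  the whole stream (w′ = w + 0.1·(1 − w)), so a system already consuming
  some whole grain is handled consistently.
- Feed repurposing (S2b) is linear: freed_i = feed_i × share_i ×
  red-meat reduction, with per-crop shares defaulting to 1 for maize and
  soybean and 0 otherwise, overridable per call.  Freed feed re-enters
  the balance before the consumer-side loss stages — it reaches consumers
  through the same chain as any food.
- Red-meat reduction scales only the red-meat term of the aggregated
  animal node; dairy, poultry, eggs and aquatic foods are unchanged.
- Self-sufficiency (S3) zeroes trade, feed and other non-food use but
  still subtracts seed (sowing is unavoidable), keeps the S2a efficiency
  settings, and routes every oilseed to direct seed consumption.
- In provincial mode, national trade and non-food-use totals are
  allocated to provinces by production share; in S3b these are zero, so
  the allocation only matters for exploratory provincial runs of other
  scenarios.
- Scenario presets are validated: constructing a config that names a
  preset id but contradicts its switches is a configuration error.

## Tunable parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| loss fractions l¹..l⁷ | data | — | from the loss table; must be in [0, 1) |
| FLW multiplier | 1.0 (S2/S3: 0.5) | — | scenario definition |
| whole-grain fraction | data (synthetic: 0.05) | — | current whole-grain share of the grain stream |
| whole-grain replacement | 0.10 | — | scenario definition |
| red-meat reduction | 0.45 | — | scenario definition |
| groundnut shelling rate | 0.7 | kernel mass fraction | processing convention |
| oil extraction rates | data (synthetic: 0.16–0.45) | oil per seed mass | typical pressing yields |
| Monte Carlo runs | 1000 | — | stable 5%/95% quantiles; configurable, seed mandatory |
| sensitivity sweep | ±20%, 2% steps | — | 21 levels including the identity point |
| retention factors | 1.0 | — | cooking-loss hook, per form × nutrient |

## The synthetic generator

The generator emulates the *schemas and structure* of food-balance-sheet
supply tables, composition tables with member items, population
structures and DRI tables — not the statistics of any real agriculture.
Defaults: 22 years (1997–2018), 31 provinces, 30 sources in six crop
groups, 18 nutrient entries, within-group content CV 0.2.  Specifics:

- Provincial productions are drawn with fixed Dirichlet province shares
  around plausible per-capita magnitudes; the national series is defined
  as their sum, so aggregation is consistent by construction.
- Non-food uses are drawn as fractions of loss-adjusted availability, so
  the balance stays positive unless `force_negative_bracket` deliberately
  exercises the clamping path.
- Member-level contents are drawn log-normally around the group value,
  mean-preserving with the configured CV — contents are positive and
  right-skewed, and a zero CV collapses members onto the group value.
- Whole-grain streams carry 1.2–1.8× the refined micronutrient contents;
  macronutrients are nearly equal across streams.
- EAR ≤ RNI per stratum and stratum shares summing to one hold by
  construction; national structure is the population-weighted mean of
  provincial structures.

Because magnitudes are plausible-range rather than calibrated, passing
tests demonstrate the *accounting and statistics* are correct — they say
nothing about any real country's nutrient adequacy.  Features of real
data not emulated: correlated year-to-year shocks, regional
nutrient-content variation, reporting gaps and methodology breaks in
trade series, and consumption-weighted (rather than uniform) member
relevance within groups.

At generation time the implied coverage and diversity are re-derived by
`nutrinet.oracle` — a literal loop transcription of the model kept free
of the vectorised pipeline code — and recorded as ground truth; the test
suite checks end-to-end recovery at 1e-9 relative tolerance on the full
default problem size (30 sources × 18 nutrients × 22 years).

## Numerical choices

- All randomness flows through explicitly seeded `numpy` generators; the
  generator uses per-table seed streams so tables are individually
  reproducible.
- Entropy terms with zero share contribute exactly zero (no epsilon).
- Vegetable shares must sum to 1 within 1e-6 (validation) while stratum
  proportions must sum to 1 within 1e-9 — the former are survey-derived,
  the latter are constructed.
- Band ties are resolved as stated above; classification is total on
  non-negative inputs.
- Test problem sizes: most tests use 1–3 provinces and 1–2 years; the
  recovery check runs the full default configuration (a few seconds); the
  Monte Carlo binomial check uses 10,000 runs on a single-region dataset.

## Known limitations

- Bioavailability is not modelled: coverage is supply relative to intake
  recommendations, not absorbed nutrient.
- The feed-repurposing rule is a declared linear stand-in; a
  herd-model-based mapping from red-meat reduction to freed feed would
  need livestock data outside this package's scope.
- Cooking losses are only a hook (retention factors default to 1).
- Inter-provincial flows are not modelled explicitly; provincial runs
  either pool nationally or isolate provinces entirely.
- Requirement uncertainty, loss-fraction uncertainty and trade-data
  uncertainty are not propagated; only composition aggregation and the
  one-crop production sensitivity are, mirroring the scope of the
  uncertainty module.
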