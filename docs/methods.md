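# Methods

## The model

`agroprior` is a Mamdani-style fuzzy inference pipeline, not a fitted
statistical model: every parameter is fixed by configuration, and a run is a
deterministic function of the input tables.  The stages are

1. **Indicators.**  Raw agricultural-statistics and food-composition tables
   are reduced to one value per species per variable (income USD ha⁻¹, Lafay
   trade-balance ratio, municipality coverage %, yield t ha⁻¹, percent
   contribution to daily Ca/Fe/Zn/energy targets, price per nutrient unit,
   traditional-consumption breadth, government-list membership).  Missing
   inputs propagate as missing; they never raise, because "undetermined" is
   a first-class outcome of the index.
2. **Normalization.**  Configurable per variable: `none`, `range_1_100`
   (affine map of the observed or a fixed window onto [1, 100]) or
   `log_range_1_100` (log₁₀ first, for income, which spans orders of
   magnitude).  Yield is normalized within each FAO food category, because
   yields are only comparable among like crops.  Affordability is normalized
   per nutrient.  Negative Lafay values (exports exceeding apparent supply)
   are clipped to 0 before fuzzification, since every membership support
   starts at or above 0.
3. **Fuzzification.**  Each normalized value is graded against the labelled
   membership functions of its variable and takes the label of maximal
   grade.  Ties break toward the label with the higher priority annotation —
   the conservative direction, flagging borderline species for attention
   rather than away from it.  A value activating no set is labelled
   `undetermined` at grade 0.
4. **Pillar aggregation.**  Composite pillars combine four labels through
   the decision index ID = Σ S_z·w_z / 4 with S_z ∈ {0..3} and w_z = ¼,
   classified by half-open intervals.  Economic: [0, 0.25) undetermined,
   [0.25, 0.46) low, [0.46, 0.65) medium, [0.65, 1] high.  Food security:
   identical except medium opens at 0.45.  Nutritional contribution and
   affordability are themselves four-input sub-indices (one label per
   nutrient) aggregated the same way with the economic threshold convention;
   their classes become two of the four food-security inputs.
5. **Imputation.**  See below.
6. **Final ranking.**  Pillar labels map onto a common ordinal scale
   (undetermined 0 / low 1 / medium 2 / high 3; geographic distant→1,
   close→2, local→3; vulnerability minor concern→1, threatened→3 — there is
   no medium vulnerability label).  Class rule: high if ≥ 3 pillars at level
   3; else medium if geographic ≥ 2 and ≥ 2 of the other three pillars ≥ 2;
   else low.  The crisp 0–100 value is the centroid of the class's output
   Gaussian: 90.0 / 55.0 / 15.0.

## Key design choices

- **Decision-index scaling.**  The published rule text writes the index as
  Σ(S_z·w_z)×100, which ranges over [0, 300] and is incompatible with its
  own [0, 1] thresholds.  We divide by 4 (the score span) instead: this is
  the unique simple scaling under which every homogeneous combination lands
  in its namesake interval (all-low → 0.25, all-medium → 0.50, all-high →
  0.75), and we treat ×100 as display scale.  The printed threshold gaps
  (0.24/0.25, 0.45/0.46, 0.64/0.65) are closed with half-open intervals.
- **Food-security scores.**  The published scores name only three levels
  (not-included/narrow/undetermined → 0; medium-use/low → 1;
  included/extensive/high → 3).  The medium label of the nutrition and
  affordability sub-indices is scored 2 by analogy with the economic scale.
- **Affordability direction.**  The parameter table annotates cheap
  nutrients ("low" price ratio) as high priority, but the rule text scores
  the literal label ("low" → 1).  The default follows the rule text; the
  `invert_affordability` switch applies the annotation (low↔high swap)
  instead.
- **Singleton semantics.**  Categorical variables are drawn as Gaussians of
  SD = 0.001 in the source figures; they are implemented as exact indicators
  with tolerance `sd_singleton`, which is behaviourally identical (inputs
  are mapped directly onto the singleton location) and numerically robust.
- **Centroid integration.**  Fixed grid, default resolution 0.01.  The grid
  extends beyond [0, 100] to cover the whole support of every activated set
  (Gaussians to μ ± 8.5σ; the income "high" trapezoid reaches 110), so the
  centroid of any symmetric activated set equals its centre to within one
  grid step — truncating at 100 would bias the high-priority centroid from
  90 to ≈ 89.7.
- **Blend mode.**  The published mechanism for intermediate priority values
  is not stated; by default activation is crisp (one class, grade 1, hence
  exactly three possible values).  An optional blend mode activates each
  output Gaussian by the share of pillars supporting it (the crisp class
  floored at 0.5 so the rule outcome dominates), producing a continuum.
- **Calibration path.**  `ckmeans_1d` provides globally optimal 1-D k-means
  (O(k·n²) dynamic programming over sorted values) for deriving label
  boundaries on new variables.  Default runs use the published membership
  parameters verbatim; the clustering is a tool for extending the index,
  not part of a default run.

## Imputation semantics

Only bank-conserved (BGVCOL) species are imputed, and only for the
geographic, economic and food-security pillars — vulnerability is
species-specific and never borrowed.  A species is a recipient when it
carries *no* own data for the pillar (species with partial data are
classified from what they have, with absent variables scoring 0).  Donor
search: first the gene pool — same genus, or same configured crop group
(`crop_groups` maps group names to genera) — then the provisional crop group
(same FAO food category).  Among eligible data-bearing donors the worst case
is chosen: the donor whose own data yield the lowest decision index for that
pillar (for the geographic pillar, the lowest ordinal level), ties broken
lexicographically on species id.  This operationalises "worst case in terms
of data" as the anti-inflation choice.  Recipients' missing variables are
copied from the donor (never overwriting own values; variables the donor
also lacks stay missing), and the pillar is tagged GP or PCG; everything
else is tagged reliable.  Government-list membership is special: a known
status (included or explicitly not included) does not make a species
data-bearing, but an unknown status is borrowed along with the rest.  The
one published per-species geographic correction is expressed as a
`geographic_overrides` config entry, not code.

## The synthetic-data generator

The generator emulates the *structure* the index consumes — genus structure
(geometric genus sizes, mean 2.5, singleton genera for the NCB group), nine
FAO categories, the 26-region vocabulary, red-list records, and the study's
observed missingness (62% economic, 73% food security, applied per pillar by
blanking a species' rows) — not the statistics of any real agricultural
economy.  For each species a target label is drawn per variable first
(class priors: geographic 0.45/0.25/0.30 local/close/distant, vulnerability
0.10/0.30/0.60, economic and food 0.40/0.35/0.25 low/medium/high); raw
table values are then constructed by inverting the indicator formulas so the
computed, normalized indicator lands strictly inside the target label's
membership plateau (3% interior padding).  Ground truth is therefore exact
by construction, and with zero missingness the pipeline recovers 100% of
planted labels — the one caveat being the trade-balance "medium" set, whose
plateau is the single printed point 20.8 and is recovered to ~1e-13 rather
than bit-exactly after CSV round-trips.

Affordability is the one variable the pipeline range-normalizes per
nutrient, so plateau planting cannot work pointwise.  The generator instead
keeps price/content separable across nutrients — price_i ∝ t_i per species,
content_ij ∝ the nutrient's daily target — so the per-nutrient affine
normalization maps every nutrient's ratio through the same function of t_i,
and pins the observed range of t at exactly [1, 100] with two anchor
species (one at the undetermined floor, one at the high ceiling).  The
normalized affordability of every species then equals its planted value
exactly.  Nutritional contributions are natural percentages of the daily
target and are generated directly on plateau; all other variables use
normalization `none` in the generator's emitted config (`config.yaml`),
which also sets TM = 1000 municipalities.

`ensure_donors` guarantees at least one complete congener per incomplete
BGVCOL species (genus sizes forced ≥ 2, one member per genus unmasked, the
two affordability anchors kept intact); `hard_mode` samples from membership
ramps instead of plateaus to exercise tie-breaking, at the cost of exact
ground truth.  What passing the recovery tests shows is that the pipeline
is the identity on the label structure it defines — it says nothing about
how well the published membership parameters describe any real country's
data, and the generator's Lafay values live on the published [0, 100]
fuzzification scale rather than the natural ratio scale.

## Parameters that matter

| Parameter | Default | Units / notes |
|---|---|---|
| universe resolution | 0.01 | grid step for centroid integration |
| weights w_z | 0.25 each | must sum to 1 (validated) |
| thresholds | 0.25/0.46/0.65 econ, 0.25/0.45/0.65 food | decision-index class bounds |
| total_municipalities (TM) | 1122 | configuration value, denominator of coverage |
| daily_targets | Ca 1000 mg, Fe 14 mg, Zn 10 mg, energy 1500 kcal | child daily intake targets |
| yield_years / trade_years | 2007–2017 | averaging windows |
| income_year | latest | single-year income |
| sd_singleton | 0.001 | singleton tolerance |
| invert_affordability | false | see above |

## Problem sizes

The test suite and the acceptance script run the full pipeline at n = 345
species (the study's collection size), the rule-table checks enumerate all
256 + 96 combinations, the final-class monotonicity check enumerates all
4⁴ level combinations, and the 1-D k-means is verified against exhaustive
split-point search on 200 random instances with n ≤ 25 — all chosen so the
entire suite completes in well under a minute.

## Known limitations

- The published traditional-consumption trapezoids (narrow 0.11–1.25,
  medium 1.05–1.35, large 1.35–100) are inconsistent with the stated 1–8 →
  1–100 range normalization of region counts; they are used as printed and
  the normalization window remains configurable.
- No currency conversion, inflation adjustment or cross-year price
  imputation; each input table is taken at its own vintage.
- Figure regeneration and web presentation are out of scope; outputs are
  CSV/JSON tables.
- Reproducing the original study's per-class counts requires its deposited
  dataset as an input directory; the package consumes such data through
  `agroprior run` but does not bundle or fetch it.
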