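# Methods

This note documents the accounting model, its parameters and defaults, the
synthetic data the package tests itself on, and the design choices made where
the design was genuinely open.

## Boundary and functional unit

The system boundary is cradle to farm gate: all on-farm emissions from
animal husbandry and feed production, plus the embedded (off-farm) emissions
of purchased fertilizer, concentrate and electricity. Emissions attached to
purchased cattle on their farm of origin are excluded; purchased animals
contribute only the emissions of their residence on the analysed farm, and
their purchase live weight is netted out of the functional unit,

    LWG = (lw_sold + lw_closing) − (lw_purchased + lw_opening)   [kg/yr].

A footprint is undefined (and raised as an error) when LWG ≤ 0. All farm
emissions are allocated to live weight on beef-only farms (beef fraction
1.0); a fractional allocation hook exists for holdings where part of the
herd's burden belongs to milk. Carcass-weight footprints divide the
per-LW-sold value by a 55% dressing percentage. Gross and net are both
reported; net = gross − sequestration, and a negative net (sink exceeding
gross) is flagged, never clamped.

## Emission pathways

All source operations are linear (homogeneous of degree 1) in their activity
datum; this is a property test. Constants: CH₄ energy density 55.65 MJ/kg,
CH₄ density 0.67 kg/m³, N₂O-N→N₂O 44/28.

| Pathway | Form | Default factors (IE_style) |
|---|---|---|
| Enteric CH₄ (tier 2) | GEI·(Ym/100)·365/55.65 per head | Ym 6.5% of GEI |
| Enteric CH₄ (per-head) | table[category]·head | FR_style table |
| Manure CH₄ | VS·365·B₀·0.67·MCF/100, system-weighted | B₀ 0.17, MCF 17/4/1% |
| Manure storage N₂O | Nex·frac_housed·EF₃(system)·44/28 | EF₃ 0.005 |
| Manure spreading N₂O | Nex·frac_housed·EF₁·44/28 | EF₁ 0.01 |
| Grazing returns N₂O | Nex·frac_grazing·EF₃_prp·44/28 | EF₃_prp 0.02 |
| Soil fertilizer N₂O | fert_N·EF₁·44/28 | EF₁ 0.01 |
| Indirect N₂O | (N·Frac_gas·EF₄ + N·Frac_leach·EF₅)·44/28 | 0.10/0.20, 0.30, EF₄ 0.01, EF₅ 0.0075 |
| Liming / diesel CO₂ | linear factors | 0.44 kg/kg, 2.67 kg/L |
| Off-farm CO₂e | linear factors, pre-aggregated | fert 6.0 kg/kg N, conc 0.55–1.0 kg/kg, elec 0.45 kg/kWh |
| Sequestration | area·rate + length·rate | 500 kg CO₂e/ha, 1.25 kg/m |

Numeric defaults follow the IPCC 2006 tier-1/2 values where such a value
exists; they are deliberately config, not code — the framework's point is
that regional factor sets differ, and every factor is overridable per set.

**Manure time apportionment.** Activity data give housing and grazing
periods but no apportionment rule, so the engine uses the grazing fraction
of the year for pasture deposition (pasture MCF and EF₃_prp) and splits the
housed remainder across the farm's storage-system shares, renormalized over
the non-pasture systems (housed manure defaults to solid storage if no
storage share is given). Stored manure N is subsequently field-spread and
routed through EF₁ under a distinct `manure_spreading` source; the soil
fertilizer term in the assembled inventory therefore covers synthetic N only
(no double counting). Whether original regional models use a distinct
spreading factor is not documented; EF₁ is the defensible IPCC route.

**Pre-aggregated CO₂e.** Off-farm factors are only available in CO₂e, not by
gas. These entries are stored under gas CO₂ with a flag, and GWP aggregation
weights them by exactly 1, so a non-standard CO₂ GWP never distorts them.

## GWP set

Default 100-year factors 25 (CH₄), 298 (N₂O), 1 (CO₂) — the values the
framework standardizes on across factor sets. Alternative sets (e.g. AR6)
can be loaded from config.

## The three packaged factor sets

The sets differ in exactly the dimensions on which regional beef models
diverge most: the enteric estimate and the embedded concentrate factors.

- `IE_style`: tier-2 enteric (Ym 6.5%), mid-range concentrate factors.
- `FR_style`: per-head enteric table whose entries exceed the tier-2 output
  for the same cohort at typical intakes (the per-head values are design
  placeholders calibrated only to sit above the tier-2 estimate, as the
  regional tier-3 models do); near-zero-carbon electricity; higher grassland
  sequestration credit.
- `ES_style`: tier-2 with a lower Ym (5.5%) and the highest embedded
  concentrate factors of the three.

These choices reproduce the comparison structure seen across regional
models: the per-head set estimates the highest footprints on suckler farms,
the low-Ym set the lowest, and the concentrate factor difference surfaces on
ad-libitum fattening systems.

## Comparison statistics

`run_sets` fills the farm × set grid of gross footprints per kg LWG
(per-cell failures are recorded and excluded pairwise, never imputed).
`pairwise_mean_diff` is the mean over common farms of (a − b).
`ranking_concordance` ranks farms within each set (ties broken by farm-id
order) and computes Kendall tau-b between set columns — tau-b because it is
the standard tie-corrected quantification of ranking consistency. A
mixed-model ranking (farm *i* scored by set *i* mod *k*) is evaluated
against each pure-set ranking to quantify how mixing models perturbs
within-group rankings.

## Mitigation engine

Measures act by one of two mechanisms. *Parameter overrides* re-run the
whole engine with engine or farm parameters replaced (feed additive: Ym →
4.95, under the <5%-of-GEI cap such additives can reach; hedgerow planting:
hedgerow length → a 4000 m planting norm; grassland preservation: a
maintained sequestration rate). Override values are absolute, and
conflicting overrides in a plan resolve last-writer-wins with a logged
warning. *Intensity deltas* scale the named gas of the affected sources by a
percentage. Sequestration measures move the net footprint only.

Stacked deltas on the same (source, gas) combine multiplicatively —
(1+δ₁/100)(1+δ₂/100) — so stacked reductions on one source are sub-additive
and can never exceed 100%; deltas on disjoint sources are exactly additive
on the whole footprint, which is the arithmetic of removing disjoint masses.
The total plan reduction is order-invariant; the reported per-measure
contributions are sequential marginals in plan order and do depend on order.

Per-measure magnitudes in the packaged catalogue are package design values
drawn from the abatement literature for Western European beef systems,
ordered by group potential (animal performance & diet > soil & land use >
manure > energy) and flagged where the literature reports high uncertainty
(feed additives, clover, urease inhibitors, grassland preservation). Under
these conditions no single measure reaches the 15% net-reduction target on
the synthetic suite (the feed additive peaks around 14% on the most
enteric-dominated farms) while the stacked plan exceeds 15% on every suite
farm — the structural finding the engine is designed to express.

## Synthetic farms

The generator emulates a 20-farm case-study panel, five per country
flavour: IE (one farm of each of the five systems, long grazing seasons,
70–110 kg fertilizer N/ha, low concentrate), FR (two suckler-to-weaning, two
suckler-to-beef, one fattening; 35–70 kg N/ha), IT (four intensive fattening
units growing maize on-farm, one suckler-to-beef selling younger/lighter
animals), ES (three extensive suckler-to-beef farms with purchased finishing
cattle — the largest land areas of the panel — and two dry-lot fattening
units on under 5 ha). Suckler-to-weaning progeny are sold at 8 months, which
fixes the weanling cohort's average annual headcount at 8/12 of the weaned
crop.

Sampling is uniform within per-archetype bounds, uncorrelated across
parameters; herds are in steady state (opening = closing mass). Bounds were
calibrated once, at build time, so that default-set footprints land in the
plausible published range for developed-country beef (roughly 8–36 kg
CO₂e/kg CW across systems), enteric fermentation is the largest source on
grass-based suckler farms (44–52% of gross here), and fattening systems show
the highest output per hectare. The generator does not reproduce any real
farm panel, models no climate/soil covariates, no herd dynamics over time
and no correlation structure (large farms are not systematically more or
less intensive), so passing tests demonstrate the engine's arithmetic and
the framework's structural findings on realistic magnitudes — not predictive
accuracy for real farms.

Determinism: one integer seed drives the whole suite; each farm draws from
`default_rng(seed·1000 + index mod 2³¹)`.

## Numerical choices and degenerate inputs

- Manure-system shares must sum to 1 within 1e-6 at engine entry (1e-9 at
  validation); profile shares sum to 100 within 1e-6.
- A farm with no livestock and no inputs yields an all-zero inventory; its
  emission profile is undefined and raises rather than returning NaNs.
- Division guards: LWG ≤ 0 and zero-gross profiles raise typed errors;
  per-LW-sold is NaN when nothing is sold.
- Reports print four significant digits; round-tripping a report is exact
  only to that precision, while farm JSON round-trips bit-exactly.

## Known limitations

Single farm-year snapshot (no herd demography, no soil-carbon dynamics —
sequestration is a fixed per-area/per-length rate); no NH₃/NO₃ water-quality
accounting beyond the indirect-N₂O pathway; no economics, no
marginal-abatement-cost ordering of measures; no protein- or
energy-corrected functional units; the FR per-head enteric table and all
mitigation magnitudes are design values, not measurements.
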