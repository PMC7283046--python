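# beefcarbon

Cradle-to-farm-gate greenhouse-gas accounting for beef farming systems, with
pluggable region-flavoured emission-factor sets, a multi-model comparison
harness, and a mitigation-scenario engine evaluated against a 15%
footprint-reduction target.

## Who this is for

Researchers and advisors who quantify the carbon footprint of beef farms —
suckler, dairy-calf-to-beef and intensive fattening systems — and who need to
(a) compare what different regional footprint models say about the same
farms, and (b) estimate how far stacked mitigation measures move a farm
towards a reduction target. Everything runs from one farm-year of activity
data: land areas, cattle inventories, purchase/sale live weights, fertilizer
and lime, concentrate feed, housing/grazing periods, manure storage systems
and energy use.

## The model

For each farm the engine computes an annual per-source, per-gas emission
inventory inside the cradle-to-farm-gate boundary:

- **Enteric CH₄** — either tier-2 from gross energy intake,
  `CH₄ (kg/head/yr) = GEI × (Ym/100) × 365 / 55.65`, where `Ym` is the
  methane conversion factor (% of GEI), or a per-head table (tier-3 style);
- **Manure CH₄** — `VS × 365 × B₀ × 0.67 × MCF/100`, time-apportioned between
  pasture deposition (grazing days) and storage systems;
- **Manure, grazing, soil and indirect N₂O** — excreted and applied N routed
  through EF₃ (storage, pasture), EF₁ (field application), and the
  volatilization/leaching pathways (Frac_gas·EF₄, Frac_leach·EF₅), with
  N₂O-N × 44/28;
- **CO₂ and embedded CO₂e** — liming, diesel, and off-farm burdens of
  fertilizer manufacture, concentrate production and electricity;
- **Carbon sequestration** by grassland soils and hedgerows, kept as a
  separate sink term.

Gas masses are aggregated with the standardized 100-year GWPs (25 CH₄,
298 N₂O, 1 CO₂). The functional unit is on-farm **live-weight gain**,
`LWG = (sold + closing) − (purchased + opening)`, so purchased cattle carry
no upstream burden. Results report gross and net (= gross − sequestration)
footprints per kg LWG, per kg LW sold, and per kg carcass weight (55%
dressing percentage), plus the percentage source profile.

Three factor sets ship with the package — `IE_style` (tier-2 enteric),
`FR_style` (per-head enteric table, systematically higher for the same
cohort) and `ES_style` (lower Ym, higher embedded concentrate factors) — and
any other set can be supplied as a flat YAML/JSON file.

## Worked example

```python
from importlib import resources
import beefcarbon as bc
from beefcarbon import io as bio
from beefcarbon.mitigation import MitigationPlan

with resources.as_file(
    resources.files("beefcarbon.data").joinpath("examples/farms_example.json")
) as p:
    farms = bio.read_farms(p)          # two synthetic example farms

efs, gwp = bc.load_ef_set("IE_style"), bc.load_gwp_set()
for farm in farms:
    r = bc.footprint(farm, efs, gwp)
    print(farm.farm_id, farm.system.value,
          round(r.gross_per_lwg, 2), round(r.net_per_lwg, 2),
          round(r.per_cw, 2), round(r.profile[bc.Source.ENTERIC], 1))

plan = MitigationPlan(measures=bc.load_measure_catalogue())
verdict = bc.evaluate_target(bc.stack_plan(farms[0], efs, plan, gwp))
print(round(verdict.reduction_pct, 1), verdict.passed)
```

prints

```
EX1 suckler_to_beef 17.14 15.29 31.16 43.5
EX2 beef_fattening 9.11 9.11 8.41 32.2
35.8 True
```

EX1, a grass-based suckler-to-beef farm, emits 17.14 kg CO₂e per kg of
live-weight gain gross and 15.29 net of grassland/hedgerow sequestration
(31.16 per kg carcass weight); enteric fermentation is its largest source at
43.5% of gross emissions. The intensive fattening unit EX2 is roughly half
that intensity and sequesters almost nothing. Stacking the full packaged
mitigation plan on EX1 cuts its net footprint by 35.8%, clearing the 15%
target.

The same workflows are available from a shell:

```sh
beefcarbon simulate --seed 42 -o out/                     # 20-farm synthetic suite
beefcarbon footprint --farms out/farms_suite.json --ef-set IE_style -o out/fp
beefcarbon compare  --farms out/farms_suite.json --ef-sets IE_style,FR_style,ES_style -o out/cmp
beefcarbon mitigate --farms out/farms_suite.json --ef-set IE_style -o out/mit
```

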