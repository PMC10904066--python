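# importcost

Import-cost measurement and accounting for medical supply shipments.

Health programs that procure abroad pay air freight, in-country land
freight and customs clearance fees on top of the purchase price.  These
*import costs* are routinely lumped together or ignored in program budgets
and cost-effectiveness analyses, yet they can amount to a tenth or more of
a shipment's value and are driven by a small subset of items.  `importcost`
is a toolkit for health-economics and supply-chain analysts that measures
these costs from ordinary procurement records (order invoices, air
waybills, a freight bill, a customs fee estimate) and allocates them down
to single units — one tablet, one vial, one test.

## Method

The package implements a five-step costing framework:

1. **Identify** the causes of import cost from the program's perspective
   (air freight, land freight, customs clearance; customs duties are waived
   for humanitarian goods).
2. **Collect** cost data per cargo type (standard 15–25 °C, cool 2–8 °C,
   frozen on dry ice): billed air freight, gross weight, volume; a lump-sum
   land freight for the truckload; an agent fee per declared customs line.
3. **Choose an allocation base** per cost: weight for transport, units per
   item line for customs.
4. **Allocate proportionally**, in three stages:
   - (a) a cargo billed with several destinations is split between its
     parts by part gross weight, keeping only the program's share;
   - (b) the land-freight lump sum is split between cargos by cargo gross
     weight;
   - (c) within a cargo, transport cost is spread over units at the cargo's
     €/kg *net weight* rate (net weight = Σ unit weight × quantity,
     excluding cargo packaging), and each line's customs fee is split
     equally among the units declared in that line:

   `unit import cost = w · (C_air + C_land) / W_net + F_line / n_line`

   where `w` is the unit weight, `W_net` the cargo order net weight,
   `C_air`, `C_land` the cargo's allocated transport totals, `F_line` the
   per-line customs fee and `n_line` the units in the item's line.
5. **Roll up**: item cost = unit cost × quantity; cargo and shipment totals
   by summation.  Allocation conserves every total exactly.

Around the core sit: unit-weight imputation for items missing a catalog
weight (donor with the same active ingredient and concentration → median of
identically packaged items in the cargo → uniform weight for a fully
unweighed frozen cargo); percentage costs relative to unit price with
nominally priced items excluded; decade cost bands; and a four-group
classification of why an item drives import cost (*costly by number*,
*costly by unit weight*, *costly by weight × number*, *low import cost*) by
a median split of the weight–quantity plane on log axes.

## Worked example

The package ships a built-in reference shipment — a 2016 import of TB drugs
and laboratory supplies from Amsterdam to a TB program in Nukus,
Karakalpakstan (Uzbekistan): 85 items, 1.8 million units, three cargo
types, €2985 land freight, a $50-per-line customs fee, at 2016 rates
€1 = $1.107 = UZS 3282.

```python
from importcost import build_reference_shipment, run_pipeline

result = run_pipeline(build_reference_shipment())
print(result.cargos[["cargo", "air_eur", "land_eur", "customs_eur",
                     "total_eur", "pct_of_order_value"]].round(2).to_string(index=False))
print(f"shipment: €{result.summary['total_eur']:,.0f} "
      f"({result.summary['pct_of_order_value']:.1f}% of order value, "
      f"€{result.summary['total_eur_per_kg']:.2f}/kg net)")
```

prints

```
   cargo  air_eur  land_eur  customs_eur  total_eur  pct_of_order_value
standard  31155.0   2824.79       316.17   34295.96                8.90
    cool   1785.0    151.37       135.50    2071.87               10.24
  frozen    199.0      8.84        45.17     253.01               28.08
shipment: €36,621 (9.0% of order value, €5.02/kg net)
```

Reading: importing the standard cargo cost €34,296 — €31,155 billed air
freight, €2,825 of the €2,985 truck rental (its share of the gross weight)
and €316 in customs fees for its seven declared item lines — i.e. 8.9% of
the €385,167 ordered value.  The small frozen cargo was proportionally the
most expensive to import (28% of its value) because dry ice quintuples its
shipped weight.  The same run yields per-unit figures, e.g. €2.53 to import
one 50 g frozen test-kit unit (€1.99 air + €0.09 land + €0.45 customs).

The same analysis runs from files via the CLI:

```sh
importcost run --fixture reference --out report/
importcost run --orders orders.csv --waybills waybills.csv \
               --config shipment.yaml --out report/
```

writing `items.csv` (per-item costs, percentage of value, cost band,
contributor class), `cargos.csv` (mirroring the breakdown above with a
Total row), `summary.json` and a run manifest.

## Layout

- `importcost.domain` — types, validation, currency conversion
- `importcost.ingest` — CSV/YAML reading, report writing
- `importcost.imputation` — unit-weight imputation hierarchy
- `importcost.allocation` — the allocation engine (steps 3–5)
- `importcost.metrics` — item costs, percentages, bands, summaries
- `importcost.classify` — import-cost-contributor classification
- `importcost.fixtures` / `importcost.synthetic` — reference shipment and
  seeded synthetic-shipment generator
- `importcost.pipeline`, `importcost.cli` — orchestration and CLI
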