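# Methods

## Cost model

Import cost is defined from the importing program's perspective as the sum
of three components per shipment: billed air freight, a lump-sum land
freight, and customs clearance agent fees.  Each component is a joint cost
and is assigned to cost objects (shipment parts, cargos, units) in
proportion to an allocation base:

| component | base | scope |
|---|---|---|
| air freight | gross weight | between destination parts of one billed cargo |
| land freight | gross weight | between the cargos sharing the truck |
| air + land within a cargo | net weight | over physical units |
| customs clearance | units per item line | over the units of one declared line |

Chargeable weight (max of gross and volumetric weight) is what airlines
bill by; it is computed and reported but deliberately not used as an
allocation base — gross weight is observable for every cargo and part,
and net weight is the item characteristic that transport cost should
follow once cargo packaging is treated as overhead.

For a unit of weight `w` grams in a cargo with allocated transport totals
`C_air`, `C_land`, order net weight `W_net` kg, line fee `F` and `n` units
in its line:

```
unit cost = (w/1000)·C_air/W_net + (w/1000)·C_land/W_net + F/n
```

Item, cargo and shipment figures are sums of these; allocation is exact
(shares always sum back to the allocated total), which the tests assert
both in closed form and against a brute-force oracle that enumerates every
physical unit.

## Parameters and defaults

- **Base currency** EUR; all arithmetic at full float precision in base
  currency; rounding is presentational only (whole euros for totals, two
  decimals for €/kg at or above 1, one decimal for percentages below 10 and
  integers above).
- **Exchange rates** default to the 2016 annual rates of the reference
  shipment, €1 = $1.107 = UZS 3282; configurable per shipment.
- **Customs fee** defaults to $50 per declared item line, converted at the
  configured USD rate (≈ €45.17).  The fee was estimated by local
  logistics staff in dollars; converting the dollar figure, rather than
  using a flat €45, is what reproduces the reference cargo totals of
  €316/€136/€45 for 7/3/1 lines.  A flat €45 mode is available
  (`--customs-fee-mode eur45flat`).
- **Nominal-price threshold** €0.01: items priced at or below it (and any
  item pre-flagged, e.g. a donation priced €0) are excluded from
  percentage-cost metrics; reported `n` counts the exclusions.

## Unit-weight imputation

Missing unit weights are filled in a fixed order, recording provenance:

1. *Same active ingredient, same concentration* — concentration matching is
   exact after whitespace/case normalization (fuzzy matching would demand a
   plausibility review no batch tool can perform).  An external reference
   list (a stand-in for a procurement product catalog) is searched before
   in-shipment donors; in-shipment ties break by closest packaging type,
   then lexicographic item id, so builds are deterministic.
2. *Median unit weight of identically packaged items in the same cargo*;
   an even-sized group takes the mean of the central pair.
3. *Frozen-cargo uniform weight* — when a frozen cargo has no usable
   weights at all, every unit is assigned the same weight: a configured
   net-weight budget divided by the unit count, or 1 g per unit otherwise.
   Either way the weight-based transport allocation degenerates to an
   equal per-unit allocation, which the tests assert directly.

Imputation is idempotent, never alters a present weight, and fails loudly
(naming the items) when no rule applies.

## Contributor classification

Items of one cargo are split into four groups by thresholds on unit weight
and ordered quantity: above/below on both axes gives *costly by
weight × number*, *costly by unit weight*, *costly by number*, and *low
import cost*.  The default threshold is the within-cargo median on log10
axes — heterogeneity in these data is multiplicative, and the log-median
split is invariant to rescaling the units of either axis.  Ties classify
into the "≥" (costly) side.  Fixed thresholds are configurable.  Whether an
item shares its customs line is reported as an annotation, not used as a
criterion.

## Reference shipment

The built-in fixture encodes the cargo-level aggregates of a 2016 shipment
to a TB program in Nukus, Uzbekistan: standard/cool/frozen cargos with
69/14/2 items, 7/3/1 lines, 1,840,928/1218/100 units, 7168/121/5 kg order
net weight, €385,167/€20,228/€901 order value, 7987/428/25 kg gross weight
and €31,155/€1785/€199 billed air freight (the standard figure is already
the program's share of a two-part billing), €2985 land freight and the
$50/line fee.  The item-level composition of that shipment is not public,
so each customs line is represented by one pseudo-item carrying the line's
share of units at a uniform unit weight and price — every cargo- and
shipment-level figure is faithful; item-level medians/IQRs are not
reproducible from aggregates and are out of scope (covered instead by
property tests on synthetic shipments).  The frozen cargo's 25 kg gross
weight includes 20 kg dry ice, recorded as a cargo note.

## Synthetic generator

`generate_shipment` draws item-level shipments for property testing:
log-normal unit weights, quantities and prices per cargo type, centred on
the reference shipment's characteristics (standard: many light cheap
units, median ≈1 g / thousands of units / €0.10; cool: few heavy expensive
units; frozen: a couple of test kits); gross weight = net weight × a
packaging factor (1.1/3.5/5 by cargo type); air freight billed at a per-kg
gross rate; 10% of unit weights blanked (never the last measured weight of
a packaging group, so imputation always has a donor pool) and 2% of items
nominally priced.  Generation is a pure function of the seed.  The
generator emulates scale heterogeneity and missingness, not real catalog
structure: items carry no real ingredient names, line membership is
random, and prices are independent of weight, so passing property tests
demonstrates the accounting invariants (conservation, homogeneity,
permutation invariance, classification monotonicity), not predictive
claims about any real shipment.

## Numerical choices and limitations

- Proportional shares are computed as `total·w/Σw`; conservation holds to
  ≤1e-9 relative and is asserted, not renormalized.
- Zero net weight, zero units in a line, or an empty cargo are hard
  errors, never silent zeros; gross weight below computed net weight is a
  warning (rounded inputs can be mildly inconsistent).
- Quantiles use linear interpolation between order statistics; other
  quantile conventions can move a median/IQR in the last digit.
- Cost bands are decades `[10^k, 10^(k+1))` with a closed lower edge and a
  dedicated band for exactly zero cost.
- The framework covers transport and customs clearance only; upstream
  warehousing, in-country distribution to the point of care,
  administration, insurance and lead-time costs are out of scope, as are
  significance tests and regressions on the generated unit costs.
- Test and acceptance runs use the reference fixture (11 pseudo-items) and
  synthetic shipments of ~42 items across ≤100 seeds — sizes chosen
  because the arithmetic is exact and larger simulations add no
  information.
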