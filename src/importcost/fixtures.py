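"""Built-in reference shipment: a 2016 TB-program import, Amsterdam → Nukus.

The case study behind this package is one major medical-supply shipment from
the MSF Procurement Unit in Amsterdam to a tuberculosis program in Nukus,
Karakalpakstan (Uzbekistan), delivered December 2016: standard, cool and
frozen cargo combining 18 orders, 85 items and 1.8 million units.  Only
cargo-level aggregates of that shipment are public (the item-level data
lives in a research data deposit), so each customs item line is modelled
here as one pseudo-item carrying the line's share of the cargo's units, net
weight and order value.  Every cargo- and shipment-level figure the
allocation engine produces from this fixture matches the published
aggregates; item-level detail is synthetic by construction.

The standard air cargo was billed in two parts (one stayed in Tashkent);
the €31,155 air freight recorded here is already the program's Nukus share,
so no part split is configured.
"""

from __future__ import annotations

from dataclasses import dataclass

from .domain import (
    Cargo,
    CargoType,
    CurrencyTable,
    ItemRecord,
    Money,
    Packaging,
    PharmForm,
    Shipment,
)

#: World Bank annual exchange rates for 2016: €1 = $1.107 = UZS 3282.
RATES_2016 = CurrencyTable(base="EUR", rates={"USD": 1.107, "UZS": 3282.0})

#: Customs agent fee per declared item line, estimated in US dollars.
CUSTOMS_FEE_USD = 50.0

#: Land freight for the full truckload Tashkent → Nukus (lump sum).
LAND_FREIGHT_EUR = 2985.0


@dataclass(frozen=True)
class CargoAggregate:
    """Published cargo-level aggregates of the reference shipment."""

    cargo_type: CargoType
    n_items: int
    n_lines: int
    units: int
    net_weight_kg: float
    order_value_eur: float
    gross_weight_kg: float
    air_freight_eur: float
    form: PharmForm
    packaging: Packaging
    notes: str = ""


REFERENCE_AGGREGATES: tuple[CargoAggregate, ...] = (
    CargoAggregate(CargoType.STANDARD, n_items=69, n_lines=7, units=1_840_928,
                   net_weight_kg=7168.0, order_value_eur=385_167.0,
                   gross_weight_kg=7987.0, air_freight_eur=31_155.0,
                   form=PharmForm.TABLET, packaging=Packaging.CAPSULE_OR_TABLET),
    CargoAggregate(CargoType.COOL, n_items=14, n_lines=3, units=1218,
                   net_weight_kg=121.0, order_value_eur=20_228.0,
                   gross_weight_kg=428.0, air_freight_eur=1785.0,
                   form=PharmForm.TEST_KIT, packaging=Packaging.VIAL),
    CargoAggregate(CargoType.FROZEN, n_items=2, n_lines=1, units=100,
                   net_weight_kg=5.0, order_value_eur=901.0,
                   gross_weight_kg=25.0, air_freight_eur=199.0,
                   form=PharmForm.TEST_KIT, packaging=Packaging.TEST_KIT,
                   notes="gross weight includes 20 kg dry ice (cargo packaging)"),
)


def _split_units(total: int, n_parts: int) -> list[int]:
    """Split a unit count into n near-equal integer parts (largest remainder)."""
    base, rem = divmod(total, n_parts)
    return [base + (1 if i < rem else 0) for i in range(n_parts)]


def _pseudo_items(agg: CargoAggregate) -> list[ItemRecord]:
    unit_weight_g = agg.net_weight_kg * 1000.0 / agg.units
    unit_price_eur = agg.order_value_eur / agg.units
    items = []
    for line_idx, qty in enumerate(_split_units(agg.units, agg.n_lines), start=1):
        items.append(
            ItemRecord(
                item_id=f"{agg.cargo_type.value}-line{line_idx}",
                description=f"{agg.cargo_type.value} cargo pseudo-item, line {line_idx}"
                            " (synthetic aggregate of one customs line)",
                form=agg.form,
                packaging=agg.packaging,
                unit_price=Money(unit_price_eur, "EUR"),
                quantity=qty,
                item_line=f"{agg.cargo_type.value}-HS{line_idx:02d}",
                cargo_type=agg.cargo_type,
                unit_weight_g=unit_weight_g,
            )
        )
    return items


def build_reference_shipment() -> Shipment:
    """Assemble the reference shipment from its published aggregates.

    Cargo-level net weight, unit counts and order values reproduce the
    published figures exactly; unit weights are uniform within a cargo (for
    the frozen cargo this is also what the original assessment assumed:
    5 kg over 100 units = 50 g per unit).
    """
    cargos = []
    for agg in REFERENCE_AGGREGATES:
        cargos.append(
            Cargo(
                cargo_type=agg.cargo_type,
                gross_weight_kg=agg.gross_weight_kg,
                air_freight=Money(agg.air_freight_eur, "EUR"),
                items=_pseudo_items(agg),
                notes=agg.notes or None,
            )
        )
    return Shipment(
        cargos=cargos,
        land_freight=Money(LAND_FREIGHT_EUR, "EUR"),
        customs_fee_per_line=Money(CUSTOMS_FEE_USD, "USD"),
        currency=RATES_2016,
    )
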