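"""Proportional allocation of import-cost totals down to single units.

The framework allocates each joint cost along its chosen base:

* air freight — billed per cargo; a cargo split across destinations is first
  divided between its parts proportionally to part gross weight, then the
  program's share is spread over units at the cargo's euro-per-kilogram net
  weight rate;
* land freight — one lump sum for the truckload, divided between cargos
  proportionally to cargo gross weight, then spread over units by net weight
  like air freight;
* customs clearance — a semifixed agent fee per declared item line, divided
  equally among the units imported within that line.

No rounding happens here; presentation rounding lives in the reporting layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .domain import (
    Cargo,
    CargoType,
    CostBreakdown,
    ItemRecord,
    Money,
    Shipment,
    ShipmentPart,
    convert_currency,
)


def chargeable_weight(gross_kg: float, volumetric_kg: float) -> float:
    """Air-freight billing weight: max of gross and volumetric weight."""
    if gross_kg < 0 or volumetric_kg < 0:
        raise ValueError("weights must be non-negative")
    return max(gross_kg, volumetric_kg)


def allocate_proportional(total: float, weights: Sequence[float]) -> list[float]:
    """Split ``total`` proportionally to ``weights``; shares sum back to total."""
    if len(weights) == 0:
        raise ValueError("cannot allocate over an empty weight list")
    if any(not w > 0 for w in weights):
        raise ValueError("all allocation weights must be strictly positive")
    if total < 0:
        raise ValueError("total to allocate must be >= 0")
    denom = sum(weights)
    return [total * w / denom for w in weights]


def split_air_freight_for_part(
    billed: float, parts: Sequence[ShipmentPart], program_part: str
) -> float:
    """Program's share of a billed air freight split across destinations."""
    labels = [p.destination for p in parts]
    if program_part not in labels:
        raise ValueError(
            f"destination {program_part!r} not among parts {labels}"
        )
    shares = allocate_proportional(billed, [p.gross_weight_kg for p in parts])
    return shares[labels.index(program_part)]


def cargo_net_weight(items: Sequence[ItemRecord]) -> float:
    """Order net weight in kg: sum of unit weight x quantity over items."""
    total_g = 0.0
    for it in items:
        if it.unit_weight_g is None:
            raise ValueError(
                f"item {it.item_id} has no unit weight; run imputation before allocation"
            )
        total_g += it.unit_weight_g * it.quantity
    return total_g / 1000.0


def transport_rate_per_kg(cargo_transport_cost: float, net_weight_kg: float) -> float:
    """Average cost of transporting one kg of order net weight."""
    if not net_weight_kg > 0:
        raise ValueError("net weight must be > 0 kg to form a per-kg rate")
    return cargo_transport_cost / net_weight_kg


def unit_transport_cost(unit_weight_g: float, rate_per_kg: float) -> float:
    """Transport cost of one unit: its weight times the per-kg rate."""
    if not unit_weight_g > 0:
        raise ValueError("unit weight must be > 0 g")
    return unit_weight_g / 1000.0 * rate_per_kg


def customs_total_for_cargo(n_lines: int, fee_per_line_eur: float) -> float:
    """Customs clearance total for a cargo: lines x fee per line."""
    if n_lines < 1:
        raise ValueError("a cargo must declare at least one item line")
    if fee_per_line_eur < 0:
        raise ValueError("customs fee must be >= 0")
    return n_lines * fee_per_line_eur


def unit_customs_cost(fee_per_line_eur: float, units_in_line: int) -> float:
    """Per-unit customs cost: the line fee spread equally over its units."""
    if units_in_line < 1:
        raise ValueError("an item line must contain at least one unit")
    return fee_per_line_eur / units_in_line


@dataclass(frozen=True)
class CargoCostContext:
    """Per-cargo rates and line sizes needed to cost a single unit."""

    cargo_type: CargoType
    air_rate_per_kg: float
    land_rate_per_kg: float
    fee_per_line_eur: float
    units_per_line: Mapping[str, int]
    air_total_eur: float
    land_total_eur: float
    customs_total_eur: float
    net_weight_kg: float


def unit_import_cost(item: ItemRecord, ctx: CargoCostContext) -> CostBreakdown:
    """Full unit-level breakdown for one item in its cargo context."""
    if item.item_line not in ctx.units_per_line:
        raise KeyError(
            f"item line {item.item_line!r} unknown to {ctx.cargo_type.value} cargo"
        )
    if item.unit_weight_g is None:
        raise ValueError(f"item {item.item_id} has no unit weight")
    air = unit_transport_cost(item.unit_weight_g, ctx.air_rate_per_kg)
    land = unit_transport_cost(item.unit_weight_g, ctx.land_rate_per_kg)
    customs = unit_customs_cost(ctx.fee_per_line_eur, ctx.units_per_line[item.item_line])
    return CostBreakdown(air=air, land=land, customs=customs, level="unit")


def cargo_import_total(ctx: CargoCostContext) -> CostBreakdown:
    """Cargo-level totals from the allocated components."""
    return CostBreakdown(
        air=ctx.air_total_eur,
        land=ctx.land_total_eur,
        customs=ctx.customs_total_eur,
        level="cargo",
    )


@dataclass
class ShipmentAllocation:
    """Result of running allocation over a whole shipment."""

    contexts: dict[CargoType, CargoCostContext] = field(default_factory=dict)
    unit_costs: dict[CargoType, list[CostBreakdown]] = field(default_factory=dict)
    land_shares: dict[CargoType, float] = field(default_factory=dict)
    fee_per_line_eur: float = 0.0

    def cargo_total(self, cargo_type: CargoType) -> CostBreakdown:
        return cargo_import_total(self.contexts[cargo_type])

    def shipment_total(self) -> CostBreakdown:
        if not self.contexts:
            raise ValueError("cannot total an empty shipment")
        parts = [self.cargo_total(ct) for ct in self.contexts]
        out = CostBreakdown(0.0, 0.0, 0.0, "shipment")
        for p in parts:
            out = CostBreakdown(out.air + p.air, out.land + p.land,
                                out.customs + p.customs, "shipment")
        return out


def allocate_shipment(shipment: Shipment) -> ShipmentAllocation:
    """Run allocation steps for every cargo of a shipment.

    Air freight for a cargo listed in ``shipment.parts`` is first split by
    part gross weight and only the program's part (``shipment.program_part``)
    is retained.  Land freight is divided between cargos by cargo gross
    weight.  The customs fee is converted to base currency once and applied
    per declared line.
    """
    if not shipment.cargos:
        raise ValueError("shipment has no cargos")
    table = shipment.currency
    fee_eur = convert_currency(shipment.customs_fee_per_line, table)
    land_total = convert_currency(shipment.land_freight, table)

    land_shares = dict(
        zip(
            (c.cargo_type for c in shipment.cargos),
            allocate_proportional(
                land_total, [c.gross_weight_kg for c in shipment.cargos]
            ),
        )
    )

    result = ShipmentAllocation(fee_per_line_eur=fee_eur, land_shares=land_shares)
    for cargo in shipment.cargos:
        billed_air = convert_currency(cargo.air_freight, table)
        parts = shipment.parts.get(cargo.cargo_type)
        if parts:
            if shipment.program_part is None:
                raise ValueError(
                    f"{cargo.cargo_type.value} cargo is split into parts but "
                    "no program part is identified"
                )
            air_total = split_air_freight_for_part(
                billed_air, list(parts), shipment.program_part
            )
        else:
            air_total = billed_air

        net_kg = cargo_net_weight(cargo.items)
        upl = cargo.units_per_line()
        ctx = CargoCostContext(
            cargo_type=cargo.cargo_type,
            air_rate_per_kg=transport_rate_per_kg(air_total, net_kg),
            land_rate_per_kg=transport_rate_per_kg(land_shares[cargo.cargo_type], net_kg),
            fee_per_line_eur=fee_eur,
            units_per_line=upl,
            air_total_eur=air_total,
            land_total_eur=land_shares[cargo.cargo_type],
            customs_total_eur=customs_total_for_cargo(len(upl), fee_eur),
            net_weight_kg=net_kg,
        )
        result.contexts[cargo.cargo_type] = ctx
        result.unit_costs[cargo.cargo_type] = [
            unit_import_cost(it, ctx) for it in cargo.items
        ]
    return result
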