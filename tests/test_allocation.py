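"""Allocation engine: proportional splits, per-kg rates, per-line customs.

Closed-form allocations are cross-checked against a brute-force oracle that
expands every physical unit and assigns cost unit by unit.
"""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from importcost import (
    CargoType,
    Money,
    ShipmentPart,
    allocate_proportional,
    allocate_shipment,
    cargo_net_weight,
    chargeable_weight,
    customs_total_for_cargo,
    split_air_freight_for_part,
    transport_rate_per_kg,
    unit_customs_cost,
    unit_import_cost,
    unit_transport_cost,
)

from conftest import make_item


@pytest.mark.parametrize(
    "gross,volumetric,expected",
    [(7987, 1200, 7987), (25, 40, 40), (10, 10, 10)],
)
def test_chargeable_weight_is_max(gross, volumetric, expected):
    assert chargeable_weight(gross, volumetric) == expected


def test_chargeable_weight_rejects_negative():
    with pytest.raises(ValueError):
        chargeable_weight(-1, 5)


class TestAllocateProportional:
    def test_truckload_split_by_cargo_gross_weight(self):
        # €2985 land freight over gross weights 7987/428/25 kg
        shares = allocate_proportional(2985.0, [7987.0, 428.0, 25.0])
        assert shares == pytest.approx([2824.79, 151.37, 8.84], abs=0.005)
        assert sum(shares) == pytest.approx(2985.0, rel=1e-12)

    @pytest.mark.parametrize(
        "total,weights,expected",
        [(100.0, [50, 50], [50, 50]), (77.0, [123], [77.0])],
    )
    def test_simple_splits(self, total, weights, expected):
        assert allocate_proportional(total, weights) == pytest.approx(expected)

    @pytest.mark.parametrize("weights", [[], [1.0, 0.0], [1.0, -2.0]])
    def test_rejects_degenerate_weights(self, weights):
        with pytest.raises(ValueError):
            allocate_proportional(10.0, weights)

    @given(
        total=st.floats(min_value=0, max_value=1e7),
        weights=st.lists(st.floats(min_value=1e-3, max_value=1e6),
                         min_size=1, max_size=20),
        scale=st.floats(min_value=1e-3, max_value=1e3),
    )
    @settings(max_examples=100, derandomize=True)
    def test_conservation_and_homogeneity(self, total, weights, scale):
        shares = allocate_proportional(total, weights)
        assert sum(shares) == pytest.approx(total, rel=1e-9, abs=1e-9)
        # scaling all weights changes nothing; scaling the total scales shares
        rescaled = allocate_proportional(total, [w * scale for w in weights])
        assert rescaled == pytest.approx(shares, rel=1e-9, abs=1e-12)
        scaled_total = allocate_proportional(total * scale, weights)
        assert scaled_total == pytest.approx(
            [s * scale for s in shares], rel=1e-9, abs=1e-12
        )


class TestPartSplit:
    def test_program_share(self):
        parts = [ShipmentPart("Nukus", 60.0), ShipmentPart("Tashkent", 40.0)]
        assert split_air_freight_for_part(100.0, parts, "Nukus") == pytest.approx(60.0)

    def test_single_part_takes_all(self):
        assert split_air_freight_for_part(
            100.0, [ShipmentPart("Nukus", 60.0)], "Nukus"
        ) == pytest.approx(100.0)

    def test_parts_conserve_billed_total(self):
        parts = [ShipmentPart("Nukus", 61.3), ShipmentPart("Tashkent", 38.7)]
        total = sum(
            split_air_freight_for_part(100.0, parts, p.destination) for p in parts
        )
        assert total == pytest.approx(100.0, rel=1e-12)

    def test_unknown_destination_errors(self):
        with pytest.raises(ValueError, match="Samarkand"):
            split_air_freight_for_part(
                100.0, [ShipmentPart("Nukus", 60.0)], "Samarkand"
            )


class TestNetWeightAndRates:
    def test_net_weight_sums_items(self):
        items = [make_item("a", weight=1.0, qty=500), make_item("b", weight=2.0, qty=250)]
        assert cargo_net_weight(items) == pytest.approx(1.0)
        # 0.9 g tablet (pyrazinamide) x 1000 units
        assert cargo_net_weight([make_item(weight=0.9, qty=1000)]) == pytest.approx(0.9)
        assert cargo_net_weight([]) == 0.0

    def test_missing_weight_directs_to_imputation(self):
        bad = make_item("x", weight=None)
        with pytest.raises(ValueError, match="imputation"):
            cargo_net_weight([bad])

    @pytest.mark.parametrize(
        "cost,net,expected",
        [(31155.0, 7168.0, 4.3464), (199.0, 5.0, 39.8), (0.0, 10.0, 0.0)],
    )
    def test_transport_rate(self, cost, net, expected):
        assert transport_rate_per_kg(cost, net) == pytest.approx(expected, abs=5e-5)

    def test_transport_rate_zero_net_weight_errors(self):
        with pytest.raises(ValueError):
            transport_rate_per_kg(100.0, 0.0)

    def test_unit_transport_cost_examples(self):
        # standard cargo: combined air+land rate over 7168 kg net
        rate = (31155.0 + 2826.0) / 7168.0
        assert unit_transport_cost(0.9, rate) == pytest.approx(0.004267, abs=5e-6)
        # frozen cargo: 50 g unit at combined rate (199+8.84)/5
        assert unit_transport_cost(50.0, (199.0 + 8.84) / 5.0) == pytest.approx(
            2.078, abs=5e-4
        )
        with pytest.raises(ValueError):
            unit_transport_cost(0.0, rate)


class TestCustoms:
    def test_totals_per_line_count(self):
        fee = 50.0 / 1.107  # $50 at the 2016 rate
        assert customs_total_for_cargo(7, fee) == pytest.approx(316.17, abs=0.005)
        assert customs_total_for_cargo(1, fee) == pytest.approx(45.17, abs=0.005)
        assert customs_total_for_cargo(3, 0.0) == 0.0

    def test_zero_lines_errors(self):
        with pytest.raises(ValueError):
            customs_total_for_cargo(0, 45.0)

    def test_unit_customs_cost(self):
        fee = 50.0 / 1.107
        assert unit_customs_cost(fee, 100) == pytest.approx(0.4517, abs=5e-5)
        assert unit_customs_cost(fee, 1) == pytest.approx(fee)
        # conservation over the units of one line
        assert unit_customs_cost(fee, 100) * 100 == pytest.approx(fee, rel=1e-12)
        with pytest.raises(ValueError):
            unit_customs_cost(fee, 0)


class TestUnitImportCost:
    def test_frozen_unit_breakdown(self, reference_shipment):
        """A 50 g frozen unit costs €1.99 air + €0.09 land + €0.45 customs."""
        alloc = allocate_shipment(reference_shipment)
        (unit,) = {
            uc for uc in alloc.unit_costs[CargoType.FROZEN]
        }  # uniform pseudo-items share one breakdown
        assert unit.air == pytest.approx(1.99, abs=0.005)
        assert unit.land == pytest.approx(0.0884, abs=5e-4)
        assert unit.customs == pytest.approx(0.4517, abs=5e-4)
        assert unit.total == pytest.approx(2.53, abs=0.005)

    def test_doubling_weight_doubles_transport_only(self, toy_shipment):
        alloc = allocate_shipment(toy_shipment)
        ctx = alloc.contexts[CargoType.STANDARD]
        light = unit_import_cost(make_item("l", weight=2.0, line="HS01"), ctx)
        heavy = unit_import_cost(make_item("h", weight=4.0, line="HS01"), ctx)
        assert heavy.air == pytest.approx(2 * light.air, rel=1e-12)
        assert heavy.land == pytest.approx(2 * light.land, rel=1e-12)
        assert heavy.customs == pytest.approx(light.customs, rel=1e-12)


def brute_force_totals(shipment):
    """Oracle: expand every physical unit and cost it one by one."""
    alloc = allocate_shipment(shipment)
    totals = {}
    for cargo in shipment.cargos:
        ctx = alloc.contexts[cargo.cargo_type]
        air = land = customs = 0.0
        for it in cargo.items:
            for _ in range(it.quantity):
                air += it.unit_weight_g / 1000.0 * ctx.air_rate_per_kg
                land += it.unit_weight_g / 1000.0 * ctx.land_rate_per_kg
                customs += ctx.fee_per_line_eur / ctx.units_per_line[it.item_line]
        totals[cargo.cargo_type] = (air, land, customs)
    return totals


class TestConservationAndInvariance:
    def test_unit_enumeration_matches_closed_form(self, toy_shipment):
        """Summing per-unit costs over all physical units recovers the
        allocated cargo totals (the toy shipment has <10^4 units)."""
        alloc = allocate_shipment(toy_shipment)
        for ctype, (air, land, customs) in brute_force_totals(toy_shipment).items():
            total = alloc.cargo_total(ctype)
            assert air == pytest.approx(total.air, rel=1e-6)
            assert land == pytest.approx(total.land, rel=1e-6)
            assert customs == pytest.approx(total.customs, rel=1e-6)

    def test_cargo_totals_sum_to_shipment_total(self, toy_shipment):
        alloc = allocate_shipment(toy_shipment)
        ship = alloc.shipment_total()
        for comp in ("air", "land", "customs"):
            assert getattr(ship, comp) == pytest.approx(
                sum(getattr(alloc.cargo_total(ct), comp) for ct in alloc.contexts),
                rel=1e-12,
            )

    def test_item_permutation_changes_nothing(self, toy_shipment):
        before = allocate_shipment(toy_shipment)
        rng = random.Random(7)
        for cargo in toy_shipment.cargos:
            rng.shuffle(cargo.items)
        toy_shipment.cargos.reverse()
        after = allocate_shipment(toy_shipment)
        assert before.shipment_total().total == pytest.approx(
            after.shipment_total().total, rel=1e-12
        )
        for ct in before.contexts:
            assert before.cargo_total(ct).total == pytest.approx(
                after.cargo_total(ct).total, rel=1e-12
            )

    def test_empty_shipment_errors(self, rates):
        from importcost import Shipment

        empty = Shipment(cargos=[], land_freight=Money(10, "EUR"),
                         customs_fee_per_line=Money(50, "USD"), currency=rates)
        with pytest.raises(ValueError):
            allocate_shipment(empty)
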