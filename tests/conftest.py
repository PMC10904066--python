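import pytest

from importcost import (
    Cargo,
    CargoType,
    CurrencyTable,
    ItemRecord,
    Money,
    Packaging,
    PharmForm,
    Shipment,
    build_reference_shipment,
)


@pytest.fixture
def rates():
    return CurrencyTable(base="EUR", rates={"USD": 1.107, "UZS": 3282.0})


@pytest.fixture
def reference_shipment():
    return build_reference_shipment()


def make_item(item_id="it-1", *, cargo=CargoType.STANDARD, weight=1.0, qty=100,
              price=0.10, line="HS01", form=PharmForm.TABLET,
              packaging=Packaging.CAPSULE_OR_TABLET, ingredient=None,
              concentration=None, nominal=False):
    return ItemRecord(
        item_id=item_id,
        description=f"toy item {item_id}",
        form=form,
        packaging=packaging,
        unit_price=Money(price, "EUR"),
        quantity=qty,
        item_line=line,
        cargo_type=cargo,
        active_ingredient=ingredient,
        concentration=concentration,
        unit_weight_g=weight,
        nominal_price=nominal,
    )


@pytest.fixture
def toy_shipment(rates):
    """Two-cargo shipment small enough for unit-by-unit enumeration."""
    standard = Cargo(
        cargo_type=CargoType.STANDARD,
        gross_weight_kg=12.0,
        air_freight=Money(120.0, "EUR"),
        items=[
            make_item("std-a", weight=2.0, qty=1000, price=0.2, line="HS01"),
            make_item("std-b", weight=5.0, qty=500, price=0.5, line="HS01"),
            make_item("std-c", weight=10.0, qty=300, price=1.0, line="HS02"),
        ],
    )
    cool = Cargo(
        cargo_type=CargoType.COOL,
        gross_weight_kg=8.0,
        air_freight=Money(60.0, "EUR"),
        items=[
            make_item("cool-a", cargo=CargoType.COOL, weight=100.0, qty=10,
                      price=25.0, line="HS03", packaging=Packaging.VIAL),
            make_item("cool-b", cargo=CargoType.COOL, weight=150.0, qty=4,
                      price=40.0, line="HS03", packaging=Packaging.VIAL),
        ],
    )
    return Shipment(
        cargos=[standard, cool],
        land_freight=Money(50.0, "EUR"),
        customs_fee_per_line=Money(50.0, "USD"),
        currency=rates,
    )
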