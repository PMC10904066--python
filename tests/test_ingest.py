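"""CSV/YAML ingestion, report writing and round-trips."""

import json

import pytest

from importcost import CargoType, Money, run_pipeline
from importcost.ingest import (
    SchemaError,
    assemble_shipment,
    read_config,
    read_orders,
    read_reference_weights,
    read_waybills,
    write_orders,
    write_report,
)

ORDERS_CSV = """\
item_id,description,form,packaging,active_ingredient,concentration,unit_price,currency,quantity,unit_weight_g,item_line,cargo
pza,pyrazinamide 400mg tablet,tablet,capsule_or_tablet,pyrazinamide,400 mg,0.10,EUR,1000,0.9,HS01,standard
nacl,sodium chloride 0.9% 100ml,fluid_ge_100ml,fluid_bag,sodium chloride,0.9%,0.80,EUR,500,,HS02,standard
ins,insulin 10ml vial,fluid_lt_100ml,vial,insulin,100 IU/ml,25.0,EUR,40,115,HS03,cool
"""

WAYBILLS_CSV = """\
cargo,air_freight,currency,gross_weight_kg,volume_m3,rate_per_kg,surcharges
standard,1200,EUR,7987,23.1,3.2,150
cool,260,EUR,50,0.9,,
frozen,80,EUR,25,0.2,,
"""

CONFIG_YAML = """\
land_freight: {amount: 2985, currency: EUR}
customs_fee_per_line: {amount: 50, currency: USD}
currency:
  base: EUR
  rates: {USD: 1.107, UZS: 3282}
parts:
  standard:
    - {destination: Nukus, gross_weight_kg: 60}
    - {destination: Tashkent, gross_weight_kg: 40}
program_part: Nukus
"""


@pytest.fixture
def orders_path(tmp_path):
    p = tmp_path / "orders.csv"
    p.write_text(ORDERS_CSV)
    return p


@pytest.fixture
def waybills_path(tmp_path):
    p = tmp_path / "waybills.csv"
    p.write_text(WAYBILLS_CSV)
    return p


@pytest.fixture
def config_path(tmp_path):
    p = tmp_path / "config.yaml"
    p.write_text(CONFIG_YAML)
    return p


class TestReadOrders:
    def test_reads_all_rows(self, orders_path):
        records = read_orders(orders_path)
        assert len(records) == 3
        assert records[0].unit_weight_g == pytest.approx(0.9)
        assert records[0].active_ingredient == "pyrazinamide"

    def test_empty_weight_stays_missing(self, orders_path):
        records = read_orders(orders_path)
        assert records[1].unit_weight_g is None
        assert records[1].weight_provenance is None

    def test_unknown_cargo_enum_names_value(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text(ORDERS_CSV.replace("HS03,cool", "HS03,chilled"))
        with pytest.raises(SchemaError, match="chilled"):
            read_orders(p)

    def test_missing_mandatory_column_names_it(self, tmp_path):
        p = tmp_path / "bad.csv"
        lines = ORDERS_CSV.splitlines()
        p.write_text("\n".join(l.replace("quantity", "qty") for l in lines))
        with pytest.raises(SchemaError, match="quantity"):
            read_orders(p)

    def test_write_read_round_trip(self, orders_path, tmp_path):
        records = read_orders(orders_path)
        out = tmp_path / "rt.csv"
        write_orders(records, out)
        assert read_orders(out) == records


class TestReadWaybills:
    def test_three_shells_with_printed_gross_weight(self, waybills_path):
        shells = read_waybills(waybills_path)
        assert [s.cargo_type for s in shells] == [
            CargoType.STANDARD, CargoType.COOL, CargoType.FROZEN
        ]
        assert shells[0].gross_weight_kg == pytest.approx(7987.0)
        assert shells[0].items == []

    def test_duplicate_cargo_type_errors(self, tmp_path):
        p = tmp_path / "dup.csv"
        p.write_text(WAYBILLS_CSV + "cool,100,EUR,10,,,\n")
        with pytest.raises(SchemaError, match="cool"):
            read_waybills(p)


class TestReadConfig:
    def test_full_config(self, config_path):
        config = read_config(config_path)
        assert config.land_freight == Money(2985.0, "EUR")
        # $50 per line resolves to ~€45.17 at the configured rate
        assert config.customs_fee_per_line == Money(50.0, "USD")
        assert config.customs_fee_per_line.amount / config.currency.rate("USD") == (
            pytest.approx(45.17, abs=0.005)
        )
        parts = config.parts[CargoType.STANDARD]
        assert [(p.destination, p.gross_weight_kg) for p in parts] == [
            ("Nukus", 60.0), ("Tashkent", 40.0)
        ]

    def test_minimal_config_gets_defaults(self, tmp_path):
        p = tmp_path / "min.yaml"
        p.write_text("land_freight: {amount: 100, currency: EUR}\n"
                     "currency: {rates: {USD: 1.107}}\n")
        config = read_config(p)
        assert config.customs_fee_per_line == Money(50.0, "USD")
        assert config.nominal_threshold_eur == 0.01
        assert config.parts == {}

    def test_missing_land_freight_errors(self, tmp_path):
        p = tmp_path / "bad.yaml"
        p.write_text("currency: {rates: {USD: 1.107}}\n")
        with pytest.raises(SchemaError, match="land_freight"):
            read_config(p)

    def test_negative_fee_errors(self, tmp_path):
        p = tmp_path / "bad.yaml"
        p.write_text("land_freight: {amount: 100}\n"
                     "customs_fee_per_line: {amount: -5}\n")
        with pytest.raises(SchemaError):
            read_config(p)


def test_assemble_shipment_joins_by_cargo_type(orders_path, waybills_path, config_path):
    shipment = assemble_shipment(
        read_orders(orders_path), read_waybills(waybills_path), read_config(config_path)
    )
    assert len(shipment.cargo(CargoType.STANDARD).items) == 2
    assert len(shipment.cargo(CargoType.COOL).items) == 1
    assert shipment.program_part == "Nukus"


def test_reference_weights_csv(tmp_path):
    p = tmp_path / "ref.csv"
    p.write_text("active_ingredient,concentration,packaging,unit_weight_g\n"
                 "pyrazinamide,400 mg,capsule_or_tablet,0.9\n")
    (ref,) = read_reference_weights(p)
    assert ref.unit_weight_g == pytest.approx(0.9)


class TestWriteReport:
    def test_report_files_and_total_row(self, tmp_path, reference_shipment):
        result = run_pipeline(reference_shipment)
        paths = write_report(result, tmp_path / "out")
        import pandas as pd

        cargos = pd.read_csv(paths["cargos"])
        assert list(cargos["cargo"]) == ["standard", "cool", "frozen", "Total"]
        total = cargos[cargos["cargo"] == "Total"].iloc[0]
        assert total["total_eur"] == 36621
        items = pd.read_csv(paths["items"])
        assert len(items) == result.summary["n_items"]
        summary = json.loads((tmp_path / "out" / "summary.json").read_text())
        assert summary["n_units"] == 1_842_246

    def test_empty_result_errors(self, tmp_path, reference_shipment):
        result = run_pipeline(reference_shipment)
        result.items = result.items.iloc[0:0]
        with pytest.raises(ValueError, match="nothing to report"):
            write_report(result, tmp_path / "out")
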