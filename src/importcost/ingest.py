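"""Reading order/waybill CSV tables and the shipment config; report writing.

File conventions: comma-separated UTF-8 with a header row, decimal point,
no thousands separators.  The order schema is an artifact convention (real
procurement invoices arrive as PDFs or spreadsheets and are transcribed):

``orders.csv`` columns
    item_id, description, form, packaging, active_ingredient, concentration,
    unit_price, currency, quantity, unit_weight_g, item_line, cargo

``waybills.csv`` columns
    cargo, air_freight, currency, gross_weight_kg, volume_m3, rate_per_kg,
    surcharges

The shipment config is YAML (land freight, customs fee per line, exchange
rates, optional part splits and thresholds).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
import yaml

from . import metrics
from .domain import (
    Cargo,
    CargoType,
    CurrencyTable,
    ItemRecord,
    Money,
    Packaging,
    PharmForm,
    Shipment,
    ShipmentPart,
)
from .imputation import ReferenceWeight

ORDER_COLUMNS = [
    "item_id", "description", "form", "packaging", "active_ingredient",
    "concentration", "unit_price", "currency", "quantity", "unit_weight_g",
    "item_line", "cargo",
]

WAYBILL_COLUMNS = [
    "cargo", "air_freight", "currency", "gross_weight_kg", "volume_m3",
    "rate_per_kg", "surcharges",
]


class SchemaError(ValueError):
    """A table or config does not match the documented schema."""


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing mandatory column(s) {missing}")


def _parse_enum(enum_cls, value: str, row: int, column: str):
    try:
        return enum_cls(str(value).strip().lower())
    except ValueError:
        valid = [e.value for e in enum_cls]
        raise SchemaError(
            f"row {row}: unknown {column} value {value!r}; expected one of {valid}"
        ) from None


def read_orders(path: Union[str, Path]) -> list[ItemRecord]:
    """Read an orders table into item records; empty weights stay missing."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    mandatory = [c for c in ORDER_COLUMNS
                 if c not in ("active_ingredient", "concentration", "unit_weight_g")]
    _require_columns(df, mandatory, f"orders table {path}")
    records = []
    for idx, row in df.iterrows():
        rowno = int(idx) + 2  # 1-based plus header
        weight = None
        if "unit_weight_g" in df.columns and row["unit_weight_g"].strip():
            weight = float(row["unit_weight_g"])
        records.append(
            ItemRecord(
                item_id=row["item_id"],
                description=row["description"],
                form=_parse_enum(PharmForm, row["form"], rowno, "form"),
                packaging=_parse_enum(Packaging, row["packaging"], rowno, "packaging"),
                unit_price=Money(float(row["unit_price"]), row["currency"]),
                quantity=int(row["quantity"]),
                item_line=row["item_line"],
                cargo_type=_parse_enum(CargoType, row["cargo"], rowno, "cargo"),
                active_ingredient=row.get("active_ingredient", "").strip() or None,
                concentration=row.get("concentration", "").strip() or None,
                unit_weight_g=weight,
            )
        )
    return records


def write_orders(items: Sequence[ItemRecord], path: Union[str, Path]) -> None:
    """Serialize item records back to the orders schema (round-trippable)."""
    rows = [
        {
            "item_id": it.item_id,
            "description": it.description,
            "form": it.form.value,
            "packaging": it.packaging.value,
            "active_ingredient": it.active_ingredient or "",
            "concentration": it.concentration or "",
            "unit_price": repr(it.unit_price.amount),
            "currency": it.unit_price.currency,
            "quantity": it.quantity,
            "unit_weight_g": "" if it.unit_weight_g is None else repr(it.unit_weight_g),
            "item_line": it.item_line,
            "cargo": it.cargo_type.value,
        }
        for it in items
    ]
    pd.DataFrame(rows, columns=ORDER_COLUMNS).to_csv(path, index=False)


def read_waybills(path: Union[str, Path]) -> list[Cargo]:
    """Read air waybills into cargo shells (items attached later by cargo type)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, ["cargo", "air_freight", "currency", "gross_weight_kg"],
                     f"waybills table {path}")
    shells = []
    seen: set[CargoType] = set()
    for idx, row in df.iterrows():
        rowno = int(idx) + 2
        ctype = _parse_enum(CargoType, row["cargo"], rowno, "cargo")
        if ctype in seen:
            raise SchemaError(f"row {rowno}: duplicate cargo type {ctype.value!r}")
        seen.add(ctype)
        vol = row.get("volume_m3", "").strip()
        sur = row.get("surcharges", "").strip()
        shells.append(
            Cargo(
                cargo_type=ctype,
                gross_weight_kg=float(row["gross_weight_kg"]),
                air_freight=Money(float(row["air_freight"]), row["currency"]),
                volume_m3=float(vol) if vol else None,
                air_surcharges=Money(float(sur), row["currency"]) if sur else None,
            )
        )
    return shells


def read_reference_weights(path: Union[str, Path]) -> list[ReferenceWeight]:
    """Read an optional unit-weight reference list
    (columns: active_ingredient, concentration, packaging, unit_weight_g)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, ["active_ingredient", "concentration", "packaging",
                          "unit_weight_g"], f"reference list {path}")
    return [
        ReferenceWeight(
            active_ingredient=row["active_ingredient"],
            concentration=row["concentration"],
            packaging=_parse_enum(Packaging, row["packaging"], int(idx) + 2, "packaging"),
            unit_weight_g=float(row["unit_weight_g"]),
        )
        for idx, row in df.iterrows()
    ]


@dataclass
class ShipmentConfig:
    """Parsed shipment-level configuration."""

    land_freight: Money
    customs_fee_per_line: Money
    currency: CurrencyTable
    parts: dict[CargoType, list[ShipmentPart]] = field(default_factory=dict)
    program_part: Optional[str] = None
    nominal_threshold_eur: float = 0.01
    frozen_net_weight_kg: dict[CargoType, float] = field(default_factory=dict)
    classification: dict = field(default_factory=dict)


def _money_from(node: dict, what: str) -> Money:
    try:
        amount = float(node["amount"])
    except (KeyError, TypeError):
        raise SchemaError(f"config: {what} needs an 'amount'") from None
    if amount < 0:
        raise SchemaError(f"config: {what} amount must be >= 0")
    return Money(amount, str(node.get("currency", "EUR")))


def read_config(path: Union[str, Path]) -> ShipmentConfig:
    """Read the YAML shipment config, applying defaults for optional blocks."""
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    if "land_freight" not in doc:
        raise SchemaError("config: 'land_freight' block is mandatory")
    currency_doc = doc.get("currency", {})
    table = CurrencyTable(
        base=currency_doc.get("base", "EUR"),
        rates=currency_doc.get("rates", {}),
    )
    fee_node = doc.get("customs_fee_per_line", {"amount": 50.0, "currency": "USD"})
    config = ShipmentConfig(
        land_freight=_money_from(doc["land_freight"], "land_freight"),
        customs_fee_per_line=_money_from(fee_node, "customs_fee_per_line"),
        currency=table,
        program_part=doc.get("program_part"),
        nominal_threshold_eur=float(doc.get("nominal_threshold_eur", 0.01)),
        classification=doc.get("classification", {}),
    )
    for key, parts in (doc.get("parts") or {}).items():
        ctype = CargoType(key)
        config.parts[ctype] = [
            ShipmentPart(p["destination"], float(p["gross_weight_kg"])) for p in parts
        ]
    for key, kg in (doc.get("frozen_net_weight_kg") or {}).items():
        config.frozen_net_weight_kg[CargoType(key)] = float(kg)
    # referenced currencies must resolve against the rate table
    table.rate(config.land_freight.currency)
    table.rate(config.customs_fee_per_line.currency)
    return config


def assemble_shipment(
    items: Sequence[ItemRecord], shells: Sequence[Cargo], config: ShipmentConfig
) -> Shipment:
    """Join order items onto waybill cargo shells by cargo type."""
    by_type: dict[CargoType, list[ItemRecord]] = {}
    for it in items:
        by_type.setdefault(it.cargo_type, []).append(it)
    cargos = []
    for shell in shells:
        shell.items = by_type.pop(shell.cargo_type, [])
        cargos.append(shell)
    if by_type:
        orphans = ", ".join(t.value for t in by_type)
        raise SchemaError(f"order items reference cargo(s) without waybill: {orphans}")
    return Shipment(
        cargos=cargos,
        land_freight=config.land_freight,
        customs_fee_per_line=config.customs_fee_per_line,
        currency=config.currency,
        parts=config.parts,
        program_part=config.program_part,
    )


def write_report(result, out_dir: Union[str, Path], rounded: bool = True) -> dict:
    """Write the per-item, per-cargo and shipment reports.

    Emits ``items.csv``, ``cargos.csv`` (with a Total row) and
    ``summary.json``; returns a dict of written paths.  ``rounded`` applies
    the presentation policy (whole euros for totals, two decimals for €/kg,
    one decimal below 10 for percentages) to the CSV tables; the JSON
    summary always keeps full precision.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if result.items.empty:
        raise ValueError("nothing to report: shipment has no items")

    items_df = result.items.copy()
    cargos_df = result.cargos.copy()

    total_row = {
        "cargo": "Total",
        "items": result.summary["n_items"],
        "item_lines": result.summary["n_item_lines"],
        "units": result.summary["n_units"],
        "net_weight_kg": result.summary["net_weight_kg"],
        "gross_weight_kg": cargos_df["gross_weight_kg"].sum(),
        "gross_to_net_ratio": (
            cargos_df["gross_weight_kg"].sum() / result.summary["net_weight_kg"]
        ),
        "order_value_eur": result.summary["order_value_eur"],
        "air_eur": result.summary["air_eur"],
        "land_eur": result.summary["land_eur"],
        "customs_eur": result.summary["customs_eur"],
        "total_eur": result.summary["total_eur"],
        "air_rate_eur_per_kg": result.summary["air_eur"] / result.summary["net_weight_kg"],
        "land_rate_eur_per_kg": result.summary["land_eur"] / result.summary["net_weight_kg"],
        "total_eur_per_kg": result.summary["total_eur_per_kg"],
        "pct_of_order_value": result.summary["pct_of_order_value"],
    }
    cargos_df = pd.concat([cargos_df, pd.DataFrame([total_row])], ignore_index=True)

    if rounded:
        for col in ("air_eur", "land_eur", "customs_eur", "total_eur",
                    "order_value_eur"):
            cargos_df[col] = cargos_df[col].map(metrics.round_money)
        for col in ("air_rate_eur_per_kg", "land_rate_eur_per_kg",
                    "total_eur_per_kg"):
            cargos_df[col] = cargos_df[col].map(metrics.round_rate)
        cargos_df["pct_of_order_value"] = cargos_df["pct_of_order_value"].map(
            metrics.round_percent
        )
        cargos_df["gross_to_net_ratio"] = cargos_df["gross_to_net_ratio"].round(2)
        items_df["pct_of_unit_price"] = items_df["pct_of_unit_price"].map(
            lambda v: v if pd.isna(v) else metrics.round_percent(v)
        )
        items_df["item_total_eur"] = items_df["item_total_eur"].map(metrics.round_money)

    paths = {
        "items": out / "items.csv",
        "cargos": out / "cargos.csv",
        "summary": out / "summary.json",
    }
    items_df.to_csv(paths["items"], index=False)
    cargos_df.to_csv(paths["cargos"], index=False)
    with open(paths["summary"], "w", encoding="utf-8") as fh:
        json.dump(result.summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {k: str(v) for k, v in paths.items()}
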