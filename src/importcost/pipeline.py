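"""End-to-end pipeline: imputation → allocation → metrics → classification.

:func:`run_pipeline` is the library's main entry point; the CLI and the
report writer are thin layers over the :class:`PipelineResult` it returns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from . import metrics
from .allocation import ShipmentAllocation, allocate_shipment
from .classify import ClassificationConfig, classify_contributors, line_sharing_flags
from .domain import (
    CargoType,
    ContributorClass,
    CostBreakdown,
    Finding,
    Shipment,
    convert_currency,
    flag_nominal_prices,
    validate_shipment,
)
from .imputation import ImputationReport, ReferenceWeight, impute_unit_weights


@dataclass
class PipelineOptions:
    nominal_threshold_eur: float = 0.01
    classification: ClassificationConfig = field(default_factory=ClassificationConfig)
    reference_weights: Sequence[ReferenceWeight] = ()
    frozen_net_weight_kg: Optional[Mapping[CargoType, float]] = None


@dataclass
class PipelineResult:
    """Everything the reports need, computed once at full precision."""

    shipment: Shipment
    allocation: ShipmentAllocation
    imputation: ImputationReport
    findings: list[Finding]
    items: pd.DataFrame       # one row per item record
    cargos: pd.DataFrame      # one row per cargo
    summary: dict             # shipment-level figures

    @property
    def warnings(self) -> list[str]:
        return [f.message for f in self.findings if f.severity == "warning"]


def run_pipeline(
    shipment: Shipment, options: Optional[PipelineOptions] = None
) -> PipelineResult:
    """Run the full import-cost assessment on one shipment.

    Raises ``ValueError`` listing the findings if validation reports errors;
    warnings are carried through to the result.
    """
    options = options or PipelineOptions()
    table = shipment.currency

    # imputation (per shipment; donors may live in another cargo per rule 1)
    all_items = [it for c in shipment.cargos for it in c.items]
    imputed, report = impute_unit_weights(
        all_items,
        reference=options.reference_weights,
        frozen_net_weight_kg=options.frozen_net_weight_kg,
    )
    imputed = flag_nominal_prices(imputed, table, options.nominal_threshold_eur)
    cursor = 0
    for cargo in shipment.cargos:
        n = len(cargo.items)
        cargo.items = list(imputed[cursor : cursor + n])
        cursor += n

    findings = validate_shipment(shipment)
    errors = [f for f in findings if f.severity == "error"]
    if errors:
        raise ValueError(
            "shipment failed validation: " + "; ".join(f.message for f in errors)
        )

    allocation = allocate_shipment(shipment)

    item_rows = []
    cargo_rows = []
    for cargo in shipment.cargos:
        ctx = allocation.contexts[cargo.cargo_type]
        unit_costs = allocation.unit_costs[cargo.cargo_type]
        classes = classify_contributors(cargo.items, options.classification)
        shared = line_sharing_flags(cargo.items)
        value_eur = sum(
            convert_currency(it.unit_price, table) * it.quantity for it in cargo.items
        )
        for it, uc in zip(cargo.items, unit_costs):
            ic = metrics.item_import_cost(uc, it.quantity)
            price_eur = convert_currency(it.unit_price, table)
            pct = metrics.percentage_unit_cost(uc.total, price_eur, it.nominal_price)
            band = metrics.assign_cost_band(ic.total)
            item_rows.append(
                {
                    "cargo": cargo.cargo_type.value,
                    "item_id": it.item_id,
                    "description": it.description,
                    "form": it.form.value,
                    "packaging": it.packaging.value,
                    "item_line": it.item_line,
                    "quantity": it.quantity,
                    "unit_weight_g": it.unit_weight_g,
                    "weight_provenance": (
                        it.weight_provenance.value if it.weight_provenance else "measured"
                    ),
                    "unit_price_eur": price_eur,
                    "nominal_price": it.nominal_price,
                    "unit_air_eur": uc.air,
                    "unit_land_eur": uc.land,
                    "unit_customs_eur": uc.customs,
                    "unit_total_eur": uc.total,
                    "item_air_eur": ic.air,
                    "item_land_eur": ic.land,
                    "item_customs_eur": ic.customs,
                    "item_total_eur": ic.total,
                    "pct_of_unit_price": pct,
                    "cost_band": band.label,
                    "contributor_class": classes[it.item_id].value,
                    "shares_item_line": shared[it.item_id],
                }
            )
        total = allocation.cargo_total(cargo.cargo_type)
        cargo_rows.append(
            {
                "cargo": cargo.cargo_type.value,
                "items": len(cargo.items),
                "item_lines": len(ctx.units_per_line),
                "units": cargo.n_units,
                "net_weight_kg": ctx.net_weight_kg,
                "gross_weight_kg": cargo.gross_weight_kg,
                "gross_to_net_ratio": metrics.gross_to_net_ratio(
                    cargo.gross_weight_kg, ctx.net_weight_kg
                ),
                "order_value_eur": value_eur,
                "air_eur": total.air,
                "land_eur": total.land,
                "customs_eur": total.customs,
                "total_eur": total.total,
                "air_rate_eur_per_kg": ctx.air_rate_per_kg,
                "land_rate_eur_per_kg": ctx.land_rate_per_kg,
                "total_eur_per_kg": metrics.average_cost_per_kg(
                    total.total, ctx.net_weight_kg
                ),
                "pct_of_order_value": 100.0 * total.total / value_eur,
            }
        )

    items_df = pd.DataFrame(item_rows)
    cargos_df = pd.DataFrame(cargo_rows)

    ship_total = allocation.shipment_total()
    ship_net = float(cargos_df["net_weight_kg"].sum())
    ship_value = float(cargos_df["order_value_eur"].sum())
    summary = {
        "n_cargos": len(shipment.cargos),
        "n_items": int(len(items_df)),
        "n_item_lines": int(cargos_df["item_lines"].sum()),
        "n_units": int(cargos_df["units"].sum()),
        "net_weight_kg": ship_net,
        "order_value_eur": ship_value,
        "air_eur": ship_total.air,
        "land_eur": ship_total.land,
        "customs_eur": ship_total.customs,
        "total_eur": ship_total.total,
        "total_eur_per_kg": metrics.average_cost_per_kg(ship_total.total, ship_net),
        "pct_of_order_value": 100.0 * ship_total.total / ship_value,
        "customs_fee_per_line_eur": allocation.fee_per_line_eur,
        "n_imputed_weights": len(report),
        "n_nominal_items": int(items_df["nominal_price"].sum()),
    }

    return PipelineResult(
        shipment=shipment,
        allocation=allocation,
        imputation=report,
        findings=findings,
        items=items_df,
        cargos=cargos_df,
        summary=summary,
    )
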