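"""Unit-weight imputation for items whose catalog weight is unavailable.

Missing unit weights are filled by a three-rule hierarchy:

1. substitute the weight of an item with the same active ingredient and the
   same concentration (an external reference list, standing in for a standard
   product catalog, is searched before the shipment itself);
2. take the median unit weight of identically packaged items in the same
   cargo;
3. frozen cargo only: assume one uniform weight for every unit, either a
   configured net-weight budget divided by the unit count or 1 g per unit.
   Either choice makes weight-based transport allocation equivalent to
   allocating per imported unit.

Imputation never touches a weight that is present and is idempotent.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .domain import CargoType, ItemRecord, Packaging, WeightProvenance


@dataclass(frozen=True)
class ReferenceWeight:
    """One row of an external unit-weight reference list."""

    active_ingredient: str
    concentration: str
    packaging: Packaging
    unit_weight_g: float


@dataclass(frozen=True)
class ImputationEntry:
    item_id: str
    rule: WeightProvenance
    imputed_weight_g: float
    donor_item_id: Optional[str] = None


@dataclass
class ImputationReport:
    """One entry per initially missing weight, in input order."""

    entries: list[ImputationEntry]

    def __len__(self) -> int:
        return len(self.entries)


class ImputationError(ValueError):
    """Raised when no rule applies to a missing weight."""


def _norm(s: Optional[str]) -> Optional[str]:
    return " ".join(s.split()).lower() if s else None


_PACKAGING_SIZE_RANK = {p: i for i, p in enumerate(Packaging)}


def _find_donor(
    item: ItemRecord,
    reference: Sequence[ReferenceWeight],
    items: Sequence[ItemRecord],
) -> Optional[tuple[float, Optional[str]]]:
    """Rule 1: same active ingredient, same (normalized) concentration."""
    ing, conc = _norm(item.active_ingredient), _norm(item.concentration)
    if ing is None or conc is None:
        return None
    for ref in reference:
        if _norm(ref.active_ingredient) == ing and _norm(ref.concentration) == conc:
            return ref.unit_weight_g, None
    candidates = [
        d
        for d in items
        if d.item_id != item.item_id
        and d.unit_weight_g is not None
        and _norm(d.active_ingredient) == ing
        and _norm(d.concentration) == conc
    ]
    if not candidates:
        return None
    # deterministic tie-break: closest packaging type, then item id
    candidates.sort(
        key=lambda d: (
            abs(_PACKAGING_SIZE_RANK[d.packaging] - _PACKAGING_SIZE_RANK[item.packaging]),
            d.item_id,
        )
    )
    donor = candidates[0]
    return donor.unit_weight_g, donor.item_id


def _packaging_median(item: ItemRecord, items: Sequence[ItemRecord]) -> Optional[float]:
    """Rule 2: median weight of identically packaged items in the same cargo."""
    weights = [
        d.unit_weight_g
        for d in items
        if d.cargo_type == item.cargo_type
        and d.packaging == item.packaging
        and d.unit_weight_g is not None
    ]
    if not weights:
        return None
    return statistics.median(weights)


def impute_unit_weights(
    items: Sequence[ItemRecord],
    reference: Sequence[ReferenceWeight] = (),
    frozen_net_weight_kg: Optional[Mapping[CargoType, float]] = None,
) -> tuple[list[ItemRecord], ImputationReport]:
    """Fill every missing unit weight; return new records plus a report.

    ``frozen_net_weight_kg`` optionally budgets the net weight of a cargo
    whose items are all missing weights (typically the frozen cargo); the
    budget is divided by the cargo's total unit count so each unit carries
    the same weight.

    Raises :class:`ImputationError` naming the items for which no rule
    applies.
    """
    out = list(items)
    entries: list[ImputationEntry] = []
    failed: list[str] = []

    uniform_weights: dict[CargoType, float] = {}
    if frozen_net_weight_kg:
        for ctype, budget_kg in frozen_net_weight_kg.items():
            units = sum(it.quantity for it in items if it.cargo_type == ctype)
            if units > 0:
                uniform_weights[ctype] = budget_kg * 1000.0 / units

    for i, item in enumerate(items):
        if item.unit_weight_g is not None:
            continue
        donor = _find_donor(item, reference, items)
        if donor is not None:
            weight, donor_id = donor
            rule = WeightProvenance.SUBSTITUTED_SAME_INGREDIENT
        else:
            median = _packaging_median(item, items)
            if median is not None:
                weight, donor_id, rule = median, None, WeightProvenance.MEDIAN_OF_PACKAGING
            elif item.cargo_type == CargoType.FROZEN:
                weight = uniform_weights.get(item.cargo_type, 1.0)
                donor_id, rule = None, WeightProvenance.UNIFORM_ASSUMED
            else:
                failed.append(item.item_id)
                continue
        out[i] = item.with_weight(weight, rule)
        entries.append(ImputationEntry(item.item_id, rule, weight, donor_id))

    if failed:
        raise ImputationError(
            "no imputation rule applies to items: " + ", ".join(failed)
        )
    return out, ImputationReport(entries)
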