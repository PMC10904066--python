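"""Import-cost-contributor classification.

Within one cargo, items fall into four groups on the (unit weight, ordered
quantity) plane: heavy-but-few items are costly by unit weight, light-but-
many by number, heavy-and-many by the product of the two, and light-and-few
items carry low import cost.  Default thresholds are the within-cargo
medians on log10 axes, which makes the split scale-free; fixed thresholds
can be configured instead.  Ties (exactly at a threshold) classify into the
">=" side.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass
from typing import Optional, Sequence, Union

from .domain import ContributorClass, ItemRecord


@dataclass(frozen=True)
class ClassificationConfig:
    """Threshold rules for the quadrant split.

    ``weight_threshold`` / ``quantity_threshold``: the string
    ``"cargo_median"`` or a fixed positive value (grams / units).
    ``log_scale`` applies the median on log10-transformed axes.
    """

    weight_threshold: Union[str, float] = "cargo_median"
    quantity_threshold: Union[str, float] = "cargo_median"
    log_scale: bool = True

    def __post_init__(self) -> None:
        for thr in (self.weight_threshold, self.quantity_threshold):
            if isinstance(thr, str):
                if thr != "cargo_median":
                    raise ValueError(f"unknown threshold rule {thr!r}")
            elif not thr > 0:
                raise ValueError("fixed thresholds must be positive")


def _median_threshold(values: Sequence[float], log_scale: bool) -> float:
    if log_scale:
        return 10.0 ** statistics.median(math.log10(v) for v in values)
    return statistics.median(values)


def classify_contributors(
    items: Sequence[ItemRecord],
    config: Optional[ClassificationConfig] = None,
) -> dict[str, ContributorClass]:
    """Assign each item of one cargo to exactly one contributor class.

    Items must have imputed weights and unique ids within the cargo.
    """
    if not items:
        raise ValueError("cannot classify an empty cargo")
    config = config or ClassificationConfig()

    ids = [it.item_id for it in items]
    if len(set(ids)) != len(ids):
        raise ValueError("item ids must be unique within a cargo for classification")
    weights = []
    for it in items:
        if it.unit_weight_g is None:
            raise ValueError(f"item {it.item_id} has no unit weight; impute first")
        weights.append(it.unit_weight_g)
    quantities = [float(it.quantity) for it in items]

    if config.weight_threshold == "cargo_median":
        w_thr = _median_threshold(weights, config.log_scale)
    else:
        w_thr = float(config.weight_threshold)
    if config.quantity_threshold == "cargo_median":
        q_thr = _median_threshold(quantities, config.log_scale)
    else:
        q_thr = float(config.quantity_threshold)

    out: dict[str, ContributorClass] = {}
    for it, w, q in zip(items, weights, quantities):
        heavy = w >= w_thr
        many = q >= q_thr
        if heavy and many:
            cls = ContributorClass.COSTLY_BY_WEIGHT_TIMES_NUMBER
        elif heavy:
            cls = ContributorClass.COSTLY_BY_UNIT_WEIGHT
        elif many:
            cls = ContributorClass.COSTLY_BY_NUMBER
        else:
            cls = ContributorClass.LOW_IMPORT_COST
        out[it.item_id] = cls
    return out


def line_sharing_flags(items: Sequence[ItemRecord]) -> dict[str, bool]:
    """Annotation: does an item share its customs line with other items?

    Line sharing lowers per-unit customs cost; it is reported alongside the
    contributor class, not used as a classification criterion.
    """
    counts: dict[str, int] = {}
    for it in items:
        counts[it.item_line] = counts.get(it.item_line, 0) + 1
    return {it.item_id: counts[it.item_line] > 1 for it in items}
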