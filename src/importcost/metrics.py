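"""Derived cost metrics: item totals, percentage costs, averages, bands.

Percentage import costs express a unit's import cost relative to its unit
price.  Items flagged as nominally priced (donations, split-kit parts booked
at €0.01) are excluded from percentage summaries rather than distorting
them; the reported ``n`` reflects the exclusions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .domain import CostBreakdown

#: Marker returned for items excluded from percentage-cost analysis.
EXCLUDED = None


def item_import_cost(unit_cost: CostBreakdown, quantity: int) -> CostBreakdown:
    """Item-level breakdown: unit breakdown scaled by the ordered quantity."""
    if quantity < 1:
        raise ValueError("quantity must be >= 1")
    return unit_cost.scaled(quantity, level="item")


def quantity_weighted_price(
    orders: Sequence[tuple[float, int]]
) -> tuple[float, int]:
    """Combine multiple orders of one item.

    Returns the quantity-weighted average price and the combined quantity.
    """
    if not orders:
        raise ValueError("no orders to combine")
    if any(q <= 0 for _, q in orders):
        raise ValueError("order quantities must be positive")
    total_q = sum(q for _, q in orders)
    avg = sum(p * q for p, q in orders) / total_q
    return avg, total_q


def percentage_unit_cost(
    unit_cost: float, unit_price: float, nominal: bool
) -> Optional[float]:
    """Unit import cost as % of unit price, or ``EXCLUDED`` for nominal prices."""
    if nominal:
        return EXCLUDED
    if unit_price < 0:
        raise ValueError("unit price must be >= 0")
    if unit_price == 0:
        raise ValueError(
            "zero unit price without a nominal-price flag; flag the item instead"
        )
    return 100.0 * unit_cost / unit_price


def average_cost_per_kg(total_cost: float, net_weight_kg: float) -> float:
    """Average import cost per kg of order net weight."""
    if not net_weight_kg > 0:
        raise ValueError("net weight must be > 0 kg")
    return total_cost / net_weight_kg


def gross_to_net_ratio(gross_kg: float, net_kg: float) -> float:
    """Cargo packaging overhead factor."""
    if not net_kg > 0:
        raise ValueError("net weight must be > 0 kg")
    return gross_kg / net_kg


@dataclass(frozen=True)
class DistributionSummary:
    """Median and interquartile range of a sample."""

    median: float
    iqr_lower: float
    iqr_upper: float
    n: int

    def __post_init__(self) -> None:
        if not (self.iqr_lower <= self.median <= self.iqr_upper):
            raise ValueError("IQR must bracket the median")


def summarize_distribution(values: Sequence[float]) -> DistributionSummary:
    """Median and 25th/75th percentiles (linear interpolation)."""
    if len(values) == 0:
        raise ValueError("cannot summarize an empty sample")
    arr = np.asarray(values, dtype=float)
    lo, med, hi = np.percentile(arr, [25, 50, 75])
    return DistributionSummary(float(med), float(lo), float(hi), n=len(arr))


@dataclass(frozen=True)
class CostBand:
    """One decade band [lower, upper) of item import cost in base currency."""

    lower: float
    upper: float

    @property
    def label(self) -> str:
        if self.upper == 0:
            return "zero"
        return f"€{self.lower:,.10g}–{self.upper:,.10g}"


def assign_cost_band(item_cost: float) -> CostBand:
    """Map a non-negative cost to its decade band; zero gets its own band."""
    if item_cost < 0:
        raise ValueError("item cost must be >= 0")
    if item_cost == 0:
        return CostBand(0.0, 0.0)
    k = math.floor(math.log10(item_cost))
    # guard against 10**k > cost from floating log at exact powers of ten
    if 10.0 ** k > item_cost:
        k -= 1
    elif 10.0 ** (k + 1) <= item_cost:
        k += 1
    return CostBand(10.0 ** k, 10.0 ** (k + 1))


def percentage_summary(
    unit_costs: Sequence[float],
    unit_prices: Sequence[float],
    nominal_flags: Sequence[bool],
) -> DistributionSummary:
    """Distribution of percentage unit costs over non-excluded items."""
    pcts = [
        percentage_unit_cost(c, p, f)
        for c, p, f in zip(unit_costs, unit_prices, nominal_flags)
    ]
    kept = [v for v in pcts if v is not EXCLUDED]
    if not kept:
        raise ValueError("all items excluded from percentage analysis")
    return summarize_distribution(kept)


def round_money(value: float) -> float:
    """Presentation rounding for euro totals: whole euros."""
    return float(round(value))


def round_percent(value: float) -> float:
    """Presentation rounding for percentages: 1 decimal below 10, integer above."""
    return round(value, 1) if abs(value) < 10 else float(round(value))


def round_rate(value: float) -> float:
    """Presentation rounding for €/kg rates: 2 decimals at or above 1,
    else 2 significant digits."""
    if abs(value) >= 1:
        return round(value, 2)
    if value == 0:
        return 0.0
    exp = math.floor(math.log10(abs(value)))
    return round(value, -exp + 1)
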