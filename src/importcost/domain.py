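"""Core domain types for import-cost accounting.

The vocabulary follows medical supply-chain costing: a *shipment* groups one
or more *cargos* (standard 15-25 °C, cool 2-8 °C, frozen on dry ice), each
cargo holds ordered *items*, and every item is ultimately broken down into
physical *units* (one tablet, one vial, one test).  Import costs are the sum
of air freight, in-country land freight and customs clearance fees; customs
duties do not apply to humanitarian goods and are out of scope.

All monetary arithmetic inside the package happens in a single base currency
(EUR by default) at full floating precision; rounding is presentational only.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence


class PharmForm(str, enum.Enum):
    """Pharmaceutical form of an item."""

    CAPSULE = "capsule"
    FLUID_LT_100ML = "fluid_lt_100ml"
    FLUID_GE_100ML = "fluid_ge_100ml"
    TABLET = "tablet"
    OINTMENT = "ointment"
    POWDER = "powder"
    TEST_KIT = "test_kit"
    WIPE = "wipe"


class Packaging(str, enum.Enum):
    """Primary packaging type of one unit."""

    AMPULLA = "ampulla"
    BOTTLE = "bottle"
    CAPSULE_OR_TABLET = "capsule_or_tablet"
    FLUID_BAG = "fluid_bag"
    SACHET = "sachet"
    TUBE = "tube"
    VIAL = "vial"
    TEST_KIT = "test_kit"


class CargoType(str, enum.Enum):
    STANDARD = "standard"
    COOL = "cool"
    FROZEN = "frozen"


class WeightProvenance(str, enum.Enum):
    """How an item's unit weight was obtained."""

    MEASURED = "measured"
    SUBSTITUTED_SAME_INGREDIENT = "substituted_same_ingredient"
    MEDIAN_OF_PACKAGING = "median_of_packaging"
    UNIFORM_ASSUMED = "uniform_assumed"


class ContributorClass(str, enum.Enum):
    """Why an item drives import cost (quadrants of the weight-quantity plane)."""

    COSTLY_BY_NUMBER = "costly_by_number"
    COSTLY_BY_UNIT_WEIGHT = "costly_by_unit_weight"
    COSTLY_BY_WEIGHT_TIMES_NUMBER = "costly_by_weight_times_number"
    LOW_IMPORT_COST = "low_import_cost"


@dataclass(frozen=True)
class Money:
    """An amount tagged with its currency code."""

    amount: float
    currency: str = "EUR"

    def __post_init__(self) -> None:
        object.__setattr__(self, "currency", self.currency.upper())


class UnknownCurrencyError(KeyError):
    """Raised when a currency code is absent from the rate table."""


@dataclass(frozen=True)
class CurrencyTable:
    """Exchange rates expressed as units of each currency per one base unit.

    Example: base EUR with ``{"USD": 1.107, "UZS": 3282}`` encodes
    €1 = $1.107 = UZS 3282 (World Bank annual rates for 2016).
    """

    base: str = "EUR"
    rates: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "base", self.base.upper())
        norm = {c.upper(): float(r) for c, r in self.rates.items()}
        norm.setdefault(self.base, 1.0)
        if not math.isclose(norm[self.base], 1.0, rel_tol=0, abs_tol=1e-12):
            raise ValueError(f"base currency {self.base} must map to 1.0")
        for code, rate in norm.items():
            if not rate > 0:
                raise ValueError(f"rate for {code} must be strictly positive")
        object.__setattr__(self, "rates", norm)

    def rate(self, currency: str) -> float:
        code = currency.upper()
        try:
            return self.rates[code]
        except KeyError:
            raise UnknownCurrencyError(
                f"unknown currency code {code!r}; known: {sorted(self.rates)}"
            ) from None


def convert_currency(amount: Money, table: CurrencyTable) -> float:
    """Convert ``amount`` to the table's base currency.

    Division by the per-base rate, so $1.107 at rate 1.107 yields €1.00
    exactly; base-to-base is the identity.
    """
    return amount.amount / table.rate(amount.currency)


@dataclass(frozen=True)
class ItemRecord:
    """One ordered medical item within a cargo.

    ``unit_weight_g`` may be missing on input; imputation
    (:mod:`importcost.imputation`) fills it and records the provenance.
    ``nominal_price`` marks items whose invoice price does not reflect value
    (e.g. donated goods or the €0.01 part of a split test kit); such items
    are excluded from percentage-cost summaries.
    """

    item_id: str
    description: str
    form: PharmForm
    packaging: Packaging
    unit_price: Money
    quantity: int
    item_line: str
    cargo_type: CargoType
    active_ingredient: Optional[str] = None
    concentration: Optional[str] = None
    unit_weight_g: Optional[float] = None
    weight_provenance: Optional[WeightProvenance] = None
    nominal_price: bool = False

    def __post_init__(self) -> None:
        if self.quantity < 1:
            raise ValueError(f"item {self.item_id}: quantity must be >= 1")
        if self.unit_weight_g is not None and not self.unit_weight_g > 0:
            raise ValueError(f"item {self.item_id}: unit weight must be > 0 g")

    def with_weight(self, grams: float, provenance: WeightProvenance) -> "ItemRecord":
        return replace(self, unit_weight_g=grams, weight_provenance=provenance)

    @property
    def net_weight_kg(self) -> float:
        if self.unit_weight_g is None:
            raise ValueError(
                f"item {self.item_id} has no unit weight; run imputation first"
            )
        return self.unit_weight_g * self.quantity / 1000.0


@dataclass
class Cargo:
    """One cargo type of a shipment with its billed air freight."""

    cargo_type: CargoType
    gross_weight_kg: float
    air_freight: Money
    items: list[ItemRecord] = field(default_factory=list)
    volume_m3: Optional[float] = None
    air_surcharges: Optional[Money] = None  # informational; billed total is all-inclusive
    notes: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.gross_weight_kg > 0:
            raise ValueError("cargo gross weight must be > 0 kg")

    @property
    def net_weight_kg(self) -> float:
        """Order net weight: unit weights x quantities, cargo packaging excluded."""
        return sum(it.net_weight_kg for it in self.items)

    @property
    def item_lines(self) -> list[str]:
        return sorted({it.item_line for it in self.items})

    @property
    def n_units(self) -> int:
        return sum(it.quantity for it in self.items)

    def units_per_line(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for it in self.items:
            out[it.item_line] = out.get(it.item_line, 0) + it.quantity
        return out


@dataclass(frozen=True)
class ShipmentPart:
    """One destination-bound part of a cargo that was billed as a whole."""

    destination: str
    gross_weight_kg: float

    def __post_init__(self) -> None:
        if not self.gross_weight_kg > 0:
            raise ValueError("shipment part gross weight must be > 0 kg")


@dataclass
class Shipment:
    """Cargos plus the shipment-level cost inputs."""

    cargos: list[Cargo]
    land_freight: Money
    customs_fee_per_line: Money
    currency: CurrencyTable
    parts: Mapping[CargoType, Sequence[ShipmentPart]] = field(default_factory=dict)
    program_part: Optional[str] = None  # destination label of the program's part

    def cargo(self, cargo_type: CargoType) -> Cargo:
        for c in self.cargos:
            if c.cargo_type == cargo_type:
                return c
        raise KeyError(f"no {cargo_type.value} cargo in shipment")

    @property
    def order_value_eur(self) -> float:
        return sum(
            convert_currency(it.unit_price, self.currency) * it.quantity
            for c in self.cargos
            for it in c.items
        )


@dataclass(frozen=True)
class CostBreakdown:
    """Air / land / customs amounts (base currency) at one accounting level."""

    air: float
    land: float
    customs: float
    level: str  # unit | item | cargo | shipment

    @property
    def total(self) -> float:
        return self.air + self.land + self.customs

    def scaled(self, factor: float, level: Optional[str] = None) -> "CostBreakdown":
        return CostBreakdown(
            self.air * factor, self.land * factor, self.customs * factor,
            level or self.level,
        )

    def __add__(self, other: "CostBreakdown") -> "CostBreakdown":
        return CostBreakdown(
            self.air + other.air, self.land + other.land,
            self.customs + other.customs, self.level,
        )


@dataclass(frozen=True)
class Finding:
    """One validation finding; ``severity`` is 'error' or 'warning'."""

    severity: str
    message: str


def validate_shipment(shipment: Shipment) -> list[Finding]:
    """Check shipment invariants without mutating anything.

    Returns an empty list iff all invariants hold.  Gross weight below the
    computed net weight is a *warning*, not an error: printed or transcribed
    inputs are rounded and may be inconsistent by small amounts.
    """
    findings: list[Finding] = []
    seen_types: set[CargoType] = set()
    for cargo in shipment.cargos:
        if cargo.cargo_type in seen_types:
            findings.append(Finding("error", f"duplicate cargo type {cargo.cargo_type.value}"))
        seen_types.add(cargo.cargo_type)
        if not cargo.gross_weight_kg > 0:
            findings.append(
                Finding("error", f"{cargo.cargo_type.value} cargo: gross weight must be > 0")
            )
        if not cargo.items:
            findings.append(Finding("error", f"{cargo.cargo_type.value} cargo has no items"))
        for it in cargo.items:
            if it.quantity < 1:
                findings.append(Finding("error", f"item {it.item_id}: quantity {it.quantity} < 1"))
            if it.unit_weight_g is not None and not it.unit_weight_g > 0:
                findings.append(Finding("error", f"item {it.item_id}: nonpositive unit weight"))
            if it.cargo_type != cargo.cargo_type:
                findings.append(
                    Finding("error",
                            f"item {it.item_id}: cargo type {it.cargo_type.value} "
                            f"inside {cargo.cargo_type.value} cargo")
                )
        if all(it.unit_weight_g is not None for it in cargo.items) and cargo.items:
            net = cargo.net_weight_kg
            if cargo.gross_weight_kg < net:
                findings.append(
                    Finding("warning",
                            f"{cargo.cargo_type.value} cargo: gross weight "
                            f"{cargo.gross_weight_kg:g} kg below computed net weight {net:g} kg")
                )
    for ctype, parts in shipment.parts.items():
        if len({p.destination for p in parts}) != len(list(parts)):
            findings.append(Finding("error", f"duplicate part destination for {ctype.value} cargo"))
    try:
        shipment.currency.rate(shipment.land_freight.currency)
        shipment.currency.rate(shipment.customs_fee_per_line.currency)
    except UnknownCurrencyError as exc:
        findings.append(Finding("error", str(exc)))
    if shipment.customs_fee_per_line.amount < 0:
        findings.append(Finding("error", "customs fee per line must be >= 0"))
    return findings


def flag_nominal_prices(
    items: Sequence[ItemRecord],
    table: CurrencyTable,
    threshold_eur: float = 0.01,
) -> list[ItemRecord]:
    """Set the nominal-price flag on items priced at or below the threshold.

    A flag already set on input is never cleared (it may encode knowledge the
    price alone cannot, e.g. a donated item with a zero price).
    """
    out = []
    for it in items:
        nominal = it.nominal_price or (
            convert_currency(it.unit_price, table) <= threshold_eur
        )
        out.append(replace(it, nominal_price=nominal))
    return out
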