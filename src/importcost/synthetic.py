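"""Seeded generator of synthetic shipments for property testing.

Real medical-supply cargos are strongly heterogeneous: unit weights span
0.1 g tablets to 1.5 kg fluid bottles, quantities span single test kits to
hundreds of thousands of tablets, and unit prices span three orders of
magnitude.  The generator emulates this with log-normal draws per cargo
type, centred on the characteristics of the reference shipment (standard
cargo: many light cheap units; cool: few heavy expensive units; frozen: a
handful of test kits).  Gross weight is net weight times a cargo-packaging
factor (defaults 1.1 / 3.5 / 5 for standard / cool / frozen).  A fraction
of unit weights is blanked so imputation paths stay exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .domain import (
    Cargo,
    CargoType,
    CurrencyTable,
    ItemRecord,
    Money,
    Packaging,
    PharmForm,
    Shipment,
)
from .fixtures import RATES_2016


@dataclass(frozen=True)
class CargoProfile:
    """Log-normal parameters (log10 scale) for one cargo type."""

    n_items: int
    n_lines: int
    log10_weight_mean: float   # grams
    log10_weight_sd: float
    log10_qty_mean: float      # units
    log10_qty_sd: float
    log10_price_mean: float    # EUR
    log10_price_sd: float
    gross_to_net: float
    air_rate_eur_per_kg_gross: float


DEFAULT_PROFILES: Mapping[CargoType, CargoProfile] = {
    CargoType.STANDARD: CargoProfile(
        n_items=30, n_lines=7,
        log10_weight_mean=0.1, log10_weight_sd=0.9,
        log10_qty_mean=3.6, log10_qty_sd=0.8,
        log10_price_mean=-1.0, log10_price_sd=0.7,
        gross_to_net=1.1, air_rate_eur_per_kg_gross=3.9,
    ),
    CargoType.COOL: CargoProfile(
        n_items=10, n_lines=3,
        log10_weight_mean=2.1, log10_weight_sd=0.4,
        log10_qty_mean=0.8, log10_qty_sd=0.6,
        log10_price_mean=1.4, log10_price_sd=0.4,
        gross_to_net=3.5, air_rate_eur_per_kg_gross=4.2,
    ),
    CargoType.FROZEN: CargoProfile(
        n_items=2, n_lines=1,
        log10_weight_mean=1.7, log10_weight_sd=0.2,
        log10_qty_mean=1.6, log10_qty_sd=0.3,
        log10_price_mean=1.2, log10_price_sd=0.8,
        gross_to_net=5.0, air_rate_eur_per_kg_gross=8.0,
    ),
}

_FORMS = [PharmForm.TABLET, PharmForm.CAPSULE, PharmForm.FLUID_GE_100ML,
          PharmForm.FLUID_LT_100ML, PharmForm.POWDER, PharmForm.TEST_KIT]
_PACKS = [Packaging.CAPSULE_OR_TABLET, Packaging.BOTTLE, Packaging.FLUID_BAG,
          Packaging.AMPULLA, Packaging.SACHET, Packaging.VIAL]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic shipment; ``seed`` is mandatory."""

    seed: int
    profiles: Mapping[CargoType, CargoProfile] = field(
        default_factory=lambda: dict(DEFAULT_PROFILES)
    )
    missing_weight_fraction: float = 0.1
    nominal_price_probability: float = 0.02
    land_freight_eur: float = 3000.0
    customs_fee: Money = Money(50.0, "USD")
    currency: CurrencyTable = RATES_2016

    def __post_init__(self) -> None:
        if not self.profiles:
            raise ValueError("spec must define at least one cargo profile")
        for ctype, prof in self.profiles.items():
            if prof.n_items < 1 or prof.n_lines < 1:
                raise ValueError(f"{ctype.value}: items and lines must be >= 1")
            if prof.n_lines > prof.n_items:
                raise ValueError(f"{ctype.value}: more lines than items")
        if not 0 <= self.missing_weight_fraction < 1:
            raise ValueError("missing fraction must be in [0, 1)")


def generate_shipment(spec: SyntheticSpec) -> Shipment:
    """Draw one reproducible synthetic shipment from ``spec``.

    Weight blanking never removes the last measured weight of a packaging
    group, so the median-of-packaging imputation rule always has a donor
    pool (the frozen cargo may still be fully blanked: it has the uniform-
    weight fallback).
    """
    rng = np.random.default_rng(spec.seed)
    cargos = []
    for ctype, prof in spec.profiles.items():
        weights = 10.0 ** rng.normal(prof.log10_weight_mean, prof.log10_weight_sd,
                                     prof.n_items)
        qtys = np.maximum(
            1, np.rint(10.0 ** rng.normal(prof.log10_qty_mean, prof.log10_qty_sd,
                                          prof.n_items))
        ).astype(int)
        prices = 10.0 ** rng.normal(prof.log10_price_mean, prof.log10_price_sd,
                                    prof.n_items)
        lines = rng.integers(1, prof.n_lines + 1, size=prof.n_items)
        lines[: prof.n_lines] = np.arange(1, prof.n_lines + 1)  # every line non-empty
        forms = rng.integers(0, len(_FORMS), size=prof.n_items)
        missing = rng.random(prof.n_items) < spec.missing_weight_fraction
        nominal = rng.random(prof.n_items) < spec.nominal_price_probability
        if ctype != CargoType.FROZEN:
            # keep one measured weight per packaging group so the
            # median-of-packaging rule always has a donor pool
            packs = np.array([forms[i] % len(_PACKS) for i in range(prof.n_items)])
            for pack in np.unique(packs):
                members = np.flatnonzero(packs == pack)
                if missing[members].all():
                    missing[members[0]] = False

        items = []
        for i in range(prof.n_items):
            fi = int(forms[i])
            items.append(
                ItemRecord(
                    item_id=f"{ctype.value}-{i:03d}",
                    description=f"synthetic {_FORMS[fi].value} item",
                    form=_FORMS[fi],
                    packaging=_PACKS[fi],
                    unit_price=Money(0.01 if nominal[i] else float(prices[i]), "EUR"),
                    quantity=int(qtys[i]),
                    item_line=f"{ctype.value}-HS{int(lines[i]):02d}",
                    cargo_type=ctype,
                    unit_weight_g=None if missing[i] else float(weights[i]),
                    nominal_price=bool(nominal[i]),
                )
            )
        # gross weight from the *true* net weight (incl. blanked items)
        net_kg = float(np.sum(weights * qtys)) / 1000.0
        gross_kg = net_kg * prof.gross_to_net
        cargos.append(
            Cargo(
                cargo_type=ctype,
                gross_weight_kg=gross_kg,
                air_freight=Money(gross_kg * prof.air_rate_eur_per_kg_gross, "EUR"),
                items=items,
            )
        )
    return Shipment(
        cargos=cargos,
        land_freight=Money(spec.land_freight_eur, "EUR"),
        customs_fee_per_line=spec.customs_fee,
        currency=spec.currency,
    )
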