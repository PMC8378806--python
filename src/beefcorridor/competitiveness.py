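"""Landed-cost ladders, transport costs, trade-record classification and
national consumption/throughput accounting.

These are deterministic value-chain arithmetic routines: the import cost
ladder from FOB to wholesale (freight, tariff, trader margin), the landed
price of regional exports (ad-valorem transport plus informal road charges),
refrigerated transport cost estimates with a West-Africa cost uplift, and
the classification of trade records into offals, low-value by-products and
high-value cuts from their unit values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .joint_pricing import CarcassSpec

__all__ = [
    "CostLadder",
    "TransportSpec",
    "WholesalePrice",
    "LandedPrice",
    "TransportCost",
    "ClassificationResult",
    "import_wholesale_price",
    "landed_export_price",
    "refrigerated_transport_cost",
    "flat_rate_transport_share",
    "classify_trade_records",
    "consumption_accounting",
    "slaughter_throughput",
]

HS_GROUPS = ("0201", "0202", "0206")  # fresh cuts, frozen cuts, offals
DEFAULT_CFA_PER_USD = 574.7
CFA_PER_EUR = 655.957  # CFA-euro peg


@dataclass(frozen=True)
class CostLadder:
    """FOB-to-wholesale cost ladder for imported offals.

    Freight defaults to a 3,500 EUR rate for a 40-foot, 25-ton container
    converted at ``usd_per_eur``; pass ``freight_usd_per_kg`` to override.
    The ladder order is fixed: FOB -> +freight = CIF -> +tariff x CIF ->
    +margin x subtotal.
    """

    fob_usd_per_kg: float = 1.11
    freight_usd_per_kg: float | None = None
    freight_total_eur: float = 3500.0
    freight_load_kg: float = 25_000.0
    usd_per_eur: float = 1.18
    tariff_rate: float = 0.35
    margin_rate: float = 0.08

    def __post_init__(self) -> None:
        if self.fob_usd_per_kg <= 0:
            raise ValueError("FOB price must be positive")
        for r in (self.tariff_rate, self.margin_rate):
            if r < 0:
                raise ValueError("rates must be non-negative")
        if self.freight_usd_per_kg is None:
            object.__setattr__(
                self,
                "freight_usd_per_kg",
                self.freight_total_eur * self.usd_per_eur / self.freight_load_kg,
            )
        if self.freight_usd_per_kg < 0:
            raise ValueError("freight must be non-negative")


@dataclass(frozen=True)
class WholesalePrice:
    """Wholesale price with both unrounded lines and 2-decimal display lines."""

    lines: Mapping[str, float]
    lines_rounded: Mapping[str, float]
    wholesale_usd_per_kg: float
    wholesale_cfa_per_kg: float

    @property
    def rounded_usd(self) -> float:
        return self.lines_rounded["wholesale"]


def import_wholesale_price(
    ladder: CostLadder, cfa_per_usd: float = DEFAULT_CFA_PER_USD
) -> WholesalePrice:
    """Wholesale price of imported offals from the cost ladder.

    Accumulates unrounded (FOB + freight = CIF; tariff on CIF; trader margin
    on CIF + tariff) and reports each line additionally rounded to 2 decimals
    for display.
    """
    fob = ladder.fob_usd_per_kg
    freight = float(ladder.freight_usd_per_kg)
    cif = fob + freight
    tariff = ladder.tariff_rate * cif
    subtotal = cif + tariff
    margin = ladder.margin_rate * subtotal
    wholesale = subtotal + margin
    lines = {
        "fob": fob,
        "freight": freight,
        "cif": cif,
        "tariff": tariff,
        "margin": margin,
        "wholesale": wholesale,
    }
    return WholesalePrice(
        lines=lines,
        lines_rounded={k: round(v, 2) for k, v in lines.items()},
        wholesale_usd_per_kg=wholesale,
        wholesale_cfa_per_kg=wholesale * cfa_per_usd,
    )


@dataclass(frozen=True)
class TransportSpec:
    """Overland transport cost parameters for the corridor.

    Refrigerated rate of 0.13 USD/ton/km with a 52% West-Africa uplift over
    the Southern-Africa benchmark; corridor exports alternatively carry a
    10% ad-valorem transport share plus 1% informal road charges.
    """

    rate_usd_per_ton_km: float = 0.13
    west_africa_uplift: float = 0.52
    load_tons: float = 25.0
    distance_km: float = 1000.0
    ad_valorem_share: float = 0.10
    informal_share: float = 0.01

    def __post_init__(self) -> None:
        for v in (
            self.rate_usd_per_ton_km,
            self.west_africa_uplift,
            self.load_tons,
            self.distance_km,
            self.ad_valorem_share,
            self.informal_share,
        ):
            if v < 0:
                raise ValueError("transport parameters must be non-negative")


@dataclass(frozen=True)
class LandedPrice:
    ex_abattoir: float
    transport: float
    informal: float
    landed: float


def landed_export_price(
    ex_abattoir_cfa_per_kg: float, transport: TransportSpec
) -> LandedPrice:
    """Landed price of corridor exports (CFA/kg).

    Ex-abattoir price plus the ad-valorem transport share, plus informal
    charges levied on the subtotal: 1,000 -> 1,100 -> 1,111 with the 10%/1%
    defaults.
    """
    if ex_abattoir_cfa_per_kg <= 0:
        raise ValueError("ex-abattoir price must be positive")
    t = transport.ad_valorem_share * ex_abattoir_cfa_per_kg
    subtotal = ex_abattoir_cfa_per_kg + t
    informal = transport.informal_share * subtotal
    return LandedPrice(
        ex_abattoir=ex_abattoir_cfa_per_kg,
        transport=t,
        informal=informal,
        landed=subtotal + informal,
    )


@dataclass(frozen=True)
class TransportCost:
    total_usd: float
    usd_per_kg: float
    share_of_value: float


def refrigerated_transport_cost(
    spec: TransportSpec, unit_value_usd_per_kg: float = 1.74
) -> TransportCost:
    """Refrigerated load cost: rate x (1 + uplift) x tons x km, and value share."""
    if spec.load_tons <= 0:
        raise ValueError("load must be positive")
    total = (
        spec.rate_usd_per_ton_km
        * (1.0 + spec.west_africa_uplift)
        * spec.load_tons
        * spec.distance_km
    )
    load_kg = spec.load_tons * 1000.0
    return TransportCost(
        total_usd=total,
        usd_per_kg=total / load_kg,
        share_of_value=total / (load_kg * unit_value_usd_per_kg),
    )


def flat_rate_transport_share(
    usd_per_km: float = 3.53,
    distance_km: float = 1000.0,
    load_tons: float = 25.0,
    unit_value_usd_per_kg: float = 1.74,
) -> float:
    """Share of load value under a flat per-km trucking rate (~8% at defaults)."""
    total = usd_per_km * distance_km
    return total / (load_tons * 1000.0 * unit_value_usd_per_kg)


@dataclass(frozen=True)
class ClassificationResult:
    """Per-category totals and shares from unit-value trade classification."""

    records: pd.DataFrame  # input rows with unit_value and category columns
    totals: pd.DataFrame  # per-category value/volume sums
    shares: pd.DataFrame  # per-category shares of grand totals
    borderline: pd.DataFrame  # rows within +/- 0.05 USD/kg of the threshold
    threshold: float

    def volume(self, category: str) -> float:
        return float(self.totals.loc[category, "volume_kg"])

    def value(self, category: str) -> float:
        return float(self.totals.loc[category, "value_usd"])


def classify_trade_records(
    table: pd.DataFrame,
    byproduct_threshold: float = 1.53,
    borderline_window: float = 0.05,
) -> ClassificationResult:
    """Classify trade records into offal, by-product and high-value cuts.

    Offal rows (HS 0206) are always category ``offal``; fresh/frozen rows
    (HS 0201/0202) are ``byproduct`` when their unit value falls below the
    threshold (default 1.53 USD/kg) and ``high_value`` otherwise.  Rows
    within ``borderline_window`` of the threshold are reported separately so
    the sensitivity of the cut-off is visible.  Zero-volume rows are excluded
    with a warning.
    """
    df = table.copy()
    required = {"origin", "hs_group", "value_usd", "volume_kg"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trade table missing columns: {sorted(missing)}")
    df["hs_group"] = df["hs_group"].astype(str).str.zfill(4)
    bad_hs = set(df["hs_group"]) - set(HS_GROUPS)
    if bad_hs:
        raise ValueError(f"unknown HS groups: {sorted(bad_hs)}")
    zero = df["volume_kg"] <= 0
    if zero.any():
        warnings.warn(
            f"excluding {int(zero.sum())} zero-volume rows from classification",
            UserWarning,
        )
        df = df[~zero].copy()
    df["unit_value"] = df["value_usd"] / df["volume_kg"]
    df["category"] = np.where(
        df["hs_group"] == "0206",
        "offal",
        np.where(df["unit_value"] < byproduct_threshold, "byproduct", "high_value"),
    )
    categories = ["offal", "byproduct", "high_value"]
    totals = (
        df.groupby("category")[["value_usd", "volume_kg"]]
        .sum()
        .reindex(categories, fill_value=0)
    )
    grand = totals.sum()
    shares = totals / grand if (grand > 0).all() else totals * 0.0
    borderline = df[
        (df["hs_group"] != "0206")
        & (df["unit_value"] - byproduct_threshold).abs().le(borderline_window)
    ]
    return ClassificationResult(
        records=df,
        totals=totals,
        shares=shares,
        borderline=borderline,
        threshold=byproduct_threshold,
    )


def consumption_accounting(
    domestic_offtake: float,
    imported: float,
    carcass: CarcassSpec,
    population: float,
) -> dict[str, float]:
    """National beef availability from domestic offtake plus imported animals.

    Returns total head, kg of carcass cuts, kg of offals, and per-capita kg.
    """
    if min(domestic_offtake, imported, population) < 0:
        raise ValueError("inputs must be non-negative")
    animals = domestic_offtake + imported
    cuts_kg = animals * carcass.carcass_weight
    offal_kg = animals * carcass.live_weight * carcass.offal_share
    out = {
        "animals_head": animals,
        "cuts_kg": cuts_kg,
        "offal_kg": offal_kg,
    }
    if population > 0:
        out["cuts_kg_per_capita"] = cuts_kg / population
        out["offal_kg_per_capita"] = offal_kg / population
    return out


def slaughter_throughput(
    head_per_day: float,
    days: float,
    carcass_kg: float,
    registered_slaughters: float | None = None,
) -> dict[str, float]:
    """Annual slaughterhouse throughput in head and tons of meat.

    Optionally reports the share of registered slaughters passing through the
    facility.
    """
    if head_per_day < 0 or days <= 0 or carcass_kg <= 0:
        raise ValueError("throughput inputs must be positive")
    head = head_per_day * days
    tons = head * carcass_kg / 1000.0
    out = {"head_per_year": head, "tons_per_year": tons}
    if registered_slaughters:
        out["share_of_registered"] = head / registered_slaughters
    return out
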