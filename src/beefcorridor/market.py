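"""Inventory-based price formation, bilateral trade, import demand and macro paths.

Price discovery for live animals follows the inventory-coverage mechanism:
traders hold a desired inventory equal to a coverage time multiplied by
recent demand, and the traded price moves with the ratio of desired to
actual inventory,

    P_t = P_{t-1} * (I*/I) ** sensitivity.

Excess supply above the bilateral trade volume is absorbed by a
rest-of-region demand sink (a Cote d'Ivoire proxy).  Ghana's offal import
demand from world markets is an imperfect-substitutes constant-elasticity
form in the world price, the domestic price and income.  Exchange rates and
the world offal price follow exogenous geometric paths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "InventoryState",
    "PriceState",
    "MacroPath",
    "MacroSnapshot",
    "DemandSpec",
    "inventory_price_update",
    "desired_inventory",
    "bilateral_trade",
    "import_demand",
    "macro_at",
]


@dataclass(frozen=True)
class InventoryState:
    """Actual vs desired inventory (head or kg) with a coverage time in months."""

    actual: float
    desired: float
    coverage_months: float = 1.0

    def __post_init__(self) -> None:
        if self.actual < 0:
            raise ValueError("actual inventory must be non-negative")
        if self.desired <= 0:
            raise ValueError("desired inventory must be positive")
        if self.coverage_months <= 0:
            raise ValueError("coverage time must be positive")


@dataclass
class PriceState:
    """Live-animal and per-product meat prices at one month."""

    live_animal_cfa_per_head: float
    meat_cfa_per_kg: Mapping[str, float]
    world_offal_usd_per_kg: float

    def __post_init__(self) -> None:
        if self.live_animal_cfa_per_head <= 0 or self.world_offal_usd_per_kg <= 0:
            raise ValueError("prices must be positive")
        for k, v in self.meat_cfa_per_kg.items():
            if v <= 0:
                raise ValueError(f"meat price {k} must be positive")


def desired_inventory(
    recent_demand: "np.ndarray | list[float]", coverage_months: float = 1.0
) -> float:
    """Desired inventory = coverage time x trailing mean of recent demand."""
    demand = np.asarray(recent_demand, dtype=float)
    if demand.size == 0:
        raise ValueError("need at least one demand observation")
    return float(coverage_months * demand.mean())


def inventory_price_update(
    prev_price: float, inv: InventoryState, sensitivity: float = 0.25
) -> float:
    """Next-period price from the inventory gap: P * (I*/I) ** sensitivity.

    Price rises when actual inventory is below desired (scarcity) and falls
    when above (pressure to liquidate).  A zero actual inventory signals
    market collapse and raises; callers should floor inventories.
    """
    if prev_price <= 0:
        raise ValueError("prev_price must be positive")
    if sensitivity < 0:
        raise ValueError("sensitivity must be non-negative")
    if inv.actual <= 0:
        raise ValueError("zero inventory: market collapse; floor inventory upstream")
    return float(prev_price * (inv.desired / inv.actual) ** sensitivity)


@dataclass(frozen=True)
class TradeOutcome:
    traded: float
    residual_supply: float


def bilateral_trade(excess_supply: float, excess_demand: float) -> TradeOutcome:
    """Bilateral live-animal trade as the short side of the market.

    Traded volume is min(excess supply, excess demand); residual supply is
    routed to the rest-of-region sink by the caller.
    """
    if excess_supply < 0 or excess_demand < 0:
        raise ValueError("excess supply and demand must be non-negative")
    traded = min(excess_supply, excess_demand)
    return TradeOutcome(traded=traded, residual_supply=excess_supply - traded)


@dataclass(frozen=True)
class DemandSpec:
    """A demand curve, constant-elasticity (default) or linear.

    Constant elasticity:  Q = scale * (P/ref_own)**e_own * (Pd/ref_cross)**e_cross * Y**e_income
    Linear:               Q = max(scale - slope * P, 0)

    ``scale`` is the quantity at the calibration point (all prices at their
    reference values, income index 1).
    """

    form: str = "constant_elasticity"
    scale: float = 1.0
    own_price_elasticity: float = -0.5
    cross_price_elasticity: float = 0.0
    income_elasticity: float = 1.0
    ref_own_price: float = 1.0
    ref_cross_price: float = 1.0
    slope: float = 0.0  # linear form only

    def __post_init__(self) -> None:
        if self.form not in ("constant_elasticity", "linear"):
            raise ValueError(f"unknown demand form {self.form!r}")
        if self.form == "constant_elasticity" and self.own_price_elasticity >= 0:
            raise ValueError("own-price elasticity of demand must be negative")
        for v in (self.scale, self.ref_own_price, self.ref_cross_price):
            if not np.isfinite(v):
                raise ValueError("demand parameters must be finite")

    def quantity(
        self, price: float, cross_price: float | None = None, income_index: float = 1.0
    ) -> float:
        if price <= 0:
            raise ValueError("price must be positive")
        if self.form == "linear":
            return float(max(self.scale - self.slope * price, 0.0))
        q = self.scale * (price / self.ref_own_price) ** self.own_price_elasticity
        if self.cross_price_elasticity != 0.0:
            if cross_price is None or cross_price <= 0:
                raise ValueError("positive cross price required")
            q *= (cross_price / self.ref_cross_price) ** self.cross_price_elasticity
        q *= income_index ** self.income_elasticity
        return float(max(q, 0.0))


def import_demand(
    spec: DemandSpec,
    world_price_local: float,
    domestic_price: float,
    income_index: float,
) -> float:
    """Monthly offal import volume (kg) demanded at local-currency prices.

    Decreasing in the world (import) price, increasing in the domestic price
    of the imperfect fresh substitute, increasing in income.
    """
    if world_price_local <= 0 or domestic_price <= 0:
        raise ValueError("prices must be positive")
    return spec.quantity(world_price_local, cross_price=domestic_price, income_index=income_index)


@dataclass(frozen=True)
class MacroSnapshot:
    """Exchange rates, world price and income indices at one month."""

    month: int
    cfa_per_usd: float
    cedi_per_usd: float
    cfa_per_cedi: float
    world_offal_usd_per_kg: float
    income_index: Mapping[str, float]


@dataclass(frozen=True)
class MacroPath:
    """Exogenous macro trajectories, compounded geometrically.

    The Cedi depreciates against the USD and against the CFA (default 5%/yr
    each); the CFA/Cedi cross is the primitive, and CFA/USD is derived as
    cross x Cedi/USD, so the currency triangle holds identically at every
    month.  Setting ``cedi_cfa_depreciation`` to zero is the fixed-cross
    (Eco-currency) regime: the Cedi still depreciates against the USD, and
    the CFA then depreciates with it.
    """

    cfa_per_usd0: float = 574.7
    cedi_per_usd0: float = 4.59
    cedi_usd_depreciation: float = 0.05
    cedi_cfa_depreciation: float = 0.05
    world_offal_usd0: float = 1.11
    world_price_growth: float = 0.02
    income_growth: Mapping[str, float] = field(
        default_factory=lambda: {"BF": 0.05, "GH": 0.05, "CIV": 0.05}
    )

    def __post_init__(self) -> None:
        if self.cfa_per_usd0 <= 0 or self.cedi_per_usd0 <= 0 or self.world_offal_usd0 <= 0:
            raise ValueError("initial rates and prices must be positive")

    @property
    def cfa_per_cedi0(self) -> float:
        return self.cfa_per_usd0 / self.cedi_per_usd0


def macro_at(path: MacroPath, month: int) -> MacroSnapshot:
    """Exchange rates, world offal price and income indices at a month.

    All paths compound geometrically: value(m) = value(0) * (1+annual)**(m/12).
    """
    if month < 0:
        raise ValueError("month must be non-negative")
    y = month / 12.0
    cedi_per_usd = path.cedi_per_usd0 * (1.0 + path.cedi_usd_depreciation) ** y
    cfa_per_cedi = path.cfa_per_cedi0 / (1.0 + path.cedi_cfa_depreciation) ** y
    cfa_per_usd = cfa_per_cedi * cedi_per_usd
    world = path.world_offal_usd0 * (1.0 + path.world_price_growth) ** y
    income = {
        country: (1.0 + g) ** y for country, g in path.income_growth.items()
    }
    return MacroSnapshot(
        month=month,
        cfa_per_usd=cfa_per_usd,
        cedi_per_usd=cedi_per_usd,
        cfa_per_cedi=cfa_per_cedi,
        world_offal_usd_per_kg=world,
        income_index=income,
    )
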