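"""Monopoly pricing of joint carcass products produced in fixed proportions.

A slaughterhouse with market power turns each animal into high-value cuts
(H), low-value cuts (L) and offals in fixed per-head proportions, and the
marginal cost of the composite unit (the animal plus processing) cannot be
allocated between products.  The monopolist produces where the sum of
non-negative marginal revenues equals marginal cost,

    sum_j max(MR_j(Q), 0) = MC(Q),

and for any product whose marginal revenue is negative at the optimum, only
the quantity at which MR_j = 0 is sold and the remainder is discarded (free
disposal).  With linear inverse demands the aggregate MR curve is piecewise
linear and the optimum has a closed form on each segment; constant-elasticity
demands are handled by a numeric profit search.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "CarcassSpec",
    "LinearInverseDemand",
    "IsoelasticInverseDemand",
    "JointProduct",
    "JointMarketSpec",
    "JointMonopolyResult",
    "solve_joint_monopoly",
    "comparative_statics",
    "carcass_disaggregate",
]


@dataclass(frozen=True)
class CarcassSpec:
    """Per-animal product yields.

    live_weight
        kg per head; 300 for corridor-traded animals, 240 for baseline
        Burkinabe slaughter animals (the productivity scenario raises it).
    carcass_yield
        Carcass weight as a fraction of live weight (default 0.55).
    offal_share
        Offal weight as a fraction of live weight (default 0.104).
    high_value_split
        Share of carcass weight in the high-value cut (remainder low-value).
    """

    live_weight: float = 300.0
    carcass_yield: float = 0.55
    offal_share: float = 0.104
    high_value_split: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.carcass_yield < 1 or not 0 < self.offal_share < 1:
            raise ValueError("yields must lie in (0, 1)")
        if self.carcass_yield + self.offal_share >= 1:
            raise ValueError("carcass yield + offal share must be < 1")
        if not 0 <= self.high_value_split <= 1:
            raise ValueError("high_value_split must be in [0, 1]")
        if self.live_weight <= 0:
            raise ValueError("live weight must be positive")

    @property
    def carcass_weight(self) -> float:
        return self.live_weight * self.carcass_yield

    def yields_per_head(self) -> dict[str, float]:
        """kg of each joint product per animal."""
        carcass = self.carcass_weight
        return {
            "high": carcass * self.high_value_split,
            "low": carcass * (1.0 - self.high_value_split),
            "offal": self.live_weight * self.offal_share,
        }


def carcass_disaggregate(animals: float, spec: CarcassSpec) -> dict[str, float]:
    """kg of high-value cuts, low-value cuts and offals from ``animals`` head."""
    if animals < 0:
        raise ValueError("animals must be non-negative")
    return {k: v * animals for k, v in spec.yields_per_head().items()}


@dataclass(frozen=True)
class LinearInverseDemand:
    """P(q) = intercept - slope * q, truncated at zero."""

    intercept: float
    slope: float

    def __post_init__(self) -> None:
        if self.intercept <= 0 or self.slope <= 0:
            raise ValueError("intercept and slope must be positive")

    def price(self, q: float) -> float:
        return max(self.intercept - self.slope * q, 0.0)

    def revenue(self, q: float) -> float:
        return self.price(q) * q

    def marginal_revenue(self, q: float) -> float:
        return self.intercept - 2.0 * self.slope * q

    def unit_revenue_max_q(self) -> float:
        """Quantity at which marginal revenue crosses zero."""
        return self.intercept / (2.0 * self.slope)


@dataclass(frozen=True)
class IsoelasticInverseDemand:
    """Inverse of Q = scale * (P/ref_price)**elasticity, elasticity < 0."""

    scale: float
    elasticity: float
    ref_price: float = 1.0

    def __post_init__(self) -> None:
        if self.scale <= 0 or self.ref_price <= 0:
            raise ValueError("scale and ref_price must be positive")
        if self.elasticity >= 0:
            raise ValueError("demand elasticity must be negative")

    def price(self, q: float) -> float:
        if q <= 0:
            return np.inf
        return self.ref_price * (q / self.scale) ** (1.0 / self.elasticity)

    def revenue(self, q: float) -> float:
        return 0.0 if q <= 0 else self.price(q) * q

    def marginal_revenue(self, q: float) -> float:
        # d(Pq)/dq = P (1 + 1/elasticity)
        return self.price(q) * (1.0 + 1.0 / self.elasticity)


@dataclass(frozen=True)
class JointProduct:
    name: str
    demand: LinearInverseDemand | IsoelasticInverseDemand
    proportion: float = 1.0  # product units per composite unit (kg per head)

    def __post_init__(self) -> None:
        if self.proportion <= 0:
            raise ValueError("proportion must be positive")


@dataclass(frozen=True)
class JointMarketSpec:
    """Joint-product market: >= 2 products and a composite marginal cost.

    Marginal cost is affine in the composite quantity, MC(Q) = mc_intercept +
    mc_slope * Q, in currency per composite unit (per head when proportions
    are kg/head).
    """

    products: Sequence[JointProduct]
    mc_intercept: float
    mc_slope: float = 0.0

    def __post_init__(self) -> None:
        if len(self.products) < 2:
            raise ValueError("need at least two joint products")
        names = [p.name for p in self.products]
        if len(set(names)) != len(names):
            raise ValueError("product names must be unique")
        if self.mc_intercept < 0 or self.mc_slope < 0:
            raise ValueError("marginal cost must be non-negative and non-decreasing")

    def marginal_cost(self, Q: float) -> float:
        return self.mc_intercept + self.mc_slope * Q

    def all_linear(self) -> bool:
        return all(isinstance(p.demand, LinearInverseDemand) for p in self.products)


@dataclass(frozen=True)
class JointMonopolyResult:
    quantity: float  # composite units (head)
    prices: Mapping[str, float]  # per product unit (currency/kg)
    sold: Mapping[str, float]  # product units
    discarded: Mapping[str, float]  # product units
    profit: float


def _profit(spec: JointMarketSpec, Q: float) -> float:
    """Profit at composite quantity Q with free disposal of glutted products."""
    if Q <= 0:
        return 0.0
    revenue = 0.0
    for p in spec.products:
        produced = p.proportion * Q
        if isinstance(p.demand, LinearInverseDemand):
            sold = min(produced, p.demand.unit_revenue_max_q())
        else:
            sold = produced  # isoelastic MR never crosses zero when |e| > 1
        revenue += p.demand.revenue(sold)
    cost = spec.mc_intercept * Q + 0.5 * spec.mc_slope * Q * Q
    return revenue - cost


def _solve_linear(spec: JointMarketSpec) -> float:
    """Closed-form composite optimum for linear demands (piecewise segments).

    Aggregate MR(Q) = sum_j k_j * max(a_j - 2 b_j k_j Q, 0) is decreasing and
    piecewise linear with breakpoints where each product's MR hits zero;
    equate with the non-decreasing affine MC segment by segment.
    """
    ks = np.array([p.proportion for p in spec.products])
    a = np.array([p.demand.intercept for p in spec.products])
    b = np.array([p.demand.slope for p in spec.products])
    breaks = a / (2.0 * b * ks)  # composite Q at which product j's MR = 0
    if spec.marginal_cost(0.0) >= float(np.sum(ks * a)):
        return 0.0
    grid = np.concatenate(([0.0], np.sort(breaks)))
    for lo, hi in zip(grid[:-1], grid[1:]):
        active = breaks > lo + 1e-15
        num = float(np.sum((ks * a)[active])) - spec.mc_intercept
        den = 2.0 * float(np.sum((b * ks * ks)[active])) + spec.mc_slope
        Q = num / den
        if lo - 1e-12 <= Q <= hi + 1e-12:
            return max(Q, 0.0)
    # beyond the last breakpoint aggregate MR is zero <= MC: optimum at the
    # last crossing (only reachable with MC == 0)
    return float(grid[-1])


def _solve_numeric(spec: JointMarketSpec) -> float:
    """Profit search for non-linear demands: coarse grid plus local refinement."""
    scales = []
    for p in spec.products:
        if isinstance(p.demand, LinearInverseDemand):
            scales.append(p.demand.intercept / p.demand.slope / p.proportion)
        else:
            scales.append(2.0 * p.demand.scale / p.proportion)
    q_max = max(scales)
    # expand the search window while marginal profit is still positive
    for _ in range(40):
        if _profit(spec, q_max) - _profit(spec, q_max * 0.999) <= 0.0:
            break
        q_max *= 2.0
    grid = np.linspace(1e-9, q_max, 2001)
    profits = np.array([_profit(spec, q) for q in grid])
    i = int(np.argmax(profits))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        lambda q: -_profit(spec, q), bounds=(lo, hi), method="bounded"
    )
    Q = float(res.x)
    if _profit(spec, Q) < profits[i]:
        warnings.warn("profit appears non-concave; using grid optimum", RuntimeWarning)
        Q = float(grid[i])
    return max(Q, 0.0)


def solve_joint_monopoly(spec: JointMarketSpec) -> JointMonopolyResult:
    """Optimal composite quantity, per-product prices, sales and disposal.

    At the optimum the sum of non-negative marginal revenues equals marginal
    cost; a product with negative marginal revenue there is sold only up to
    the revenue-maximising quantity and the surplus is discarded.
    """
    Q = _solve_linear(spec) if spec.all_linear() else _solve_numeric(spec)
    prices: dict[str, float] = {}
    sold: dict[str, float] = {}
    discarded: dict[str, float] = {}
    for p in spec.products:
        produced = p.proportion * Q
        if isinstance(p.demand, LinearInverseDemand):
            cap = p.demand.unit_revenue_max_q()
            s = min(produced, cap)
        else:
            s = produced
        sold[p.name] = s
        discarded[p.name] = produced - s
        prices[p.name] = p.demand.price(s) if s > 0 else p.demand.price(0.0)
    return JointMonopolyResult(
        quantity=Q,
        prices=prices,
        sold=sold,
        discarded=discarded,
        profit=_profit(spec, Q),
    )


def comparative_statics(
    spec: JointMarketSpec,
    demand_intercept_shift: Mapping[str, float] | None = None,
    mc_shift: float = 0.0,
) -> dict[str, float]:
    """Signed price responses to demand and/or marginal-cost perturbations.

    Shifting one product's demand outward raises its price and, through the
    joint-production linkage, lowers the other products' prices; a
    simultaneous marginal-cost rise can reverse the fall in the low-value
    price.  Returns the change in each product's price.
    """
    base = solve_joint_monopoly(spec)
    shifts = demand_intercept_shift or {}
    new_products = []
    for p in spec.products:
        if p.name in shifts:
            if not isinstance(p.demand, LinearInverseDemand):
                raise ValueError("intercept shifts require linear demand")
            p = replace(
                p, demand=replace(p.demand, intercept=p.demand.intercept + shifts[p.name])
            )
        new_products.append(p)
    shifted = replace(
        spec, products=tuple(new_products), mc_intercept=spec.mc_intercept + mc_shift
    )
    new = solve_joint_monopoly(shifted)
    return {name: new.prices[name] - base.prices[name] for name in base.prices}
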