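"""Monthly corridor simulation and scenario analysis.

Couples the herd demography of both countries, the inventory-based live
animal market, the joint-product slaughter monopolies, Ghana's offal import
demand and the exogenous macro paths into one deterministic monthly loop,
and runs the policy scenarios: market segmentation for high-value cuts,
improved slaughter-animal weight, lower processing costs, their
combination, a fixed CFA/Cedi cross (Eco-currency regime), and a
Northern-Ghana destination market.

Calibration is front-loaded: demand curves are anchored so that month-0
prices reproduce the observed anchors (offals 1,000 CFA/kg ex-abattoir in
Ouagadougou, landed 1,111 CFA/kg; Ghana butcher-equivalent 1,416 CFA/kg;
imported wholesale from the cost ladder; live animals 300,000 CFA/head),
and quantities are set consistently with each country's herd offtake.
Marginal cost is carried as an index: an animal-cost share that moves with
the live-animal price (and slaughter weight) and a processing share that
scenario multipliers act on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .competitiveness import (
    CostLadder,
    TransportSpec,
    import_wholesale_price,
    landed_export_price,
)
from .herd import HerdState, OfftakePolicy, project_offtake_supply, step_herd
from .joint_pricing import (
    CarcassSpec,
    JointMarketSpec,
    JointProduct,
    LinearInverseDemand,
    solve_joint_monopoly,
)
from .market import (
    DemandSpec,
    InventoryState,
    MacroPath,
    import_demand,
    inventory_price_update,
    macro_at,
)
from .synth import calibrate_herd, default_initial_herd

__all__ = [
    "EngineParams",
    "ScenarioConfig",
    "SCENARIOS",
    "CorridorModel",
    "run_scenario",
    "run_all_scenarios",
    "compare",
    "gap_series",
    "sign_table",
]

PRODUCTS = ("high", "low", "offal")


@dataclass(frozen=True)
class EngineParams:
    """Structural calibration constants shared by every scenario.

    Price anchors are CFA/kg (Ghana anchors are CFA-equivalents converted to
    Cedi at the month-0 cross rate).  Demand elasticities are point
    elasticities at the calibration anchor.  ``animal_cost_share`` is the
    share of slaughter marginal cost that moves with the live-animal price.
    """

    bf_price_anchors: Mapping[str, float] = field(
        default_factory=lambda: {"high": 2000.0, "low": 1200.0, "offal": 1000.0}
    )
    gh_price_anchors_cfa: Mapping[str, float] = field(
        default_factory=lambda: {"high": 2500.0, "low": 1500.0, "offal": 1416.0}
    )
    demand_elasticities: Mapping[str, float] = field(
        default_factory=lambda: {"high": -3.0, "low": -2.5, "offal": -2.0}
    )
    live_price0: float = 300_000.0  # CFA per 300-kg corridor animal
    bf_herd0: float = 9.0e6
    gh_herd0: float = 1.734e6
    herd_growth: float = 0.019
    bf_domestic_share: float = 0.437  # of BF marketed offtake, to BF slaughter
    bf_ghana_share: float = 0.135  # of BF marketed offtake, traded to Ghana
    animal_cost_share: float = 0.8
    civ_price_elasticity: float = -1.0
    inventory_sensitivity: float = 0.25
    flow_sensitivity: float = 0.5  # response to the demand/supply flow ratio
    inventory_coverage: float = 1.0
    inventory_floor: float = 0.05  # fraction of desired inventory
    # income growth shifts meat demand both vertically (willingness to pay)
    # and horizontally (quantity at a given price); see docs/methods.md
    income_price_transmission: float = 0.3
    income_quantity_transmission: float = 0.3
    # Cedi depreciation passes through into nominal Ghanaian meat prices
    # (meat is a tradable; 1 = full pass-through)
    fx_passthrough: float = 1.0
    import_own_elasticity: float = -0.5
    import_cross_elasticity: float = 0.3
    import_income_elasticity: float = 1.0
    import_volume0: float = 34_024_121.0 / 12.0  # kg/month, 2018 offal imports
    world_margin_rate: float = 0.08
    baseline_bf_live_weight: float = 240.0
    gh_live_weight: float = 300.0


@dataclass(frozen=True)
class ScenarioConfig:
    """One scenario: parameter overrides on the calibrated baseline.

    high_value_price_bf
        Price (CFA/kg) obtained for Burkinabe high-value cuts in a premium
        segmented market (baseline 2,000 = the domestic anchor, segmentation
        scenario 4,000).
    segmentation_share
        Share of high-value cut output diverted to the segmented market at
        ``high_value_price_bf``; the segment is perfectly elastic, so the
        diverted revenue enters the monopoly problem as a flat per-head
        offset against marginal cost while the domestic high-value curve
        faces only the remaining output.
    bf_live_weight
        Slaughter live weight in Burkina Faso (productivity scenario raises
        240 -> 300 kg).
    processing_cost_multiplier
        Multiplier on the processing share of Burkinabe marginal cost.
    cedi_cfa_depreciation
        Annual Cedi depreciation against the CFA (0 = fixed cross regime).
    destination
        ``coast`` (ad-valorem corridor transport; importers land at Tema) or
        ``north`` (distance-based refrigerated haulage for Burkinabe offals,
        inland haulage added to third-country imports).
    """

    name: str = "baseline"
    horizon: int = 120
    report_start: int = 36
    high_value_price_bf: float = 2000.0
    segmentation_share: float = 0.0
    bf_live_weight: float = 240.0
    processing_cost_multiplier: float = 1.0
    cedi_cfa_depreciation: float = 0.05
    destination: str = "coast"
    bf_distance_km: float = 150.0  # north scenario only
    inland_haul_km: float = 800.0  # north scenario only

    def __post_init__(self) -> None:
        if self.horizon < self.report_start:
            raise ValueError("horizon must be >= reporting start")
        if self.destination not in ("coast", "north"):
            raise ValueError("destination must be 'coast' or 'north'")
        if self.bf_live_weight <= 0 or self.high_value_price_bf <= 0:
            raise ValueError("overrides must be positive")
        if not 0.0 <= self.segmentation_share < 1.0:
            raise ValueError("segmentation share must lie in [0, 1)")
        if self.processing_cost_multiplier < 0:
            raise ValueError("processing cost multiplier must be non-negative")


SCENARIOS: dict[str, dict] = {
    "baseline": {},
    "segmentation": {"high_value_price_bf": 4000.0, "segmentation_share": 0.2},
    "productivity": {"bf_live_weight": 300.0},
    "cost": {"processing_cost_multiplier": 0.8},
    "combined": {
        "high_value_price_bf": 4000.0,
        "segmentation_share": 0.2,
        "bf_live_weight": 300.0,
        "processing_cost_multiplier": 0.8,
    },
    "no-depreciation": {"cedi_cfa_depreciation": 0.0},
    "north": {"destination": "north"},
}


@dataclass
class _CountryMarket:
    """Calibrated joint-product market for one country's slaughter sector."""

    demands: dict[str, LinearInverseDemand]
    mc0: float
    q0: float
    carcass: CarcassSpec


def _calibrate_market(
    anchors: Mapping[str, float],
    elasticities: Mapping[str, float],
    carcass: CarcassSpec,
    q0: float,
) -> _CountryMarket:
    """Linear demands anchored so the monopoly optimum sits at (q0, anchors).

    Slopes come from the point elasticities (b = P0/(|e| q0_product)); the
    implied marginal cost at the optimum is the sum of per-head marginal
    revenues, sum_j k_j P0_j (1 - 1/|e_j|).
    """
    k = carcass.yields_per_head()
    demands: dict[str, LinearInverseDemand] = {}
    mc0 = 0.0
    for name in PRODUCTS:
        p0 = anchors[name]
        e = abs(elasticities[name])
        if e <= 1.0:
            raise ValueError("monopoly calibration needs |elasticity| > 1")
        q_prod = k[name] * q0
        b = p0 / (e * q_prod)
        a = p0 * (1.0 + 1.0 / e)
        demands[name] = LinearInverseDemand(intercept=a, slope=b)
        mc0 += k[name] * p0 * (1.0 - 1.0 / e)
    return _CountryMarket(demands=demands, mc0=mc0, q0=q0, carcass=carcass)


def _monthly_offtake_head(herd: HerdState, policy: OfftakePolicy) -> float:
    """Season-neutral offtake head count at the reference price."""
    return sum(policy.base_rate[c] * herd.stocks[c] for c in herd.stocks)


class CorridorModel:
    """Deterministic monthly simulation of the corridor under one scenario."""

    def __init__(self, config: ScenarioConfig, params: EngineParams | None = None):
        self.config = config
        self.params = params or EngineParams()
        self._calibrate()

    def _calibrate(self) -> None:
        p = self.params
        cfg = self.config
        self.macro = MacroPath(cedi_cfa_depreciation=cfg.cedi_cfa_depreciation)
        m0 = macro_at(self.macro, 0)
        self.cross0 = m0.cfa_per_cedi

        rates, policy = calibrate_herd(
            p.herd_growth, initial=default_initial_herd(p.bf_herd0, "BF")
        )
        self.herd_rates = rates
        self.herd_policy = policy
        self.bf_herd0 = default_initial_herd(p.bf_herd0, "BF")
        self.gh_herd0 = default_initial_herd(p.gh_herd0, "GH")

        s_bf0 = _monthly_offtake_head(self.bf_herd0, policy)
        s_gh0 = _monthly_offtake_head(self.gh_herd0, policy)
        self.q_bf0 = p.bf_domestic_share * s_bf0
        trade0 = p.bf_ghana_share * s_bf0
        self.civ0 = s_bf0 - self.q_bf0 - trade0
        self.q_gh0 = s_gh0 + trade0

        # demand systems are always calibrated at the baseline carcass;
        # scenario overrides act on yields and costs, not on the curves
        bf_carcass = CarcassSpec(live_weight=p.baseline_bf_live_weight)
        gh_carcass = CarcassSpec(live_weight=p.gh_live_weight)
        self.bf_market = _calibrate_market(
            p.bf_price_anchors, p.demand_elasticities, bf_carcass, self.q_bf0
        )
        gh_anchors_cedi = {
            k: v / self.cross0 for k, v in p.gh_price_anchors_cfa.items()
        }
        self.gh_market = _calibrate_market(
            gh_anchors_cedi, p.demand_elasticities, gh_carcass, self.q_gh0
        )

        # third-country import ladder and import demand calibration
        self.ladder0 = CostLadder(margin_rate=p.world_margin_rate)
        world_usd0 = import_wholesale_price(self.ladder0).wholesale_usd_per_kg
        self.world_wholesale_cedi0 = world_usd0 * m0.cedi_per_usd
        self.import_spec = DemandSpec(
            form="constant_elasticity",
            scale=p.import_volume0,
            own_price_elasticity=p.import_own_elasticity,
            cross_price_elasticity=p.import_cross_elasticity,
            income_elasticity=p.import_income_elasticity,
            ref_own_price=self.world_wholesale_cedi0,
            ref_cross_price=gh_anchors_cedi["offal"],
        )
        self.transport = TransportSpec()

    # -- per-month building blocks -------------------------------------------------

    def _market_spec(
        self, market: _CountryMarket, income: float, carcass: CarcassSpec,
        mc: float, segmented_high_share: float = 0.0, nominal_scale: float = 1.0,
    ) -> JointMarketSpec:
        p = self.params
        k = carcass.yields_per_head()
        products = []
        for name in PRODUCTS:
            d = market.demands[name]
            prop = k[name]
            if name == "high":
                prop *= 1.0 - segmented_high_share
            # nominal_scale rescales the price axis (currency-level effects);
            # income shifts willingness to pay and quantity separately
            products.append(
                JointProduct(
                    name=name,
                    demand=LinearInverseDemand(
                        intercept=nominal_scale
                        * d.intercept
                        * income ** p.income_price_transmission,
                        slope=nominal_scale
                        * d.slope
                        / income ** p.income_quantity_transmission,
                    ),
                    proportion=prop,
                )
            )
        return JointMarketSpec(products=tuple(products), mc_intercept=mc)

    def _bf_landed_cfa(self, ex_cfa: float, cfa_per_usd: float) -> float:
        cfg = self.config
        if cfg.destination == "coast":
            return landed_export_price(ex_cfa, self.transport).landed
        t = self.transport
        usd_per_kg = (
            t.rate_usd_per_ton_km * (1.0 + t.west_africa_uplift) * cfg.bf_distance_km
        ) / 1000.0
        subtotal = ex_cfa + usd_per_kg * cfa_per_usd
        return subtotal * (1.0 + t.informal_share)

    def _world_wholesale_cedi(self, snapshot) -> float:
        ladder = replace(self.ladder0, fob_usd_per_kg=snapshot.world_offal_usd_per_kg)
        usd = import_wholesale_price(ladder).wholesale_usd_per_kg
        if self.config.destination == "north":
            t = self.transport
            usd += (
                t.rate_usd_per_ton_km
                * (1.0 + t.west_africa_uplift)
                * self.config.inland_haul_km
            ) / 1000.0
        return usd * snapshot.cedi_per_usd

    # -- main loop -------------------------------------------------------------------

    def run(self) -> pd.DataFrame:
        """Simulate the configured horizon; one tidy row per month."""
        p = self.params
        cfg = self.config
        bf_scen_carcass = CarcassSpec(live_weight=cfg.bf_live_weight)
        gh_carcass = self.gh_market.carcass
        weight_ratio = cfg.bf_live_weight / p.baseline_bf_live_weight
        seg_share = cfg.segmentation_share
        seg_price = cfg.high_value_price_bf
        k_high_bf = bf_scen_carcass.yields_per_head()["high"]

        bf_state, gh_state = self.bf_herd0, self.gh_herd0
        live_price = p.live_price0
        demand0 = self.q_bf0 + self.q_gh0 + self.civ0
        inventory = p.inventory_coverage * demand0
        demand_history = [demand0] * 3
        rows = []
        for t in range(cfg.horizon):
            snap = macro_at(self.macro, t)
            y_bf = snap.income_index["BF"]
            y_gh = snap.income_index["GH"]
            y_civ = snap.income_index["CIV"]

            bf_state, bf_off = step_herd(
                bf_state, self.herd_rates, self.herd_policy, live_price
            )
            gh_state, gh_off = step_herd(
                gh_state, self.herd_rates, self.herd_policy, live_price
            )
            s_bf = float(project_offtake_supply([bf_off])[0])
            s_gh = float(project_offtake_supply([gh_off])[0])

            live_index = live_price / p.live_price0
            mc_bf = self.bf_market.mc0 * (
                p.animal_cost_share * live_index * weight_ratio
                + (1.0 - p.animal_cost_share) * cfg.processing_cost_multiplier
            )
            mc_gh = self.gh_market.mc0 * (
                p.animal_cost_share * live_index + (1.0 - p.animal_cost_share)
            )
            # revenue from the perfectly elastic premium segment is linear in
            # the composite quantity, so it enters as an offset against MC;
            # the segment price follows the same income transmission as
            # domestic willingness to pay
            seg_price_t = seg_price * y_bf ** p.income_price_transmission
            mc_bf_eff = max(mc_bf - seg_share * k_high_bf * seg_price_t, 0.0)
            bf_solution = solve_joint_monopoly(
                self._market_spec(
                    self.bf_market, y_bf, bf_scen_carcass, mc_bf_eff, seg_share
                )
            )
            gh_nominal = (self.cross0 / snap.cfa_per_cedi) ** p.fx_passthrough
            gh_solution = solve_joint_monopoly(
                self._market_spec(
                    self.gh_market, y_gh, gh_carcass, mc_gh, nominal_scale=gh_nominal
                )
            )
            q_bf, q_gh = bf_solution.quantity, gh_solution.quantity

            civ_demand = self.civ0 * (live_price / p.live_price0) ** (
                p.civ_price_elasticity
            ) * y_civ
            excess_supply = max(s_bf - q_bf, 0.0)
            excess_demand = max(q_gh - s_gh, 0.0)
            traded = min(excess_supply, excess_demand)

            total_demand = q_bf + q_gh + civ_demand
            desired = p.inventory_coverage * float(np.mean(demand_history))
            inventory = max(
                inventory + s_bf + s_gh - total_demand, p.inventory_floor * desired
            )
            demand_history = demand_history[1:] + [total_demand]

            bf_offal_cfa = bf_solution.prices["offal"]
            bf_landed_cfa = self._bf_landed_cfa(bf_offal_cfa, snap.cfa_per_usd)
            bf_landed_cedi = bf_landed_cfa / snap.cfa_per_cedi
            world_cedi = self._world_wholesale_cedi(snap)
            gh_offal_cedi = gh_solution.prices["offal"]
            imports_kg = import_demand(
                self.import_spec, world_cedi, gh_offal_cedi, y_gh
            )

            rows.append(
                {
                    "month": t,
                    "live_price_cfa": live_price,
                    "bf_offal_cfa": bf_offal_cfa,
                    "bf_landed_cfa": bf_landed_cfa,
                    "bf_landed_cedi": bf_landed_cedi,
                    "world_wholesale_cedi": world_cedi,
                    "gh_offal_cedi": gh_offal_cedi,
                    "gap_world_cedi": bf_landed_cedi - world_cedi,
                    "gap_domestic_cedi": bf_landed_cedi - gh_offal_cedi,
                    "bf_high_cfa": bf_solution.prices["high"],
                    "bf_low_cfa": bf_solution.prices["low"],
                    "bf_slaughter_head": q_bf,
                    "gh_slaughter_head": q_gh,
                    "traded_head": traded,
                    "civ_head": civ_demand,
                    "bf_supply_head": s_bf,
                    "gh_supply_head": s_gh,
                    "offal_imports_kg": imports_kg,
                    "bf_herd_head": bf_state.total,
                    "gh_herd_head": gh_state.total,
                    "cfa_per_cedi": snap.cfa_per_cedi,
                    "cedi_per_usd": snap.cedi_per_usd,
                }
            )
            # inventory-coverage term plus a flow-balance term: responding to
            # the current demand/supply ratio damps the otherwise undamped
            # inventory-price oscillator (the flow is the inventory's
            # derivative, so this is derivative feedback)
            live_price = inventory_price_update(
                live_price,
                InventoryState(actual=inventory, desired=desired),
                p.inventory_sensitivity,
            ) * (total_demand / (s_bf + s_gh)) ** p.flow_sensitivity
        return pd.DataFrame(rows)

    def report(self) -> pd.DataFrame:
        """Trajectory restricted to the post-burn-in reporting window."""
        df = self.run()
        return df[df["month"] >= self.config.report_start].reset_index(drop=True)


def run_scenario(
    name: str,
    params: EngineParams | None = None,
    horizon: int = 120,
    report_start: int = 36,
    **overrides,
) -> pd.DataFrame:
    """Run a named preset scenario and return its full monthly trajectory."""
    if name not in SCENARIOS:
        raise KeyError(f"unknown scenario {name!r}; presets: {sorted(SCENARIOS)}")
    kwargs = dict(SCENARIOS[name])
    kwargs.update(overrides)
    config = ScenarioConfig(
        name=name, horizon=horizon, report_start=report_start, **kwargs
    )
    return CorridorModel(config, params).run()


def run_all_scenarios(
    params: EngineParams | None = None, horizon: int = 120, report_start: int = 36
) -> dict[str, pd.DataFrame]:
    return {
        name: run_scenario(name, params, horizon, report_start)
        for name in SCENARIOS
    }


def compare(scenario: pd.DataFrame, baseline: pd.DataFrame) -> pd.DataFrame:
    """Per-month differences (scenario minus baseline) of the outcome series."""
    if len(scenario) != len(baseline):
        raise ValueError("scenario and baseline horizons differ")
    out = pd.DataFrame({"month": scenario["month"]})
    for col in ("gh_offal_cedi", "bf_landed_cedi", "gap_world_cedi"):
        out[f"d_{col}"] = scenario[col].values - baseline[col].values
    return out


def gap_series(
    trajectory: pd.DataFrame, reference: str = "world"
) -> pd.Series:
    """Monthly Burkinabe landed-price gap (Cedi/kg) against a reference series."""
    refs = {"world": "world_wholesale_cedi", "ghana_domestic": "gh_offal_cedi"}
    if reference not in refs:
        raise ValueError(f"reference must be one of {sorted(refs)}")
    return trajectory["bf_landed_cedi"] - trajectory[refs[reference]]


def sign_table(
    results: Mapping[str, pd.DataFrame], report_start: int = 36
) -> dict[str, dict]:
    """Qualitative scenario outcomes over the reporting window.

    Summarises, per scenario, the direction of the Ghana domestic offal
    price, the Burkinabe landed price and the world-price gap relative to
    baseline, plus the baseline's own gap sign and trend.
    """
    def window(df: pd.DataFrame) -> pd.DataFrame:
        return df[df["month"] >= report_start]

    base = window(results["baseline"])
    table: dict[str, dict] = {
        "baseline": {
            "gap_world_positive_all_months": bool((base["gap_world_cedi"] > 0).all()),
            "gap_widens": float(base["gap_world_cedi"].iloc[-1])
            > float(base["gap_world_cedi"].iloc[0]),
            "mean_gap_world_cedi": float(base["gap_world_cedi"].mean()),
        }
    }
    for name, df in results.items():
        if name == "baseline":
            continue
        w = window(df)
        diff = compare(w.reset_index(drop=True), base.reset_index(drop=True))
        table[name] = {
            "d_gh_offal_mean": float(diff["d_gh_offal_cedi"].mean()),
            "d_bf_landed_mean": float(diff["d_bf_landed_cedi"].mean()),
            "d_gap_world_mean": float(diff["d_gap_world_cedi"].mean()),
            "gap_world_positive_all_months": bool((w["gap_world_cedi"] > 0).all()),
            "mean_gap_world_cedi": float(w["gap_world_cedi"].mean()),
        }
    return table
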