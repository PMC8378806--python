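"""Synthetic inputs and packaged reference tables.

Generates every input the pipeline needs without downloads: balanced
synthetic SAMs with named live-cattle and meat accounts (standing in for
the external 2013 Burkina Faso SAM), trade-record tables with the observed
unit-value mixture structure (offals and by-products around 0.4-1.5 USD/kg,
high-value cuts 2-30 USD/kg), and herd parameter sets calibrated so the
simulated national herd reproduces the observed stock trend (7.6 M head in
2005 growing to just over 9 M in 2014, ~1.9%/yr).  Printed reference
tables (live-animal exports, import series, the disaggregated 2018 import
table, and the two cost ladders) are packaged as CSV fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize

from .herd import (
    COHORTS,
    DEFAULT_ELASTICITY,
    DemographicRates,
    HerdState,
    OfftakePolicy,
    monthly_rate,
    simulate_herd,
)
from .sam import SAM

__all__ = [
    "SynthSpec",
    "generate_sam",
    "generate_trade_table",
    "calibrate_herd",
    "load_fixture",
    "default_initial_herd",
    "DEFAULT_BASE_OFFTAKE",
    "DEFAULT_SEASONAL",
]

FIXTURES = ("table1", "table2", "table3", "table4", "table5")

#: Annual base offtake rates before calibration scaling.  Sale frequency
#: rises with age for males; juvenile females are never sold; breeding
#: females are sold sparingly.
DEFAULT_BASE_OFFTAKE: Mapping[str, float] = {
    "female_juvenile": 0.0,
    "female_subadult": 0.02,
    "female_adult": 0.06,
    "male_juvenile": 0.04,
    "male_subadult": 0.15,
    "male_adult": 0.45,
}

#: Smooth 12-month offtake profile (mean one) peaking around the festival/
#: dry-season trading months late in the year and lowest mid-rainy-season.
DEFAULT_SEASONAL: tuple[float, ...] = tuple(
    1.0 + 0.25 * np.cos(2.0 * np.pi * (np.arange(12) - 11.0) / 12.0)
)

#: Default annual demographic rates for a Sahelian cattle herd.
_DEFAULT_ANNUAL = {
    "parturition": 0.62,  # calves per adult female per year
    "mortality": {
        "female_juvenile": 0.14,
        "female_subadult": 0.06,
        "female_adult": 0.05,
        "male_juvenile": 0.14,
        "male_subadult": 0.06,
        "male_adult": 0.05,
    },
}
#: Mean residence times: 12 months as juvenile, 24 as sub-adult.
_MATURATION_MONTHLY = {
    "female_juvenile": 1.0 / 12.0,
    "female_subadult": 1.0 / 24.0,
    "male_juvenile": 1.0 / 12.0,
    "male_subadult": 1.0 / 24.0,
}


def default_demographic_rates() -> DemographicRates:
    return DemographicRates(
        parturition=monthly_rate(_DEFAULT_ANNUAL["parturition"]),
        mortality={
            c: monthly_rate(v) for c, v in _DEFAULT_ANNUAL["mortality"].items()
        },
        maturation=dict(_MATURATION_MONTHLY),
    )


def default_initial_herd(
    total: float = 7.6e6, country: str = "BF", month: int = 0
) -> HerdState:
    """A herd of ``total`` head with a plausible stable cohort structure."""
    shares = {
        "female_juvenile": 0.15,
        "female_subadult": 0.18,
        "female_adult": 0.30,
        "male_juvenile": 0.15,
        "male_subadult": 0.13,
        "male_adult": 0.09,
    }
    return HerdState(country, month, {c: total * s for c, s in shares.items()})


@dataclass(frozen=True)
class SynthSpec:
    """Specification for all synthetic inputs; a fixed seed fixes every output."""

    seed: int = 0
    n_activity: int = 6
    n_commodity: int = 6
    n_factor: int = 2
    n_household: int = 2
    leakage: float = 0.25
    n_trade_rows: int = 60
    mixture_weights: Mapping[str, float] = field(
        default_factory=lambda: {"offal": 0.5, "byproduct": 0.3, "high_value": 0.2}
    )
    unit_value_ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "offal": (0.4, 1.5),
            "byproduct": (0.4, 1.5),
            "high_value": (2.0, 30.0),
        }
    )
    herd_growth_target: float = 0.019

    def __post_init__(self) -> None:
        if min(self.n_activity, self.n_commodity, self.n_factor, self.n_household) < 1:
            raise ValueError("need at least one account of each endogenous class")
        if not 0 < self.leakage < 1:
            raise ValueError("leakage must lie in (0, 1)")
        for lo, hi in self.unit_value_ranges.values():
            if lo <= 0 or hi <= lo:
                raise ValueError("unit-value ranges must be positive and ordered")


def _sam_labels(spec: SynthSpec) -> tuple[list[str], dict[str, str]]:
    activities = ["act_cattle", "act_meat"] + [
        f"act_other{i}" for i in range(1, spec.n_activity - 1)
    ]
    commodities = ["com_cattle", "com_meat"] + [
        f"com_other{i}" for i in range(1, spec.n_commodity - 1)
    ]
    if spec.n_activity < 2 or spec.n_commodity < 2:
        raise ValueError("need at least two activities and commodities "
                         "(cattle and meat accounts are required)")
    factors = [f"fac_{i}" for i in range(1, spec.n_factor + 1)]
    households = [f"hh_{i}" for i in range(1, spec.n_household + 1)]
    exogenous = ["government", "investment", "rest_of_world"]
    labels = activities + commodities + factors + households + exogenous
    classes = (
        {a: "activity" for a in activities}
        | {c: "commodity" for c in commodities}
        | {f: "factor" for f in factors}
        | {h: "household" for h in households}
        | {"government": "government", "investment": "investment",
           "rest_of_world": "rest_of_world"}
    )
    return labels, classes


def generate_sam(spec: SynthSpec) -> SAM:
    """A balanced synthetic SAM with cattle and meat activity/commodity accounts.

    Construction guarantees exact balance: endogenous expenditure shares are
    drawn (Dirichlet) with a fixed leakage to exogenous accounts, endogenous
    totals are closed through the Leontief inverse against drawn exogenous
    injections, and exogenous accounts are balanced by clearing transfers
    through the government account.  The resulting coefficient matrix has
    column sums 1 - leakage < 1, hence spectral radius < 1.
    """
    rng = np.random.default_rng(spec.seed)
    labels, classes = _sam_labels(spec)
    endo = [a for a in labels if classes[a] in
            ("activity", "commodity", "factor", "household")]
    exo = [a for a in labels if a not in endo]
    n = len(endo)

    # Column expenditure shares over endogenous rows.  The meat activity is
    # given a deliberately longer upstream chain (it buys the cattle
    # commodity heavily) than the cattle activity, so a meat-commodity shock
    # propagates through more intermediate rounds.
    A = np.empty((n, n))
    idx = {a: i for i, a in enumerate(endo)}
    for j, a in enumerate(endo):
        alpha = np.full(n, 0.5)
        if a == "act_meat":
            alpha[idx["com_cattle"]] = 250.0  # long upstream chain
            alpha[idx["fac_1"]] = 60.0
        elif a == "act_cattle":
            alpha[idx["fac_1"]] = 250.0  # mostly value added, short chain
        elif a == "com_meat":
            alpha[idx["act_meat"]] = 300.0
        elif a == "com_cattle":
            alpha[idx["act_cattle"]] = 300.0
        elif a.startswith("com_"):
            twin = "act_other" + a.removeprefix("com_other")
            alpha[idx.get(twin, idx["act_meat"])] = 200.0
        elif a.startswith("fac_"):
            alpha[[idx[h] for h in endo if h.startswith("hh_")]] = 100.0
        A[:, j] = rng.dirichlet(alpha) * (1.0 - spec.leakage)

    f = rng.uniform(50.0, 200.0, size=n)  # exogenous injections into endo rows
    y = np.linalg.solve(np.eye(n) - A, f)  # positive account totals
    Z = A * y[None, :]

    table = pd.DataFrame(0.0, index=labels, columns=labels)
    table.loc[endo, endo] = Z
    # endogenous incomes from exogenous columns
    inj_shares = rng.dirichlet(np.ones(len(exo)), size=n)
    for i, a in enumerate(endo):
        table.loc[a, exo] = f[i] * inj_shares[i]
    # endogenous leakage to exogenous rows
    leak_shares = rng.dirichlet(np.ones(len(exo)), size=n)
    for j, a in enumerate(endo):
        table.loc[exo, a] = spec.leakage * y[j] * leak_shares[j]
    # clear exogenous imbalances through the government account
    deficits = {
        e: float(table[e].sum() - table.loc[e].sum()) for e in exo
    }  # spending minus income
    for e in exo:
        if e == "government":
            continue
        d = deficits[e]
        if d > 0:
            table.loc[e, "government"] += d
        else:
            table.loc["government", e] += -d
    return SAM(table, classes, rtol=1e-8)


_ORIGINS = (
    "Belgium", "Brazil", "Germany", "Ireland", "Italy", "Netherlands",
    "Poland", "Spain", "United Kingdom", "USA", "India", "Ukraine",
    "Argentina", "France", "South Africa",
)


def generate_trade_table(spec: SynthSpec) -> pd.DataFrame:
    """A trade-record table with the observed unit-value mixture structure.

    Rows carry HS group labels (offals 0206; cuts 0201/0202), unit values are
    drawn uniformly within the configured range for each latent category, and
    volumes are log-normal.  Value is unit value x volume.
    """
    rng = np.random.default_rng(spec.seed + 1)
    weights = spec.mixture_weights
    cats = list(weights)
    p = np.array([weights[c] for c in cats], dtype=float)
    if p.sum() <= 0:
        raise ValueError("mixture weights must sum to a positive value")
    p = p / p.sum()
    rows = []
    for _ in range(spec.n_trade_rows):
        cat = rng.choice(cats, p=p)
        lo, hi = spec.unit_value_ranges[cat]
        uv = rng.uniform(lo, hi)
        volume = float(np.round(rng.lognormal(mean=12.0, sigma=1.2)))
        if cat == "offal":
            hs = "0206"
        else:
            hs = rng.choice(["0201", "0202"], p=[0.15, 0.85])
        rows.append(
            {
                "origin": rng.choice(_ORIGINS),
                "hs_group": hs,
                "value_usd": float(np.round(uv * volume)),
                "volume_kg": volume,
                "true_category": cat,
            }
        )
    return pd.DataFrame(rows)


def calibrate_herd(
    target_growth: float,
    initial: HerdState | None = None,
    months: int = 108,
    reference_price: float = 300_000.0,
    rates: DemographicRates | None = None,
) -> tuple[DemographicRates, OfftakePolicy]:
    """Scale base offtake rates so the simulated herd grows at ``target_growth``/yr.

    Elasticities and the seasonal profile are untouched: only the base
    offtake rates are scaled by a common factor found by root finding on the
    simulated compound annual growth rate over ``months`` at the reference
    price.  Raises with the feasible range when the target is unreachable.
    """
    initial = initial or default_initial_herd()
    rates = rates or default_demographic_rates()

    def policy_for(scale: float) -> OfftakePolicy:
        base = {
            c: min(1.0, monthly_rate(DEFAULT_BASE_OFFTAKE[c]) * scale)
            for c in COHORTS
        }
        return OfftakePolicy(
            base_rate=base,
            reference_price=reference_price,
            seasonal=DEFAULT_SEASONAL,
        )

    def cagr(scale: float) -> float:
        states, _ = simulate_herd(
            initial, rates, policy_for(scale), reference_price, months
        )
        return (states[-1].total / states[0].total) ** (12.0 / months) - 1.0

    lo, hi = 0.0, 4.0
    g_lo, g_hi = cagr(lo), cagr(hi)
    while g_hi > target_growth and hi < 512.0:
        hi *= 2.0
        g_hi = cagr(hi)
    if not (g_hi <= target_growth <= g_lo):
        raise ValueError(
            f"target growth {target_growth:.4f}/yr outside feasible range "
            f"[{g_hi:.4f}, {g_lo:.4f}] for the default demography"
        )
    scale = optimize.brentq(
        lambda s: cagr(s) - target_growth, lo, hi, xtol=1e-10, rtol=1e-12
    )
    return rates, policy_for(scale)


def load_fixture(name: str) -> pd.DataFrame:
    """Load a packaged reference table by name (``table1`` .. ``table5``).

    ``table3`` is the disaggregated 2018 import table (49 origin-product
    rows); ``table4``/``table5`` hold the cost-ladder inputs and anchors as
    item/value pairs.
    """
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: {FIXTURES}")
    path = resources.files("beefcorridor.fixtures").joinpath(f"{name}.csv")
    with resources.as_file(path) as p:
        df = pd.read_csv(p, dtype={"hs_group": str} if name in ("table2", "table3") else None)
    return df
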