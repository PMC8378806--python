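"""Monthly cohort-based herd demography with price-endogenous, seasonal offtake.

The herd is a set of stocks over six sex x age cohorts (female/male x
juvenile/sub-adult/adult).  Each month a fraction of each cohort dies,
matures into the next age class, or is sold (offtake).  Offtake is
price-responsive through a double-log (constant-elasticity) supply form

    rate(c, P, m) = r0_c * s_m * (P / P0) ** eps_c

clamped to [0, 1], where ``s_m`` is a mean-one seasonal multiplier and
``eps_c`` a cohort-specific supply elasticity.  Adult females carry a
negative elasticity: they are breeding capital, so a higher sale price
induces retention rather than sale.

Stocks are continuous (fractional head): the model integrates rates, not
individuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "COHORTS",
    "DEFAULT_ELASTICITY",
    "HerdState",
    "DemographicRates",
    "OfftakePolicy",
    "offtake_rate",
    "step_herd",
    "simulate_herd",
    "project_offtake_supply",
    "monthly_rate",
    "trajectory_frame",
]

#: Canonical cohort order used throughout the package.
COHORTS: tuple[str, ...] = (
    "female_juvenile",
    "female_subadult",
    "female_adult",
    "male_juvenile",
    "male_subadult",
    "male_adult",
)

#: Cohort offtake elasticities: male animals respond positively to price
#: (0.05 juvenile, 0.10 sub-adult/adult), juvenile females are not sold,
#: sub-adult females respond weakly, and adult females negatively (-0.05).
DEFAULT_ELASTICITY: Mapping[str, float] = {
    "female_juvenile": 0.0,
    "female_subadult": 0.05,
    "female_adult": -0.05,
    "male_juvenile": 0.05,
    "male_subadult": 0.10,
    "male_adult": 0.10,
}

#: juvenile -> subadult -> adult, within sex.
_MATURATION_EDGES: tuple[tuple[str, str], ...] = (
    ("female_juvenile", "female_subadult"),
    ("female_subadult", "female_adult"),
    ("male_juvenile", "male_subadult"),
    ("male_subadult", "male_adult"),
)


def monthly_rate(annual: float) -> float:
    """Convert an annual probability to the equivalent monthly one.

    Uses the survival-consistent convention ``monthly = 1 - (1 - annual)**(1/12)``,
    applied uniformly to all demographic rates in the package.
    """
    if not 0.0 <= annual <= 1.0:
        raise ValueError(f"annual rate must be in [0, 1], got {annual}")
    return 1.0 - (1.0 - annual) ** (1.0 / 12.0)


def _validate_cohort_map(m: Mapping[str, float], what: str) -> dict[str, float]:
    out = {c: float(m.get(c, 0.0)) for c in COHORTS}
    extra = set(m) - set(COHORTS)
    if extra:
        raise ValueError(f"unknown cohorts in {what}: {sorted(extra)}")
    return out


@dataclass(frozen=True)
class HerdState:
    """Stocks of animals (head, continuous) by cohort for one country at month t."""

    country: str
    month: int
    stocks: Mapping[str, float]

    def __post_init__(self) -> None:
        stocks = _validate_cohort_map(self.stocks, "stocks")
        if set(self.stocks) != set(COHORTS):
            raise ValueError(
                f"stocks must cover exactly the cohorts {COHORTS}, got {sorted(self.stocks)}"
            )
        for c, v in stocks.items():
            if v < 0:
                raise ValueError(f"negative stock for {c}: {v}")
        object.__setattr__(self, "stocks", stocks)

    @property
    def total(self) -> float:
        return float(sum(self.stocks.values()))

    def as_array(self) -> np.ndarray:
        return np.array([self.stocks[c] for c in COHORTS], dtype=float)


@dataclass(frozen=True)
class DemographicRates:
    """Monthly demographic transition probabilities.

    parturition
        Calves born per adult female per month (may exceed mortality but is a
        rate in [0, 1]); calves split between sexes by ``female_birth_share``.
    mortality
        Death probability per cohort per month.
    maturation
        Probability of moving to the next age class, defined only for
        juvenile->subadult and subadult->adult within each sex.
    """

    parturition: float
    mortality: Mapping[str, float]
    maturation: Mapping[str, float]
    female_birth_share: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.parturition <= 1.0:
            raise ValueError(f"parturition must be in [0, 1], got {self.parturition}")
        if not 0.0 <= self.female_birth_share <= 1.0:
            raise ValueError("female_birth_share must be in [0, 1]")
        mort = _validate_cohort_map(self.mortality, "mortality")
        for c, v in mort.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"mortality[{c}] must be in [0, 1], got {v}")
        allowed = {src for src, _ in _MATURATION_EDGES}
        bad = set(self.maturation) - allowed
        if bad:
            raise ValueError(
                f"maturation only defined for juvenile/subadult cohorts, got {sorted(bad)}"
            )
        mat = {c: float(self.maturation.get(c, 0.0)) for c in allowed}
        for c, v in mat.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"maturation[{c}] must be in [0, 1], got {v}")
        object.__setattr__(self, "mortality", mort)
        object.__setattr__(self, "maturation", mat)


@dataclass(frozen=True)
class OfftakePolicy:
    """Price-endogenous, seasonal offtake rule.

    base_rate
        Offtake probability per cohort per month at the reference price and
        neutral season.
    reference_price
        Live-animal price P0 (CFA/head) at which the base rate applies.
    elasticity
        Cohort-level price elasticity of offtake (double-log form).
    seasonal
        Twelve positive multipliers; normalised to mean one on construction.
    """

    base_rate: Mapping[str, float]
    reference_price: float = 300_000.0
    elasticity: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_ELASTICITY))
    seasonal: Sequence[float] = (1.0,) * 12

    def __post_init__(self) -> None:
        if self.reference_price <= 0:
            raise ValueError("reference_price must be positive")
        base = _validate_cohort_map(self.base_rate, "base_rate")
        for c, v in base.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"base_rate[{c}] must be in [0, 1], got {v}")
        elas = _validate_cohort_map(self.elasticity, "elasticity")
        season = np.asarray(self.seasonal, dtype=float)
        if season.shape != (12,):
            raise ValueError("seasonal must have exactly 12 entries")
        if np.any(season <= 0):
            raise ValueError("seasonal multipliers must be positive")
        season = season / season.mean()
        object.__setattr__(self, "base_rate", base)
        object.__setattr__(self, "elasticity", elas)
        object.__setattr__(self, "seasonal", tuple(season))

    def scaled(self, factor: float) -> "OfftakePolicy":
        """Return a copy with all base rates multiplied by ``factor`` (clipped to 1)."""
        scaled = {c: min(1.0, r * factor) for c, r in self.base_rate.items()}
        return replace(self, base_rate=scaled)


def offtake_rate(
    policy: OfftakePolicy, cohort: str, price: float, month: int
) -> float:
    """Monthly offtake probability for a cohort at a live-animal price.

    Evaluates ``r0 * s_month * (price / P0) ** eps`` and clamps to [0, 1].
    ``month`` is a zero-based month index; the seasonal multiplier cycles with
    period 12.
    """
    if cohort not in COHORTS:
        raise ValueError(f"unknown cohort {cohort!r}")
    if price <= 0:
        raise ValueError(f"price must be positive, got {price}")
    r0 = policy.base_rate[cohort]
    s = policy.seasonal[month % 12]
    eps = policy.elasticity[cohort]
    rate = r0 * s * (price / policy.reference_price) ** eps
    return float(min(1.0, max(0.0, rate)))


def step_herd(
    state: HerdState,
    rates: DemographicRates,
    policy: OfftakePolicy,
    price: float,
) -> tuple[HerdState, dict[str, float]]:
    """Advance the herd by one month; return the new state and cohort offtakes.

    All outflows (death, sale, maturation) are computed from beginning-of-month
    stocks; if their combined probability would exceed one for a cohort they
    are scaled down proportionally (competing risks).  Births flow into the
    juvenile cohorts.  The accounting identity

        total(t+1) - total(t) = births - deaths - offtake

    holds exactly since maturation is an internal transfer.
    """
    deaths: dict[str, float] = {}
    offtake: dict[str, float] = {}
    mat_out: dict[str, float] = {c: 0.0 for c in COHORTS}
    mat_in: dict[str, float] = {c: 0.0 for c in COHORTS}

    for c in COHORTS:
        stock = state.stocks[c]
        m = rates.mortality[c]
        o = offtake_rate(policy, c, price, state.month)
        g = rates.maturation.get(c, 0.0)
        total_rate = m + o + g
        if total_rate > 1.0:  # competing risks: scale proportionally
            m, o, g = (r / total_rate for r in (m, o, g))
        deaths[c] = m * stock
        offtake[c] = o * stock
        mat_out[c] = g * stock
    for src, dst in _MATURATION_EDGES:
        mat_in[dst] += mat_out[src]

    births = rates.parturition * state.stocks["female_adult"]
    mat_in["female_juvenile"] += births * rates.female_birth_share
    mat_in["male_juvenile"] += births * (1.0 - rates.female_birth_share)

    new_stocks = {
        c: max(
            0.0,
            state.stocks[c] - deaths[c] - offtake[c] - mat_out[c] + mat_in[c],
        )
        for c in COHORTS
    }
    new_state = HerdState(state.country, state.month + 1, new_stocks)
    return new_state, offtake


def simulate_herd(
    initial: HerdState,
    rates: DemographicRates,
    policy: OfftakePolicy,
    prices: float | Sequence[float],
    months: int,
) -> tuple[list[HerdState], list[dict[str, float]]]:
    """Run the herd forward ``months`` steps under a price path.

    ``prices`` may be a scalar (constant price) or a sequence of length
    ``months``.  Returns the state trajectory (length ``months + 1``) and the
    per-month cohort offtakes (length ``months``).
    """
    if np.isscalar(prices):
        price_path = [float(prices)] * months
    else:
        price_path = [float(p) for p in prices]
        if len(price_path) != months:
            raise ValueError("price path length must equal months")
    states = [initial]
    offtakes: list[dict[str, float]] = []
    for t in range(months):
        state, off = step_herd(states[-1], rates, policy, price_path[t])
        states.append(state)
        offtakes.append(off)
    return states, offtakes


def project_offtake_supply(
    offtakes: Iterable[Mapping[str, float]],
    saleable: Iterable[str] = COHORTS,
) -> np.ndarray:
    """Monthly sellable-animal supply (head): sum of saleable cohort offtakes."""
    saleable = tuple(saleable)
    for c in saleable:
        if c not in COHORTS:
            raise ValueError(f"unknown cohort {c!r}")
    return np.array(
        [sum(off[c] for c in saleable) for off in offtakes], dtype=float
    )


def trajectory_frame(
    states: Sequence[HerdState], offtakes: Sequence[Mapping[str, float]]
) -> pd.DataFrame:
    """Tidy monthly trajectory: (country, month, cohort, stock, offtake)."""
    rows = []
    for i, st in enumerate(states):
        off = offtakes[i] if i < len(offtakes) else {c: np.nan for c in COHORTS}
        for c in COHORTS:
            rows.append(
                {
                    "country": st.country,
                    "month": st.month,
                    "cohort": c,
                    "stock": st.stocks[c],
                    "offtake": off.get(c, np.nan),
                }
            )
    return pd.DataFrame(rows)
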