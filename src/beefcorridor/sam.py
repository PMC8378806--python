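"""Social accounting matrix data model, Leontief multipliers and employment
impacts.

A SAM is a square, balanced double-entry ledger: each account's row records
its incomes and its column its expenditures, and row and column totals must
agree.  Activities, commodities, factors and households are endogenous;
government, investment and rest-of-world are exogenous.  Dividing each
endogenous cell by its full column total gives the coefficient matrix A;
the multiplier matrix M = (I - A)^-1 maps exogenous final-demand shocks
(for instance export demand landing on a commodity row) to total endogenous
impacts, which are aggregated into gross production (activity rows), GDP
(factor rows) and household income (household rows).

Employment impacts use the wage-bill method: sector-aggregate employment is
allocated to SAM accounts in proportion to their wage bills (account jobs =
account wage bill / aggregate average wage), giving employment-output
ratios e_j (workers per million CFA of output) that are applied to the
activity-output impacts of a shock.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ACCOUNT_CLASSES",
    "ENDOGENOUS_CLASSES",
    "SAM",
    "MultiplierResult",
    "ImpactResult",
    "EmploymentModel",
    "ShockSpec",
    "a_matrix",
    "multiplier_matrix",
    "apply_shock",
    "employment_impacts",
    "ras_balance",
]

ACCOUNT_CLASSES = (
    "activity",
    "commodity",
    "factor",
    "household",
    "government",
    "investment",
    "rest_of_world",
)
ENDOGENOUS_CLASSES = ("activity", "commodity", "factor", "household")


class SAM:
    """A balanced social accounting matrix with account-class labels.

    Parameters
    ----------
    table
        Square non-negative DataFrame; rows = incomes, columns = expenditures,
        identical labels on both axes.  Units are million CFA throughout.
    classes
        Mapping account label -> class (one of ``ACCOUNT_CLASSES``).
    rtol
        Relative row/column balance tolerance.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        classes: Mapping[str, str],
        rtol: float = 1e-6,
    ) -> None:
        if table.shape[0] != table.shape[1]:
            raise ValueError("SAM must be square")
        if list(table.index) != list(table.columns):
            raise ValueError("SAM row and column labels must match in order")
        if (table.values < -1e-12).any():
            raise ValueError("SAM entries must be non-negative")
        missing = set(table.index) - set(classes)
        if missing:
            raise ValueError(f"accounts without a class: {sorted(missing)}")
        bad = {a: c for a, c in classes.items() if c not in ACCOUNT_CLASSES}
        if bad:
            raise ValueError(f"unknown account classes: {bad}")
        self.table = table.astype(float)
        self.classes = {a: classes[a] for a in table.index}
        self._check_balance(rtol)

    def _check_balance(self, rtol: float) -> None:
        rows = self.table.sum(axis=1)
        cols = self.table.sum(axis=0)
        scale = np.maximum(np.maximum(rows.values, cols.values), 1.0)
        rel = np.abs(rows.values - cols.values) / scale
        if (rel > rtol).any():
            worst = self.table.index[int(np.argmax(rel))]
            raise ValueError(
                f"SAM is unbalanced: account {worst!r} row/col totals differ "
                f"by {rel.max():.2e} (rtol {rtol})"
            )

    @property
    def accounts(self) -> list[str]:
        return list(self.table.index)

    def accounts_of(self, *classes: str) -> list[str]:
        return [a for a in self.accounts if self.classes[a] in classes]

    @property
    def endogenous(self) -> list[str]:
        return self.accounts_of(*ENDOGENOUS_CLASSES)

    @property
    def exogenous(self) -> list[str]:
        return [a for a in self.accounts if self.classes[a] not in ENDOGENOUS_CLASSES]

    def totals(self) -> pd.Series:
        return self.table.sum(axis=1)

    # --- round-trippable CSV I/O (matrix + sidecar class map) ---

    def to_csv(self, matrix_path, classes_path) -> None:
        self.table.to_csv(matrix_path)
        pd.Series(self.classes, name="class").rename_axis("account").to_csv(
            classes_path
        )

    @classmethod
    def from_csv(cls, matrix_path, classes_path, rtol: float = 1e-6) -> "SAM":
        table = pd.read_csv(matrix_path, index_col=0)
        classes = pd.read_csv(classes_path, index_col=0)["class"].to_dict()
        return cls(table, classes, rtol=rtol)


def a_matrix(sam: SAM) -> pd.DataFrame:
    """Coefficient matrix over endogenous accounts.

    Each cell is the SAM entry divided by the account's full column total, so
    endogenous column sums are at most one, with the shortfall the leakage to
    exogenous accounts.
    """
    endo = sam.endogenous
    col_totals = sam.table.sum(axis=0)
    zero = [a for a in endo if col_totals[a] <= 0]
    if zero:
        raise ValueError(f"endogenous accounts with zero column total: {zero}")
    return sam.table.loc[endo, endo].div(col_totals[endo], axis=1)


def spectral_radius(A: pd.DataFrame | np.ndarray) -> float:
    values = A.values if isinstance(A, pd.DataFrame) else np.asarray(A)
    return float(np.max(np.abs(np.linalg.eigvals(values))))


@dataclass(frozen=True)
class MultiplierResult:
    A: pd.DataFrame
    M: pd.DataFrame
    spectral_radius: float


def multiplier_matrix(A: pd.DataFrame) -> MultiplierResult:
    """Leontief inverse M = (I - A)^-1 of the endogenous coefficient matrix."""
    rho = spectral_radius(A)
    if rho >= 1.0:
        raise ValueError(
            f"spectral radius {rho:.3f} >= 1: economy is not productive, "
            "multipliers do not converge"
        )
    n = A.shape[0]
    M_values = np.linalg.inv(np.eye(n) - A.values)
    M = pd.DataFrame(M_values, index=A.index, columns=A.columns)
    residual = np.abs(M_values @ (np.eye(n) - A.values) - np.eye(n)).max()
    if residual > 1e-8:
        raise ArithmeticError(f"Leontief inversion residual {residual:.2e}")
    return MultiplierResult(A=A, M=M, spectral_radius=rho)


@dataclass(frozen=True)
class ShockSpec:
    """Exogenous export-demand shock on endogenous commodity account(s).

    ``values`` maps commodity account -> shock size in million CFA.
    """

    values: Mapping[str, float]
    interpretation: str = "export demand"


@dataclass(frozen=True)
class ImpactResult:
    """Aggregated impacts of a shock: absolute (million CFA) and as a
    fraction of the SAM's baseline account totals (``pct_*`` fields)."""

    by_account: pd.Series
    gross_production: float
    commodity_demand: float
    gdp: float
    household_income: float
    pct_gross_production: float
    pct_gdp: float
    pct_household_income: float


def apply_shock(mult: MultiplierResult, shock: ShockSpec, sam: SAM) -> ImpactResult:
    """Total endogenous impacts of an exogenous demand shock, x = M f.

    Gross production aggregates activity-account impacts (commodity impacts
    are reported separately to avoid double counting), GDP aggregates factor
    rows (value added), household income the household rows; percentages are
    relative to the SAM's baseline account totals.
    """
    endo = sam.endogenous
    commodities = set(sam.accounts_of("commodity"))
    for account in shock.values:
        if account not in commodities:
            raise ValueError(
                f"shock account {account!r} is not an endogenous commodity"
            )
    f = pd.Series(0.0, index=endo)
    for account, value in shock.values.items():
        f[account] = value
    x = mult.M @ f
    baseline = sam.totals()

    def agg(kind: str) -> tuple[float, float]:
        accounts = sam.accounts_of(kind)
        absolute = float(x[accounts].sum())
        base = float(baseline[accounts].sum())
        return absolute, (absolute / base if base > 0 else np.nan)

    gross, pct_gross = agg("activity")
    commodity, _ = agg("commodity")
    gdp, pct_gdp = agg("factor")
    hh, pct_hh = agg("household")
    return ImpactResult(
        by_account=x,
        gross_production=gross,
        commodity_demand=commodity,
        gdp=gdp,
        household_income=hh,
        pct_gross_production=pct_gross,
        pct_gdp=pct_gdp,
        pct_household_income=pct_hh,
    )


@dataclass(frozen=True)
class EmploymentModel:
    """Employment-output ratios derived by the wage-bill method.

    jobs_by_account
        Workers allocated to each activity account.
    ratios
        e_j = workers per million CFA of account output.
    """

    jobs_by_account: pd.Series
    ratios: pd.Series

    @classmethod
    def from_wage_bills(
        cls,
        wage_bills: Mapping[str, float],
        aggregate_of: Mapping[str, str],
        aggregate_employment: Mapping[str, float],
        output: Mapping[str, float],
    ) -> "EmploymentModel":
        """Allocate sector-aggregate employment to accounts via wage bills.

        The aggregate average wage is the aggregate wage bill divided by its
        employees; each account's jobs are its wage bill divided by that
        average wage, so scaling all wages leaves job counts unchanged.
        """
        accounts = list(wage_bills)
        missing = [a for a in accounts if a not in aggregate_of]
        if missing:
            raise ValueError(f"accounts without a sector aggregate: {missing}")
        agg_bills: dict[str, float] = {}
        for a in accounts:
            agg_bills[aggregate_of[a]] = agg_bills.get(aggregate_of[a], 0.0) + wage_bills[a]
        missing_emp = [g for g in agg_bills if g not in aggregate_employment]
        if missing_emp:
            raise ValueError(
                f"aggregates without employment data: {sorted(missing_emp)}"
            )
        jobs = {}
        for a in accounts:
            g = aggregate_of[a]
            if agg_bills[g] <= 0:
                raise ValueError(f"aggregate {g!r} has zero wage bill")
            avg_wage = agg_bills[g] / aggregate_employment[g]
            jobs[a] = wage_bills[a] / avg_wage
        jobs_s = pd.Series(jobs)
        out_s = pd.Series({a: output[a] for a in accounts})
        if (out_s <= 0).any():
            raise ValueError("account outputs must be positive")
        return cls(jobs_by_account=jobs_s, ratios=jobs_s / out_s)


def employment_impacts(
    model: EmploymentModel, mult: MultiplierResult, shock: ShockSpec, sam: SAM
) -> pd.Series:
    """Job impacts of a shock: e_j applied to activity-output impacts.

    Returns jobs per activity account with a ``total`` entry appended;
    non-negative for non-negative shocks.
    """
    activities = sam.accounts_of("activity")
    missing = [a for a in activities if a not in model.ratios.index]
    if missing:
        raise ValueError(f"employment ratios missing for activities: {missing}")
    impact = apply_shock(mult, shock, sam)
    jobs = model.ratios[activities] * impact.by_account[activities]
    jobs["total"] = jobs.sum()
    return jobs


def ras_balance(
    table: pd.DataFrame, max_iter: int = 1000, tol: float = 1e-10
) -> pd.DataFrame:
    """Balance a non-negative square matrix by iterative row/column scaling.

    Utility for user-supplied, slightly unbalanced SAMs: alternately scales
    rows and columns toward the average of the row and column totals until
    they agree.
    """
    Z = table.values.astype(float).copy()
    if (Z < 0).any():
        raise ValueError("RAS requires non-negative entries")
    target = 0.5 * (Z.sum(axis=1) + Z.sum(axis=0))
    for _ in range(max_iter):
        rows = Z.sum(axis=1)
        r = np.divide(target, rows, out=np.ones_like(rows), where=rows > 0)
        Z = Z * r[:, None]
        cols = Z.sum(axis=0)
        s = np.divide(target, cols, out=np.ones_like(cols), where=cols > 0)
        Z = Z * s[None, :]
        if np.abs(Z.sum(axis=1) - Z.sum(axis=0)).max() <= tol * max(target.max(), 1.0):
            break
    return pd.DataFrame(Z, index=table.index, columns=table.columns)
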