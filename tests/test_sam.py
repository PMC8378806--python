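"""SAM model: coefficients, Leontief inverse vs Neumann oracle, shocks,
employment, balance round trips."""

import numpy as np
import pandas as pd
import pytest

from beefcorridor.sam import (
    SAM,
    EmploymentModel,
    ShockSpec,
    a_matrix,
    apply_shock,
    employment_impacts,
    multiplier_matrix,
    ras_balance,
    spectral_radius,
)


def tiny_sam():
    """Two endogenous accounts engineered so A = [[0.2, 0.3], [0.4, 0.1]]."""
    labels = ["act", "com", "government"]
    t = pd.DataFrame(0.0, index=labels, columns=labels)
    # column totals 100 each for act and com
    t.loc["act", "act"] = 20.0
    t.loc["act", "com"] = 30.0
    t.loc["com", "act"] = 40.0
    t.loc["com", "com"] = 10.0
    t.loc["government", "act"] = 40.0
    t.loc["government", "com"] = 60.0
    t.loc["act", "government"] = 50.0
    t.loc["com", "government"] = 50.0
    classes = {"act": "activity", "com": "commodity", "government": "government"}
    return SAM(t, classes)


def neumann(A: np.ndarray, terms: int = 200) -> np.ndarray:
    """Independent oracle: truncated Neumann series sum of A^k."""
    out = np.eye(A.shape[0])
    power = np.eye(A.shape[0])
    for _ in range(terms):
        power = power @ A
        out += power
    return out


class TestSAMModel:
    def test_unbalanced_sam_rejected_naming_account(self):
        labels = ["act", "government"]
        t = pd.DataFrame([[0.0, 10.0], [5.0, 0.0]], index=labels, columns=labels)
        with pytest.raises(ValueError, match="act"):
            SAM(t, {"act": "activity", "government": "government"})

    def test_csv_round_trip_is_lossless(self, tmp_path, synth_sam):
        synth_sam.to_csv(tmp_path / "sam.csv", tmp_path / "classes.csv")
        back = SAM.from_csv(tmp_path / "sam.csv", tmp_path / "classes.csv")
        pd.testing.assert_frame_equal(back.table, synth_sam.table)
        assert back.classes == synth_sam.classes

    def test_ras_balances_a_perturbed_matrix(self, synth_sam):
        rng = np.random.default_rng(0)
        noisy = synth_sam.table * rng.uniform(0.9, 1.1, synth_sam.table.shape)
        balanced = ras_balance(noisy)
        rows, cols = balanced.sum(axis=1), balanced.sum(axis=0)
        assert np.abs(rows - cols).max() < 1e-6 * rows.max()


class TestCoefficientsAndMultipliers:
    def test_hand_example_coefficients(self):
        A = a_matrix(tiny_sam())
        expected = np.array([[0.2, 0.3], [0.4, 0.1]])
        np.testing.assert_allclose(A.values, expected, atol=1e-12)

    def test_hand_example_multiplier_matrix(self):
        """(I - A)^-1 for A = [[.2,.3],[.4,.1]] is [[1.5,.5],[2/3,4/3]]."""
        mult = multiplier_matrix(a_matrix(tiny_sam()))
        expected = np.array([[1.5, 0.5], [2.0 / 3.0, 4.0 / 3.0]])
        np.testing.assert_allclose(mult.M.values, expected, rtol=1e-10)

    def test_zero_coefficients_give_identity(self):
        A = pd.DataFrame(np.zeros((3, 3)), index=list("abc"), columns=list("abc"))
        np.testing.assert_allclose(multiplier_matrix(A).M.values, np.eye(3))

    def test_column_sums_bounded_by_one_with_leakage(self, synth_sam):
        A = a_matrix(synth_sam)
        assert (A.sum(axis=0) <= 1.0 + 1e-12).all()

    def test_multiplier_matches_neumann_oracle_on_random_matrices(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(3, 13))
            raw = rng.uniform(0.0, 1.0, (n, n))
            raw *= rng.uniform(0.3, 0.8) / spectral_radius(raw)
            A = pd.DataFrame(raw, index=range(n), columns=range(n))
            mult = multiplier_matrix(A)
            np.testing.assert_allclose(
                mult.M.values, neumann(raw), rtol=0, atol=1e-6
            )

    def test_m_at_least_identity_elementwise(self, synth_sam):
        mult = multiplier_matrix(a_matrix(synth_sam))
        assert (mult.M.values - np.eye(len(mult.M)) >= -1e-12).all()

    def test_non_productive_economy_rejected(self):
        A = pd.DataFrame(np.full((2, 2), 0.6), index=list("ab"), columns=list("ab"))
        with pytest.raises(ValueError, match="spectral radius"):
            multiplier_matrix(A)

    def test_enlarging_a_coefficient_weakly_increases_all_multipliers(self):
        A = a_matrix(tiny_sam())
        base = multiplier_matrix(A).M.values
        bigger = A.copy()
        bigger.iloc[0, 1] += 0.05
        up = multiplier_matrix(bigger).M.values
        assert (up - base >= -1e-12).all()


class TestShocks:
    def test_zero_shock_zero_impact(self, synth_sam):
        mult = multiplier_matrix(a_matrix(synth_sam))
        impact = apply_shock(mult, ShockSpec({"com_meat": 0.0}), synth_sam)
        assert impact.gross_production == 0.0
        assert impact.gdp == 0.0

    def test_impacts_linear_in_shock(self, synth_sam):
        mult = multiplier_matrix(a_matrix(synth_sam))
        one = apply_shock(mult, ShockSpec({"com_meat": 1000.0}), synth_sam)
        two = apply_shock(mult, ShockSpec({"com_meat": 2000.0}), synth_sam)
        assert two.gross_production == pytest.approx(2 * one.gross_production)
        assert two.household_income == pytest.approx(2 * one.household_income)

    def test_impacts_match_direct_linear_solve(self, synth_sam):
        """M f equals the solution of (I - A) x = f (independent route)."""
        A = a_matrix(synth_sam)
        mult = multiplier_matrix(A)
        shock = ShockSpec({"com_meat": 23_090.0})
        impact = apply_shock(mult, shock, synth_sam)
        f = np.zeros(len(A))
        f[list(A.index).index("com_meat")] = 23_090.0
        x = np.linalg.solve(np.eye(len(A)) - A.values, f)
        np.testing.assert_allclose(impact.by_account.values, x, atol=1e-8 * 23_090)

    def test_shock_on_exogenous_account_rejected(self, synth_sam):
        mult = multiplier_matrix(a_matrix(synth_sam))
        with pytest.raises(ValueError):
            apply_shock(mult, ShockSpec({"government": 100.0}), synth_sam)

    def test_meat_shock_outranks_equal_cattle_shock(self, synth_sam):
        """Meat processing has the longer upstream chain, so an equal-value
        meat-commodity shock generates more gross production."""
        mult = multiplier_matrix(a_matrix(synth_sam))
        meat = apply_shock(mult, ShockSpec({"com_meat": 19_170.0}), synth_sam)
        cattle = apply_shock(mult, ShockSpec({"com_cattle": 19_170.0}), synth_sam)
        assert meat.gross_production > cattle.gross_production


class TestEmployment:
    def toy_model(self):
        """One activity with 10 workers per 100 MCFA of output."""
        return EmploymentModel.from_wage_bills(
            wage_bills={"act": 50.0},
            aggregate_of={"act": "all"},
            aggregate_employment={"all": 10.0},
            output={"act": 100.0},
        )

    def test_wage_bill_allocation_toy_example(self):
        model = self.toy_model()
        assert model.jobs_by_account["act"] == pytest.approx(10.0)
        assert model.ratios["act"] == pytest.approx(0.1)

    def test_direct_only_multiplier_gives_hand_computed_jobs(self):
        """e = 0.1 jobs/MCFA and a direct-only multiplier: 50 MCFA -> 5 jobs."""
        model = self.toy_model()
        assert model.ratios["act"] * 50.0 == pytest.approx(5.0)

    def test_wage_rescaling_leaves_jobs_invariant(self):
        model = self.toy_model()
        scaled = EmploymentModel.from_wage_bills(
            wage_bills={"act": 500.0},
            aggregate_of={"act": "all"},
            aggregate_employment={"all": 10.0},
            output={"act": 100.0},
        )
        pd.testing.assert_series_equal(model.jobs_by_account, scaled.jobs_by_account)

    def test_missing_aggregate_employment_raises_listing_accounts(self):
        with pytest.raises(ValueError, match="industry"):
            EmploymentModel.from_wage_bills(
                {"act": 50.0}, {"act": "industry"}, {"services": 5.0}, {"act": 100.0}
            )

    def test_shock_job_impacts_non_negative_and_scale(self, synth_sam):
        acts = synth_sam.accounts_of("activity")
        model = EmploymentModel.from_wage_bills(
            wage_bills={a: float(synth_sam.table.loc["fac_1", a]) for a in acts},
            aggregate_of={a: "all" for a in acts},
            aggregate_employment={"all": 1.0e4},
            output={a: float(synth_sam.table[a].sum()) for a in acts},
        )
        mult = multiplier_matrix(a_matrix(synth_sam))
        jobs = employment_impacts(
            model, mult, ShockSpec({"com_meat": 1000.0}), synth_sam
        )
        assert (jobs >= -1e-9).all()
        double = employment_impacts(
            model, mult, ShockSpec({"com_meat": 2000.0}), synth_sam
        )
        assert double["total"] == pytest.approx(2 * jobs["total"])
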