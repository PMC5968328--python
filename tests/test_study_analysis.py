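"""Statistical battery: summaries, reliability, stepwise regression, ANOVA,
correlations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sr2kit import (
    SessionTable,
    bonferroni_critical_p,
    correlation_matrix,
    grand_means,
    relative_change,
    rm_anova,
    stepwise_regression,
    summarize,
)
from sr2kit.exceptions import DegenerateDesignError, PairingError, SchemaError
from sr2kit.study_analysis import PREDICTORS


def threshold_table(rows):
    df = pd.DataFrame(
        rows, columns=["listener_id", "run", "test", "separation_deg", "threshold_db"]
    )
    df["n_correct"] = (10 - df.threshold_db).astype(int)
    return SessionTable(thresholds=df)


class TestSummaries:
    def test_constant_cell_mean_and_zero_sd(self):
        session = threshold_table(
            [("A", 1, "SR2", 0, 3.0), ("B", 1, "SR2", 0, 3.0)]
        )
        summary = summarize(session)
        row = summary.iloc[0]
        assert row.mean_threshold == 3.0 and row.sd_threshold == 0.0 and row.n == 2

    def test_mean_srm_averages_per_listener_releases(self):
        session = threshold_table(
            [
                ("A", 1, "SR2", 0, 2.0),
                ("B", 1, "SR2", 0, 4.0),
                ("A", 1, "SR2", 45, -2.0),
                ("B", 1, "SR2", 45, -4.0),
            ]
        )
        summary = summarize(session)
        sep_row = summary[summary.separation_deg == 45].iloc[0]
        assert sep_row.mean_srm == pytest.approx(6.0)  # releases 4 and 8

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_difference_of_means_identity(self, seed):
        """Mean SRM = mean colocated − mean separated on any complete table."""
        rng = np.random.default_rng(seed)
        rows = []
        for lid in "ABCDE":
            for run in (1, 2):
                for sep in (0, 45):
                    rows.append((lid, run, "SR2", sep, float(rng.integers(-10, 11))))
        summary = summarize(threshold_table(rows))
        for run in (1, 2):
            coloc = summary[(summary.separation_deg == 0) & (summary.run == run)]
            sep = summary[(summary.separation_deg == 45) & (summary.run == run)]
            assert sep.mean_srm.iloc[0] == pytest.approx(
                coloc.mean_threshold.iloc[0] - sep.mean_threshold.iloc[0]
            )

    def test_missing_colocated_partner_is_pairing_error(self):
        session = threshold_table([("A", 1, "SR2", 45, -2.0)])
        with pytest.raises(PairingError):
            summarize(session)

    def test_grand_mean_is_unweighted_across_runs(self):
        rows = []
        for run, (coloc, sep) in enumerate(
            [(2.0, -4.0), (1.0, -5.0), (3.0, -3.0)], start=1
        ):
            rows += [("A", run, "SR2", 0, coloc), ("A", run, "SR2", 45, sep)]
        summary = summarize(threshold_table(rows))
        gm = grand_means(summary, "SR2", 0)
        assert gm["mean_threshold"] == pytest.approx(2.0)
        gm45 = grand_means(summary, "SR2", 45)
        assert gm45["mean_threshold"] == pytest.approx(-4.0)
        assert gm45["mean_srm"] == pytest.approx(6.0)


class TestRelativeChange:
    def test_constant_listener_has_zero_change(self):
        mat = pd.DataFrame({1: [2.0], 2: [2.0], 3: [2.0]}, index=["A"])
        assert relative_change(mat).group_mean == 0.0

    def test_direct_arithmetic(self):
        mat = pd.DataFrame({1: [2.0], 2: [0.0], 3: [1.0]}, index=["A"])
        assert relative_change(mat).per_listener["A"] == pytest.approx(1.5)

    def test_invariant_to_global_negation(self):
        rng = np.random.default_rng(0)
        mat = pd.DataFrame(rng.integers(-8, 8, (6, 4)).astype(float))
        a = relative_change(mat)
        b = relative_change(-mat)
        assert a.group_mean == pytest.approx(b.group_mean)

    def test_listeners_with_missing_runs_excluded(self):
        mat = pd.DataFrame({1: [2.0, 1.0], 2: [0.0, np.nan]}, index=["A", "B"])
        report = relative_change(mat)
        assert report.n_listeners == 1 and report.n_excluded == 1

    def test_single_run_rejected(self):
        with pytest.raises(SchemaError):
            relative_change(pd.DataFrame({1: [2.0]}, index=["A"]))


class TestStepwiseRegression:
    def _covariates(self, rng, n):
        return pd.DataFrame(rng.standard_normal((n, 3)), columns=PREDICTORS)

    def test_perfect_predictor_selected_with_unit_coefficient(self):
        rng = np.random.default_rng(1)
        cov = self._covariates(rng, 60)
        y = cov["age"].to_numpy()
        report = stepwise_regression(y, cov)
        assert report.selected == ("age",)
        c = report.coefficient("age")
        assert c.std_coefficient == pytest.approx(1.0)
        assert report.adjusted_r2 == pytest.approx(1.0)

    def test_null_selection_rate_matches_entry_threshold(self):
        """Under the null, any predictor enters at roughly the familywise
        entry rate 1 − (1 − .05)^3 ≈ 0.14."""
        hits = 0
        n_rep = 150
        for rep in range(n_rep):
            rng = np.random.default_rng(10_000 + rep)
            cov = self._covariates(rng, 200)
            report = stepwise_regression(rng.standard_normal(200), cov)
            hits += bool(report.selected)
        rate = hits / n_rep
        expected = 1 - 0.95**3
        # 3-sigma binomial band around the familywise entry rate
        assert abs(rate - expected) < 3 * np.sqrt(expected * (1 - expected) / n_rep)

    def test_single_effect_recovery(self):
        from sr2kit import CohortModel, Condition, sample_cohort
        from sr2kit.listener_sim import covariate_frame

        model = CohortModel.single_effect(500, Condition("SR2", 45), "pta_standard", 0.69)
        cohort = sample_cohort(model, 21)
        y = [p.true_thresholds[Condition("SR2", 45)] for p in cohort]
        report = stepwise_regression(pd.Series(y), covariate_frame(cohort)[PREDICTORS])
        c = report.coefficient("pta_standard")
        assert c.selected
        assert c.std_coefficient == pytest.approx(0.69, abs=0.08)

    def test_standardized_coefficients_invariant_to_rescaling(self):
        rng = np.random.default_rng(3)
        cov = self._covariates(rng, 120)
        y = 0.6 * cov["pta_standard"] + rng.standard_normal(120)
        a = stepwise_regression(y, cov)
        cov2 = cov.copy()
        cov2["pta_standard"] = cov2["pta_standard"] * 37.0 + 5.0
        b = stepwise_regression(y * 3.0 + 1.0, cov2)
        for name in PREDICTORS:
            assert a.coefficient(name).std_coefficient == pytest.approx(
                b.coefficient(name).std_coefficient
            )

    def test_constant_covariate_is_degenerate(self):
        rng = np.random.default_rng(4)
        cov = self._covariates(rng, 50)
        cov["age"] = 7.0
        with pytest.raises(DegenerateDesignError):
            stepwise_regression(rng.standard_normal(50), cov)

    def test_adjusted_r2_never_exceeds_r2(self):
        rng = np.random.default_rng(5)
        cov = self._covariates(rng, 40)
        y = 0.5 * cov["age"] + rng.standard_normal(40)
        report = stepwise_regression(y, cov)
        assert report.adjusted_r2 <= report.r2 + 1e-12


def _oneway_oracle(data: np.ndarray):
    """Hand-coded one-way repeated-measures ANOVA + GG epsilon.

    data: subjects × conditions.  Returns (F, df1, df2, epsilon).
    """
    n, k = data.shape
    grand = data.mean()
    ss_cond = n * ((data.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((data.mean(axis=1) - grand) ** 2).sum()
    ss_tot = ((data - grand) ** 2).sum()
    ss_err = ss_tot - ss_cond - ss_subj
    df1, df2 = k - 1, (k - 1) * (n - 1)
    F = (ss_cond / df1) / (ss_err / df2)
    # GG epsilon from the double-centered covariance matrix
    S = np.cov(data, rowvar=False, ddof=1)
    Sc = S - S.mean(axis=0) - S.mean(axis=1)[:, None] + S.mean()
    eps = np.trace(Sc) ** 2 / ((k - 1) * (Sc**2).sum())
    return F, df1, df2, eps


class TestRmAnova:
    def _long(self, data, tests=None):
        n, k = data.shape
        rows = []
        for i in range(n):
            for j in range(k):
                rows.append(dict(listener_id=f"S{i}", run=j + 1, y=data[i, j]))
        return pd.DataFrame(rows)

    def test_matches_hand_computed_oneway_oracle(self):
        rng = np.random.default_rng(6)
        data = rng.normal(size=(10, 4)) + np.array([0.0, 0.5, 1.0, 1.5])
        F, df1, df2, eps = _oneway_oracle(data)
        report = rm_anova(self._long(data), "y", "run", "listener_id")
        e = report.effects[0]
        assert e.f_statistic == pytest.approx(F, abs=1e-3)
        assert (e.df1, e.df2) == (df1, df2)
        assert e.epsilon == pytest.approx(eps, abs=1e-3)

    def test_partial_eta_squared_matches_ss_ratio(self):
        rng = np.random.default_rng(7)
        data = rng.normal(size=(8, 3)) + np.array([0.0, 1.0, 2.0])
        n, k = data.shape
        grand = data.mean()
        ss_cond = n * ((data.mean(axis=0) - grand) ** 2).sum()
        ss_subj = k * ((data.mean(axis=1) - grand) ** 2).sum()
        ss_err = ((data - grand) ** 2).sum() - ss_cond - ss_subj
        report = rm_anova(self._long(data), "y", "run", "listener_id")
        assert report.effects[0].partial_eta_sq == pytest.approx(
            ss_cond / (ss_cond + ss_err), abs=1e-9
        )

    def test_two_level_factor_has_epsilon_exactly_one(self):
        rng = np.random.default_rng(8)
        data = rng.normal(size=(12, 2))
        report = rm_anova(self._long(data), "y", "run", "listener_id")
        assert report.effects[0].epsilon == 1.0

    def test_constructed_null_and_effect(self):
        """Zero between-run differences → run F ≈ 0; a large separation
        effect → separation p < .001."""
        rng = np.random.default_rng(9)
        rows = []
        run_dev = {1: 0.0, 2: 0.5, 3: -0.5}
        for i in range(12):
            base = rng.normal()
            sign = 1 if i % 2 == 0 else -1  # run deviations cancel across subjects
            for run in (1, 2, 3):
                for sep in (0, 45):
                    rows.append(
                        dict(
                            listener_id=f"S{i}",
                            run=run,
                            separation_deg=sep,
                            y=base + (-6.0 if sep else 0.0) + sign * run_dev[run],
                        )
                    )
        df = pd.DataFrame(rows)
        report = rm_anova(df, "y", ["run", "separation_deg"], "listener_id")
        assert report.effect("run").f_statistic == pytest.approx(0.0, abs=1e-6)
        assert report.effect("separation_deg").p_gg < 0.001

    def test_unbalanced_design_rejected(self):
        df = self._long(np.zeros((5, 3)))
        with pytest.raises(DegenerateDesignError):
            rm_anova(df.iloc[:-1], "y", "run", "listener_id")


class TestCorrelations:
    def test_bonferroni_critical_p_for_39_comparisons(self):
        assert round(bonferroni_critical_p(0.05, 39), 4) == 0.0013

    def test_self_correlation_is_one_and_matrix_symmetric(self):
        rng = np.random.default_rng(10)
        df = pd.DataFrame(rng.standard_normal((30, 3)), columns=list("abc"))
        report = correlation_matrix(df)
        assert np.allclose(np.diag(report.r), 1.0)
        assert np.allclose(report.r, report.r.T)
        assert report.n_correlations == 3

    def test_independent_samples_have_small_correlation(self):
        rng = np.random.default_rng(11)
        df = pd.DataFrame(rng.standard_normal((1000, 2)), columns=["x", "y"])
        report = correlation_matrix(df)
        assert abs(report.r.loc["x", "y"]) < 0.1

    def test_constant_variable_flagged_not_nan_propagated(self):
        rng = np.random.default_rng(12)
        df = pd.DataFrame(
            {"x": rng.standard_normal(20), "y": rng.standard_normal(20), "c": 5.0}
        )
        report = correlation_matrix(df)
        assert report.undefined == ("c",)
        assert np.isnan(report.r.loc["x", "c"])
        assert np.isfinite(report.r.loc["x", "y"])
        assert not report.significant.loc["x", "c"]


def test_summary_identity_on_simulated_study(mini_session):
    summary = summarize(mini_session)
    for run in sorted(mini_session.thresholds.run.unique()):
        coloc = summary[(summary.separation_deg == 0) & (summary.run == run)]
        sep = summary[(summary.separation_deg == 45) & (summary.run == run)]
        assert sep.mean_srm.iloc[0] == pytest.approx(
            coloc.mean_threshold.iloc[0] - sep.mean_threshold.iloc[0]
        )
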