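import numpy as np
import pandas as pd
import pytest

import musclesect as ms
from musclesect.stats import (
    PERIODS,
    build_differences,
    cohort_from_measurements,
    correlate_periods,
    difference_correlation_table,
    filter_key,
    fit_covariate_model,
    icc_two_rater,
    paired_ttest,
    regression_table,
    serial_change_table,
)

from _oracles import (
    icc21_closed_form,
    ols_closed_form,
    paired_t_closed_form,
    pearson_closed_form,
)


def _mini_cohort(values_by_tp, metric="volume", muscle="Ssc", section="Y"):
    """Cohort table with one metric key; values_by_tp: {tp: {subject: v}}."""
    rows = []
    for tp, d in values_by_tp.items():
        for s, v in d.items():
            rows.append({"subject_id": s, "timepoint": tp, "rater_id": None,
                         "muscle": muscle, "section": section,
                         "metric": metric, "value": v})
    return pd.DataFrame(rows)


class TestPairedTTest:
    def test_identical_vectors(self):
        res = paired_ttest([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert res.t == 0.0 and res.p == 1.0 and res.degenerate

    def test_constant_nonzero_difference_degenerate(self):
        res = paired_ttest([1, 2, 3, 4], [2, 3, 4, 5])
        assert res.degenerate
        assert np.isinf(res.t) and res.t < 0
        assert res.p == 0.0

    def test_matches_closed_form_on_random_pairs(self):
        rng = np.random.default_rng(2024)
        a = rng.normal(10, 3, 100)
        b = rng.normal(9, 3, 100)
        res = paired_ttest(a, b)
        t, p = paired_t_closed_form(a, b)
        assert res.t == pytest.approx(t, abs=1e-10)
        assert res.p == pytest.approx(p, abs=1e-10)
        assert np.sign(res.t) == np.sign(np.mean(a - b))

    def test_incomplete_pairs_dropped(self):
        a = [1.0, np.nan, 3.0, 4.0, 5.0]
        b = [2.0, 1.0, np.nan, 3.0, 6.0]
        res = paired_ttest(a, b)
        assert res.n == 3

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            paired_ttest([1.0, 2.0], [2.0, 1.0])


class TestDifferences:
    def test_sign_convention_drop_is_negative(self):
        cohort = _mini_cohort({"pre": {"A": 100.0}, "1mo": {"A": 90.0},
                               "12mo": {"A": 98.0}})
        d = build_differences(cohort).set_index("period")["value"]
        assert d["Dif.pre.1mo"] == -10.0
        assert d["Dif.1.12mo"] == 8.0
        assert d["Dif.pre.12mo"] == -2.0

    def test_additivity_exact(self):
        rng = np.random.default_rng(5)
        cohort = _mini_cohort({
            tp: {f"S{i}": float(v) for i, v in
                 enumerate(rng.normal(100, 17, 30))}
            for tp in ("pre", "1mo", "6mo", "12mo")})
        d = build_differences(cohort)
        wide = d.pivot_table(index="subject_id", columns="period",
                             values="value")
        resid = wide["Dif.pre.12mo"] - (wide["Dif.pre.1mo"]
                                        + wide["Dif.1.12mo"])
        assert (resid == 0.0).all()

    def test_missing_timepoint_still_produces_other_periods(self):
        cohort = _mini_cohort({"pre": {"A": 100.0}, "1mo": {"A": 90.0},
                               "12mo": {"A": 95.0}})
        # no 6mo record at all
        periods = set(build_differences(cohort)["period"])
        assert periods == set(PERIODS)

    def test_subject_missing_one_endpoint_omitted_for_that_period(self):
        cohort = _mini_cohort({"pre": {"A": 100.0, "B": 80.0},
                               "1mo": {"A": 90.0},
                               "12mo": {"A": 95.0, "B": 85.0}})
        d = build_differences(cohort)
        b_periods = set(d.loc[d.subject_id == "B", "period"])
        assert b_periods == {"Dif.pre.12mo"}

    def test_rater_measurements_averaged(self):
        rows = []
        for rater, v in (("R1", 100.0), ("R2", 104.0)):
            rows.append({"subject_id": "A", "timepoint": "pre",
                         "rater_id": rater, "muscle": "Ssc", "section": "Y",
                         "metric": "volume", "value": v})
        rows.append({"subject_id": "A", "timepoint": "1mo", "rater_id": "R1",
                     "muscle": "Ssc", "section": "Y", "metric": "volume",
                     "value": 92.0})
        d = build_differences(pd.DataFrame(rows))
        assert d.loc[d.period == "Dif.pre.1mo", "value"].iloc[0] == \
            pytest.approx(92.0 - 102.0)


class TestCorrelation:
    def test_perfect_anticorrelation(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 5, 20)
        cohort_rows = []
        for i, xi in enumerate(x):
            for period, v in (("Dif.pre.1mo", xi), ("Dif.1.12mo", -xi)):
                cohort_rows.append({"subject_id": f"S{i}", "muscle": "Ssc",
                                    "section": "Y", "metric": "volume",
                                    "period": period, "value": v})
        res = correlate_periods(pd.DataFrame(cohort_rows),
                                "Dif.pre.1mo", "Dif.1.12mo")
        assert res.r == pytest.approx(-1.0, abs=1e-12)

    def test_matches_closed_form(self):
        rng = np.random.default_rng(77)
        x = rng.normal(0, 1, 50)
        y = 0.4 * x + rng.normal(0, 1, 50)
        rows = []
        for i in range(50):
            rows.append({"subject_id": f"S{i}", "muscle": "Ssc",
                         "section": "Y", "metric": "volume",
                         "period": "Dif.pre.1mo", "value": x[i]})
            rows.append({"subject_id": f"S{i}", "muscle": "Ssc",
                         "section": "Y", "metric": "volume",
                         "period": "Dif.1.12mo", "value": y[i]})
        res = correlate_periods(pd.DataFrame(rows), "Dif.pre.1mo",
                                "Dif.1.12mo")
        r, p = pearson_closed_form(x, y)
        assert res.r == pytest.approx(r, abs=1e-10)
        assert res.p == pytest.approx(p, abs=1e-10)

    def test_constant_vector_flagged(self):
        rows = []
        for i in range(5):
            rows.append({"subject_id": f"S{i}", "muscle": "Ssc",
                         "section": "Y", "metric": "volume",
                         "period": "Dif.pre.1mo", "value": 1.0})
            rows.append({"subject_id": f"S{i}", "muscle": "Ssc",
                         "section": "Y", "metric": "volume",
                         "period": "Dif.1.12mo", "value": float(i)})
        res = correlate_periods(pd.DataFrame(rows), "Dif.pre.1mo",
                                "Dif.1.12mo")
        assert res.degenerate and np.isnan(res.r)

    def test_mixed_keys_rejected(self):
        rows = [{"subject_id": "S0", "muscle": m, "section": "Y",
                 "metric": "volume", "period": "Dif.pre.1mo", "value": 1.0}
                for m in ("Ssc", "Isp+TM")]
        with pytest.raises(ValueError, match="keys"):
            correlate_periods(pd.DataFrame(rows), "Dif.pre.1mo", "Dif.1.12mo")


def _diffs_from_outcome(y, subjects):
    return pd.DataFrame([
        {"subject_id": s, "muscle": "Ssc", "section": "Y",
         "metric": "volume", "period": "Dif.pre.1mo", "value": float(v)}
        for s, v in zip(subjects, y)])


OUTCOME = {"metric": "volume", "muscle": "Ssc", "section": "Y",
           "period": "Dif.pre.1mo"}


class TestCovariateRegression:
    def test_pure_age_effect_recovered_exactly(self):
        from musclesect.phantom import simulate_covariates

        cov = simulate_covariates(80, np.random.default_rng(3))
        coded = ms.io.encode_covariates(cov)
        y = 2.0 * coded["age"].to_numpy()
        res = fit_covariate_model(_diffs_from_outcome(y, cov.index), cov,
                                  OUTCOME)
        assert res.params["age"] == pytest.approx(2.0, abs=1e-8)
        assert res.params.drop("age").abs().max() < 1e-8
        assert not res.rank_deficient

    def test_matches_ols_closed_form(self):
        from musclesect.phantom import simulate_covariates

        rng = np.random.default_rng(9)
        cov = simulate_covariates(60, rng)
        coded = ms.io.encode_covariates(cov)
        y = coded.to_numpy() @ rng.normal(0, 1, coded.shape[1]) \
            + rng.normal(0, 1, 60)
        res = fit_covariate_model(_diffs_from_outcome(y, cov.index), cov,
                                  OUTCOME)
        x = np.column_stack([np.ones(60), coded.to_numpy()])
        beta, _, pvals = ols_closed_form(x, y)
        np.testing.assert_allclose(res.params.to_numpy(), beta[1:],
                                   atol=1e-10)
        np.testing.assert_allclose(res.pvalues.to_numpy(), pvals[1:],
                                   atol=1e-10)

    def test_recovery_within_three_se(self):
        traj = ms.TrajectorySpec(
            covariate_effects={"age": 2.0, "sex": -5.0, "rom_flexion": 0.5},
            drop_mean=0.10, drop_sd=0.05, obs_noise_frac=0.02)
        cohort, cov, _ = ms.simulate_cohort(500, traj, seed=17)
        diffs = build_differences(cohort)
        res = fit_covariate_model(diffs, cov, OUTCOME)
        fit_se = _ols_se(cov, diffs)
        truth = {c: traj.covariate_effects.get(c, 0.0)
                 for c in ms.COVARIATE_COLUMNS}
        for c in ms.COVARIATE_COLUMNS:
            assert abs(res.params[c] - truth[c]) < 3 * fit_se[c], c

    def test_rank_deficiency_flagged(self):
        from musclesect.phantom import simulate_covariates

        cov = simulate_covariates(5, np.random.default_rng(4))
        y = np.arange(5, dtype=float)
        res = fit_covariate_model(_diffs_from_outcome(y, cov.index), cov,
                                  OUTCOME)
        assert res.rank_deficient
        assert len(res.aliased) > 0


def _ols_se(cov, diffs):
    """Standard errors from an independent statsmodels fit (for the 3-SE
    recovery band)."""
    import statsmodels.api as sm

    sel = diffs
    for col, v in OUTCOME.items():
        key = {"metric": "metric", "muscle": "muscle", "section": "section",
               "period": "period"}[col]
        sel = sel[sel[key] == v]
    y = sel.set_index("subject_id")["value"]
    x = ms.io.encode_covariates(cov.loc[y.index])
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    return fit.bse


class TestICC:
    def test_duplicate_rater_gives_unity(self):
        rng = np.random.default_rng(0)
        v = rng.normal(50, 3, 20)
        res = icc_two_rater(np.column_stack([v, v]))
        assert res.icc == pytest.approx(1.0, abs=1e-9)

    def test_matches_mean_squares_oracle_and_pingouin(self):
        rng = np.random.default_rng(8)
        mat = rng.normal(50, 3, size=(30, 2)) \
            + rng.normal(0, 1, size=(30, 2))
        res = icc_two_rater(mat)
        assert res.icc == pytest.approx(icc21_closed_form(mat), abs=1e-12)
        import pingouin as pg

        long = pd.DataFrame({
            "s": np.repeat(np.arange(30), 2),
            "r": np.tile(np.arange(2), 30),
            "v": mat.ravel()})
        tab = pg.intraclass_corr(long, targets="s", raters="r",
                                 ratings="v").set_index("Type")
        key = "ICC(A,1)" if "ICC(A,1)" in tab.index else "ICC2"
        assert res.icc == pytest.approx(float(tab.loc[key, "ICC"]), abs=1e-10)

    def test_variance_component_recovery(self):
        rng = np.random.default_rng(12)
        truth = rng.normal(0, 3.0, 1000)
        mat = ms.simulate_raters(truth, sigma_error=1.0, k=2, seed=13)
        res = icc_two_rater(mat)
        assert 0.88 <= res.icc <= 0.92
        assert res.var_subject == pytest.approx(9.0, rel=0.15)
        assert res.var_error == pytest.approx(1.0, rel=0.15)
        assert res.ci95[0] <= res.icc <= res.ci95[1]

    def test_pure_noise_near_zero(self):
        mat = ms.simulate_raters(np.zeros(1000), sigma_error=1.0, k=2,
                                 seed=14)
        res = icc_two_rater(mat)
        assert abs(res.icc) <= 0.05

    def test_incomplete_matrix_rejected(self):
        mat = np.ones((10, 2))
        mat[3, 1] = np.nan
        with pytest.raises(ValueError, match="complete"):
            icc_two_rater(mat)


class TestSerialChangeTable:
    def test_shape_and_columns(self):
        cohort, _, _ = ms.simulate_cohort(24, seed=2)
        table = serial_change_table(cohort)
        # 2 muscles x 3 sections x 2 metrics + ratio keys 3 sections x 2
        assert len(table) == 18
        for col in ("mean_pre", "sd_pre", "mean_1mo", "p_a", "p_b", "p_c"):
            assert col in table.columns

    def test_drop_and_recover_pattern_detected(self):
        traj = ms.TrajectorySpec(drop_mean=0.15, drop_sd=0.03,
                                 obs_noise_frac=0.02)
        cohort, _, _ = ms.simulate_cohort(24, traj, seed=6)
        table = serial_change_table(cohort).set_index(
            ["muscle", "section", "metric"])
        row = table.loc[("Ssc", "Y+5", "volume")]
        assert row["p_a"] < 0.05          # pre vs 1mo drop
        assert row["mean_1mo"] < row["mean_pre"]
        assert row["mean_12mo"] > row["mean_1mo"]   # recovery

    def test_identical_subjects_degenerate_but_no_crash(self):
        cohort = _mini_cohort({tp: {f"S{i}": 50.0 for i in range(6)}
                               for tp in ("pre", "1mo", "6mo", "12mo")})
        table = serial_change_table(cohort)
        assert table["p_a_degenerate"].iloc[0]
        assert table["p_a"].iloc[0] == 1.0

    def test_difference_correlation_table_shape(self):
        cohort, _, _ = ms.simulate_cohort(24, seed=3)
        diffs = build_differences(cohort)
        tab = difference_correlation_table(diffs)
        assert len(tab) == 18
        assert {"r_a", "p_a", "r_b", "p_b"} <= set(tab.columns)

    def test_regression_table_covers_all_covariates(self):
        cohort, cov, _ = ms.simulate_cohort(40, seed=4)
        diffs = build_differences(cohort)
        tab = regression_table(diffs, cov, "volume", "Ssc")
        assert list(tab["covariate"]) == list(ms.COVARIATE_COLUMNS)
        assert "RC[Dif.pre.1mo][Y]" in tab.columns


class TestCohortAssembly:
    def test_round_trip_measurement_to_cohort(self, coarse_exam):
        meas = ms.measure_exam(coarse_exam.volume, coarse_exam.labels,
                               coarse_exam.landmarks, subject_id="S0",
                               timepoint="pre")
        ratios = ms.compute_ratios(meas)
        table = cohort_from_measurements(ms.measurements_to_frame(meas),
                                         ms.ratios_to_frame(ratios))
        assert len(table) == 12 + 6
        assert set(table["metric"]) == {"volume", "mean_hu", "vr", "ct_dr"}

    def test_duplicate_rows_rejected(self, coarse_exam):
        meas = ms.measure_exam(coarse_exam.volume, coarse_exam.labels,
                               coarse_exam.landmarks, subject_id="S0",
                               timepoint="pre")
        frame = ms.measurements_to_frame(meas + meas[:1])
        with pytest.raises(ValueError, match="duplicate"):
            cohort_from_measurements(frame)
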