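import numpy as np
import pandas as pd
import pytest
import scipy.stats

from reachadapt.adaptation import AdaptationConfig
from reachadapt.analysis import (
    ConditionCoding,
    SegmentDurationModel,
    change_statistics,
    change_statistics_from_r2,
    condition_duration_table,
    encode,
    iteration_level_summary,
    predict_duration,
    records_from_logs,
    segment_level_summary,
)
from reachadapt.fixtures_io import model2_coefficients
from reachadapt.protocol import Protocol
from reachadapt.user_sim import default_user_factory, simulate_cohort


class TestConditionCoding:
    def test_embedded_return_towards_small_segment(self, segment_map):
        coding = encode(segment_map[6])
        assert (coding.ev1, coding.rr1, coding.g1, coding.g2, coding.cb1) == (1, 0, 1, 0, 1)
        inter = coding.interactions
        assert inter["EV1G1"] == 1 and inter["G1CB1"] == 1
        assert sum(inter.values()) == 2

    def test_all_reference_segment_codes_to_zeros(self, segment_map):
        coding = encode(segment_map[13])
        assert coding.as_dict() == {k: 0 for k in coding.as_dict()}

    def test_embedded_reach_ground_large_segment(self, segment_map):
        coding = encode(segment_map[1])
        assert (coding.ev1, coding.rr1, coding.g1, coding.g2, coding.cb1) == (1, 1, 0, 1, 0)
        inter = coding.interactions
        assert inter["EV1G2"] == 1 and inter["RR1G2"] == 1
        assert sum(inter.values()) == 2

    def test_participant_dummy_skips_the_reference(self, segment_map):
        assert encode(segment_map[1], participant_id=1).participant is None
        assert encode(segment_map[1], participant_id=5).participant == "Participant 5"

    def test_gravity_dummies_are_exclusive(self):
        with pytest.raises(ValueError):
            ConditionCoding(g1=1, g2=1)

    def test_decode_round_trips_all_segments(self, segments):
        for seg in segments:
            labels = encode(seg).decode()
            assert (labels["embedded_virtual"] == "Embedded") == seg.embedded
            assert (labels["reach_return"] == "Reach") == seg.reach
            expected_gravity = {
                "against": "Against Gravity",
                "towards": "Towards Gravity",
                "ground": "Ground Level",
            }[seg.gravity]
            assert labels["gravity"] == expected_gravity
            assert labels["cross_body"].lower() == seg.cross_body


def _toy_model(y, X):
    exog = pd.DataFrame(X)
    exog.insert(0, "Constant", 1.0)
    return SegmentDurationModel(pd.Series(y, dtype=float), exog)


class TestOlsFit:
    def test_exact_line_is_recovered(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        fit = _toy_model(2 * x + 1, {"x": x}).fit()
        assert fit.params["Constant"] == pytest.approx(1.0, abs=1e-12)
        assert fit.params["x"] == pytest.approx(2.0, abs=1e-12)
        assert fit.rsquared == pytest.approx(1.0)

    def test_intercept_only_fits_the_mean(self):
        y = np.array([1.0, 2.0, 4.0, 5.0])
        exog = pd.DataFrame({"Constant": np.ones_like(y)})
        fit = SegmentDurationModel(pd.Series(y), exog).fit()
        assert fit.params["Constant"] == pytest.approx(y.mean())
        assert fit.rsquared == pytest.approx(0.0)

    def test_known_coefficients_recovered_at_vanishing_noise(self, rng):
        n = 400
        X = {"a": rng.normal(size=n), "b": rng.normal(size=n)}
        y = 3.0 + 1.5 * X["a"] - 0.75 * X["b"] + rng.normal(0.0, 1e-8, n)
        fit = _toy_model(y, X).fit()
        assert fit.params["Constant"] == pytest.approx(3.0, abs=1e-6)
        assert fit.params["a"] == pytest.approx(1.5, abs=1e-6)
        assert fit.params["b"] == pytest.approx(-0.75, abs=1e-6)

    def test_matches_normal_equations_on_random_designs(self, rng):
        for _ in range(50):
            n = int(rng.integers(6, 20))
            p = int(rng.integers(1, 4))
            X = rng.normal(size=(n, p))
            y = rng.normal(size=n)
            exog = pd.DataFrame(X, columns=[f"x{j}" for j in range(p)])
            exog.insert(0, "Constant", 1.0)
            fit = SegmentDurationModel(pd.Series(y), exog).fit()
            Xc = exog.to_numpy()
            brute = np.linalg.solve(Xc.T @ Xc, Xc.T @ y)
            np.testing.assert_allclose(fit.params.to_numpy(), brute, atol=1e-9)

    def test_rank_deficiency_reports_offending_columns(self, rng):
        x = rng.normal(size=10)
        with pytest.raises(ValueError, match="rank deficient"):
            _toy_model(rng.normal(size=10), {"x": x, "x2": 2 * x})

    def test_constant_predictor_rejected(self, rng):
        with pytest.raises(ValueError, match="variation"):
            _toy_model(rng.normal(size=5), {"flat": np.ones(5)})

    def test_adjusted_r2_never_exceeds_r2(self, rng):
        X = {"a": rng.normal(size=30), "b": rng.normal(size=30)}
        y = X["a"] + rng.normal(size=30)
        fit = _toy_model(y, X).fit()
        assert fit.rsquared_adj <= fit.rsquared

    def test_mean_prediction_equals_mean_outcome(self, rng):
        # residuals sum to zero whenever an intercept is present
        X = {"a": rng.normal(size=25)}
        y = 2.0 + X["a"] + rng.normal(size=25)
        fit = _toy_model(y, X).fit()
        assert fit.predict().mean() == pytest.approx(np.mean(y))

    def test_durbin_watson_matches_its_definition(self, rng):
        X = {"a": rng.normal(size=40)}
        y = X["a"] + rng.normal(size=40)
        fit = _toy_model(y, X).fit()
        e = fit.resid.to_numpy()
        expected = np.sum(np.diff(e) ** 2) / np.sum(e**2)
        assert fit.durbin_watson == pytest.approx(expected, rel=1e-12)

    def test_standardized_betas_scale_relation(self, rng):
        X = {"a": 3.0 * rng.normal(size=60)}
        y = 0.5 * X["a"] + rng.normal(size=60)
        fit = _toy_model(y, X).fit()
        expected = fit.params["a"] * np.std(X["a"], ddof=1) / np.std(y, ddof=1)
        assert fit.std_betas["a"] == pytest.approx(expected)
        assert np.isnan(fit.std_betas["Constant"])


class TestChangeStatistics:
    def test_identical_models_give_zero_change(self):
        cs = change_statistics_from_r2(0.5, 0.5, 3, 100)
        assert cs.r2_change == 0.0 and cs.f_change == 0.0 and cs.p_value == 1.0

    def test_reported_f_consistent_with_rounded_r2_inputs(self):
        # the published pair (0.544 -> 0.651, df1=7, df2=2390) prints F = 104.518;
        # with R^2 values rounded to 3 decimals the implied F lies in a band
        cs = change_statistics_from_r2(0.544, 0.651, 7, 2390)
        lo = change_statistics_from_r2(0.5445, 0.6505, 7, 2390).f_change
        hi = change_statistics_from_r2(0.5435, 0.6515, 7, 2390).f_change
        assert lo < 104.518 < hi
        assert lo < cs.f_change < hi
        assert cs.p_value < 0.001

    def test_non_nested_models_rejected(self, rng):
        y = rng.normal(size=20)
        a = _toy_model(y, {"a": rng.normal(size=20)}).fit()
        b = _toy_model(y, {"b": rng.normal(size=20)}).fit()
        with pytest.raises(ValueError, match="nested"):
            change_statistics(a, b)

    def test_nested_f_matches_anova_identity(self, rng):
        n = 50
        x1, x2 = rng.normal(size=n), rng.normal(size=n)
        y = 1.0 + x1 + 0.5 * x2 + rng.normal(size=n)
        restricted = _toy_model(y, {"x1": x1}).fit()
        full = _toy_model(y, {"x1": x1, "x2": x2}).fit()
        cs = change_statistics(restricted, full)
        # the single added predictor's F equals its squared t value
        assert cs.f_change == pytest.approx(float(full.tvalues["x2"]) ** 2, rel=1e-9)
        assert cs.df1 == 1

    def test_pure_noise_predictor_p_values_are_uniform(self):
        rng = np.random.default_rng(2024)
        pvals = []
        for _ in range(200):
            n = 100
            y = rng.normal(size=n)
            x = rng.normal(size=n)
            restricted_exog = pd.DataFrame({"Constant": np.ones(n)})
            restricted = SegmentDurationModel(pd.Series(y), restricted_exog).fit()
            full = _toy_model(y, {"x": x}).fit()
            pvals.append(change_statistics(restricted, full).p_value)
        assert scipy.stats.kstest(pvals, "uniform").pvalue > 0.01


class TestPredictDuration:
    def test_published_interaction_substitution(self):
        coeffs = model2_coefficients()
        profile = ConditionCoding(ev1=1, g1=1)
        assert predict_duration(coeffs, profile) == pytest.approx(7.191, abs=5e-4)

    def test_all_reference_profile_returns_the_constant(self):
        coeffs = model2_coefficients()
        assert predict_duration(coeffs, ConditionCoding()) == pytest.approx(6.358)

    def test_missing_coefficient_raises(self):
        with pytest.raises(KeyError):
            predict_duration({"Constant": 1.0}, ConditionCoding(ev1=1))

    def test_condition_grid_matches_published_cells(self):
        grid = condition_duration_table(model2_coefficients())
        assert grid.loc["Embedded (EV1)", "Against Gravity (G0)"] == pytest.approx(2.881, abs=5e-4)
        assert grid.loc["Virtual (EV0)", "Towards Gravity (G1)"] == pytest.approx(6.475, abs=5e-4)
        assert grid.loc["Embedded (EV1)", "Towards Gravity (G1)"] == pytest.approx(7.191, abs=5e-4)
        assert grid.loc["Embedded (EV1)", "Ground Level (G2)"] == pytest.approx(7.543, abs=5e-4)
        # the return row re-expresses the all-reference virtual row
        pd.testing.assert_series_equal(
            grid.loc["Return (RR0)"], grid.loc["Virtual (EV0)"], check_names=False
        )


@pytest.fixture(scope="module")
def cohort(request):
    segments = request.getfixturevalue("segments")
    protocol = Protocol.default(segments)
    factory = default_user_factory(segments)
    return simulate_cohort(6, protocol, factory, AdaptationConfig(), seed=42), segments


class TestCohortAnalysis:
    def test_planted_condition_effects_recovered_with_correct_signs(self, cohort):
        logs, segments = cohort
        records = records_from_logs(logs, segments)
        fit = SegmentDurationModel.from_records(records, include_interactions=False).fit()
        # the generator plants embedded-faster and reach-slower effects
        assert fit.params["Embedded"] < 0
        assert fit.params["Reach"] > 0

    def test_interactions_are_nested_on_top_of_the_main_effects(self, cohort):
        logs, segments = cohort
        records = records_from_logs(logs, segments)
        main = SegmentDurationModel.from_records(records, include_interactions=False).fit()
        full = SegmentDurationModel.from_records(records, include_interactions=True).fit()
        cs = change_statistics(main, full)
        assert cs.df1 == 7
        assert full.rsquared >= main.rsquared

    def test_summaries_count_converged_segments(self, cohort):
        logs, _ = cohort
        it = iteration_level_summary(logs)
        seg = segment_level_summary(logs)
        assert len(it) == 6 and len(seg) == 13
        assert (it["n_converged"] <= it["n_segments"]).all()
        assert (seg["n_converged"] <= seg["n_participants"]).all()

    def test_fixed_seed_cohort_reproduces_frozen_convergence_counts(self, segments):
        # regression against the first verified run of this generator
        protocol = Protocol.default(segments)
        factory = default_user_factory(segments)
        logs = simulate_cohort(8, protocol, factory, AdaptationConfig(), seed=7)
        seg_counts = segment_level_summary(logs)["n_converged"].tolist()
        it_counts = iteration_level_summary(logs)["n_converged"].tolist()
        assert seg_counts == [8, 8, 7, 8, 8, 8, 8, 8, 8, 7, 8, 8, 8]
        assert it_counts == [13, 13, 12, 12, 13, 13, 13, 13]
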