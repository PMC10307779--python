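"""Unit and property tests for the outcome-measure derivations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ethopharm import measures as m
from ethopharm import synthetic as syn
from ethopharm.errors import ConfigError, InsufficientDataError

latency = st.floats(min_value=5.0, max_value=20.0, allow_nan=False)


class TestPawLatency:
    @pytest.mark.parametrize("trials, expected", [
        ([7.0, 7.4, 9.0], 7.2),          # closest pair is (7.0, 7.4)
        ([6.0, 6.0], 6.0),               # identical pair
        ([5.0, 6.0, 7.0], 5.5),          # two pairs tie at gap 1; earliest wins
        ([20.0, 5.0, 19.5], 19.75),
    ])
    def test_two_closest_average(self, trials, expected):
        assert m.paw_latency(trials) == pytest.approx(expected)

    def test_requires_two_trials(self):
        with pytest.raises(InsufficientDataError):
            m.paw_latency([8.0])

    @given(st.lists(latency, min_size=2, max_size=6))
    def test_matches_pair_enumeration_oracle(self, trials):
        pairs = [(abs(a - b), i, j)
                 for i, a in enumerate(trials)
                 for j, b in enumerate(trials) if i < j]
        gap, i, j = min(pairs, key=lambda p: (p[0], p[1], p[2]))
        assert m.paw_latency(trials) == pytest.approx((trials[i] + trials[j]) / 2)


class TestSessionLatency:
    def test_mean_of_paws(self):
        assert m.session_latency({"left": [10.0, 10.0], "right": [12.0, 12.0]}) == 11.0
        assert m.session_latency({"left": [18.7, 18.7], "right": [18.7, 18.7]}) == 18.7

    def test_composes_paw_latency(self):
        got = m.session_latency({"left": [7.0, 7.4, 9.0], "right": [6.0, 6.0]})
        assert got == pytest.approx(6.6)

    def test_missing_paw(self):
        with pytest.raises(InsufficientDataError):
            m.session_latency({"left": [7.0, 7.4]})


class TestOlsSlope:
    def test_exact_line(self):
        slope, intercept = m.ols_slope([1, 2, 3, 4], [2, 4, 6, 8])
        assert slope == pytest.approx(2.0) and intercept == pytest.approx(0.0)

    def test_flat(self):
        assert m.ols_slope([1, 2, 3], [5, 5, 5])[0] == 0.0

    def test_degenerate_abscissa(self):
        with pytest.raises(InsufficientDataError):
            m.ols_slope([3, 3, 3], [1, 2, 3])

    @given(st.lists(st.integers(-100, 100), min_size=3, max_size=10, unique=True),
           st.data())
    def test_matches_normal_equations(self, x, data):
        x = [float(v) for v in x]
        y = data.draw(st.lists(st.floats(-100, 100), min_size=len(x),
                               max_size=len(x)))
        a = np.vstack([np.ones(len(x)), x]).T
        beta = np.linalg.solve(a.T @ a, a.T @ np.asarray(y))
        slope, intercept = m.ols_slope(x, y)
        assert slope == pytest.approx(beta[1], abs=1e-8)
        assert intercept == pytest.approx(beta[0], abs=1e-8)


class TestReflexMeasures:
    def test_basal_is_first_session_any_input_order(self):
        days, lats = [8, 6, 9, 7], [17.4, 18.7, 16.7, 18.0]
        assert m.basal_reflex_pain(days, lats) == 18.7
        assert m.basal_reflex_pain(days[::-1], lats[::-1]) == 18.7

    def test_rate_change_on_group_trajectory(self):
        # linear decline from 18.7 to 16.7 over four sessions
        lats = [18.7 - (2.0 / 3.0) * s for s in range(4)]
        assert m.rate_change_reflex_pain([6, 7, 8, 9], lats) == pytest.approx(2 / 3)

    def test_rate_change_signs(self):
        assert m.rate_change_reflex_pain([6, 7, 8], [15, 15, 15]) == 0.0
        assert m.rate_change_reflex_pain([6, 7, 8], [14, 15, 16]) < 0


class TestLocomotorMeasures:
    def test_basal_loco_first_day(self):
        assert m.basal_loco([14, 13, 15, 16], [592, 675, 509, 427]) == 675

    def test_habituation_slope_and_transform(self):
        raw = m.raw_habituation_slope([13, 14, 15, 16], [675, 592, 509, 427])
        assert raw == pytest.approx(82.7)
        assert m.signed_sqrt(raw) == pytest.approx(np.sqrt(82.7))
        assert m.signed_sqrt(raw) == pytest.approx(9.094, abs=5e-4)
        assert m.signed_sqrt(0.0) == 0.0
        assert m.signed_sqrt(-4.0) == -2.0

    def test_transform_not_triggered_on_normal_cohort(self):
        rng = np.random.default_rng(7)
        slopes = pd.Series(rng.normal(80, 10, size=30))
        vals, flag = m.rate_loco_habituation(slopes)
        assert not flag
        pd.testing.assert_series_equal(vals, slopes)

    def test_transform_triggered_on_skewed_cohort(self):
        rng = np.random.default_rng(7)
        slopes = pd.Series(rng.exponential(80.0, size=40))
        vals, flag = m.rate_loco_habituation(slopes)
        assert flag
        # monotone, order-preserving transform
        assert (vals.sort_values().index == slopes.sort_values().index).all()

    def test_acute_oxy_loco(self):
        assert m.acute_oxy_loco(1117, 675) == 442
        assert m.acute_oxy_loco(500, 500) == 0
        assert m.acute_oxy_loco(400, 500) == -100

    def test_sensitization_slope_uninverted(self):
        days = [13, 14, 15, 16]
        veh = [0, 0, 0, 0]
        assert m.rate_behavioral_sensitization(days, [442, 546, 650, 754], veh) \
            == pytest.approx(104.0)
        assert m.rate_behavioral_sensitization(days, [500] * 4, veh) == 0.0
        assert m.rate_behavioral_sensitization(days, [754, 650, 546, 442], veh) < 0


def _pt(day, oxy, veh=None, center=0.0, total=1200.0):
    veh = total - oxy - center if veh is None else veh
    return m.PlaceTest(day=day, oxy_s=oxy, veh_s=veh, center_s=center)


class TestCppScores:
    def test_scoring_methods(self):
        pre, test = _pt(10, 400.0), _pt(17, 500.0)
        assert m.cpp_score(test, pre, "pre_subtraction") == pytest.approx(100.0)
        even = _pt(17, 600.0, veh=600.0)
        assert m.cpp_score(even, pre, "veh_subtraction") == 0.0
        assert m.cpp_score(even, pre, "proportion") == 0.5

    def test_identity_and_errors(self):
        t = _pt(17, 393.4)
        assert m.cpp_score(t, t, "pre_subtraction") == 0.0
        with pytest.raises(InsufficientDataError):
            m.cpp_score(_pt(17, 0.0, veh=0.0, center=1200.0), t, "proportion")
        with pytest.raises(ConfigError):
            m.cpp_score(t, t, "nope")

    def test_first_test_uses_earliest(self):
        pre = _pt(10, 393.0)
        tests = [_pt(24, 430.0), _pt(17, 493.0), _pt(51, 300.0)]
        assert m.cpp_at_first_test(pre, tests) == pytest.approx(100.0)

    def test_extinction_uses_day_abscissa(self):
        pre = _pt(10, 393.4)
        days = syn.CPP_TEST_DAYS
        tests = [_pt(d, pre.oxy_s + 120 - 4.4 * (d - days[0])) for d in days]
        assert m.rate_cpp_extinction(pre, tests) == pytest.approx(4.4)
        # index abscissa would give a different (wrong) slope
        scores = [m.cpp_score(t, pre) for t in sorted(tests, key=lambda t: t.day)]
        idx_slope = -m.ols_slope(np.arange(len(scores)), scores)[0]
        assert idx_slope != pytest.approx(4.4, abs=1e-3)

    def test_constant_cpp_zero_slope(self):
        pre = _pt(10, 393.4)
        tests = [_pt(d, 450.0) for d in syn.CPP_TEST_DAYS]
        assert m.rate_cpp_extinction(pre, tests) == 0.0


class TestPostSurgeryMeasures:
    def test_reflex_triple(self):
        sessions = [{"right": [8.0, 8.0], "left": [16.0, 16.0]},
                    {"right": [9.0, 9.0], "left": [18.0, 18.0]},
                    {"right": [10.0, 10.0], "left": [20.0, 20.0]}]
        a, b, c = m.post_surgery_reflex_measures(9.0, sessions, "right")
        assert a == pytest.approx(9.0)
        assert b == pytest.approx(50.0)
        assert c == pytest.approx(0.0)

    def test_symmetric_paws_are_100_percent(self):
        sessions = [{"right": [12.0, 12.0], "left": [12.0, 12.0]}] * 3
        _, b, _ = m.post_surgery_reflex_measures(12.0, sessions, "right")
        assert b == pytest.approx(100.0)

    def test_cpp_deltas(self):
        tests = {10: _pt(10, 393.4), 17: _pt(17, 493.4),
                 51: _pt(51, 300.0), 66: _pt(66, 300.0)}
        d1, d2, d3 = m.post_surgery_cpp_measures(tests)
        assert d1 == pytest.approx(-93.4)
        assert d2 == pytest.approx(-193.4)
        assert d3 == pytest.approx(0.0)

    def test_all_identical_tests_zero(self):
        t = _pt(0, 400.0)
        tests = {d: m.PlaceTest(day=d, oxy_s=400.0, veh_s=400.0, center_s=400.0)
                 for d in (10, 17, 51, 66)}
        assert m.post_surgery_cpp_measures(tests) == (0.0, 0.0, 0.0)

    def test_missing_day_raises(self):
        with pytest.raises(InsufficientDataError):
            m.post_surgery_cpp_measures({10: _pt(10, 400.0)})


class TestDoseTranslation:
    @pytest.mark.parametrize("dose, divisor, mass, expected", [
        (0.56, 6.2, 70.0, 6.3),
        (0.0, 6.2, 70.0, 0.0),
        (6.2, 6.2, 1.0, 1.0),
    ])
    def test_conversion(self, dose, divisor, mass, expected):
        assert m.human_equivalent_dose(dose, divisor, mass) == expected

    def test_invalid_params(self):
        with pytest.raises(ConfigError):
            m.human_equivalent_dose(0.56, 0.0, 70.0)


class TestBuildMeasureTable:
    def test_complete_cohort_shape(self, default_measures):
        assert default_measures.data.shape == (15, 14)
        assert not default_measures.data.isna().any().any()
        assert list(default_measures.data.columns) == list(m.ALL_MEASURES)

    def test_permutation_invariance(self, default_cohort, default_measures):
        rng = np.random.default_rng(0)
        shuffled = syn.StudyDataset(
            reflex_trials=default_cohort.reflex_trials.sample(frac=1, random_state=1),
            conditioning=default_cohort.conditioning.sample(frac=1, random_state=2),
            place_tests=default_cohort.place_tests.sample(frac=1, random_state=3),
            animals=default_cohort.animals.sample(frac=1, random_state=4),
        )
        got = m.build_measure_table(shuffled)
        pd.testing.assert_frame_equal(
            got.data.sort_index(), default_measures.data.sort_index())

    def test_missing_phase_yields_missing_columns_only(self, default_cohort):
        animal = default_cohort.animals["animal"].iloc[0]
        trimmed = syn.StudyDataset(
            reflex_trials=default_cohort.reflex_trials[
                ~((default_cohort.reflex_trials["animal"] == animal)
                  & (default_cohort.reflex_trials["day"] >= syn.SURGERY_DAY))],
            conditioning=default_cohort.conditioning,
            place_tests=default_cohort.place_tests[
                ~((default_cohort.place_tests["animal"] == animal)
                  & (default_cohort.place_tests["day"] == syn.POST_TEST_DAY))],
            animals=default_cohort.animals,
        )
        got = m.build_measure_table(trimmed).data
        assert got.loc[animal, list(m.PRE_MEASURES)].notna().all()
        assert got.loc[animal, list(m.POST_MEASURES)].isna().all()
        others = got.drop(index=animal)
        assert others.notna().all().all()

    def test_empty_dataset(self):
        empty = syn.StudyDataset(
            reflex_trials=pd.DataFrame(columns=["animal", "day", "session", "paw",
                                                "trial_index", "latency_s"]),
            conditioning=pd.DataFrame(columns=["animal", "day", "drug", "counts"]),
            place_tests=pd.DataFrame(columns=["animal", "day", "compartment", "time_s"]),
            animals=pd.DataFrame(columns=["animal", "sex", "surgery_arm",
                                          "surgeried_paw"]),
        )
        with pytest.raises(InsufficientDataError):
            m.build_measure_table(empty)
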