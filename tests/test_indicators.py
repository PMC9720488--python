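import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from oracles import naive_ln_variance, naive_rauto, naive_skewness
from resgwas import indicators as ind
from resgwas.simulate import EggLogSet

series_strategy = st.lists(
    st.floats(min_value=-50, max_value=50, allow_nan=False), min_size=4, max_size=60
)


def well_spread(xs) -> bool:
    """Guard for shift/scale-invariance checks: near-degenerate series make
    the central moments numerically meaningless."""
    return float(np.var(xs)) > 1e-3


def make_logs(rows, last_day=None):
    rec = pd.DataFrame(rows, columns=["hen", "day", "eggs"])
    if last_day is None:
        last_day = rec.groupby("hen")["day"].max()
    return EggLogSet(rec, pd.Series(last_day))


class TestWeeklyCounts:
    def test_records_within_a_week_are_summed(self):
        # week 26 covers days 175..181
        s = ind.weekly_counts([176, 179, 181], [3, 3, 1], coverage_start=175)
        assert s.loc[26] == 7

    def test_decreasing_days_rejected(self):
        with pytest.raises(ind.InputError):
            ind.weekly_counts([10, 9], [1, 1])

    def test_empty_log_gives_empty_series(self):
        assert len(ind.weekly_counts([], [])) == 0

    def test_no_weeks_after_death(self):
        logs = make_logs(
            [("h", d, 1) for d in range(175, 200, 3)], last_day={"h": 199}
        )
        weekly = ind.weekly_production(logs, coverage_start=175)
        observed = weekly.columns[weekly.loc["h"].notna()]
        # day 199 falls in week 29 (196..202): that partial week is dropped
        assert observed.max() * 7 - 1 <= 199

    def test_partial_first_week_dropped(self):
        s = ind.weekly_counts([176, 181, 188], [2, 2, 7], coverage_start=176)
        assert 26 not in s.index  # coverage starts mid-week
        assert s.loc[27] == 7


class TestBatchCurveAndDeviations:
    def test_mean_of_two_hens(self):
        weekly = pd.DataFrame({25: [6.0, 8.0]}, index=["a", "b"])
        assert ind.batch_mean(weekly)[25] == 7.0

    def test_single_hen_curve_is_identity(self):
        weekly = pd.DataFrame({25: [6.0], 26: [5.0]}, index=["a"])
        curve = ind.batch_mean(weekly)
        assert list(curve) == [6.0, 5.0]
        dev = ind.deviations(weekly, curve)
        assert np.allclose(dev.to_numpy(), 0.0)

    def test_elementwise_subtraction(self):
        weekly = pd.DataFrame({25: [5.0]}, index=["a"])
        curve = pd.Series({25: 6.5})
        assert ind.deviations(weekly, curve).iloc[0, 0] == -1.5

    def test_constant_hen_against_declining_curve_increases(self):
        weeks = np.arange(29, 93)
        curve = pd.Series(np.linspace(6.8, 4.9, weeks.size), index=weeks)
        weekly = pd.DataFrame([np.full(weeks.size, 7.0)], index=["h"], columns=weeks)
        dev = ind.deviations(weekly, curve).loc["h"].to_numpy()
        assert (np.diff(dev) > 0).all()

    def test_missing_curve_week_raises(self):
        weekly = pd.DataFrame({25: [5.0], 26: [5.0]}, index=["a"])
        with pytest.raises(ind.InputError):
            ind.deviations(weekly, pd.Series({25: 6.0}))


class TestLnVariance:
    def test_hand_value(self):
        assert ind.ln_variance([1, -1, 1, -1]) == pytest.approx(math.log(4 / 3), abs=1e-12)

    def test_constant_series_missing(self):
        assert math.isnan(ind.ln_variance([2, 2, 2, 2]))
        assert math.isnan(ind.ln_variance([1.0]))

    @given(series_strategy, st.floats(min_value=0.1, max_value=10))
    def test_scaling_adds_two_log_c(self, xs, c):
        if not well_spread(xs):
            return
        base = ind.ln_variance(xs)
        if not math.isnan(base):
            scaled = ind.ln_variance([c * x for x in xs])
            assert scaled == pytest.approx(base + 2 * math.log(c), abs=1e-8)


class TestSkewness:
    def test_symmetric_series_zero(self):
        assert ind.skewness([-1, 0, 1]) == pytest.approx(0.0, abs=1e-12)

    def test_hand_value(self):
        # mean 0.25, m2 = 0.1875, m3 = 0.09375 -> 1.1547
        assert ind.skewness([0, 0, 0, 1]) == pytest.approx(1.154700538, abs=1e-8)

    @given(series_strategy)
    def test_negation_flips_sign(self, xs):
        if not well_spread(xs):
            return
        s = ind.skewness(xs)
        if not math.isnan(s):
            assert ind.skewness([-x for x in xs]) == pytest.approx(-s, abs=1e-8)

    @given(series_strategy, st.floats(min_value=-100, max_value=100))
    def test_location_invariance(self, xs, c):
        if not well_spread(xs):
            return
        s = ind.skewness(xs)
        if not math.isnan(s):
            assert ind.skewness([x + c for x in xs]) == pytest.approx(s, abs=1e-6)


class TestRauto:
    def test_alternating_series_approaches_minus_one(self):
        xs = [(-1.0) ** t for t in range(400)]
        assert ind.lag1_autocorrelation(xs) == pytest.approx(-1.0, abs=5e-3)

    def test_linear_trend_64_weeks(self):
        xs = np.linspace(0.2, 2.1, 64)  # deviations of a constant-7 hen
        assert ind.lag1_autocorrelation(xs) == pytest.approx(0.953125, abs=1e-9)

    def test_iid_noise_near_zero(self, rng):
        xs = rng.normal(size=20000)
        assert abs(ind.lag1_autocorrelation(xs)) < 0.03

    @given(series_strategy)
    def test_bounded_in_minus_one_one(self, xs):
        r = ind.lag1_autocorrelation(xs)
        if not math.isnan(r):
            assert -1.0 - 1e-12 <= r <= 1.0 + 1e-12

    @given(series_strategy, st.floats(min_value=-100, max_value=100))
    def test_location_invariance(self, xs, c):
        if not well_spread(xs):
            return
        r = ind.lag1_autocorrelation(xs)
        if not math.isnan(r):
            assert ind.lag1_autocorrelation([x + c for x in xs]) == pytest.approx(
                r, abs=1e-6
            )

    def test_gap_pairs_excluded_from_numerator(self):
        xs = np.array([1.0, -1.0, 1.0, -1.0])
        weeks = np.array([25, 26, 28, 29])  # gap between 26 and 28
        r = ind.lag1_autocorrelation(xs, weeks=weeks)
        # only pairs (25,26) and (28,29) contribute: num = -2, denom = 4
        assert r == pytest.approx(-0.5, abs=1e-12)

    def test_pearson_variant_available(self):
        xs = np.linspace(0, 1, 30)
        r = ind.lag1_autocorrelation(xs, method="pearson")
        assert r == pytest.approx(1.0, abs=1e-9)


class TestOracleEquivalence:
    @given(series_strategy)
    def test_indicators_match_naive_formulas(self, xs):
        for mine, naive in (
            (ind.ln_variance, naive_ln_variance),
            (ind.skewness, naive_skewness),
            (ind.lag1_autocorrelation, naive_rauto),
        ):
            a, b = mine(xs), naive(xs)
            if math.isnan(a) or math.isnan(b):
                assert math.isnan(a) and math.isnan(b)
            else:
                assert a == pytest.approx(b, abs=1e-10)


class TestResilienceRecords:
    @staticmethod
    def records(total_eggs, n_weeks=10, start=25):
        weeks = np.arange(start, start + n_weeks)
        # non-constant pattern so the variance-based indicators are defined
        per_week = np.ones(n_weeks, dtype=float)
        per_week[0] = total_eggs - (n_weeks - 1)
        weekly = pd.DataFrame([per_week], index=["h"], columns=weeks)
        curve = pd.Series(5.0, index=weeks)
        dev = ind.deviations(weekly, curve)
        return ind.resilience_indicators(dev, weekly)

    def test_under_twenty_eggs_all_missing(self):
        table, counts = self.records(19)
        rec = table[(table["period"] == "25-83")].iloc[0]
        assert math.isnan(rec["ln_var"]) and math.isnan(rec["skew"])
        assert counts[0].n_filtered_low_eggs == 1

    def test_twenty_eggs_computed(self):
        table, counts = self.records(20)
        rec = table[(table["period"] == "25-83")].iloc[0]
        assert not math.isnan(rec["ln_var"])
        assert counts[0].n_filtered_low_eggs == 0

    def test_death_before_second_period_gives_no_data(self):
        weeks = np.arange(25, 80)
        weekly = pd.DataFrame(
            [np.full(weeks.size, 6.0)], index=["h"], columns=weeks
        )
        dev = ind.deviations(weekly, pd.Series(5.5, index=weeks))
        table, counts = ind.resilience_indicators(dev, weekly)
        late = table[table["period"] == "83-end"].iloc[0]
        assert late["n_weeks"] == 0 and math.isnan(late["r_auto"])
        assert counts[1].n_no_data == 1
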