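"""Daily activity summaries, profiles, and activity bouts."""

from datetime import date, datetime, time, timedelta

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from damkit import (Condition, ExperimentLayout, LightCalendar,
                    activity_bouts, activity_by_day, activity_profile,
                    condition_daily_activity, fly_day_table)
from damkit.activity import runs, sem
from tests.conftest import minute_series


def brute_force_runs(mask):
    out, start = [], None
    for i, v in enumerate(list(mask) + [False]):
        if v and start is None:
            start = i
        elif not v and start is not None:
            out.append((start, i - start))
            start = None
    return out


@settings(deadline=None, max_examples=50)
@given(st.lists(st.booleans(), max_size=300))
def test_run_detection_matches_brute_force(mask):
    assert runs(np.array(mask, dtype=bool)) == brute_force_runs(mask)


def two_fly_layout(calendar):
    return ExperimentLayout(
        [Condition("ctrl", "#000000", (("M", 1), ("M", 2)))], calendar, 1.0)


def flies_with_daily_totals(calendar, rates):
    """Constant-rate deterministic flies over the three LD days."""
    start = datetime(2017, 1, 2, 6, 0)
    return {f"ctrl_M_{i+1:02d}": minute_series([r] * (3 * 1440), start=start)
            for i, r in enumerate(rates)}


class TestConditionSummary:
    def test_mean_and_sem_across_flies(self, calendar):
        layout = two_fly_layout(calendar)
        # fly totals per day: 100 and 200 counts
        flies = {}
        for i, per_min in enumerate([100, 200]):
            vals = ([per_min] + [0] * 1439) * 3
            flies[f"ctrl_M_{i+1:02d}"] = minute_series(
                vals, start=datetime(2017, 1, 2, 6, 0))
        table = fly_day_table(flies, calendar, 1.0)
        summary = condition_daily_activity(table, layout, "LD", "all")
        row = summary.table.loc["ctrl"]
        assert row["mean"] == pytest.approx(150.0)
        assert row["sem"] == pytest.approx(50.0)
        assert row["n"] == 2

    def test_single_fly_has_zero_sem(self, calendar):
        layout = ExperimentLayout(
            [Condition("ctrl", "#000000", (("M", 1),))], calendar, 1.0)
        flies = flies_with_daily_totals(calendar, [1])
        table = fly_day_table(flies, calendar, 1.0)
        row = condition_daily_activity(table, layout, "LD").table.loc["ctrl"]
        assert row["n"] == 1
        assert row["sem"] == 0.0

    def test_empty_condition_reports_n_zero(self, calendar):
        layout = two_fly_layout(calendar)
        table = fly_day_table({}, calendar, 1.0)
        row = condition_daily_activity(table, layout, "LD").table.loc["ctrl"]
        assert row["n"] == 0
        assert np.isnan(row["mean"])

    def test_day_night_totals_sum_to_whole_day(self, calendar,
                                               fixture_monitor):
        from damkit import extract_fly_series
        data, _ = fixture_monitor
        layout = ExperimentLayout(
            [Condition("ctrl", "#000000",
                       tuple(("MonitorA", ch) for ch in range(1, 7)))],
            calendar, 1.0)
        flies = extract_fly_series({"MonitorA": data}, layout)
        table = fly_day_table(flies, calendar, 1.0)
        ld = table[(table["regime"] == "LD") & table["complete"]]
        assert len(ld) > 0
        np.testing.assert_allclose(
            ld["day_total"] + ld["night_total"], ld["total"])

    def test_simulated_mean_recovers_programmed_rate(self, calendar):
        rng = np.random.default_rng(99)
        layout = ExperimentLayout(
            [Condition("ctrl", "#000000",
                       tuple(("M", ch) for ch in range(1, 33)))],
            calendar, 1.0)
        rate = 0.5  # counts/min -> 720/day
        start = datetime(2017, 1, 2, 6, 0)
        flies = {f"ctrl_M_{ch:02d}": minute_series(
            rng.poisson(rate, 3 * 1440), start=start) for ch in range(1, 33)}
        table = fly_day_table(flies, calendar, 1.0)
        row = condition_daily_activity(table, layout, "LD").table.loc["ctrl"]
        assert abs(row["mean"] - 720.0) <= 3 * row["sem"] + 1e-9


class TestByDay:
    def test_constant_fixture_identical_days(self, calendar):
        layout = two_fly_layout(calendar)
        flies = flies_with_daily_totals(calendar, [1, 1])
        table = fly_day_table(flies, calendar, 1.0)
        by_day = activity_by_day(table, layout)
        complete = by_day[by_day["n"] == 2]
        assert complete["mean"].nunique() == 1

    def test_doubled_rate_day_detected(self, calendar):
        layout = two_fly_layout(calendar)
        start = datetime(2017, 1, 2, 6, 0)
        vals = [1] * 1440 + [2] * 1440 + [1] * 1440
        flies = {f"ctrl_M_{i:02d}": minute_series(vals, start=start)
                 for i in (1, 2)}
        by_day = activity_by_day(fly_day_table(flies, calendar, 1.0), layout)
        d = by_day.set_index("day")["mean"]
        assert d[date(2017, 1, 3)] == pytest.approx(2 * d[date(2017, 1, 2)])


class TestProfiles:
    def square_wave_flies(self, calendar, n=2):
        """Active (1/min) during day phase only, over the 3 LD days."""
        start = datetime(2017, 1, 2, 6, 0)
        vals = ([1] * 720 + [0] * 720) * 3
        return {f"ctrl_M_{i+1:02d}": minute_series(vals, start=start)
                for i in range(n)}

    def test_ld_average_square_wave_has_silent_night(self, calendar):
        layout = two_fly_layout(calendar)
        flies = self.square_wave_flies(calendar)
        (profile,) = activity_profile(flies, layout, 30.0, mode="ld_average")
        tbl = profile.table
        day_bins = tbl[tbl.index < 12.0]
        night_bins = tbl[tbl.index >= 12.0]
        assert (day_bins["mean"] == 30.0).all()
        assert (night_bins["mean"] == 0.0).all()

    def test_ld_average_idempotent_over_identical_days(self, calendar):
        layout = two_fly_layout(calendar)
        flies = self.square_wave_flies(calendar)
        (p3,) = activity_profile(flies, layout, 30.0, mode="ld_average")
        one_day = {k: v.iloc[:1440] for k, v in flies.items()}
        (p1,) = activity_profile(one_day, layout, 30.0, mode="ld_average")
        pd.testing.assert_frame_equal(p3.table, p1.table)

    def test_full_experiment_identity_bin(self, calendar):
        layout = two_fly_layout(calendar)
        flies = self.square_wave_flies(calendar)
        (profile,) = activity_profile(flies, layout, 1.0,
                                      mode="full_experiment")
        first_fly = next(iter(flies.values()))
        np.testing.assert_allclose(profile.table["mean"].to_numpy(),
                                   first_fly.to_numpy(dtype=float))
        assert (profile.table["sem"] == 0.0).all()

    def test_no_complete_ld_day_raises(self, calendar):
        layout = two_fly_layout(calendar)
        flies = {k: v.iloc[:100]
                 for k, v in self.square_wave_flies(calendar).items()}
        with pytest.raises(ValueError):
            activity_profile(flies, layout, 30.0, mode="ld_average")


class TestBouts:
    def test_hand_counted_example(self, calendar):
        s = minute_series([0, 2, 3, 0, 0, 1, 0],
                          start=datetime(2017, 1, 2, 6, 0))
        out = activity_bouts(s, calendar, 1.0)
        row = out.loc[date(2017, 1, 2)]
        assert row["bout_count"] == 2
        assert row["mean_bout_length_min"] == pytest.approx(1.5)

    def test_all_zero_day(self, calendar):
        s = minute_series([0] * 1440, start=datetime(2017, 1, 2, 6, 0))
        row = activity_bouts(s, calendar, 1.0).loc[date(2017, 1, 2)]
        assert row["bout_count"] == 0
        assert row["mean_bout_length_min"] == 0.0

    @settings(deadline=None, max_examples=30)
    @given(values=st.lists(st.integers(min_value=0, max_value=3),
                           min_size=1, max_size=500))
    def test_bout_lengths_conserve_active_readings(self, calendar, values):
        s = minute_series(values, start=datetime(2017, 1, 5, 6, 0))
        out = activity_bouts(s, calendar, 1.0)
        total_bout_min = (out["bout_count"] * out["mean_bout_length_min"]).sum()
        assert total_bout_min == pytest.approx(sum(1 for v in values if v > 0))

    def test_bout_assigned_to_day_of_onset(self, calendar):
        # bout starts 2 min before the Jan 3 day boundary and crosses it
        start = datetime(2017, 1, 3, 5, 58)
        s = minute_series([1, 1, 1, 1, 0, 0], start=start)
        out = activity_bouts(s, calendar, 1.0)
        assert out.loc[date(2017, 1, 2), "bout_count"] == 1
        assert out.loc[date(2017, 1, 2), "mean_bout_length_min"] == 4.0
        assert out.loc[date(2017, 1, 3), "bout_count"] == 0
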