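"""Chi-square periodogram, rhythmicity filtering, and actograms."""

from datetime import date, datetime, time, timedelta

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from damkit import (FlySpec, LightCalendar, aggregate_periodogram,
                    build_actogram, chi_square_periodogram, filter_arrhythmic,
                    generate_monitor)
from damkit.circadian import PeriodogramResult, periodogram_bin_minutes
from tests.conftest import minute_series


def brute_force_Q(binned, period_bins):
    """Independent fold: explicit loops over cycles and columns."""
    x = [float(v) for v in binned]
    K = len(x) // period_bins
    n_used = K * period_bins
    col_means = []
    for h in range(period_bins):
        s = 0.0
        for k in range(K):
            s += x[k * period_bins + h]
        col_means.append(s / K)
    grand = sum(x[:n_used]) / n_used
    num = 0.0
    for m in col_means:
        num += (m - grand) ** 2
    den = 0.0
    for i in range(n_used):
        den += (x[i] - grand) ** 2
    return K * n_used * num / den


def dd_series(rng, n_days=6, rate=1.0):
    idx = pd.DatetimeIndex([datetime(2017, 1, 1) + timedelta(minutes=k)
                            for k in range(n_days * 1440)])
    return pd.Series(rng.poisson(rate, len(idx)), index=idx, name="f")


class TestPeriodogram:
    def test_matches_brute_force_fold(self):
        rng = np.random.default_rng(11)
        s = dd_series(rng)
        res = chi_square_periodogram(s, 1.0, (18.0, 30.0), 0.5)
        binned = s.to_numpy().reshape(-1, int(res.bin_minutes)).sum(axis=1)
        for j, p_h in enumerate(res.periods_h):
            p_bins = int(round(p_h * 60 / res.bin_minutes))
            expect = brute_force_Q(binned, p_bins)
            assert res.Q[j] == pytest.approx(expect, rel=1e-9)

    def test_square_wave_peak_at_24h(self, calendar):
        specs = [FlySpec(baseline_rate=0.0, amplitude=3.0, period_h=24.0,
                         phase_h=6.0, waveform="square")]
        data, _ = generate_monitor(specs, calendar, 1.0, seed=5)
        s = data.channel_series(1)
        dd = s[[t.date() >= date(2017, 1, 5) for t in s.index]]
        res = chi_square_periodogram(dd, 1.0, (18.0, 30.0), 0.5)
        assert res.peak_period_h == 24.0
        assert res.rhythmic

    def test_pure_sinusoid_recovered_within_resolution(self):
        for tau in (22.0, 25.0):
            idx = pd.DatetimeIndex([datetime(2017, 1, 1) + timedelta(minutes=k)
                                    for k in range(8 * 1440)])
            hours = np.arange(len(idx)) / 60.0
            vals = 10.0 * (1.0 + np.sin(2 * np.pi * hours / tau))
            s = pd.Series(vals, index=idx, name="sin")
            res = chi_square_periodogram(s, 1.0, (18.0, 30.0), 0.5)
            assert abs(res.peak_period_h - tau) <= 0.5

    def test_scale_invariance(self):
        rng = np.random.default_rng(21)
        s = dd_series(rng)
        r1 = chi_square_periodogram(s, 1.0, (20.0, 28.0), 0.5)
        r2 = chi_square_periodogram(s * 7.5, 1.0, (20.0, 28.0), 0.5)
        np.testing.assert_allclose(r1.Q, r2.Q, rtol=1e-12)

    def test_constant_series_is_arrhythmic(self):
        s = minute_series([4] * 6 * 1440, start=datetime(2017, 1, 1))
        res = chi_square_periodogram(s, 1.0, (18.0, 30.0), 0.5)
        assert not res.rhythmic
        assert res.rhythm_strength == 0.0
        assert np.isnan(res.peak_period_h)

    def test_too_short_series_rejected(self):
        s = minute_series([1] * 1440, start=datetime(2017, 1, 1))
        with pytest.raises(ValueError):
            chi_square_periodogram(s, 1.0, (18.0, 30.0), 0.5)

    def test_significance_line_is_chi_square_quantile(self):
        rng = np.random.default_rng(2)
        s = dd_series(rng)
        res = chi_square_periodogram(s, 1.0, (20.0, 28.0), 0.5, alpha=0.05,
                                     correction="none")
        delta = res.bin_minutes
        for j, p_h in enumerate(res.periods_h):
            df = int(round(p_h * 60 / delta)) - 1
            assert res.S[j] == pytest.approx(sps.chi2.ppf(0.95, df))

    def test_bin_width_makes_all_periods_integer_bins(self):
        delta = periodogram_bin_minutes((18.0, 30.0), 0.1, 1.0)
        assert delta >= 1
        for p in np.arange(18.0, 30.0 + 1e-9, 0.1):
            assert round(p * 60) % delta == 0

    def test_unrepresentable_resolution_rejected(self):
        with pytest.raises(ValueError):
            periodogram_bin_minutes((18.0, 30.0), 0.1, interval_minutes=7.0)


class TestFilter:
    def mk(self, strength):
        return PeriodogramResult("f", np.array([24.0]), np.array([1.0]),
                                 np.array([1.0]), 24.0, strength,
                                 strength >= 1.0, 10.0)

    def test_threshold_boundary_is_inclusive(self):
        rs = [self.mk(0.4), self.mk(1.0), self.mk(2.3)]
        rhythmic, arrhythmic = filter_arrhythmic(rs, 1.0)
        assert [r.rhythm_strength for r in rhythmic] == [1.0, 2.3]
        assert [r.rhythm_strength for r in arrhythmic] == [0.4]

    def test_zero_threshold_keeps_all(self):
        rs = [self.mk(0.0), self.mk(0.4)]
        rhythmic, arrhythmic = filter_arrhythmic(rs, 0.0)
        assert len(rhythmic) == 2 and not arrhythmic


class TestAggregate:
    def test_single_fly_identity(self):
        rng = np.random.default_rng(3)
        s = dd_series(rng)
        r = chi_square_periodogram(s, 1.0, (20.0, 28.0), 0.5)
        agg = aggregate_periodogram([r])
        np.testing.assert_allclose(agg["mean_Q"], r.Q)

    def test_identical_flies_have_zero_sem(self):
        rng = np.random.default_rng(4)
        s = dd_series(rng)
        r = chi_square_periodogram(s, 1.0, (20.0, 28.0), 0.5)
        agg = aggregate_periodogram([r, r])
        np.testing.assert_allclose(agg["mean_Q"], r.Q)
        assert (agg["sem_Q"] == 0.0).all()

    def test_mixed_grids_rejected(self):
        rng = np.random.default_rng(6)
        s = dd_series(rng)
        r1 = chi_square_periodogram(s, 1.0, (20.0, 28.0), 0.5)
        r2 = chi_square_periodogram(s, 1.0, (20.0, 26.0), 0.5)
        with pytest.raises(ValueError):
            aggregate_periodogram([r1, r2])


class TestActogram:
    @pytest.fixture
    def two_day_series(self):
        # two complete onset-anchored days starting at the 06:00 onset
        rng = np.random.default_rng(8)
        return minute_series(rng.poisson(1.0, 2 * 1440),
                             start=datetime(2017, 1, 5, 6, 0))

    def test_single_plot_shape(self, calendar, two_day_series):
        mat = build_actogram(two_day_series, calendar, 1.0, 30.0, "single")
        assert mat.matrix.shape == (2, 48)
        assert not mat.matrix.isna().any().any()

    def test_double_plot_layout(self, calendar, two_day_series):
        mat = build_actogram(two_day_series, calendar, 1.0, 30.0, "double")
        assert mat.matrix.shape == (2, 96)
        row1 = mat.matrix.iloc[0]
        row2 = mat.matrix.iloc[1]
        # right half of row d equals left half of row d+1
        np.testing.assert_allclose(row1.iloc[48:].to_numpy(),
                                   row2.iloc[:48].to_numpy())
        assert row2.iloc[48:].isna().all()

    def test_double_plot_redundancy_many_days(self, calendar,
                                              fixture_monitor):
        data, _ = fixture_monitor
        s = data.channel_series(1)
        mat = build_actogram(s, calendar, 1.0, 60.0, "double")
        m = mat.matrix.to_numpy()
        half = m.shape[1] // 2
        for d in range(m.shape[0] - 1):
            right, nxt = m[d, half:], m[d + 1, :half]
            ok = ~(np.isnan(right) | np.isnan(nxt))
            np.testing.assert_allclose(right[ok], nxt[ok])

    def test_median_aggregate(self, calendar):
        start = datetime(2017, 1, 5, 6, 0)
        flies = {f"f{i}": minute_series([c] * 1440, start=start)
                 for i, c in enumerate([0, 5, 100])}
        mat = build_actogram(flies, calendar, 1.0, 60.0, "single",
                             aggregate="median")
        np.testing.assert_allclose(mat.matrix.to_numpy(), 5 * 60.0)
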