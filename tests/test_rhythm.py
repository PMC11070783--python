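"""Slot averaging, actograms, periodograms, acrophase and phase contrasts."""

from __future__ import annotations

import numpy as np
import pytest

import gryllometry as g
from gryllometry.errors import DegenerateDataError
from gryllometry.rhythm import EventSeries, lomb_power

DAY = 1440


class TestMeanPerSlot:
    def test_single_daily_event_lands_in_its_hour(self):
        values = np.zeros(14 * DAY)
        for d in range(14):
            values[d * DAY + 13 * 60 + 7] = 1
        table = g.mean_per_slot(EventSeries(values), "1h")
        assert table.loc[table["zt_start_min"] == 13 * 60, "mean"].item() == 1.0
        assert table["mean"].sum() == 1.0

    def test_all_ones_conservation(self):
        series = EventSeries(np.ones(2 * DAY))
        hourly = g.mean_per_slot(series, "1h")
        halves = g.mean_per_slot(series, "12h")
        assert (hourly["mean"] == 60.0).all()
        assert (halves["mean"] == 720.0).all()

    def test_matches_brute_force_tabulation(self, rng):
        values = rng.poisson(0.3, 5 * DAY).astype(float)
        table = g.mean_per_slot(EventSeries(values), "1h")
        daily = values.reshape(5, DAY)
        for h in range(24):
            expected = daily[:, h * 60 : (h + 1) * 60].sum(axis=1).mean()
            assert table.loc[h, "mean"] == pytest.approx(expected)

    def test_partial_day_needs_truncate_flag(self):
        with pytest.raises(ValueError, match="whole number of days"):
            g.mean_per_slot(EventSeries(np.ones(2000)), "1h")
        table = g.mean_per_slot(EventSeries(np.ones(2000)), "1h", truncate=True)
        assert (table["mean"] == 60.0).all()


class TestDoublePlot:
    def test_two_day_layout(self):
        values = np.arange(2 * DAY, dtype=float)
        mat = g.double_plot_matrix(EventSeries(values))
        assert mat.shape == (2, 2 * DAY)
        np.testing.assert_array_equal(mat[0], values)
        np.testing.assert_array_equal(mat[1, :DAY], values[DAY:])
        assert np.isnan(mat[1, DAY:]).all()

    def test_first_half_column_sums_conserve_totals(self, rng):
        values = rng.poisson(0.2, 4 * DAY).astype(float)
        mat = g.double_plot_matrix(EventSeries(values))
        np.testing.assert_array_equal(
            mat[:, :DAY].sum(axis=0), values.reshape(4, DAY).sum(axis=0)
        )

    def test_matches_index_arithmetic_oracle(self, rng):
        values = rng.random(3 * DAY)
        mat = g.double_plot_matrix(EventSeries(values))
        for d in range(3):
            for col in range(2 * DAY):
                i = d * DAY + col
                expected = values[i] if i < len(values) else np.nan
                got = mat[d, col]
                assert (np.isnan(expected) and np.isnan(got)) or expected == got


class TestChiSquarePeriodogram:
    def test_toy_series_hand_computation(self):
        """[1,2,3,1,2,3] at P=3: column means (1,2,3), s^2 = 2/3, Q = 6."""
        pg = g.chi_square_periodogram(
            EventSeries(np.array([1.0, 2, 3, 1, 2, 3])), p_min=2, p_max=3,
            correction="pointwise",
        )
        q3 = pg.statistic[pg.periods == 3][0]
        assert q3 == pytest.approx(6.0)

    def test_square_wave_peaks_at_its_period(self):
        zt = np.arange(14 * DAY) % DAY
        series = EventSeries((zt >= 720).astype(float))
        pg = g.chi_square_periodogram(series)
        assert pg.peak_period == 1440.0
        assert pg.significant

    def test_constant_offset_invariance(self, rng):
        values = rng.poisson(0.3, 14 * DAY).astype(float)
        pg0 = g.chi_square_periodogram(EventSeries(values))
        pg1 = g.chi_square_periodogram(EventSeries(values + 7.0))
        np.testing.assert_allclose(pg0.statistic, pg1.statistic, rtol=1e-9)

    def test_circular_shift_by_period_multiple_invariance(self):
        zt = np.arange(14 * DAY) % DAY
        values = (zt >= 720).astype(float) + 0.05 * (1 + np.sin(np.arange(14 * DAY)))
        pg0 = g.chi_square_periodogram(EventSeries(values), p_min=1440, p_max=1440)
        pg1 = g.chi_square_periodogram(
            EventSeries(np.roll(values, 1440)), p_min=1440, p_max=1440
        )
        assert pg0.statistic[0] == pytest.approx(pg1.statistic[0], rel=1e-9)

    def test_constant_series_rejected(self):
        with pytest.raises(DegenerateDataError):
            g.chi_square_periodogram(EventSeries(np.ones(14 * DAY)))

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="2\\*p_max"):
            g.chi_square_periodogram(EventSeries(np.ones(3000)))


class TestLombScargle:
    def test_noisy_cosine_peak_on_grid(self):
        t = np.arange(14 * DAY, dtype=float)
        y = 2 + np.cos(2 * np.pi * t / 1440) + np.random.default_rng(5).normal(0, 0.1, len(t))
        pg = g.lomb_scargle_periodogram(EventSeries(np.clip(y, 0, None)))
        assert abs(pg.peak_period - 1440) <= 1

    def test_matches_classical_periodogram_on_even_sinusoid(self):
        """At a Fourier frequency of an evenly sampled sinusoid the Lomb power
        equals the classical DFT periodogram |X(f)|^2 / N."""
        n = 2880
        t = np.arange(n, dtype=float)
        y = np.cos(2 * np.pi * t * 4 / n + 0.7)
        yc = y - y.mean()
        dft = np.abs(np.fft.rfft(yc)) ** 2 / n
        mine = lomb_power(t, yc, np.array([2 * np.pi * 4 / n]))[0]
        assert mine == pytest.approx(dft[4], rel=1e-6)

    def test_matches_scipy_reference(self, rng):
        from scipy.signal import lombscargle

        t = np.arange(600, dtype=float)
        y = rng.normal(0, 1, 600)
        y -= y.mean()
        freqs = 2 * np.pi / np.linspace(40, 300, 80)
        np.testing.assert_allclose(
            lomb_power(t, y, freqs), lombscargle(t, y, freqs), rtol=1e-9
        )

    def test_constant_offset_invariance(self, rng):
        values = rng.poisson(0.3, 14 * DAY).astype(float)
        pg0 = g.lomb_scargle_periodogram(EventSeries(values))
        pg1 = g.lomb_scargle_periodogram(EventSeries(values + 3.0))
        np.testing.assert_allclose(pg0.statistic, pg1.statistic, rtol=1e-6)


class TestAcrophase:
    def test_single_phase_events(self):
        values = np.zeros(2 * DAY)
        values[[720, 720 + DAY]] = 1
        res = g.acrophase(EventSeries(values))
        assert res.acrophase_zt == pytest.approx(720)
        assert res.resultant_length == pytest.approx(1.0)

    def test_symmetric_pair_averages_between(self):
        values = np.zeros(DAY)
        values[[660, 780]] = 1
        res = g.acrophase(EventSeries(values))
        assert res.acrophase_zt == pytest.approx(720)

    def test_uniform_events_undefined(self):
        res = g.acrophase(EventSeries(np.ones(DAY)))
        assert not res.defined

    def test_empty_series_rejected(self):
        with pytest.raises(DegenerateDataError):
            g.acrophase(EventSeries(np.zeros(DAY)))

    def test_shift_equivariance(self, rng):
        values = np.zeros(DAY)
        values[rng.integers(0, 300, 40)] += 1
        base = g.acrophase(EventSeries(values)).acrophase_zt
        shifted = g.acrophase(EventSeries(np.roll(values, 200))).acrophase_zt
        assert shifted == pytest.approx((base + 200) % DAY, abs=1e-6)

    def test_von_mises_events_recover_generator_mean(self):
        """Acrophase of von Mises-distributed events within 10 min of ZT16."""
        r = np.random.default_rng(7)
        mu = 2 * np.pi * 960 / DAY
        minutes = ((r.vonmises(mu, 2.0, 2000) % (2 * np.pi)) * DAY / (2 * np.pi)).astype(int)
        values = np.zeros(14 * DAY)
        for m in minutes:
            values[r.integers(0, 14) * DAY + m] += 1
        res = g.acrophase(EventSeries(values))
        assert res.acrophase_zt == pytest.approx(960, abs=10)
        assert res.daily_circular_mean_zt == pytest.approx(960, abs=20)


class TestLightDarkTtest:
    def test_identical_phases_give_t_zero(self):
        values = np.tile(np.ones(DAY), 3)
        res = g.light_dark_ttest(EventSeries(values))
        assert res["t"] == 0.0 and res["p"] == 1.0

    def test_matches_closed_form_pooled_t(self):
        """Hand-computed pooled-variance Student's t on known daily totals."""
        dark = np.array([400.0, 402, 398, 401])
        light = np.array([50.0, 52, 49, 50])
        values = np.zeros(4 * DAY)
        for d in range(4):
            values[d * DAY : d * DAY + int(light[d])] = 1.0
            values[d * DAY + 720 : d * DAY + 720 + int(dark[d])] = 1.0
        res = g.light_dark_ttest(EventSeries(values))
        sp2 = (dark.var(ddof=1) * 3 + light.var(ddof=1) * 3) / 6
        t_hand = (dark.mean() - light.mean()) / np.sqrt(sp2 * (1 / 4 + 1 / 4))
        assert res["t"] == pytest.approx(t_hand)
        assert res["p"] < 0.05
        assert res["mean_dark"] == pytest.approx(dark.mean())

    def test_simulated_nocturnal_locomotion_is_dark_dominant(self, pipeline_default):
        series = EventSeries(pipeline_default.ethogram.event_series("locomotion"))
        res = g.light_dark_ttest(series, pipeline_default.sim.config)
        assert res["mean_dark"] > res["mean_light"]
        assert res["p"] < 0.05

    def test_simulated_sls_is_light_dominant(self, pipeline_default):
        series = EventSeries(pipeline_default.ethogram.event_series("sls"))
        res = g.light_dark_ttest(series, pipeline_default.sim.config)
        assert res["mean_light"] > res["mean_dark"]
        assert res["p"] < 0.05


class TestLinearRegression:
    def test_exact_line(self):
        x = np.arange(10.0)
        res = g.linear_regression(x, 2 * x + 1)
        assert res["slope"] == pytest.approx(2.0)
        assert res["intercept"] == pytest.approx(1.0)
        assert res["r_squared"] == pytest.approx(1.0)

    def test_five_points_match_normal_equations(self):
        x = np.array([1.0, 2, 4, 5, 7])
        y = np.array([2.0, 2.5, 5.5, 5.0, 8.5])
        res = g.linear_regression(x, y)
        slope = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        intercept = y.mean() - slope * x.mean()
        assert res["slope"] == pytest.approx(slope)
        assert res["intercept"] == pytest.approx(intercept)

    def test_null_rejection_rate_near_alpha(self):
        hits = 0
        for seed in range(500):
            r = np.random.default_rng(seed)
            x = r.normal(0, 1, 20)
            y = r.normal(0, 1, 20)
            if g.linear_regression(x, y)["p"] < 0.05:
                hits += 1
        assert 0.02 <= hits / 500 <= 0.09

    def test_zero_variance_x_rejected(self):
        with pytest.raises(DegenerateDataError):
            g.linear_regression(np.ones(5), np.arange(5.0))


class TestEventSeries:
    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            EventSeries(np.array([1.0, -1.0]))

    def test_zt_wraps(self):
        s = EventSeries(np.zeros(2000), t0_zt=1400)
        assert s.zt[0] == 1400 and s.zt[40] == 0
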