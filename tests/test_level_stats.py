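"""Level averages, percentiles, SPD and temporal aggregation."""

from datetime import datetime

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pamkit import (
    BandSeries,
    SpectralConfig,
    SynthSpec,
    exceedance_levels,
    generate,
    mode_level,
    percentile_levels,
    psd_welch,
    rms_average,
    spd,
    summary_stats,
    temporal_aggregate,
)

db_samples = st.lists(
    st.floats(min_value=0.0, max_value=150.0, allow_nan=False), min_size=1, max_size=60
)


class TestRmsAverage:
    def test_constant_input_is_identity(self):
        assert rms_average([60.0, 60.0, 60.0]) == pytest.approx(60.0)

    def test_two_level_hand_value(self):
        # 10*log10((1e6 + 1e7)/2) = 67.4036
        assert rms_average([60.0, 70.0]) == pytest.approx(67.4036, abs=1e-3)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(db_samples)
    def test_jensen_power_mean_at_least_arithmetic_mean(self, levels):
        assert rms_average(levels) >= np.mean(levels) - 1e-9

    def test_rare_loud_windows_push_rms_above_95th_percentile(self):
        # 1 window at +40 dB among 99 at baseline: the power mean is
        # dominated by the single loud event
        levels = np.full(100, 60.0)
        levels[0] = 100.0
        assert rms_average(levels) > np.percentile(levels, 95)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rms_average([])


class TestPercentiles:
    def test_exceedance_l95_is_fifth_percentile(self):
        rng = np.random.default_rng(0)
        levels = rng.normal(70, 5, 500)
        assert exceedance_levels(levels, 95) == pytest.approx(
            np.percentile(levels, 5)
        )

    def test_median_is_fiftieth(self):
        levels = [3.0, 1.0, 2.0, 5.0, 4.0]
        assert percentile_levels(levels, 50) == pytest.approx(np.median(levels))

    def test_order_statistic_interpolation(self):
        # {1..100} at q=5: linear interpolation gives 5.95
        assert percentile_levels(np.arange(1.0, 101.0), 5) == pytest.approx(5.95)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(db_samples, st.floats(min_value=-40, max_value=40))
    def test_equivariant_under_db_offset(self, levels, offset):
        q = [5, 50, 95]
        shifted = percentile_levels(np.asarray(levels) + offset, q)
        np.testing.assert_allclose(
            shifted, percentile_levels(levels, q) + offset, atol=1e-9
        )

    def test_out_of_range_percentage_rejected(self):
        with pytest.raises(ValueError):
            percentile_levels([1.0], 101)


class TestMode:
    def test_constant_input_returns_its_bin_center(self):
        m = mode_level(np.full(50, 63.2), bin_width=1.0)
        assert abs(m.level - 63.2) <= 0.5
        assert not m.multimodal

    def test_unimodal_symmetric_mode_near_median(self):
        rng = np.random.default_rng(1)
        levels = rng.normal(80, 3, 20000)
        m = mode_level(levels, bin_width=1.0)
        assert m.level == pytest.approx(np.median(levels), abs=1.0)

    def test_bimodal_mixture_flags_multimodality(self):
        # 60/40 mixture: the minor peak's density is within 3 dB of the
        # major peak's (10*log10(0.6/0.4) = 1.76 dB), so the flag is set
        # and the reported mode sits in the heavier (lower) hump
        rng = np.random.default_rng(2)
        levels = np.concatenate(
            [rng.normal(50, 1, 6000), rng.normal(80, 1, 4000)]
        )
        m = mode_level(levels, bin_width=1.0)
        assert abs(m.level - 50) <= 2.0
        assert m.multimodal

    def test_well_separated_minor_peak_below_3db_not_flagged(self):
        rng = np.random.default_rng(3)
        levels = np.concatenate(
            [rng.normal(50, 1, 10000), rng.normal(80, 1, 100)]
        )
        assert not mode_level(levels, bin_width=1.0).multimodal


class TestSpd:
    def _grid(self, seed=4, duration=20.0):
        p = generate(
            SynthSpec(
                kind="white_noise",
                duration=duration,
                sample_rate=2000.0,
                seed=seed,
                parameters={"psd_level": 60.0},
            )
        )
        return psd_welch(
            p, SpectralConfig(segment_length=500, overlap=0.0, average_seconds=1.0)
        )

    def test_each_frequency_integrates_to_one(self):
        dist = spd(self._grid())
        integrals = dist.density.sum(axis=1) * dist.bin_width
        np.testing.assert_allclose(integrals, 1.0, atol=1e-12)

    def test_density_nonnegative(self):
        assert np.all(spd(self._grid()).density >= 0)

    def test_db_offset_shifts_density_shape_preserved(self):
        grid = self._grid()
        shifted = type(grid)(
            times=grid.times,
            frequencies=grid.frequencies,
            levels=grid.levels + 10.0,
            config=grid.config,
            p_ref=grid.p_ref,
            sample_rate=grid.sample_rate,
        )
        a, b = spd(grid, 1.0), spd(shifted, 1.0)
        np.testing.assert_allclose(b.level_bin_edges, a.level_bin_edges + 10.0)
        np.testing.assert_allclose(b.density, a.density)

    def test_chi_square_segment_average_distribution(self):
        # stationary Gaussian noise: the K-segment-averaged periodogram at
        # one frequency is chi^2_{2K}/2K-distributed around the true PSD;
        # compare the empirical dB distribution with a Monte-Carlo oracle
        from scipy import stats

        k = 4
        grid = psd_welch(
            generate(
                SynthSpec(
                    kind="white_noise",
                    duration=400.0,
                    sample_rate=500.0,
                    seed=5,
                    parameters={"psd_level": 60.0},
                )
            ),
            SpectralConfig(segment_length=500, overlap=0.0, average_seconds=float(k)),
        )
        observed = grid.levels[50, :]  # one interior frequency, 100 samples
        rng = np.random.default_rng(6)
        oracle = 60.0 + 10 * np.log10(rng.chisquare(2 * k, 20000) / (2 * k))
        res = stats.ks_2samp(observed, oracle)
        assert res.pvalue > 0.01

    def test_single_time_step_rejected(self):
        grid = self._grid(duration=1.0)
        assert grid.levels.shape[1] == 1
        with pytest.raises(ValueError, match="2 time steps"):
            spd(grid)

    def test_noise_floor_narrows_low_tail_at_high_frequency(self):
        # A low-frequency habitat whose level varies slowly over tens of dB,
        # recorded by an instrument with a flat self-noise floor: at
        # floor-dominated high frequencies the lowest populated level bins
        # converge onto the mode, while at signal-dominated low frequencies
        # the distribution keeps a long lower tail.
        from scipy import signal as sps

        from pamkit import CalibrationSpec, apply_calibration, simulate_recorder

        fs, block_s = 2000.0, 2.0
        scene = generate(
            SynthSpec(
                kind="pink_noise",
                duration=120.0,
                sample_rate=fs,
                seed=7,
                parameters={"psd_level": 90.0, "reference_hz": 10.0},
            )
        )
        sos = sps.butter(8, 100.0, btype="lowpass", fs=fs, output="sos")
        x = sps.sosfilt(sos, scene.pressure)
        rng = np.random.default_rng(8)
        block = int(block_s * fs)
        n_blocks = len(x) // block
        gains_db = rng.normal(0.0, 8.0, n_blocks)  # slow level wandering
        x[: n_blocks * block] *= np.repeat(10 ** (gains_db / 20.0), block)
        varied = type(scene)(pressure=x, sample_rate=fs, p_ref=1.0)

        spec = CalibrationSpec(domain="water", end_to_end_sensitivity=-130.0)
        audio = simulate_recorder(varied, spec, bit_depth="float",
                                  self_noise_density=40.0, seed=9)
        p = apply_calibration(audio, spec)
        grid = psd_welch(p, SpectralConfig(segment_length=1000, overlap=0.0,
                                           average_seconds=block_s))
        dist = spd(grid, bin_width=1.0)

        def mode_minus_lowest(f_hz):
            i = np.argmin(np.abs(dist.frequencies - f_hz))
            populated = np.flatnonzero(dist.density[i] > 0)
            mode_bin = np.argmax(dist.density[i])
            return dist.level_bin_centers[mode_bin] - dist.level_bin_centers[populated[0]]

        assert mode_minus_lowest(900.0) < mode_minus_lowest(20.0) / 2


class TestTemporalAggregation:
    def _diel_band_series(self):
        rng = np.random.default_rng(9)
        hours = np.arange(96)  # 4 days hourly
        levels = 60.0 + rng.normal(0, 0.5, 96)
        day = ((hours % 24) >= 6) & ((hours % 24) < 18)
        levels[day] += 10.0
        return BandSeries(
            times=hours * 3600.0,
            band_centers=[63.0],
            band_edges=[(56.2, 70.8)],
            levels=levels[np.newaxis, :],
            labels=["63"],
            start_time=datetime(2013, 10, 19, 0, 0, 0),
        )

    def test_hourly_medians_recover_diel_step(self):
        out = temporal_aggregate(self._diel_band_series(), "hour-of-day", "median")
        day = out[(out.group >= 6) & (out.group < 18)].level_db
        night = out[(out.group < 6) | (out.group >= 18)].level_db
        assert day.mean() - night.mean() == pytest.approx(10.0, abs=1.0)

    def test_single_group_equals_ungrouped_statistic(self):
        series = self._diel_band_series()
        out = temporal_aggregate(series, "month", "median")
        assert len(out) == 1
        assert out.level_db.iloc[0] == pytest.approx(np.median(series.levels))

    def test_boxplot_five_numbers_ordered(self):
        out = temporal_aggregate(self._diel_band_series(), "hour-of-day", "boxplot")
        for _, row in out.iterrows():
            assert row["min"] <= row.q1 <= row["median"] <= row.q3 <= row["max"]

    def test_missing_timestamps_rejected(self):
        series = self._diel_band_series()
        series.start_time = 0.0
        with pytest.raises(ValueError, match="start_time"):
            temporal_aggregate(series, "hour-of-day", "median")


class TestSummaryStats:
    def test_percentiles_monotone_and_bounded(self):
        rng = np.random.default_rng(10)
        stats = summary_stats(rng.normal(70, 8, 1000))
        q = [stats.percentiles[p] for p in sorted(stats.percentiles)]
        assert all(a <= b for a, b in zip(q, q[1:]))
        assert stats.minimum <= min(q) and max(q) <= stats.maximum
        assert stats.rms_level >= stats.median
        box = stats.boxplot()
        assert box["min"] <= box["q1"] <= box["median"] <= box["q3"] <= box["max"]
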