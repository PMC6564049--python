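"""Spike-pattern statistics, checked against naive oracle implementations
and analytic forms."""

import numpy as np
import pytest
from scipy import stats

from vmnnet import SpikeTrain
from vmnnet.analysis import (EmptyTrainError, crosscorrelogram, hazard, iod,
                             iod_range, isi_histogram, isi_modes,
                             oscillation_frequency, pooled_isi_histogram,
                             population_rate, postsynaptic_signal,
                             segment_bistable_states, spike_triggered_average)
from vmnnet.fixtures import (burst_train, poisson_train, regular_train,
                             sinusoid_train)


# --- naive oracles (deliberately dumb, loop-based) -------------------------

def naive_isi_counts(times, binwidth):
    counts = {}
    for a, b in zip(times[:-1], times[1:]):
        idx = int((b - a) // binwidth)
        counts[idx] = counts.get(idx, 0) + 1
    n_bins = max(counts) + 1
    return np.array([counts.get(i, 0) for i in range(n_bins)])


def naive_hazard(times, binwidth):
    isis = [b - a for a, b in zip(times[:-1], times[1:])]
    n_bins = int(max(isis) // binwidth) + 1
    vals = []
    for b in range(n_bins):
        left = b * binwidth
        in_bin = sum(1 for i in isis if left <= i < left + binwidth)
        survivors = sum(1 for i in isis if i >= left)
        vals.append(in_bin / survivors if survivors else 0.0)
    return np.array(vals)


def naive_iod(times, duration, binwidth_ms):
    n_bins = int(duration // binwidth_ms)
    counts = []
    for b in range(n_bins):
        lo, hi = b * binwidth_ms, (b + 1) * binwidth_ms
        counts.append(sum(1 for t in times if lo <= t < hi))
    counts = np.array(counts, dtype=float)
    return counts.var(ddof=1) / counts.mean()


def naive_psp(times, n_bins, amplitude, half_life):
    out = np.zeros(n_bins)
    for k in range(n_bins):
        for t in times:
            spike_bin = int(t)  # 1-ms bins; spike in bin floor(t)
            if spike_bin <= k:
                out[k] += amplitude * 2.0 ** (-(k - spike_bin) / half_life)
    return out


class TestISIHistogram:
    def test_regular_train_single_bin(self):
        train = regular_train(100.0, 1.0)  # ISIs exactly 10 ms
        hist = isi_histogram(train, binwidth=5.0)
        assert hist.counts[2] == hist.n_intervals
        assert hist.normalised[2] == pytest.approx(10_000.0)

    def test_counts_total_n_minus_one(self, small_train):
        hist = isi_histogram(small_train, 5.0)
        assert hist.counts.sum() == small_train.n - 1

    def test_normalisation_totals_10000(self, poisson_5hz_1000s):
        hist = isi_histogram(poisson_5hz_1000s)
        assert hist.normalised.sum() == pytest.approx(10_000.0, abs=1e-6)

    def test_matches_naive_oracle(self, small_train):
        hist = isi_histogram(small_train, 5.0)
        np.testing.assert_array_equal(
            hist.counts, naive_isi_counts(small_train.times, 5.0))

    def test_exponential_isis_match_analytic_cdf(self):
        # 10^4 intervals at 10 Hz: KS against Exp(rate) non-significant
        train = poisson_train(10.0, 1000.0, seed=3)
        isis_s = train.isis / 1000.0
        res = stats.kstest(isis_s, "expon", args=(0, 0.1))
        assert res.pvalue > 0.01

    def test_too_few_spikes_raises(self):
        with pytest.raises(EmptyTrainError):
            isi_histogram(SpikeTrain(np.array([5.0]), 10.0))

    def test_pooled_histogram_counts_all_intervals(self):
        a = regular_train(10.0, 10.0)
        b = regular_train(5.0, 10.0)
        hist = pooled_isi_histogram([a, b], binwidth=5.0)
        assert hist.n_intervals == (a.n - 1) + (b.n - 1)


class TestHazard:
    def test_single_bin_distribution_has_hazard_one(self):
        train = regular_train(100.0, 1.0)
        h = hazard(isi_histogram(train, 5.0))
        assert h.values[2] == pytest.approx(1.0)

    def test_values_in_unit_interval(self, poisson_5hz_1000s):
        h = hazard(isi_histogram(poisson_5hz_1000s))
        assert np.all((h.values >= 0) & (h.values <= 1))

    def test_flat_for_exponential_isis(self):
        # memorylessness: hazard ~ 1 - exp(-r * 5 ms) in well-sampled bins
        train = poisson_train(10.0, 2000.0, seed=4)
        h = hazard(isi_histogram(train))
        expected = 1.0 - np.exp(-10.0 * 0.005)
        well_sampled = h.survivors > 500
        assert np.allclose(h.values[well_sampled], expected, atol=0.02)

    def test_matches_naive_oracle(self):
        train = poisson_train(8.0, 15.0, seed=5)  # ~100 spikes
        h = hazard(isi_histogram(train, 5.0))
        np.testing.assert_allclose(h.values, naive_hazard(train.times, 5.0))

    def test_reconstruction_identity(self, poisson_5hz_1000s):
        """hazard * survivors reproduces the interval counts exactly."""
        hist = isi_histogram(poisson_5hz_1000s)
        h = hazard(hist)
        np.testing.assert_allclose(h.values * h.survivors, hist.counts)


class TestIoD:
    def test_poisson_near_one_at_all_binwidths(self, poisson_5hz_1000s):
        """Poisson IoD is 1 at every timescale, within the null sampling
        error of the estimator (IoD*(n-1) ~ chi^2 with n-1 df for n count
        bins, so SD = sqrt(2/(n-1)))."""
        train = poisson_5hz_1000s
        for bw, val in zip((0.5, 1.0, 2.0, 4.0, 6.0, 8.0, 10.0),
                           iod_range(train).values):
            n_bins = int(train.duration // (bw * 1000.0))
            null_sd = np.sqrt(2.0 / (n_bins - 1))
            assert abs(val - 1.0) < 4 * null_sd, (bw, val)

    def test_regular_train_well_below_one(self):
        # regularity shows at binwidths well beyond the 200-ms ISI; the
        # 0.5-s bin still carries 2-vs-3 count quantisation (IoD = 0.1)
        train = regular_train(5.0, 1000.0)
        vals = iod_range(train).values
        assert vals[0] <= 0.11
        assert np.all(vals[1:] < 0.1)

    def test_bursty_train_above_one_and_rising(self):
        # clustered spiking: IoD >> 1, growing with binwidth while bins
        # stay below the 10-s silence/burst period (at binwidths that are
        # multiples of the period the count variance collapses again)
        train = burst_train(10.0, 5.0, 1000.0, seed=6)
        vals = iod_range(train, binwidths_s=(0.5, 1.0, 2.0, 4.0)).values
        assert np.all(vals > 1.0)
        assert np.all(np.diff(vals) > 0)

    def test_matches_naive_oracle(self):
        train = poisson_train(8.0, 120.0, seed=7)
        got = iod(train, 1.0)
        want = naive_iod(train.times, train.duration, 1000.0)
        assert got == pytest.approx(want, rel=1e-12)

    def test_shift_crop_round_trip_invariance(self):
        train = poisson_train(5.0, 200.0, seed=8)
        shifted = train.shift(5000.0).crop(5000.0)
        assert iod(shifted, 2.0) == pytest.approx(iod(train, 2.0))

    def test_empty_train_flagged(self):
        with pytest.raises(EmptyTrainError):
            iod(SpikeTrain(np.empty(0), 100_000.0), 0.5)


class TestPopulationSignals:
    def test_population_rate_conserves_counts(self):
        trains = [poisson_train(5.0, 50.0, seed=s) for s in range(4)]
        counts = population_rate(trains, 1.0)
        assert counts.sum() == sum(t.n for t in trains)

    def test_single_train_equals_own_counts(self):
        train = poisson_train(5.0, 50.0, seed=9)
        np.testing.assert_array_equal(population_rate([train], 1.0),
                                      train.binned_counts(1.0))

    def test_psp_signal_matches_convolution_oracle(self):
        train = poisson_train(20.0, 5.0, seed=10)
        got = postsynaptic_signal([train], amplitude=3.0, half_life=7.5)
        want = naive_psp(train.times, got.size, 3.0, 7.5)
        np.testing.assert_allclose(got, want, atol=1e-9)

    def test_psp_no_spikes_is_zero(self):
        train = SpikeTrain(np.empty(0), 1000.0)
        assert np.all(postsynaptic_signal([train]) == 0.0)


class TestSpikeTriggeredAverage:
    def test_constant_trace_gives_flat_sta(self):
        trace = np.full(10_000, -55.0)
        train = poisson_train(5.0, 10.0, seed=11)
        lags, sta, dropped = spike_triggered_average(trace, train, 100.0)
        np.testing.assert_allclose(sta, -55.0)
        assert lags[0] == -100.0 and lags[-1] == 100.0

    def test_independent_noise_averages_to_mean(self):
        rng = np.random.default_rng(12)
        trace = rng.normal(0.0, 1.0, 200_000)
        train = poisson_train(5.0, 200.0, seed=13)
        _, sta, _ = spike_triggered_average(trace, train, 50.0)
        se = 1.0 / np.sqrt(train.n)
        assert np.all(np.abs(sta) < 4 * se)

    def test_edge_spikes_dropped_and_counted(self):
        trace = np.zeros(1000)
        train = SpikeTrain(np.array([5.0, 500.0, 998.0]), 1000.0)
        _, _, dropped = spike_triggered_average(trace, train, 100.0)
        assert dropped == 2


class TestCrossCorrelogram:
    def test_identical_trains_peak_at_zero(self):
        train = poisson_train(10.0, 100.0, seed=14)
        centres, counts = crosscorrelogram(train, train, 20.0, 1.0)
        assert centres[np.argmax(counts)] == pytest.approx(0.0, abs=0.5)

    def test_shifted_train_peak_at_shift(self):
        train = poisson_train(10.0, 100.0, seed=15)
        shifted = SpikeTrain(train.times + 5.0, train.duration + 5.0)
        centres, counts = crosscorrelogram(train, shifted, 20.0, 1.0)
        assert centres[np.argmax(counts)] == pytest.approx(5.0, abs=0.5)

    def test_independent_poisson_is_flat(self):
        a = poisson_train(10.0, 500.0, seed=16)
        b = poisson_train(10.0, 500.0, seed=17)
        _, counts = crosscorrelogram(a, b, 50.0, 1.0)
        expected = a.n * b.n / (a.duration / 1.0)  # pairs per 1-ms lag bin
        sd = np.sqrt(expected)
        assert np.all(np.abs(counts - expected) < 4.5 * sd)

    def test_matches_naive_pair_loop(self):
        a = poisson_train(8.0, 12.0, seed=18)
        b = poisson_train(8.0, 12.0, seed=19)
        centres, counts = crosscorrelogram(a, b, 30.0, 2.0)
        edges = np.arange(-30.0, 32.0, 2.0)
        naive = np.zeros(edges.size - 1)
        for ta in a.times:
            for tb in b.times:
                lag = tb - ta
                if -30.0 <= lag < 30.0:
                    naive[int((lag + 30.0) // 2.0)] += 1
        np.testing.assert_array_equal(counts, naive)


class TestOscillationFrequency:
    def test_sinusoid_modulated_population_detected(self):
        trains = [sinusoid_train(5.0, 0.8, 3.0, 200.0, seed=s)
                  for s in range(20)]
        counts = population_rate(trains, 1.0)
        freq, significant, _ = oscillation_frequency(counts)
        assert significant
        assert freq == pytest.approx(3.0, abs=0.1)

    def test_homogeneous_poisson_not_significant(self):
        trains = [poisson_train(5.0, 200.0, seed=100 + s) for s in range(20)]
        counts = population_rate(trains, 1.0)
        _, significant, _ = oscillation_frequency(counts)
        assert not significant

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            oscillation_frequency(np.zeros(50_000))


class TestISIModes:
    def test_regular_train_single_mode(self):
        train = regular_train(5.0, 500.0)  # ISI 200 ms
        modes = isi_modes(isi_histogram(train, 5.0))
        assert modes.size == 1
        assert modes[0] == pytest.approx(202.5, abs=5.0)


class TestBistableSegmentation:
    def test_constant_fast(self):
        segs = segment_bistable_states(np.full(100, 6.0), 1.0)
        assert segs == [(0.0, 100.0, "fast")]

    def test_constant_slow(self):
        segs = segment_bistable_states(np.full(100, 0.85), 1.0)
        assert segs == [(0.0, 100.0, "slow")]

    def test_step_change_boundary(self):
        rate = np.concatenate([np.full(100, 0.85), np.full(100, 6.0)])
        segs = segment_bistable_states(rate, 1.0)
        assert [s[2] for s in segs] == ["slow", "fast"]
        # boundary within the smoothing window of the true step at 100 s
        assert segs[0][1] == pytest.approx(100.0, abs=10.0)

    def test_short_blips_merged(self):
        rate = np.full(200, 0.5)
        rate[50:53] = 10.0  # 3-s blip, below the 10-s minimum duration
        segs = segment_bistable_states(rate, 1.0)
        assert [s[2] for s in segs] == ["slow"]
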