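"""Population analytics: PSTH, selectivity sorting, phase, bursts, spectra."""

import numpy as np
import pytest

from oscmux import analysis
from oscmux.params import ConfigurationError
from oscmux.srnn_core import SpikeTrain


def _train(neurons, times, duration=1000.0, size=None):
    neurons = np.asarray(neurons, int)
    size = int(neurons.max()) + 1 if size is None and len(neurons) else \
        (size or 1)
    return SpikeTrain(neurons=neurons, times=np.asarray(times, float),
                      duration=duration, size=size)


class TestPSTH:
    def test_empty_trials_give_zero_rates(self):
        out = analysis.psth([_train([], [], size=4)], size=4)
        assert np.all(out == 0)

    def test_single_spike_has_unit_mass(self):
        out = analysis.psth([_train([0], [500.0], size=1)], size=1,
                            bin_ms=2.5)
        # integral of the rate (Hz) over time (s) equals one spike
        assert out[0].sum() * 2.5 / 1000.0 == pytest.approx(1.0, rel=1e-6)

    def test_trial_averaging(self):
        a = _train([0], [100.0], size=1)
        b = _train([0], [100.0], size=1)
        avg = analysis.psth([a, b], size=1)
        single = analysis.psth([a], size=1)
        assert np.allclose(avg, single)


class TestSelectivity:
    def _staggered(self, n=20, n_bins=200):
        rates = np.zeros((n, n_bins))
        for i in range(n):
            c = 10 + i * 9
            rates[i] = np.exp(-0.5 * ((np.arange(n_bins) - c) / 5.0) ** 2)
        return rates

    def test_recovers_construction_order(self):
        rates = self._staggered()
        rng = np.random.default_rng(0)
        perm = rng.permutation(20)
        sel = analysis.selectivity_sort(rates[perm])
        assert np.array_equal(sel.retained[sel.order], np.argsort(perm))

    def test_rows_are_z_scored(self):
        sel = analysis.selectivity_sort(self._staggered())
        assert np.max(np.abs(sel.z.mean(axis=1))) < 1e-9
        assert np.max(np.abs(sel.z.std(axis=1) - 1)) < 1e-9

    def test_sorting_is_idempotent(self):
        sel = analysis.selectivity_sort(self._staggered())
        again = analysis.selectivity_sort(sel.z)
        assert np.array_equal(again.order, np.arange(len(sel.z)))

    def test_inactive_neurons_dropped(self):
        rates = self._staggered()
        rates[5] = 0.0
        sel = analysis.selectivity_sort(rates)
        assert 5 not in sel.retained
        assert sel.active_fraction == pytest.approx(19 / 20)

    def test_all_inactive_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            sel = analysis.selectivity_sort(np.zeros((4, 10)))
        assert sel.z.shape[0] == 0


class TestThetaPhase:
    def test_pure_tone_phase_advances_linearly(self):
        dt = 1.0
        t = np.arange(0, 3000.0, dt)
        rate = np.sin(2 * np.pi * 8.0 * t / 1000.0)
        phase = analysis.theta_phase(rate, dt)
        slope = np.polyfit(t[500:-500] / 1000.0,
                           np.unwrap(phase)[500:-500], 1)[0]
        assert abs(slope - 2 * np.pi * 8.0) / (2 * np.pi * 8.0) < 0.02

    def test_noisy_tone_slope_within_two_percent(self):
        rng = np.random.default_rng(4)
        dt = 1.0
        t = np.arange(0, 4000.0, dt)
        rate = np.sin(2 * np.pi * 8.0 * t / 1000.0) + \
            0.2 * rng.normal(size=t.size)
        phase = analysis.theta_phase(rate, dt)
        slope = np.polyfit(t[500:-500] / 1000.0,
                           np.unwrap(phase)[500:-500], 1)[0]
        assert abs(slope - 2 * np.pi * 8.0) / (2 * np.pi * 8.0) < 0.02

    def test_chirp_tracks_instantaneous_frequency(self):
        dt = 1.0
        t = np.arange(0, 5000.0, dt) / 1000.0
        f0, f1 = 6.0, 10.0
        finst = f0 + (f1 - f0) * t / t[-1]
        phase_true = 2 * np.pi * np.cumsum(finst) * dt / 1000.0
        rate = np.sin(phase_true)
        ph = np.unwrap(analysis.theta_phase(rate, dt))
        est = np.gradient(ph, t)[1000:-1000] / (2 * np.pi)
        assert np.max(np.abs(est - finst[1000:-1000])) < 1.0  # Hz

    def test_too_short_rejected(self):
        with pytest.raises(ConfigurationError):
            analysis.theta_phase(np.zeros(100), 1.0)


def _brute_force_bursts(times, k=3, window=50.0):
    """Independent greedy oracle: scan every index, consume triplets."""
    out = []
    i = 0
    times = list(times)
    while i + k - 1 < len(times):
        if times[i + k - 1] - times[i] <= window:
            out.append(times[i])
            i += k
        else:
            i += 1
    return out


class TestBursts:
    @pytest.mark.parametrize("times,expected", [
        ([0.0, 10.0, 20.0], [0.0]),
        ([0.0, 30.0, 70.0], []),
        ([0.0, 10.0, 20.0, 30.0], [0.0]),       # overlapping triplets merge
        ([0.0, 10.0, 20.0, 25.0, 30.0, 40.0], [0.0, 25.0]),
        ([], []),
        ([5.0], []),
    ])
    def test_known_patterns(self, times, expected):
        assert analysis.detect_bursts(np.array(times)).tolist() == expected

    def test_matches_bruteforce_on_poisson_trains(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            t = np.sort(rng.uniform(0, 2000.0, rng.integers(5, 120)))
            got = analysis.detect_bursts(t).tolist()
            assert got == _brute_force_bursts(t)

    def test_unsorted_input_rejected(self):
        with pytest.raises(ConfigurationError):
            analysis.detect_bursts(np.array([5.0, 1.0, 9.0]))


class TestSpectra:
    def test_sinusoidal_rate_peak_frequency(self):
        dt = 1.0
        t = np.arange(0, 4000.0, dt)
        rate = 5 + 4 * np.sin(2 * np.pi * 8.0 * t / 1000.0)
        f = analysis.dominant_frequency(rate, dt)
        assert f == pytest.approx(8.0, abs=0.5)

    def test_white_noise_has_no_dominant_peak(self):
        rng = np.random.default_rng(2)
        assert analysis.dominant_frequency(rng.normal(5, 1, 4000),
                                           1.0) is None

    def test_synchrony_ratio_separates_collective_from_regular(self):
        rng = np.random.default_rng(3)
        n, dur = 100, 4000.0
        # asynchronous: independent regular trains with jittered rates
        neurons, times = [], []
        for i in range(n):
            period = 80.0 + 40.0 * rng.random()
            t = np.arange(rng.uniform(0, period), dur, period)
            times.append(t)
            neurons.append(np.full(t.size, i))
        async_train = _train(np.concatenate(neurons),
                             np.concatenate(times), dur, n)
        order = np.argsort(async_train.times)
        async_train.times = async_train.times[order]
        async_train.neurons = async_train.neurons[order]
        # synchronous: all neurons spike together every 100 ms
        ev = np.arange(50.0, dur, 100.0)
        sync_train = _train(np.tile(np.arange(n), ev.size),
                            np.repeat(ev, n) + rng.normal(0, 2,
                                                          ev.size * n),
                            dur, n)
        order = np.argsort(sync_train.times)
        sync_train.times = np.clip(sync_train.times[order], 0, dur - 1e-6)
        sync_train.neurons = sync_train.neurons[order]
        f_async, r_async = analysis.synchrony_spectrum(async_train)
        f_sync, r_sync = analysis.synchrony_spectrum(sync_train)
        assert r_sync > 5 * r_async
        assert f_sync == pytest.approx(10.0, abs=0.5)


class TestPCA:
    def test_rank_one_data_loads_on_first_component(self):
        t = np.linspace(0, 1, 100)
        X = np.outer(np.sin(2 * np.pi * t), np.random.default_rng(0)
                     .normal(size=30))
        proj = analysis.pca_trajectory(X)
        var = proj.var(axis=0)
        assert var[0] / var.sum() > 0.999

    def test_too_few_samples_rejected(self):
        with pytest.raises(ConfigurationError):
            analysis.pca_trajectory(np.zeros((2, 5)))


class TestCurrentDecomposition:
    def test_missing_traces_rejected(self):
        with pytest.raises(ConfigurationError):
            analysis.current_decomposition({"rate": np.zeros(10)},
                                           np.array([1.0]))

    def test_zero_conductances_give_zero_recurrent_currents(self):
        n_t, n = 200, 5
        traces = {
            "t_rec": np.arange(n_t) * 2.5,
            "V": np.full((n_t, n), -60.0),
            "g_ex": np.zeros((n_t, n)),
            "g_in": np.zeros((n_t, n)),
            "I_ext": np.ones((n_t, n)),
        }
        out = analysis.current_decomposition(
            traces, np.full(n, 250.0), window_ms=100.0)
        assert np.all(out["excitation"] == 0)
        assert np.all(out["inhibition"] == 0)
        assert np.all(out["combined"] == out["external"])


class TestNetworkCurrentAlignment:
    def test_combined_current_elevated_at_selectivity_peaks(self):
        # build a driven network, find each neuron's selectivity peak,
        # and check that its summed input current is elevated there
        from oscmux import drive, srnn_core as core
        from oscmux.params import MAIN_SRNN

        pop = core.sample_population(MAIN_SRNN, 300, seed=11)
        W = core.build_recurrent_weights(300, 0.1, 1.0, seed=12)
        bank = drive.sample_bank(4, 5.0, 10.0, A=30.0, seed=13)
        proj = drive.build_projection(300, 4, 0.3, 1.0, seed=14)
        S = drive.signals(bank, np.arange(int(1000 / 0.05)) * 0.05)
        spk, tr = core.run(pop, W, (proj.M, S), 1000.0, seed=15,
                           record=core.RecordConfig(every_ms=2.5,
                                                    record_traces=True))
        rates = analysis.psth([spk], size=300)
        sel = analysis.selectivity_sort(rates)
        peaks = (np.argmax(sel.z, axis=1) + 0.5) * sel.bin_ms
        out = analysis.current_decomposition(
            tr, peaks, window_ms=150.0,
            neurons=sel.retained[sel.order])
        c = out["combined"]
        assert c[len(c) // 2] > c.mean()
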