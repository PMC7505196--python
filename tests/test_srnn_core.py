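"""Core simulator: parameter sampling, weights, LIF dynamics, clamping."""

import numpy as np
import pytest

from oscmux import srnn_core as core
from oscmux.params import MAIN_SRNN, ConfigurationError


class TestSamplePopulation:
    def test_exact_excitatory_count_and_moments(self):
        pop = core.sample_population(MAIN_SRNN, 1000, seed=1)
        assert pop.n_excitatory == 800
        # E_L stays unbiased despite the ordering constraints
        se = 1.2 / np.sqrt(1000)
        assert abs(pop.E_L.mean() - (-60.0)) < 3 * se

    def test_threshold_spread_matches_table(self):
        pop = core.sample_population(MAIN_SRNN, 10000, seed=7)
        assert abs(pop.V_theta.std() - 0.5) / 0.5 < 0.05

    def test_zero_sigma_collapses_to_means(self, zero_sigma_table):
        pop = core.sample_population(zero_sigma_table, 10, seed=3)
        assert np.all(pop.E_L == -60.0)
        assert np.all(pop.V_theta == -50.0)
        assert np.all(pop.tau_in == 20.0)

    def test_ordering_and_positivity_invariants(self):
        pop = core.sample_population(MAIN_SRNN, 2000, seed=5)
        assert np.all(pop.V_reset <= pop.E_L)
        assert np.all(pop.E_L < pop.V_theta)
        for f in ("R", "C", "tau_ref", "T_delay", "tau_ex", "tau_in"):
            assert np.all(getattr(pop, f) > 0)

    def test_deterministic_given_seed(self):
        a = core.sample_population(MAIN_SRNN, 50, seed=9)
        b = core.sample_population(MAIN_SRNN, 50, seed=9)
        assert np.array_equal(a.V_theta, b.V_theta)
        assert np.array_equal(a.T_delay, b.T_delay)

    @pytest.mark.parametrize("size,frac", [(0, 0.8), (-5, 0.8), (10, 0.0),
                                           (10, 1.0)])
    def test_invalid_arguments_rejected(self, size, frac):
        with pytest.raises(ConfigurationError):
            core.sample_population(MAIN_SRNN, size, frac_ex=frac)

    def test_missing_field_named_in_error(self):
        import dataclasses

        with pytest.raises(ConfigurationError, match="tau_in"):
            dataclasses.replace(
                MAIN_SRNN,
                fields={k: v for k, v in MAIN_SRNN.fields.items()
                        if k != "tau_in"})


class TestRecurrentWeights:
    def test_density_within_binomial_band(self):
        W = core.build_recurrent_weights(1000, 0.1, 1.0, seed=2)
        n_pairs = 1000 * 999
        expect = n_pairs * 0.1
        sd = np.sqrt(n_pairs * 0.1 * 0.9)
        assert abs(W.nnz - expect) < 3 * sd
        assert np.all(W.magnitudes.data >= 0)

    def test_no_self_connections(self):
        W = core.build_recurrent_weights(200, 0.5, 1.0, seed=4)
        assert np.all(W.magnitudes.diagonal() == 0)

    def test_half_normal_second_moment(self):
        # E[w^2] of |N(0, sigma)| equals sigma^2
        W = core.build_recurrent_weights(2000, 0.1, 1.0, seed=8)
        emp = np.mean(W.magnitudes.data ** 2)
        assert abs(emp - W.sigma ** 2) / W.sigma ** 2 < 0.05

    def test_zero_gain_gives_zero_magnitudes(self):
        W = core.build_recurrent_weights(50, 1.0, 0.0, seed=1)
        assert W.magnitudes.nnz == 0 or np.all(W.magnitudes.data == 0)

    def test_invalid_density_rejected(self):
        with pytest.raises(ConfigurationError):
            core.build_recurrent_weights(100, 0.0, 1.0)
        with pytest.raises(ConfigurationError):
            core.build_recurrent_weights(100, 1.5, 1.0)

    def test_sigma_follows_balanced_scaling(self):
        W = core.build_recurrent_weights(1000, 0.1, 1.0, seed=0)
        assert W.sigma == pytest.approx(1.0 / np.sqrt(100.0))


class TestDynamics:
    def test_leak_fixed_point(self, zero_sigma_table):
        tab = zero_sigma_table.with_overrides(I_tonic=(0.0, 0.0))
        pop = core.sample_population(tab, 3, frac_ex=0.5, seed=0)
        state = core.init_state(pop, seed=0, v_init="rest")
        for _ in range(100):
            state, spiked = core.step(state, pop, None, np.zeros(3))
            assert not spiked.any()
        assert np.allclose(state.V, pop.E_L)

    def test_tonic_charging_matches_closed_form(self, zero_sigma_table):
        # V(t) = E_L + I R (1 - exp(-t / RC)), error < 0.5% of I R
        pop = core.sample_population(zero_sigma_table, 2, frac_ex=0.5,
                                     seed=0)
        state = core.init_state(pop, seed=0, v_init="rest")
        _, tr = core.run(pop, None, None, 40.0, seed=0, state=state,
                         record=core.RecordConfig(every_ms=0.05,
                                                  record_traces=True))
        t = tr["t_rec"]
        R, C, I = 0.1, 200.0, 90.0  # GOhm, pF, pA
        analytic = -60.0 + I * R * (1 - np.exp(-t / (R * C)))
        err = np.max(np.abs(tr["V"][:, 0] - analytic)) / (I * R)
        assert err < 0.005

    def test_synaptic_kick_decays_like_closed_form(self, zero_sigma_table):
        # presynaptic spike at t0, delay 1 ms: g_ex jumps by G_ex * w then
        # decays as exp(-t/tau_ex) within 1%
        import scipy.sparse as sp

        tab = zero_sigma_table.with_overrides(I_tonic=(0.0, 0.0))
        pop = core.sample_population(tab, 2, frac_ex=0.5, seed=0)
        w = 0.7
        mat = sp.csc_matrix(([w], ([1], [0])), shape=(2, 2))
        W = core.SynapticMatrix(mat, density=1.0, sigma=0.0, gain=1.0)
        drive = np.zeros((int(50 / 0.05), 2))
        drive[:60, 0] = 3000.0  # force one presynaptic spike early
        state = core.init_state(pop, seed=0, v_init="rest")
        spikes, tr = core.run(pop, W, drive, 50.0, state=state,
                              record=core.RecordConfig(every_ms=0.05,
                                                       record_traces=True))
        pre = spikes.times[spikes.neurons == 0]
        assert len(pre) == 1
        g = tr["g_ex"][:, 1]
        jump = g.max()
        assert jump == pytest.approx(0.020 * w, rel=1e-9)  # pS -> nS
        i0 = int(np.argmax(g))
        t_rel = (np.arange(len(g)) - i0) * 0.05
        sel = t_rel > 0
        analytic = jump * np.exp(-t_rel[sel] / 20.0)
        assert np.max(np.abs(g[sel] - analytic)) / jump < 0.01

    def test_dale_routing_by_presynaptic_identity(self, zero_sigma_table):
        # one E and one I presynaptic neuron onto the same target: the E
        # spike raises only g_ex, the I spike only g_in
        import scipy.sparse as sp

        tab = zero_sigma_table.with_overrides(I_tonic=(0.0, 0.0))
        pop = core.sample_population(tab, 3, frac_ex=1 / 3, seed=0)
        assert pop.is_excitatory[0] and not pop.is_excitatory[1]
        mat = sp.csc_matrix(([1.0, 1.0], ([2, 2], [0, 1])), shape=(3, 3))
        W = core.SynapticMatrix(mat, 1.0, 0.0, 1.0)
        drive = np.zeros((int(10 / 0.05), 3))
        drive[:60, 0] = 3000.0
        state = core.init_state(pop, seed=0, v_init="rest")
        _, tr = core.run(pop, W, drive, 10.0, state=state,
                         record=core.RecordConfig(every_ms=0.05,
                                                  record_traces=True))
        assert tr["g_ex"][:, 2].max() > 0
        assert tr["g_in"][:, 2].max() == 0
        drive2 = np.zeros((int(10 / 0.05), 3))
        drive2[:60, 1] = 3000.0
        state2 = core.init_state(pop, seed=0, v_init="rest")
        _, tr2 = core.run(pop, W, drive2, 10.0, state=state2,
                          record=core.RecordConfig(every_ms=0.05,
                                                   record_traces=True))
        assert tr2["g_in"][:, 2].max() > 0
        assert tr2["g_ex"][:, 2].max() == 0

    def test_refractory_floor_on_isis(self, tiny_population, tiny_weights,
                                      tiny_driven_run):
        spikes = tiny_driven_run["spikes"]
        for i in range(tiny_population.size):
            t = np.sort(spikes.for_neuron(i))
            if len(t) > 1:
                assert np.min(np.diff(t)) >= tiny_population.tau_ref[i] - 1e-9

    def test_conductances_stay_nonnegative(self, tiny_driven_run):
        tr = tiny_driven_run["traces"]
        assert tr["g_ex"].min() >= 0
        assert tr["g_in"].min() >= 0

    def test_spike_times_inside_run(self, tiny_driven_run):
        spikes = tiny_driven_run["spikes"]
        assert np.all(spikes.times > 0)
        assert np.all(spikes.times <= spikes.duration + 1e-9)

    def test_identical_seeds_identical_spikes(self, tiny_population,
                                              tiny_weights):
        a, _ = core.run(tiny_population, tiny_weights, None, 300.0, seed=5)
        b, _ = core.run(tiny_population, tiny_weights, None, 300.0, seed=5)
        assert np.array_equal(a.neurons, b.neurons)
        assert np.array_equal(a.times, b.times)

    def test_zero_duration_empty_train(self, tiny_population, tiny_weights):
        spikes, _ = core.run(tiny_population, tiny_weights, None, 0.0,
                             seed=1)
        assert len(spikes) == 0

    def test_nonfinite_drive_raises_with_location(self, tiny_population):
        drive = np.zeros((int(5 / 0.05), 100))
        drive[40, 7] = np.nan
        with pytest.raises(core.NumericalInstabilityError) as exc:
            core.run(tiny_population, None, drive, 5.0, seed=0)
        assert exc.value.neuron == 7


class TestClamping:
    def test_clamp_all_silences_network(self, tiny_population, tiny_weights):
        spikes, _ = core.run(tiny_population, tiny_weights, None, 300.0,
                             seed=3, clamped=np.arange(100))
        assert len(spikes) == 0

    def test_clamp_none_is_identity(self, tiny_population, tiny_weights):
        a, _ = core.run(tiny_population, tiny_weights, None, 300.0, seed=3)
        b, _ = core.run(tiny_population, tiny_weights, None, 300.0, seed=3,
                        clamped=[])
        assert np.array_equal(a.times, b.times)

    def test_clamped_neurons_pinned_at_rest(self, tiny_population,
                                            tiny_weights):
        state = core.init_state(tiny_population, seed=0)
        core.clamp_neurons(state, [0, 1, 2])
        spikes, tr = core.run(tiny_population, tiny_weights, None, 100.0,
                              state=state,
                              record=core.RecordConfig(every_ms=2.5,
                                                       record_traces=True))
        assert not np.any(np.isin(spikes.neurons, [0, 1, 2]))
        # V pinned at E_L after the first recorded step
        assert np.allclose(tr["V"][1:, :3], tiny_population.E_L[:3])

    def test_invalid_indices_rejected(self, tiny_population):
        state = core.init_state(tiny_population, seed=0)
        with pytest.raises(ConfigurationError):
            core.clamp_neurons(state, [5, 5])
        with pytest.raises(ConfigurationError):
            core.clamp_neurons(state, [100])


class TestDriveForms:
    def test_callable_drive_matches_dense(self, tiny_population,
                                          tiny_weights):
        rng = np.random.default_rng(8)
        M = rng.normal(size=(100, 2))

        def drive_fn(t_ms):
            s = np.column_stack([np.sin(2 * np.pi * 4 * t_ms / 1000.0),
                                 np.sin(2 * np.pi * 5 * t_ms / 1000.0)])
            return (M @ s.T).T * 10.0

        t = np.arange(int(200 / 0.05)) * 0.05
        dense = drive_fn(t)
        a, _ = core.run(tiny_population, tiny_weights, drive_fn, 200.0,
                        seed=4)
        b, _ = core.run(tiny_population, tiny_weights, dense, 200.0,
                        seed=4)
        assert np.array_equal(a.times, b.times)
        assert np.array_equal(a.neurons, b.neurons)
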