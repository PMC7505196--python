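"""Targets, training protocol, clamping, multitask, rescaling."""

import numpy as np
import pytest
from scipy import signal as ss

from oscmux import readout, tasks
from oscmux.params import ConfigurationError


@pytest.fixture(scope="module")
def tiny_system():
    return tasks.build_driven_network(size=120, freqs=[4.0, 5.0], seed=21)


@pytest.fixture(scope="module")
def tiny_protocol():
    return tasks.ExperimentProtocol(n_epochs=3, trial_duration=500.0,
                                    seed=5, n_test_trials=2,
                                    burn_in_trials=1)


@pytest.fixture(scope="module")
def tiny_trained(tiny_system, tiny_protocol):
    target = tasks.make_filtered_noise_target(500.0, seed=91)
    return tasks.train_network(tiny_system, target, tiny_protocol)


class TestNoiseTarget:
    def test_power_concentrated_below_cutoff(self):
        # the zero-phase 4th-order design keeps ~97% of the power in
        # band; average a few seeds to tame periodogram fluctuations
        fracs = []
        for seed in range(5):
            target = tasks.make_filtered_noise_target(20000.0, cutoff=6.0,
                                                      seed=seed)
            f, p = ss.periodogram(target.y[:, 0],
                                  fs=1000.0 / target.grid_ms)
            fracs.append(p[f <= 6.0].sum() / p.sum())
        assert np.mean(fracs) >= 0.95

    def test_disabled_filter_returns_raw_noise(self):
        t1 = tasks.make_filtered_noise_target(1000.0, cutoff=1e9, seed=4)
        rng = np.random.default_rng(4)
        assert np.allclose(t1.y[:, 0], rng.normal(0, 30, 400))

    def test_same_seed_is_reproducible(self):
        a = tasks.make_filtered_noise_target(1000.0, seed=6)
        b = tasks.make_filtered_noise_target(1000.0, seed=6)
        assert np.array_equal(a.y, b.y)

    def test_band_pass_variant(self):
        target = tasks.make_filtered_noise_target(8000.0, seed=8,
                                                  band=(5.0, 20.0))
        f, p = ss.periodogram(target.y[:, 0], fs=1000.0 / target.grid_ms)
        inside = p[(f >= 5.0) & (f <= 20.0)].sum() / p.sum()
        assert inside >= 0.9

    def test_invalid_duration(self):
        with pytest.raises(ConfigurationError):
            tasks.make_filtered_noise_target(0.0)


class TestShapeTarget:
    def test_circle_has_constant_radius(self):
        t = tasks.make_shape_target("circle", 500.0)
        r = np.hypot(t.y[:, 0], t.y[:, 1])
        assert np.allclose(r, 1.0, atol=1e-9)

    def test_closed_curves(self):
        for shape in ("circle", "star"):
            t = tasks.make_shape_target(shape, 500.0)
            assert np.allclose(t.y[0], t.y[-1], atol=1e-9)

    def test_star_five_fold_symmetry(self):
        t = tasks.make_shape_target("star", 1000.0)
        pts = t.y
        ang = 2 * np.pi / 5
        rot = pts @ np.array([[np.cos(ang), np.sin(ang)],
                              [-np.sin(ang), np.cos(ang)]]).T
        # rotated vertex set stays on the original outline
        from scipy.spatial import cKDTree

        d, _ = cKDTree(pts).query(rot)
        assert d.max() < 0.05

    def test_unknown_shape_rejected(self):
        with pytest.raises(ConfigurationError):
            tasks.make_shape_target("triangle", 500.0)


class TestTraining:
    def test_history_and_finite_result(self, tiny_trained):
        hist = tiny_trained.history
        assert list(hist["epoch"]) == [1, 2, 3]
        assert np.isfinite(tiny_trained.final_test_r)

    def test_test_trials_do_not_mutate_readout(self, tiny_system,
                                               tiny_protocol, tiny_trained):
        W_before = tiny_trained.rls.W_out.copy()
        P_before = tiny_trained.rls.P.copy()
        state = tiny_system.fresh_state(seed=3)
        tasks._averaged_output(tiny_system, state, tiny_protocol,
                               tiny_trained.rls.W_out)
        assert np.array_equal(tiny_trained.rls.W_out, W_before)
        assert np.array_equal(tiny_trained.rls.P, P_before)

    def test_grid_mismatch_rejected(self, tiny_system, tiny_protocol):
        bad = tasks.make_filtered_noise_target(500.0, grid=5.0, seed=1)
        with pytest.raises(ConfigurationError):
            tasks.train_network(tiny_system, bad, tiny_protocol)

    def test_zero_epoch_baseline_reported(self, tiny_system):
        proto = tasks.ExperimentProtocol(n_epochs=0, trial_duration=500.0,
                                         seed=2, n_test_trials=1,
                                         burn_in_trials=0)
        target = tasks.make_filtered_noise_target(500.0, seed=1)
        res = tasks.train_network(tiny_system, target, proto)
        assert res.history["test_r"].iloc[-1] == 0.0


class TestClamping:
    def test_full_clamp_flagged_degenerate(self, tiny_trained):
        curve = tasks.clamping_curve(tiny_trained, [1.0], seed=0)
        assert bool(curve["degenerate_output"].iloc[0])
        assert curve["test_r"].iloc[0] == 0.0

    def test_fraction_zero_reproduces_unclamped_test(self, tiny_trained):
        curve = tasks.clamping_curve(tiny_trained, [0.0], seed=0)
        assert np.isfinite(curve["test_r"].iloc[0])
        assert not curve["degenerate_output"].iloc[0]

    def test_invalid_fraction_rejected(self, tiny_trained):
        with pytest.raises(ConfigurationError):
            tasks.clamping_curve(tiny_trained, [1.5], seed=0)


class TestMultitask:
    def test_two_shapes_two_cues_smoke(self, tiny_system):
        proto = tasks.ExperimentProtocol(n_epochs=2, trial_duration=500.0,
                                         seed=9, n_test_trials=1,
                                         burn_in_trials=1)
        rng = np.random.default_rng(0)
        configs = [rng.uniform(-np.pi, np.pi, 2) for _ in range(2)]
        targets = [tasks.make_shape_target("circle", 500.0),
                   tasks.make_shape_target("star", 500.0)]
        out = tasks.multitask_train(tiny_system, configs, targets, proto)
        assert len(out["test_r"]) == 2
        assert out["outputs"][0].shape == (200, 2)
        assert len(out["unseen_r"]) == 2

    def test_mismatched_lengths_rejected(self, tiny_system):
        proto = tasks.ExperimentProtocol(n_epochs=1, trial_duration=500.0)
        with pytest.raises(ConfigurationError):
            tasks.multitask_train(
                tiny_system, [np.zeros(2)],
                [tasks.make_shape_target("circle", 500.0),
                 tasks.make_shape_target("star", 500.0)], proto)


class TestRescaling:
    def test_identity_factor_close_to_baseline(self, tiny_trained):
        res = tasks.rescaling_experiment(tiny_trained, [1.0], seed=3)
        assert res.r.shape == (1, 1)
        assert np.isfinite(res.r[0, 0])

    def test_factor_changes_run_duration(self, tiny_trained):
        res = tasks.rescaling_experiment(tiny_trained, [0.5, 1.0, 2.0],
                                         seed=3)
        assert res.r.shape == (1, 3)

    def test_nonpositive_factor_rejected(self, tiny_trained):
        with pytest.raises(ConfigurationError):
            tasks.rescaling_experiment(tiny_trained, [0.0], seed=1)

    def test_frame_output(self, tiny_trained):
        res = tasks.rescaling_experiment(tiny_trained, [1.0, 2.0],
                                         noise_sigmas=[0.0, 1.0], seed=2)
        df = res.to_frame()
        assert len(df) == 4
        assert set(df.columns) == {"noise_sigma", "factor", "test_r"}


class TestCapacityMap:
    def test_single_cell_grid(self):
        proto = tasks.ExperimentProtocol(n_epochs=2, trial_duration=500.0,
                                         seed=4, n_test_trials=1,
                                         burn_in_trials=1)
        grid = tasks.capacity_map([500.0], [6.0], proto, size=120,
                                  n_inp=2)
        assert len(grid) == 1
        assert np.isfinite(grid["test_r"].iloc[0])

    def test_empty_grid_rejected(self):
        proto = tasks.ExperimentProtocol(n_epochs=1)
        with pytest.raises(ConfigurationError):
            tasks.capacity_map([], [6.0], proto)
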