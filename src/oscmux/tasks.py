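"""Experiment protocols: target generation, RLS training, robustness.

The canonical task drives a reservoir with a small bank of sinusoids,
trains the excitatory-to-readout weights by recursive least squares on a
2.5 ms grid against a low-pass-filtered noise target, and interleaves
frozen test trials.  On top of that sit the robustness protocols:
clamping an increasing fraction of neurons, multitask training cued by
input phase configurations, the duration-by-frequency capacity map, and
temporal rescaling of a learned output by compressing or expanding all
input periods by a common factor.

Trials run back to back in one continuous simulation (membrane state
carries over; input phases are reset at every trial onset), after a
burn-in trial that lets the network settle onto its input-locked
trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import signal as ss

from . import readout, srnn_core as core
from .drive import (InputProjection, OscillatorBank, PhaseJitterConfig,
                    build_projection, fixed_bank, jitter_phases,
                    rescale_bank, reset_phases, sample_bank, signals)
from .params import DT_MS, GRID_MS, MAIN_SRNN, ConfigurationError, \
    ParameterTable
from .readout import TargetSignal

__all__ = [
    "DrivenNetwork", "ExperimentProtocol", "TrainResult", "RescalingResult",
    "build_driven_network", "make_filtered_noise_target",
    "make_shape_target", "train_network", "clamping_curve",
    "multitask_train", "capacity_map", "rescaling_experiment",
]


@dataclass
class ExperimentProtocol:
    """Training schedule shared by all supervised tasks."""

    n_epochs: int = 10
    trial_duration: float = 1000.0   # ms
    test_every: int = 1              # frozen test trial every k epochs
    n_test_trials: int = 5           # outputs averaged per evaluation
    seed: int = 0
    noise_sigma: float = 0.0         # white noise on the input unit signals
    jitter: Optional[PhaseJitterConfig] = None
    alpha: float = 1e-2              # RLS P(0) = I/alpha
    grid: float = GRID_MS
    dt: float = DT_MS
    burn_in_trials: int = 2

    def __post_init__(self):
        if self.n_epochs < 0:
            raise ConfigurationError("n_epochs must be >= 0")
        if self.trial_duration <= 0:
            raise ConfigurationError("trial_duration must be positive")


@dataclass
class DrivenNetwork:
    """A reservoir plus its oscillatory input bank and projection."""

    network: core.Network
    bank: Optional[OscillatorBank]
    projection: Optional[InputProjection]
    seed: int = 0

    @property
    def population(self) -> core.NeuronPopulation:
        return self.network.population

    @property
    def exc_readout_indices(self) -> np.ndarray:
        return self.population.excitatory_indices

    def fresh_state(self, seed: int) -> core.NetworkState:
        return core.init_state(self.population, seed=seed)

    def trial_drive(self, n_steps: int, dt: float,
                    bank: Optional[OscillatorBank] = None,
                    noise_sigma: float = 0.0,
                    jitter: Optional[PhaseJitterConfig] = None,
                    rng: Optional[np.random.Generator] = None):
        """Low-rank (M, S) drive for one trial with phases reset at onset."""
        bank = self.bank if bank is None else bank
        if bank is None or self.projection is None:
            return None
        t = np.arange(n_steps) * dt
        phases = None
        if jitter is not None and jitter.sigma_phi_sq > 0:
            cfg = replace(jitter, seed=int(rng.integers(2 ** 31))
                          if rng is not None else jitter.seed)
            phases = jitter_phases(bank, cfg, n_steps)
        S = signals(bank, t, phases)
        if noise_sigma > 0 and rng is not None:
            S = S + rng.normal(0.0, noise_sigma, S.shape)
        return (self.projection.M, S)

    def simulate_trial(self, state: core.NetworkState, duration: float,
                       dt: float = DT_MS,
                       bank: Optional[OscillatorBank] = None,
                       noise_sigma: float = 0.0,
                       jitter: Optional[PhaseJitterConfig] = None,
                       rng: Optional[np.random.Generator] = None,
                       record: Optional[core.RecordConfig] = None,
                       ) -> Tuple[core.SpikeTrain, dict]:
        n_steps = int(round(duration / dt))
        drv = self.trial_drive(n_steps, dt, bank, noise_sigma, jitter, rng)
        return core.run(self.population, self.network.W, drv, duration,
                        dt=dt, record=record, state=state)


def build_driven_network(table: ParameterTable = MAIN_SRNN,
                         size: Optional[int] = None,
                         freqs: Optional[Sequence[float]] = None,
                         n_inp: int = 2,
                         f_range: Tuple[float, float] = (4.0, 5.0),
                         A: float = 30.0, p_inp: Optional[float] = None,
                         seed: int = 0) -> DrivenNetwork:
    """Sample a reservoir plus input bank from a parameter table.

    Explicit ``freqs`` fix the sinusoid frequencies (phases still drawn
    uniformly); otherwise ``n_inp`` frequencies are drawn from
    U(f_range).
    """
    size = table.N if size is None else size
    p_inp = table.p_inp if p_inp is None else p_inp
    pop = core.sample_population(table, size, seed=seed)
    W = core.build_recurrent_weights(size, table.p_rnn, table.gamma_rnn,
                                     seed=seed + 1)
    if freqs is not None:
        rng = np.random.default_rng(seed + 2)
        bank = fixed_bank(freqs, phi0=rng.uniform(-np.pi, np.pi, len(freqs)),
                          A=A)
    else:
        bank = sample_bank(n_inp, f_range[0], f_range[1], A=A, seed=seed + 2)
    proj = build_projection(size, bank.n_inp, p_inp, 1.0, seed=seed + 3)
    return DrivenNetwork(network=core.Network(pop, W), bank=bank,
                         projection=proj, seed=seed)


def make_filtered_noise_target(duration: float, cutoff: float = 6.0,
                               scale: float = 30.0, n_out: int = 1,
                               seed: int = 0, grid: float = GRID_MS,
                               order: int = 4,
                               band: Optional[Tuple[float, float]] = None,
                               ) -> TargetSignal:
    """White Gaussian noise N(0, scale) low-pass filtered (zero phase).

    ``scale`` is the noise standard deviation; ``band`` switches to a
    band-pass design.  Sampled directly on the readout grid.
    """
    if duration <= 0:
        raise ConfigurationError("duration must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration / grid))
    fs = 1000.0 / grid
    # pad with extra noise on both sides and trim, so zero-phase
    # filtering leaves no boundary transient inside the target
    if band is None and cutoff >= fs / 2:  # filter disabled
        return TargetSignal(y=rng.normal(0.0, scale, (n, n_out)),
                            grid_ms=grid)
    low = band[0] if band is not None else cutoff
    pad = int(round(4.0 * fs / max(low, 1e-6)))
    wn = rng.normal(0.0, scale, (n + 2 * pad, n_out))
    if band is not None:
        sos = ss.butter(order, [band[0] / (fs / 2), band[1] / (fs / 2)],
                        btype="band", output="sos")
    else:
        sos = ss.butter(order, cutoff / (fs / 2), output="sos")
    y = ss.sosfiltfilt(sos, wn, axis=0)[pad:pad + n]
    return TargetSignal(y=np.ascontiguousarray(y), grid_ms=grid)


def make_shape_target(shape: str, duration: float, n_points: int = 5,
                      grid: float = GRID_MS,
                      inner_ratio: float = 0.5) -> TargetSignal:
    """Closed 2-D parametric curve traversed once per trial.

    ``circle``: unit radius.  ``star``: n_points-fold star with inner
    radius ``inner_ratio``.
    """
    n = int(round(duration / grid))
    theta = 2 * np.pi * np.arange(n) / (n - 1)
    if shape == "circle":
        x, y = np.cos(theta), np.sin(theta)
    elif shape == "star":
        # piecewise-linear star outline resampled uniformly in arc index
        k = 2 * n_points
        ang = np.pi / 2 + 2 * np.pi * np.arange(k + 1) / k
        rad = np.where(np.arange(k + 1) % 2 == 0, 1.0, inner_ratio)
        vx, vy = rad * np.cos(ang), rad * np.sin(ang)
        u = np.linspace(0, k, n)
        x = np.interp(u, np.arange(k + 1), vx)
        y = np.interp(u, np.arange(k + 1), vy)
    else:
        raise ConfigurationError(f"unknown shape {shape!r}")
    return TargetSignal(y=np.column_stack([x, y]), grid_ms=grid)


@dataclass
class TrainResult:
    rls: readout.RLSState
    history: pd.DataFrame            # epoch, test_r
    state: core.NetworkState         # entrained network state after training
    system: DrivenNetwork
    target: TargetSignal
    protocol: ExperimentProtocol

    @property
    def final_test_r(self) -> float:
        return float(self.history["test_r"].dropna().iloc[-1])


def _trial_rates(system: DrivenNetwork, state: core.NetworkState,
                 protocol: ExperimentProtocol,
                 bank: Optional[OscillatorBank] = None,
                 rng: Optional[np.random.Generator] = None,
                 duration: Optional[float] = None) -> np.ndarray:
    dur = protocol.trial_duration if duration is None else duration
    t0 = state.t
    spk, _ = system.simulate_trial(
        state, dur, dt=protocol.dt, bank=bank,
        noise_sigma=protocol.noise_sigma, jitter=protocol.jitter, rng=rng)
    fr = readout.filter_spikes(spk, system.exc_readout_indices,
                               dt=protocol.grid, duration=state.t, t0=t0)
    return fr.r


def _averaged_output(system: DrivenNetwork, state: core.NetworkState,
                     protocol: ExperimentProtocol, W_out: np.ndarray,
                     bank=None, rng=None, duration=None) -> np.ndarray:
    """Readout output averaged over ``n_test_trials`` frozen trials."""
    outs = []
    for _ in range(max(protocol.n_test_trials, 1)):
        R = _trial_rates(system, state, protocol, bank=bank, rng=rng,
                         duration=duration)
        outs.append(readout.readout_output(W_out, R))
    return np.mean(outs, axis=0)


def train_network(system: DrivenNetwork, target: TargetSignal,
                  protocol: ExperimentProtocol,
                  rls: Optional[readout.RLSState] = None) -> TrainResult:
    """Train the readout with interleaved frozen test trials.

    Per epoch: one training trial (phases reset at onset, membrane state
    continuous) with an RLS update at every grid point, then a frozen
    test trial whose Pearson r against the target is logged.
    """
    if target.grid_ms != protocol.grid:
        raise ConfigurationError("target grid must match protocol grid")
    n_ex = len(system.exc_readout_indices)
    rls = rls or readout.rls_init(n_ex, target.n_out, alpha=protocol.alpha)
    rng = np.random.default_rng(protocol.seed)
    state = system.fresh_state(seed=protocol.seed)
    for _ in range(protocol.burn_in_trials):
        _trial_rates(system, state, protocol, rng=rng)

    rows = []
    for ep in range(1, protocol.n_epochs + 1):
        R = _trial_rates(system, state, protocol, rng=rng)
        readout.rls_train_pass(rls, R, target.y)
        test_r = np.nan
        if protocol.test_every and ep % protocol.test_every == 0:
            out = _averaged_output(system, state, protocol, rls.W_out,
                                   rng=rng)
            try:
                _, test_r = readout.evaluate(out, target.y)
            except ConfigurationError:
                test_r = 0.0
        rows.append({"epoch": ep, "test_r": test_r})
    if protocol.n_epochs == 0:
        out = _averaged_output(system, state, protocol, rls.W_out, rng=rng)
        rows.append({"epoch": 0, "test_r": 0.0 if np.ptp(out) == 0
                     else readout.evaluate(out, target.y)[1]})
    return TrainResult(rls=rls, history=pd.DataFrame(rows), state=state,
                       system=system, target=target, protocol=protocol)


def clamping_curve(result: TrainResult, fractions: Sequence[float],
                   seed: int = 0) -> pd.DataFrame:
    """Test Pearson r with growing random fractions of neurons clamped.

    Each fraction clamps an independent uniform subset (weights frozen);
    fully clamped networks give a flat output, reported as r = 0 with a
    flag.
    """
    system, protocol, target = result.system, result.protocol, result.target
    rng = np.random.default_rng(seed)
    N = system.population.size
    rows = []
    for frac in fractions:
        if not 0.0 <= frac <= 1.0:
            raise ConfigurationError("fractions must lie in [0, 1]")
        n_clamp = int(round(frac * N))
        idx = rng.choice(N, size=n_clamp, replace=False)
        state = system.fresh_state(seed=seed + 1)
        core.clamp_neurons(state, idx)
        trial_rng = np.random.default_rng(seed + 2)
        for _ in range(protocol.burn_in_trials):
            _trial_rates(system, state, protocol, rng=trial_rng)
        out = _averaged_output(system, state, protocol, result.rls.W_out,
                               rng=trial_rng)
        degenerate = bool(np.ptp(out) == 0)
        r = 0.0 if degenerate else readout.evaluate(out, target.y)[1]
        rows.append({"fraction": frac, "test_r": r,
                     "degenerate_output": degenerate})
    return pd.DataFrame(rows)


def multitask_train(system: DrivenNetwork,
                    phase_configs: Sequence[np.ndarray],
                    targets: Sequence[TargetSignal],
                    protocol: ExperimentProtocol) -> dict:
    """Train one shared readout on several (phase configuration, target)
    pairs presented in alternation; probe an unseen random configuration.

    Returns per-task test correlations and the unseen-config outputs.
    """
    if len(phase_configs) != len(targets):
        raise ConfigurationError("need one target per phase configuration")
    n_out = targets[0].n_out
    if any(t.n_out != n_out for t in targets):
        raise ConfigurationError("all targets must share n_out")
    n_ex = len(system.exc_readout_indices)
    rls = readout.rls_init(n_ex, n_out, alpha=protocol.alpha)
    rng = np.random.default_rng(protocol.seed)
    state = system.fresh_state(seed=protocol.seed)
    banks = [reset_phases(system.bank, np.asarray(cfg, float))
             for cfg in phase_configs]
    for _ in range(protocol.burn_in_trials):
        _trial_rates(system, state, protocol, bank=banks[0], rng=rng)
    for _ in range(protocol.n_epochs):
        for bank, target in zip(banks, targets):
            R = _trial_rates(system, state, protocol, bank=bank, rng=rng)
            readout.rls_train_pass(rls, R, target.y)
    test_r = []
    outputs = []
    for bank, target in zip(banks, targets):
        R = _trial_rates(system, state, protocol, bank=bank, rng=rng)
        out = readout.readout_output(rls.W_out, R)
        outputs.append(out)
        test_r.append(readout.evaluate(out, target.y)[1])
    unseen = reset_phases(
        system.bank, rng.uniform(-np.pi, np.pi, system.bank.n_inp))
    R = _trial_rates(system, state, protocol, bank=unseen, rng=rng)
    unseen_out = readout.readout_output(rls.W_out, R)
    unseen_r = [readout.evaluate(unseen_out, t.y)[1] for t in targets]
    return {
        "rls": rls, "test_r": test_r, "outputs": outputs,
        "unseen_output": unseen_out, "unseen_r": unseen_r,
        "targets": targets,
    }


def capacity_map(durations: Sequence[float], cutoffs: Sequence[float],
                 protocol: ExperimentProtocol,
                 table: ParameterTable = MAIN_SRNN,
                 size: Optional[int] = None, n_inp: int = 3,
                 f_range: Tuple[float, float] = (2.0, 8.0),
                 ) -> pd.DataFrame:
    """Test Pearson r over a duration x cutoff grid of noise targets.

    Each cell trains a fresh readout (same reservoir realization) on a
    band-limited target of the given duration.
    """
    if not len(durations) or not len(cutoffs):
        raise ConfigurationError("need nonempty duration and cutoff grids")
    system = build_driven_network(table=table, size=size, n_inp=n_inp,
                                  f_range=f_range, seed=protocol.seed)
    rows = []
    for dur in durations:
        for cut in cutoffs:
            target = make_filtered_noise_target(
                dur, cutoff=cut, seed=protocol.seed + int(dur) + int(cut),
                grid=protocol.grid)
            proto = replace(protocol, trial_duration=float(dur))
            res = train_network(system, target, proto)
            rows.append({"duration_ms": dur, "cutoff_hz": cut,
                         "test_r": res.final_test_r})
    return pd.DataFrame(rows)


@dataclass
class RescalingResult:
    factors: np.ndarray
    noise_sigmas: np.ndarray
    r: np.ndarray                # (n_noise, n_factors)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, s in enumerate(self.noise_sigmas):
            for j, f in enumerate(self.factors):
                rows.append({"noise_sigma": s, "factor": f,
                             "test_r": self.r[i, j]})
        return pd.DataFrame(rows)


def _resample_target(y: np.ndarray, n_new: int) -> np.ndarray:
    old = np.linspace(0.0, 1.0, y.shape[0])
    new = np.linspace(0.0, 1.0, n_new)
    return np.column_stack([np.interp(new, old, y[:, k])
                            for k in range(y.shape[1])])


def rescaling_experiment(result: TrainResult, factors: Sequence[float],
                         noise_sigmas: Sequence[float] = (0.0,),
                         seed: int = 0) -> RescalingResult:
    """Replay a trained task at compressed/expanded input periods.

    For each factor the bank's periods are multiplied by the factor, the
    frozen network runs for factor x trial_duration, and the output is
    compared with the target linearly resampled to the same length.
    """
    system, protocol, target = result.system, result.protocol, result.target
    factors = np.asarray(list(factors), dtype=float)
    if np.any(factors <= 0):
        raise ConfigurationError("factors must be positive")
    noise_sigmas = np.asarray(list(noise_sigmas), dtype=float)
    r = np.zeros((noise_sigmas.size, factors.size))
    for i, sig in enumerate(noise_sigmas):
        for j, fac in enumerate(factors):
            bank = rescale_bank(system.bank, fac)
            dur = protocol.trial_duration * fac
            # keep the duration on the simulation grid
            dur = round(dur / protocol.grid) * protocol.grid
            proto = replace(protocol, noise_sigma=sig)
            rng = np.random.default_rng(seed + i)
            state = system.fresh_state(seed=seed + 3 + j)
            for _ in range(protocol.burn_in_trials):
                _trial_rates(system, state, proto, bank=bank, rng=rng,
                             duration=dur)
            out = _averaged_output(system, state, proto, result.rls.W_out,
                                   bank=bank, rng=rng, duration=dur)
            y_res = _resample_target(target.y, out.shape[0])
            r[i, j] = 0.0 if np.ptp(out) == 0 else \
                readout.evaluate(out, y_res)[1]
    return RescalingResult(factors=factors, noise_sigmas=noise_sigmas, r=r)
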