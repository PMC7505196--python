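"""Conductance-based leaky integrate-and-fire network simulation.

The membrane potential of every neuron follows

    C dV/dt = (E_L - V)/R + g_ex (E_ex - V) + g_in (E_in - V)
              + I_tonic + I_ext(t)

with exponentially decaying excitatory/inhibitory conductances incremented
by delayed presynaptic spikes, an absolute refractory period during which V
is pinned at V_reset, and Dale's law: a presynaptic neuron increments g_ex
in all its targets if it is excitatory, g_in if inhibitory, never both.

All ODEs are integrated by forward Euler at dt = 0.05 ms.  Units: mV, pA,
nS, ms (resistance is converted from MOhm to GOhm internally so that
mV/GOhm = pA; conductance increments from pS to nS).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Tuple, Union

import numpy as np
import scipy.sparse as sp

from . import _kernel
from .params import DT_MS, ConfigurationError, NEURON_FIELDS, ParameterTable

__all__ = [
    "NeuronPopulation", "SynapticMatrix", "NetworkState", "SpikeTrain",
    "Network", "RecordConfig", "NumericalInstabilityError",
    "sample_population", "build_recurrent_weights", "init_state",
    "step", "run", "clamp_neurons", "sigma_rnn",
]

_MAX_RESAMPLE = 100


class NumericalInstabilityError(RuntimeError):
    """Membrane potential became non-finite during integration."""

    def __init__(self, neuron: int, t_ms: float):
        self.neuron = neuron
        self.t_ms = t_ms
        super().__init__(
            f"non-finite membrane potential for neuron {neuron} "
            f"at t = {t_ms:.3f} ms"
        )


@dataclass
class NeuronPopulation:
    """Per-neuron electrophysiology with an 80/20 E/I split by default."""

    size: int
    is_excitatory: np.ndarray
    R: np.ndarray          # MOhm
    C: np.ndarray          # pF
    E_L: np.ndarray        # mV
    V_theta: np.ndarray    # mV
    V_reset: np.ndarray    # mV
    I_tonic: np.ndarray    # pA
    T_delay: np.ndarray    # ms
    tau_ref: np.ndarray    # ms
    G_ex: np.ndarray       # pS
    G_in: np.ndarray       # pS
    tau_ex: np.ndarray     # ms
    tau_in: np.ndarray     # ms
    E_ex: np.ndarray       # mV
    E_in: np.ndarray       # mV

    @property
    def n_excitatory(self) -> int:
        return int(self.is_excitatory.sum())

    @property
    def excitatory_indices(self) -> np.ndarray:
        return np.flatnonzero(self.is_excitatory)

    @property
    def inhibitory_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.is_excitatory)


@dataclass
class SynapticMatrix:
    """Nonnegative synaptic magnitudes W[post, pre], presyn-sign routed."""

    magnitudes: sp.csc_matrix
    density: float
    sigma: float
    gain: float

    @property
    def size(self) -> int:
        return self.magnitudes.shape[0]

    @property
    def nnz(self) -> int:
        return self.magnitudes.nnz


@dataclass
class SpikeTrain:
    """Spike events as parallel (neuron, time) arrays, times in (0, T]."""

    neurons: np.ndarray
    times: np.ndarray
    duration: float
    size: int

    def __len__(self) -> int:
        return len(self.times)

    def for_neuron(self, i: int) -> np.ndarray:
        return self.times[self.neurons == i]

    def counts(self) -> np.ndarray:
        return np.bincount(self.neurons, minlength=self.size)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"neuron_id": self.neurons, "time_ms": self.times})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, duration: float, size: int) -> "SpikeTrain":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(df["neuron_id"].to_numpy(np.int64),
                   df["time_ms"].to_numpy(float), duration, size)


@dataclass
class NetworkState:
    """Mutable integration state (V, conductances, delays, refractoriness)."""

    V: np.ndarray
    g_ex: np.ndarray
    g_in: np.ndarray
    I_cur: np.ndarray                 # signed current-synapse state (pA)
    refractory_remaining: np.ndarray  # steps, int64
    delay_buffer: np.ndarray          # (D, N) uint8 ring buffer
    buf_pos: np.ndarray               # length-1 int64
    t: float                          # ms
    clamped: np.ndarray               # bool per neuron
    step_index: int = 0


@dataclass
class Network:
    """A population plus its recurrent weights."""

    population: NeuronPopulation
    W: SynapticMatrix


@dataclass
class RecordConfig:
    """What ``run`` should record besides spikes.

    ``every_ms`` sets the cadence of V/g/I_ext traces (0 disables them);
    the per-step population spike count is always recorded.
    """

    every_ms: float = 0.0
    record_traces: bool = False


def sigma_rnn(size: int, p_rnn: float, gamma_rnn: float) -> float:
    """Balanced-network weight scale gamma / sqrt(N * p)."""
    return gamma_rnn / np.sqrt(size * p_rnn)


def sample_population(spec: ParameterTable, size: int,
                      frac_ex: float = 0.8, seed: int = 0) -> NeuronPopulation:
    """Draw per-neuron parameters from the Gaussian columns of ``spec``.

    Exactly round(frac_ex * size) neurons (the lowest indices) are
    excitatory.  Sampled values violating positivity or the ordering
    V_reset <= E_L < V_theta are resampled field-wise: E_L against
    V_theta, then V_reset against the accepted E_L.  This keeps the
    moments of E_L and V_theta unbiased; only V_reset is truncated.
    """
    if size <= 0:
        raise ConfigurationError("population size must be positive")
    if not 0.0 < frac_ex < 1.0:
        raise ConfigurationError("frac_ex must lie in (0, 1)")
    for f in NEURON_FIELDS:
        if f not in spec.fields:
            raise ConfigurationError(f"parameter table missing field {f!r}")

    rng = np.random.default_rng(seed)

    def draw(name: str) -> np.ndarray:
        mu, sd = spec.fields[name]
        return rng.normal(mu, sd, size) if sd > 0 else np.full(size, mu)

    vals = {name: draw(name) for name in NEURON_FIELDS}

    def resample_until(name: str, ok: Callable[[np.ndarray], np.ndarray]) -> None:
        mu, sd = spec.fields[name]
        x = vals[name]
        bad = ~ok(x)
        tries = 0
        while bad.any():
            tries += 1
            if tries > _MAX_RESAMPLE:
                raise ConfigurationError(
                    f"could not sample valid values for {name!r} "
                    f"after {_MAX_RESAMPLE} attempts"
                )
            x[bad] = rng.normal(mu, sd, int(bad.sum()))
            bad = ~ok(x)

    for name in ("R", "C", "tau_ref", "T_delay", "tau_ex", "tau_in",
                 "G_ex", "G_in"):
        resample_until(name, lambda x: x > 0)
    resample_until("E_L", lambda x: x < vals["V_theta"])
    # V_reset <= E_L: per-neuron rejection can be arbitrarily slow when
    # E_L draws low (the two share a distribution), so sample the exact
    # truncated normal the rejection scheme targets.
    mu_r, sd_r = spec.fields["V_reset"]
    if sd_r > 0:
        from scipy.stats import truncnorm

        b = (vals["E_L"] - mu_r) / sd_r
        vals["V_reset"] = truncnorm.rvs(
            -np.inf, b, loc=mu_r, scale=sd_r, size=size, random_state=rng
        )
    elif np.any(mu_r > vals["E_L"]):
        raise ConfigurationError(
            "V_reset mean exceeds sampled E_L and sd is zero"
        )

    n_ex = int(round(frac_ex * size))
    is_ex = np.zeros(size, dtype=bool)
    is_ex[:n_ex] = True

    return NeuronPopulation(size=size, is_excitatory=is_ex, **vals)


def build_recurrent_weights(size: int, p_rnn: float, gamma_rnn: float,
                            seed: int = 0,
                            sigma: Optional[float] = None) -> SynapticMatrix:
    """Sparse half-normal |N(0, sigma_rnn)| magnitudes, no self-loops.

    sigma_rnn defaults to gamma_rnn / sqrt(size * p_rnn); pass ``sigma``
    to override the scaling convention.
    """
    if not 0.0 < p_rnn <= 1.0:
        raise ConfigurationError("p_rnn must lie in (0, 1]")
    if gamma_rnn < 0:
        raise ConfigurationError("gamma_rnn must be nonnegative")
    sig = sigma_rnn(size, p_rnn, gamma_rnn) if sigma is None else sigma

    rng = np.random.default_rng(seed)
    mask = rng.random((size, size)) < p_rnn
    np.fill_diagonal(mask, False)
    rows, cols = np.nonzero(mask)
    data = np.abs(rng.normal(0.0, sig, rows.shape[0])) if sig > 0 else \
        np.zeros(rows.shape[0])
    mat = sp.csc_matrix((data, (rows, cols)), shape=(size, size))
    return SynapticMatrix(magnitudes=mat, density=p_rnn, sigma=sig,
                          gain=gamma_rnn)


def init_state(population: NeuronPopulation, dt: float = DT_MS,
               seed: int = 0, v_init: str = "uniform") -> NetworkState:
    """Fresh state: V ~ U[V_reset, V_theta) (or E_L), g = 0, empty buffers."""
    rng = np.random.default_rng(seed)
    N = population.size
    if v_init == "uniform":
        u = rng.random(N)
        V = population.V_reset + u * (population.V_theta - population.V_reset)
    elif v_init == "rest":
        V = population.E_L.copy()
    else:
        raise ConfigurationError(f"unknown v_init {v_init!r}")
    delay_steps = _delay_steps(population, dt)
    D = int(delay_steps.max()) + 1
    return NetworkState(
        V=V.astype(float),
        g_ex=np.zeros(N),
        g_in=np.zeros(N),
        I_cur=np.zeros(N),
        refractory_remaining=np.zeros(N, dtype=np.int64),
        delay_buffer=np.zeros((D, N), dtype=np.uint8),
        buf_pos=np.zeros(1, dtype=np.int64),
        t=0.0,
        clamped=np.zeros(N, dtype=bool),
    )


def clamp_neurons(state: NetworkState, indices: Sequence[int]) -> NetworkState:
    """Hold the listed neurons at resting potential; they never spike."""
    idx = np.asarray(indices, dtype=np.int64)
    if idx.size:
        if idx.min() < 0 or idx.max() >= state.V.shape[0]:
            raise ConfigurationError("clamp index out of range")
        if np.unique(idx).size != idx.size:
            raise ConfigurationError("duplicate clamp indices")
        state.clamped[idx] = True
        # a clamped neuron emits nothing, including already-scheduled spikes
        state.delay_buffer[:, idx] = 0
    return state


def _delay_steps(population: NeuronPopulation, dt: float) -> np.ndarray:
    d = np.rint(population.T_delay / dt).astype(np.int64)
    return np.maximum(d, 1)


def _refr_steps(population: NeuronPopulation, dt: float) -> np.ndarray:
    r = np.ceil(population.tau_ref / dt).astype(np.int64)
    return np.maximum(r, 1)


_EMPTY_CSC = (np.zeros(1, dtype=np.int64), np.zeros(0, dtype=np.int64),
              np.zeros(0, dtype=float))


def _csc_arrays(W: Optional[SynapticMatrix], size: int):
    if W is None:
        indptr = np.zeros(size + 1, dtype=np.int64)
        return indptr, np.zeros(0, dtype=np.int64), np.zeros(0, dtype=float)
    m = W.magnitudes
    return (m.indptr.astype(np.int64), m.indices.astype(np.int64),
            m.data.astype(float))


def _kernel_args(population: NeuronPopulation, dt: float):
    p = population
    return dict(
        C=p.C.astype(float),
        R_gohm=p.R.astype(float) * 1e-3,   # MOhm -> GOhm so mV/GOhm = pA
        E_L=p.E_L.astype(float),
        V_theta=p.V_theta.astype(float),
        V_reset=p.V_reset.astype(float),
        I_tonic=p.I_tonic.astype(float),
        tau_ex=p.tau_ex.astype(float),
        tau_in=p.tau_in.astype(float),
        E_ex=p.E_ex.astype(float),
        E_in=p.E_in.astype(float),
        G_ex_ns=p.G_ex.astype(float) * 1e-3,  # pS -> nS
        G_in_ns=p.G_in.astype(float) * 1e-3,
        is_ex=p.is_excitatory,
        delay_steps=_delay_steps(p, dt),
        refr_steps=_refr_steps(p, dt),
    )


_NO_PLASTIC = dict(
    plastic_rows=np.zeros(0, dtype=np.int64), n_bank=0, alpha=0.0,
    w_lo=0.0, w_hi=0.0, burst_win_steps=0,
    plast_refr_steps=0,
    plast_last_update=np.zeros(0, dtype=np.int64),
    plast_prev1=np.zeros(0, dtype=np.int64),
    plast_prev2=np.zeros(0, dtype=np.int64),
)


def _spike_capacity(population: NeuronPopulation, n_steps: int,
                    dt: float) -> int:
    # ISI >= tau_ref guarantees at most n_steps/refr_steps + 1 per neuron
    refr = _refr_steps(population, dt)
    return int(np.sum(n_steps // refr + 1))


def step(state: NetworkState, population: NeuronPopulation,
         W: Optional[SynapticMatrix], external_current: np.ndarray,
         dt: float = DT_MS) -> Tuple[NetworkState, np.ndarray]:
    """Advance the network by one forward-Euler step.

    ``external_current`` is the per-neuron I_ext (pA) held constant over
    the step.  Returns the mutated state and a boolean spike mask.
    """
    if dt <= 0:
        raise ConfigurationError("dt must be positive")
    ext = np.asarray(external_current, dtype=float)
    if ext.shape != (population.size,):
        raise ConfigurationError("external_current length must equal size")

    w_indptr, w_indices, w_data = _csc_arrays(W, population.size)
    spike_neuron = np.zeros(population.size, dtype=np.int64)
    spike_step = np.zeros(population.size, dtype=np.int64)
    n_spikes = np.zeros(1, dtype=np.int64)
    n_bursts = np.zeros(1, dtype=np.int64)
    rate = np.zeros(1, dtype=np.int64)
    empty2 = np.zeros((0, 0))
    status, bad_i, bad_n = _kernel._simulate(
        1, dt, 0,
        **_kernel_args(population, dt),
        w_indptr=w_indptr, w_indices=w_indices, w_data=w_data,
        c_indptr=np.zeros(population.size + 1, dtype=np.int64),
        c_indices=np.zeros(0, dtype=np.int64),
        c_data=np.zeros(0, dtype=float), tau_cur=20.0,
        M_drive=np.zeros((population.size, 0)), S=np.zeros((1, 0)),
        I_dense=ext[None, :],
        **_NO_PLASTIC,
        V=state.V, g_ex=state.g_ex, g_in=state.g_in, I_cur=state.I_cur,
        refr_left=state.refractory_remaining, clamped=state.clamped,
        buf=state.delay_buffer, buf_pos_arr=state.buf_pos,
        spike_neuron=spike_neuron, spike_step=spike_step,
        n_spikes_arr=n_spikes, rate_counts=rate,
        rec_every=0, recV=empty2, recGex=empty2, recGin=empty2,
        recIext=empty2,
        burst_row=np.zeros(0, dtype=np.int64),
        burst_step=np.zeros(0, dtype=np.int64), n_bursts_arr=n_bursts,
    )
    if status != _kernel.OK:
        raise NumericalInstabilityError(bad_i, (bad_n + 1) * dt)
    spiked = np.zeros(population.size, dtype=bool)
    spiked[spike_neuron[: n_spikes[0]]] = True
    state.t += dt
    state.step_index += 1
    return state, spiked


DriveLike = Union[
    None,
    np.ndarray,                       # dense (n_steps, N) pA
    Tuple[np.ndarray, np.ndarray],    # low-rank (M (N,K), S (n_steps,K))
    Callable[[np.ndarray], np.ndarray],  # t_ms-vector -> (n_steps, N)
]


def run(population: NeuronPopulation, W: Optional[SynapticMatrix],
        drive: DriveLike, duration: float, dt: float = DT_MS,
        record: Optional[RecordConfig] = None, seed: int = 0,
        state: Optional[NetworkState] = None,
        clamped: Optional[Sequence[int]] = None,
        plasticity: Optional[dict] = None,
        current_synapses: Optional[Tuple] = None,
        ) -> Tuple[SpikeTrain, dict]:
    """Simulate for ``duration`` ms and collect spikes and traces.

    ``drive`` may be None, a dense (n_steps, N) current array, a low-rank
    (M, S) pair with I_ext = M @ S[n], or a callable mapping the step-time
    vector to a dense array.  Bitwise reproducible for fixed seed/inputs.

    ``plasticity`` (used by the hippocampus module) is a dict with keys
    rows, n_bank, alpha, w_lo, w_hi, window_ms; updates rows of the
    low-rank M in place when a place-cell spike triplet lands within the
    window.  ``current_synapses`` is a (indptr, indices, data, tau) CSC
    triple of signed per-spike current increments by presynaptic neuron.
    """
    n_steps = int(round(duration / dt))
    if abs(n_steps * dt - duration) > 1e-9 * max(1.0, duration):
        raise ConfigurationError("duration must be a multiple of dt")
    N = population.size
    if state is None:
        state = init_state(population, dt=dt, seed=seed)
    if clamped is not None:
        clamp_neurons(state, clamped)

    M_drive = np.zeros((N, 0))
    S = np.zeros((max(n_steps, 1), 0))
    I_dense = np.zeros((0, 0))
    if drive is None:
        pass
    elif callable(drive):
        t = (np.arange(n_steps) * dt) + state.t
        I_dense = np.asarray(drive(t), dtype=float)
        if I_dense.shape != (n_steps, N):
            raise ConfigurationError("drive callable must return (n_steps, N)")
    elif isinstance(drive, tuple):
        M_drive, S = drive
        M_drive = np.ascontiguousarray(M_drive, dtype=float)
        S = np.ascontiguousarray(S, dtype=float)
        if M_drive.shape[0] != N or S.shape[0] < n_steps:
            raise ConfigurationError("low-rank drive shapes inconsistent")
    else:
        I_dense = np.asarray(drive, dtype=float)
        if I_dense.shape != (n_steps, N):
            raise ConfigurationError("dense drive must be (n_steps, N)")

    w_indptr, w_indices, w_data = _csc_arrays(W, N)
    if current_synapses is None:
        c_indptr = np.zeros(N + 1, dtype=np.int64)
        c_indices = np.zeros(0, dtype=np.int64)
        c_data = np.zeros(0, dtype=float)
        tau_cur = 20.0
    else:
        c_indptr, c_indices, c_data, tau_cur = current_synapses

    if plasticity is None:
        plast = dict(_NO_PLASTIC)
        burst_cap = 0
    else:
        rows = np.asarray(plasticity["rows"], dtype=np.int64)
        plast = dict(
            plastic_rows=rows,
            n_bank=int(plasticity["n_bank"]),
            alpha=float(plasticity["alpha"]),
            w_lo=float(plasticity["w_lo"]),
            w_hi=float(plasticity["w_hi"]),
            burst_win_steps=int(round(plasticity["window_ms"] / dt)),
            plast_refr_steps=int(round(
                plasticity.get("refractory_ms", 0.0) / dt)),
            plast_last_update=np.full(rows.shape[0], -1, dtype=np.int64),
            plast_prev1=np.full(rows.shape[0], -1, dtype=np.int64),
            plast_prev2=np.full(rows.shape[0], -1, dtype=np.int64),
        )
        burst_cap = rows.shape[0] * (n_steps // 40 + 1)
    burst_row = np.zeros(burst_cap, dtype=np.int64)
    burst_step = np.zeros(burst_cap, dtype=np.int64)

    cap = _spike_capacity(population, n_steps, dt)
    spike_neuron = np.zeros(cap, dtype=np.int64)
    spike_step = np.zeros(cap, dtype=np.int64)
    n_spikes = np.zeros(1, dtype=np.int64)
    n_bursts = np.zeros(1, dtype=np.int64)
    rate_counts = np.zeros(max(n_steps, 1), dtype=np.int64)

    record = record or RecordConfig()
    if record.record_traces and record.every_ms > 0:
        rec_every = int(round(record.every_ms / dt))
        n_rec = (n_steps + rec_every - 1) // rec_every
        recV = np.zeros((n_rec, N))
        recGex = np.zeros((n_rec, N))
        recGin = np.zeros((n_rec, N))
        recIext = np.zeros((n_rec, N))
    else:
        rec_every = 0
        recV = recGex = recGin = recIext = np.zeros((0, 0))

    if n_steps > 0:
        status, bad_i, bad_n = _kernel._simulate(
            n_steps, dt, state.step_index,
            **_kernel_args(population, dt),
            w_indptr=w_indptr, w_indices=w_indices, w_data=w_data,
            c_indptr=c_indptr, c_indices=c_indices, c_data=c_data,
            tau_cur=tau_cur,
            M_drive=M_drive, S=S, I_dense=I_dense,
            **plast,
            V=state.V, g_ex=state.g_ex, g_in=state.g_in, I_cur=state.I_cur,
            refr_left=state.refractory_remaining, clamped=state.clamped,
            buf=state.delay_buffer, buf_pos_arr=state.buf_pos,
            spike_neuron=spike_neuron, spike_step=spike_step,
            n_spikes_arr=n_spikes, rate_counts=rate_counts,
            rec_every=rec_every, recV=recV, recGex=recGex, recGin=recGin,
            recIext=recIext,
            burst_row=burst_row, burst_step=burst_step,
            n_bursts_arr=n_bursts,
        )
        if status != _kernel.OK:
            raise NumericalInstabilityError(bad_i, (bad_n + 1) * dt)

    ns = int(n_spikes[0])
    spikes = SpikeTrain(
        neurons=spike_neuron[:ns].copy(),
        times=(spike_step[:ns] + 1) * dt,
        duration=state.t + duration, size=N,
    )
    traces = {
        "rate": rate_counts[: n_steps],
        "dt": dt,
    }
    if rec_every > 0:
        traces.update(
            t_rec=state.t + (np.arange(recV.shape[0]) * rec_every) * dt,
            V=recV, g_ex=recGex, g_in=recGin, I_ext=recIext,
        )
    if plasticity is not None:
        nb = min(int(n_bursts[0]), burst_cap)
        rows_arr = np.asarray(plasticity["rows"], dtype=np.int64)
        traces["burst_rows"] = rows_arr[burst_row[:nb]]
        traces["burst_times"] = (burst_step[:nb] + 1) * dt
        traces["M_drive"] = M_drive  # mutated in place by the kernel
    state.t += duration
    state.step_index += n_steps
    return spikes, traces
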