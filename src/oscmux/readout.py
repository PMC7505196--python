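"""Spike filtering and recursive-least-squares readout training.

Excitatory spike trains are low-pass filtered by a double exponential
(rise 6 ms, decay 60 ms, unit-area impulse response) and fed to linear
readout units y_hat = W_out^T r.  W_out is trained online by RLS on a
fixed 2.5 ms grid:

    e      = W_out^T r - y                  (pre-update weights)
    P     <- P - (P r)(P r)^T / (1 + r^T P r)
    W_out <- W_out - (P r) e^T

with P(0) = I / alpha and W_out(0) = 0.  Iterating these updates over a
fixed design is algebraically identical to ridge regression
(R^T R + alpha I)^{-1} R^T Y, which the test suite uses as an oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from . import _kernel
from .params import ConfigurationError, GRID_MS
from .srnn_core import SpikeTrain

__all__ = [
    "FilteredRate", "RLSState", "TargetSignal",
    "filter_spikes", "rls_init", "rls_update", "rls_train_pass",
    "readout_output", "evaluate",
]

TAU_R = 6.0   # ms, synaptic rise
TAU_D = 60.0  # ms, synaptic decay


@dataclass
class FilteredRate:
    """Filtered rates r (n_grid, n_neurons) sampled on a time grid (ms)."""

    r: np.ndarray
    grid: np.ndarray
    neurons: np.ndarray
    tau_r: float = TAU_R
    tau_d: float = TAU_D


@dataclass
class TargetSignal:
    """Target y (n_grid, n_out) on a grid with fixed spacing (ms)."""

    y: np.ndarray
    grid_ms: float

    @property
    def n_out(self) -> int:
        return self.y.shape[1]

    @property
    def n_grid(self) -> int:
        return self.y.shape[0]

    @property
    def duration(self) -> float:
        return self.n_grid * self.grid_ms


@dataclass
class RLSState:
    """Readout weights and running inverse-correlation estimate."""

    W_out: np.ndarray
    P: np.ndarray
    alpha: float
    update_interval: float = GRID_MS

    @property
    def n_neurons(self) -> int:
        return self.W_out.shape[0]

    @property
    def n_out(self) -> int:
        return self.W_out.shape[1]


def filter_spikes(spikes: SpikeTrain, neurons: Sequence[int],
                  dt: float = GRID_MS, duration: Optional[float] = None,
                  tau_r: float = TAU_R, tau_d: float = TAU_D,
                  t0: float = 0.0) -> FilteredRate:
    """Filter the spike trains of ``neurons`` onto a grid with spacing dt.

    Integration is exact (exponential propagators between events); each
    spike contributes the unit-area kernel
    [exp(-t/tau_d) - exp(-t/tau_r)] / (tau_d - tau_r).
    """
    if not tau_r < tau_d:
        raise ConfigurationError("need tau_r < tau_d")
    duration = spikes.duration if duration is None else duration
    neurons = np.asarray(neurons, dtype=np.int64)
    n_grid = int(round((duration - t0) / dt))
    grid = t0 + (np.arange(1, n_grid + 1)) * dt
    neuron_map = np.full(spikes.size, -1, dtype=np.int64)
    neuron_map[neurons] = np.arange(len(neurons))
    order = np.argsort(spikes.times, kind="stable")
    r = _kernel.filter_spike_grid(
        np.ascontiguousarray(spikes.times[order] - t0, dtype=float),
        np.ascontiguousarray(spikes.neurons[order], dtype=np.int64),
        neuron_map, len(neurons), grid - t0, tau_r, tau_d,
    )
    return FilteredRate(r=r, grid=grid, neurons=neurons,
                        tau_r=tau_r, tau_d=tau_d)


def rls_init(n_neurons: int, n_out: int, alpha: float = 1.0,
             update_interval: float = GRID_MS) -> RLSState:
    """W_out = 0, P = I / alpha."""
    if alpha <= 0:
        raise ConfigurationError("alpha must be positive")
    return RLSState(
        W_out=np.zeros((n_neurons, n_out)),
        P=np.eye(n_neurons) / alpha,
        alpha=alpha,
        update_interval=update_interval,
    )


def rls_update(state: RLSState, r: np.ndarray, y: np.ndarray) -> RLSState:
    """One RLS step; mutates and returns ``state``.

    The error uses the pre-update weights; P is updated by the
    Sherman-Morrison rank-one formula; the weight step uses the
    post-update gain P(t) r = (P r) / (1 + r^T P r).
    """
    r = np.asarray(r, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if r.shape[0] != state.n_neurons or y.shape[0] != state.n_out:
        raise ConfigurationError("rls_update: dimension mismatch")
    e = state.W_out.T @ r - y
    Pr = state.P @ r
    denom = 1.0 + r @ Pr
    if not np.isfinite(denom) or denom <= 0:
        raise FloatingPointError(
            f"RLS update unstable: 1 + r'Pr = {denom!r}"
        )
    state.P -= np.outer(Pr, Pr) / denom
    gain = Pr / denom  # equals P(t) r after the update
    state.W_out -= np.outer(gain, e)
    if not np.isfinite(state.W_out).all():
        raise FloatingPointError("non-finite readout weights after update")
    return state


def rls_train_pass(state: RLSState, R: np.ndarray, Y: np.ndarray) -> RLSState:
    """Apply rls_update over every row of the design R against targets Y."""
    if R.shape[0] != Y.shape[0]:
        raise ConfigurationError("design and target lengths differ")
    for i in range(R.shape[0]):
        rls_update(state, R[i], Y[i])
    return state


def readout_output(W_out: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Linear readout: r (n_grid, n) @ W_out (n, n_out), or a single sample."""
    r = np.asarray(r, dtype=float)
    if r.ndim == 1:
        return W_out.T @ r
    return r @ W_out


def evaluate(output: np.ndarray, target: np.ndarray) -> Tuple[np.ndarray, float]:
    """Pearson r per output channel and their mean."""
    output = np.atleast_2d(np.asarray(output, float).T).T
    target = np.atleast_2d(np.asarray(target, float).T).T
    if output.shape != target.shape:
        raise ConfigurationError("output/target shapes differ")
    if output.shape[0] < 2:
        raise ConfigurationError("need at least two samples")
    rs = np.empty(output.shape[1])
    for k in range(output.shape[1]):
        y = target[:, k]
        if np.ptp(y) == 0:
            raise ConfigurationError(
                f"target channel {k} is constant; correlation undefined"
            )
        x = output[:, k]
        if np.ptp(x) == 0:
            rs[k] = 0.0  # flat output carries no signal
        else:
            rs[k] = stats.pearsonr(x, y).statistic
    return rs, float(np.mean(rs))
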