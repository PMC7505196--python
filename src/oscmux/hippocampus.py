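"""Place-cell sequence formation, replay and phase precession.

A reservoir (CA1) receives a dense bank of 20 theta-band oscillators
(CA3, 7.5-8.5 Hz, full-range signals A(sin+1) with A = 1).  Ten random
excitatory neurons are designated place cells; during a single 5 s
training lap each receives a 600 ms depolarizing 10 Hz oscillation (60 pA)
at its field onset — the environmental input runs slightly faster than
the background theta, which produces phase precession.  Whenever a place
cell emits a burst (three spikes within 50 ms), its input weights are
potentiated by the instantaneous input signals,

    M[i, k] <- clip(M[i, k] + alpha * s_k(t_burst), 0, 5 sigma_inp)

with alpha = 0.25 and sigma_inp = 0.1, so each cell becomes tuned to the
unique oscillator phase configuration of its field.  Replaying the
oscillations compressed by 0.15 yields ripple-frequency (>= 50 Hz) bursts
and a time-compressed forward sequence; reversing the compressed input
sequence yields reverse replay.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from . import analysis, srnn_core as core
from .drive import OscillatorBank, rescale_bank, sample_bank, signals
from .params import DT_MS, MAIN_SRNN, ConfigurationError, ParameterTable

__all__ = [
    "HippocampalConfig", "HippocampalModel", "build_hippocampal_model",
    "training_lap", "test_recall", "replay", "phase_precession",
    "activation_order", "order_correlation",
]


@dataclass(frozen=True)
class HippocampalConfig:
    """Defaults of the spatial-navigation model."""

    n_inp: int = 20
    f_range: Tuple[float, float] = (7.5, 8.5)   # Hz, CA3 theta band
    input_amplitude: float = 1.0                # a.u.; signals in [0, 2]
    size: int = 1000
    capacitance: float = 100.0                  # pF, all neurons
    gamma_rnn: float = 0.5
    n_place: int = 10
    lap_duration: float = 5000.0                # ms, one virtual-track lap
    field_duration: float = 600.0               # ms
    field_frequency: float = 10.0               # Hz environmental input
    field_amplitude: float = 60.0               # pA
    field_onsets: Optional[Tuple[float, ...]] = None  # default: even spacing
    sigma_inp: float = 0.1                      # half-normal init scale
    alpha: float = 0.25                         # potentiation rate
    burst_window: float = 50.0                  # ms
    plateau_refractory: float = 600.0           # ms between plasticity events
    ms_per_cm: float = 20.0                     # 100 ms = 5 cm

    def onsets(self) -> np.ndarray:
        if self.field_onsets is not None:
            on = np.asarray(self.field_onsets, dtype=float)
        else:
            # evenly spaced with the last field ending at the lap's end
            span = self.lap_duration - self.field_duration
            on = np.linspace(0.0, span, self.n_place)
        if np.any(on < 0) or np.any(
                on + self.field_duration > self.lap_duration):
            raise ConfigurationError("field onsets must fit inside the lap")
        return on

    @property
    def weight_bound(self) -> float:
        return 5.0 * self.sigma_inp


@dataclass
class HippocampalModel:
    cfg: HippocampalConfig
    population: core.NeuronPopulation
    W: core.SynapticMatrix
    bank: OscillatorBank
    M_input: np.ndarray          # (N, n_inp) nonnegative input weights
    place_cells: np.ndarray      # indices into the population
    seed: int


def build_hippocampal_model(cfg: HippocampalConfig = HippocampalConfig(),
                            seed: int = 0,
                            table: ParameterTable = MAIN_SRNN,
                            ) -> HippocampalModel:
    """Sample the CA1 reservoir, CA3 bank and initial input weights.

    The reservoir uses the main parameter table with C = 100 pF and
    gamma_rnn = 0.5.  Place cells are drawn among excitatory neurons;
    their resting potential is pinned to the E_L mean so none is
    spontaneously depolarized into firing.  There is no readout: the
    observable is the place-cell spike sequence itself.
    """
    tab = table.with_overrides(
        N=cfg.size, gamma_rnn=cfg.gamma_rnn,
        C=(cfg.capacitance, table.fields["C"][1]),
    )
    pop = core.sample_population(tab, cfg.size, seed=seed)
    if pop.n_excitatory < cfg.n_place:
        raise ConfigurationError("fewer excitatory cells than place cells")
    rng = np.random.default_rng(seed + 1)
    place = np.sort(rng.choice(pop.excitatory_indices, size=cfg.n_place,
                               replace=False))
    # homogenize place-cell excitability: pin resting potential and
    # threshold to their table means so recall selectivity is carried by
    # the learned input tuning, not by millivolt-scale excitability
    # differences between the ten cells
    mu_EL = table.fields["E_L"][0]
    pop.E_L[place] = mu_EL
    pop.V_theta[place] = table.fields["V_theta"][0]
    pop.V_reset[place] = np.minimum(pop.V_reset[place], mu_EL)

    W = core.build_recurrent_weights(cfg.size, tab.p_rnn, tab.gamma_rnn,
                                     seed=seed + 2)
    bank = sample_bank(cfg.n_inp, cfg.f_range[0], cfg.f_range[1],
                       A=cfg.input_amplitude, variant="full_range",
                       seed=seed + 3)
    # dense input weights: signed N(0, 1) entries for the reservoir at
    # large (the general input-projection convention), while the plastic
    # place-cell rows start from the nonnegative half-normal
    # f(0, sigma_inp) the learning rule's bounds refer to
    M_input = rng.normal(0.0, 1.0, (cfg.size, cfg.n_inp))
    M_input[place] = np.abs(rng.normal(0.0, cfg.sigma_inp,
                                       (cfg.n_place, cfg.n_inp)))
    return HippocampalModel(cfg=cfg, population=pop, W=W, bank=bank,
                            M_input=M_input, place_cells=place, seed=seed)


def _field_signals(cfg: HippocampalConfig, n_steps: int,
                   dt: float) -> np.ndarray:
    """Per-place-cell depolarizing field stimulus on the step grid.

    A half-range oscillation (A/2)(sin(2 pi f (t - onset) - pi/2) + 1)
    in [0, A]: it ramps from zero at field entry, peaking mid-cycle.
    """
    t = np.arange(n_steps) * dt
    S = np.zeros((n_steps, cfg.n_place))
    for i, on in enumerate(cfg.onsets()):
        m = (t >= on) & (t < on + cfg.field_duration)
        tt = (t[m] - on) / 1000.0
        S[m, i] = (cfg.field_amplitude / 2.0) * (
            np.sin(2 * np.pi * cfg.field_frequency * tt - np.pi / 2) + 1.0)
    return S


def _drive(model: HippocampalModel, S_bank: np.ndarray,
           S_field: Optional[np.ndarray] = None,
           M_input: Optional[np.ndarray] = None):
    M_in = model.M_input if M_input is None else M_input
    if S_field is None:
        return (M_in.copy(), S_bank)
    M_field = np.zeros((model.cfg.size, model.cfg.n_place))
    M_field[model.place_cells, np.arange(model.cfg.n_place)] = 1.0
    return (np.concatenate([M_in, M_field], axis=1),
            np.concatenate([S_bank, S_field], axis=1))


def training_lap(model: HippocampalModel, lap_duration: Optional[float] =
                 None, dt: float = DT_MS, seed: int = 0
                 ) -> Tuple[np.ndarray, core.SpikeTrain, dict]:
    """One lap with field stimuli and burst-gated plasticity enabled.

    Returns (trained input matrix, spike record, traces); traces carry
    the burst log (burst_rows, burst_times).
    """
    cfg = model.cfg
    dur = cfg.lap_duration if lap_duration is None else lap_duration
    n_steps = int(round(dur / dt))
    S_bank = signals(model.bank, np.arange(n_steps) * dt)
    S_field = _field_signals(cfg, n_steps, dt)
    M, S = _drive(model, S_bank, S_field)
    plast = dict(rows=model.place_cells, n_bank=cfg.n_inp, alpha=cfg.alpha,
                 w_lo=0.0, w_hi=cfg.weight_bound,
                 window_ms=cfg.burst_window,
                 refractory_ms=cfg.plateau_refractory)
    spikes, traces = core.run(model.population, model.W, (M, S), dur,
                              dt=dt, seed=seed, plasticity=plast)
    M_trained = traces["M_drive"][:, :cfg.n_inp].copy()
    return M_trained, spikes, traces


def test_recall(model: HippocampalModel, M_trained: np.ndarray,
                lap_duration: Optional[float] = None, dt: float = DT_MS,
                seed: int = 0, record: Optional[core.RecordConfig] = None,
                ) -> dict:
    """Run with oscillator drive only (no fields, no plasticity)."""
    cfg = model.cfg
    dur = cfg.lap_duration if lap_duration is None else lap_duration
    n_steps = int(round(dur / dt))
    S_bank = signals(model.bank, np.arange(n_steps) * dt)
    M, S = _drive(model, S_bank, M_input=M_trained)
    spikes, traces = core.run(model.population, model.W, (M, S), dur,
                              dt=dt, seed=seed, record=record)
    order, peaks = activation_order(spikes, model.place_cells, dur)
    return {"spikes": spikes, "traces": traces, "order": order,
            "peak_times": peaks, "duration": dur}


def replay(model: HippocampalModel, M_trained: np.ndarray,
           factor: float = 0.15, reverse: bool = False,
           dt: float = DT_MS, seed: int = 0,
           ripple_band: Tuple[float, float] = (40.0, 200.0)) -> dict:
    """Compressed (and optionally time-reversed) replay of the drive.

    All oscillator periods are multiplied by ``factor``; the lap shrinks
    by the same factor.  ``reverse`` flips the compressed input sequence
    in time (inverted ripple).  Returns activation order and the dominant
    frequency of the reservoir population rate.
    """
    if factor <= 0:
        raise ConfigurationError("factor must be positive")
    cfg = model.cfg
    bank = rescale_bank(model.bank, factor)
    dur = round(cfg.lap_duration * factor / dt) * dt
    n_steps = int(round(dur / dt))
    S_bank = signals(bank, np.arange(n_steps) * dt)
    if reverse:
        S_bank = S_bank[::-1].copy()
    M, S = _drive(model, S_bank, M_input=M_trained)
    spikes, traces = core.run(model.population, model.W, (M, S), dur,
                              dt=dt, seed=seed)
    order, peaks = activation_order(spikes, model.place_cells, dur,
                                    kernel_sd=max(2.0, 20.0 * factor))
    f_dom = analysis.dominant_frequency(
        analysis.smooth_rate(traces["rate"], dt, kernel_sd=2.0), dt,
        f_min=ripple_band[0], f_max=ripple_band[1])
    return {"spikes": spikes, "order": order, "peak_times": peaks,
            "dominant_frequency": f_dom, "duration": dur}


def activation_order(spikes: core.SpikeTrain, cells: np.ndarray,
                     duration: float, kernel_sd: float = 20.0,
                     bin_ms: float = 1.0
                     ) -> Tuple[np.ndarray, np.ndarray]:
    """Order of cells by peak smoothed rate (ties: first spike; silent
    cells get peak time NaN and sort last)."""
    peaks = np.full(len(cells), np.nan)
    firsts = np.full(len(cells), np.inf)
    n_bins = int(round(duration / bin_ms))
    for j, c in enumerate(cells):
        t = spikes.for_neuron(int(c))
        if t.size == 0:
            continue
        firsts[j] = t.min()
        hist = np.zeros(n_bins)
        b = np.minimum((t / bin_ms).astype(int), n_bins - 1)
        np.add.at(hist, b, 1.0)
        sm = analysis.smooth_rate(hist, bin_ms, kernel_sd=kernel_sd)
        peaks[j] = (np.argmax(sm) + 0.5) * bin_ms
    key = np.where(np.isnan(peaks), np.inf, peaks)
    order = np.lexsort((firsts, key))
    return order, peaks


def order_correlation(order_a: Sequence[int],
                      order_b: Sequence[int]) -> float:
    """Kendall tau between two activation orders of the same cells."""
    a = np.asarray(order_a)
    b = np.asarray(order_b)
    rank_a = np.argsort(a)
    rank_b = np.argsort(b)
    return float(stats.kendalltau(rank_a, rank_b).statistic)


def phase_precession(spikes: core.SpikeTrain, model: HippocampalModel,
                     rate_counts: np.ndarray, dt: float = DT_MS,
                     min_spikes: int = 3) -> dict:
    """Spike theta phases along each place field and precession slopes.

    The reference phase comes from the 4-12 Hz band-passed population
    rate (Hilbert transform).  The slope per cell is a circular-linear
    regression of spike phase on time-in-field (rad/ms; negative =
    precession toward earlier phases).  Cells with fewer than
    ``min_spikes`` in-field spikes are flagged and skipped.
    """
    cfg = model.cfg
    phase = analysis.theta_phase(
        analysis.smooth_rate(rate_counts, dt, kernel_sd=5.0), dt)
    onsets = cfg.onsets()
    cells = []
    for j, c in enumerate(model.place_cells):
        t = spikes.for_neuron(int(c))
        m = (t >= onsets[j]) & (t < onsets[j] + cfg.field_duration)
        t_in = t[m]
        entry = {"cell": int(c), "onset": float(onsets[j]),
                 "n_spikes": int(t_in.size)}
        if t_in.size < min_spikes:
            entry.update(skipped=True, slope=np.nan, phases=np.array([]),
                         x_ms=np.array([]))
        else:
            idx = np.minimum((t_in / dt).astype(int), phase.size - 1)
            ph = phase[idx]
            x = t_in - onsets[j]
            entry.update(skipped=False, phases=ph, x_ms=x,
                         x_cm=x / cfg.ms_per_cm,
                         slope=circular_linear_slope(x, ph))
        cells.append(entry)
    slopes = np.array([c["slope"] for c in cells if not c["skipped"]])
    return {"cells": cells, "slopes": slopes,
            "median_slope": float(np.median(slopes)) if slopes.size else
            np.nan}


def circular_linear_slope(x: np.ndarray, phase: np.ndarray,
                          max_cycles: float = 2.0) -> float:
    """Slope (rad per unit x) maximizing the resultant length of
    phase - slope * x; searched over +-max_cycles over the x span."""
    x = np.asarray(x, float)
    phase = np.asarray(phase, float)
    span = max(np.ptp(x), 1e-9)
    grid = np.linspace(-max_cycles * 2 * np.pi / span,
                       max_cycles * 2 * np.pi / span, 2001)
    R = np.abs(np.exp(1j * (phase[None, :] - grid[:, None] * x[None, :]))
               .mean(axis=1))
    return float(grid[np.argmax(R)])
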