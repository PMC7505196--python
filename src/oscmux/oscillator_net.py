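"""Endogenous oscillator sub-networks and their coupling to the reservoir.

A densely connected (p = 1) balanced LIF network with slow inhibitory
decay transitions from asynchronous firing to periodic population events
when its excitatory neurons receive a step current; the event frequency
grows with the cue amplitude and falls with the inhibitory time constant.
Screened-for-stability oscillators replace artificial sinusoid banks as
the drive of the main reservoir: their spikes reach the reservoir through
a signed current projection M (scale sigma_inp = gamma_inp /
sqrt(p_inp * N_osc)), and the reservoir optionally projects back through
M' (gamma_fb = 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import scipy.sparse as sp

from . import srnn_core as core
from .analysis import dominant_frequency, smooth_rate, synchrony_spectrum
from .drive import CueInput, cue_lowrank, sigma_inp
from .params import DT_MS, OSCILLATOR, ConfigurationError, ParameterTable

__all__ = [
    "OscillatorNetwork", "StabilityReport", "ComposedModel",
    "build_oscillator", "simulate_oscillator", "measure_frequency",
    "stability_screen", "compose_full_model",
]

#: decay of the current pulse a presynaptic spike injects through M / M'
TAU_PROJECTION_MS = 20.0


@dataclass
class OscillatorNetwork:
    population: core.NeuronPopulation
    W: core.SynapticMatrix
    cue: CueInput
    tau_in_mean: float
    seed: int


@dataclass
class StabilityReport:
    trial_rates: np.ndarray      # (n_trials, n_bins) smoothed rates
    mean_correlation: float
    stable: bool
    threshold: float


def build_oscillator(tau_in_mean: float = 80.0, seed: int = 0,
                     size: Optional[int] = None,
                     table: ParameterTable = OSCILLATOR,
                     cue: Optional[CueInput] = None,
                     gamma_rnn: float = 4.0) -> OscillatorNetwork:
    """Sample an oscillator network with an overridden tau_in mean.

    ``gamma_rnn`` defaults to 4: with the balanced weight scale
    sigma = gamma / sqrt(N p), that coupling strength puts the dense
    network into the inhibition-paced regime where the event frequency
    falls with tau_in and grows with the cue amplitude; at weaker
    coupling the rhythm is paced by delays instead and loses its tau_in
    dependence.
    """
    if tau_in_mean <= 0:
        raise ConfigurationError("tau_in_mean must be positive")
    size = table.N if size is None else size
    _, sd = table.fields["tau_in"]
    tab = table.with_overrides(tau_in=(tau_in_mean, sd),
                               gamma_rnn=gamma_rnn)
    pop = core.sample_population(tab, size, seed=seed)
    W = core.build_recurrent_weights(size, tab.p_rnn, tab.gamma_rnn,
                                     seed=seed + 1)
    return OscillatorNetwork(
        population=pop, W=W, cue=cue or CueInput(),
        tau_in_mean=tau_in_mean, seed=seed,
    )


def simulate_oscillator(osc: OscillatorNetwork, duration: float,
                        dt: float = DT_MS, seed: int = 0,
                        cue_on: bool = True,
                        record: Optional[core.RecordConfig] = None,
                        ) -> Tuple[core.SpikeTrain, dict]:
    """Run the oscillator alone, cued or spontaneous."""
    n_steps = int(round(duration / dt))
    pop = osc.population
    if cue_on:
        targets = {"excitatory": pop.excitatory_indices,
                   "inhibitory": pop.inhibitory_indices}
        drive = cue_lowrank(osc.cue, n_steps, dt, targets, pop.size)
    else:
        drive = None
    return core.run(pop, osc.W, drive, duration, dt=dt, record=record,
                    seed=seed)


def measure_frequency(population_rate: np.ndarray, dt: float,
                      f_min: float = 1.0, f_max: float = 200.0,
                      spikes: Optional[core.SpikeTrain] = None,
                      t0: float = 0.0,
                      peak_factor: float = 10.0) -> Optional[float]:
    """Dominant population-rate frequency; None when asynchronous.

    With ``spikes`` provided, collective synchrony is isolated by the
    circular-shift shuffle predictor (regularly firing neurons put
    single-cell combs in the raw rate spectrum even when the population
    is asynchronous); the peak must exceed ``peak_factor`` times the
    shuffled spectrum.  Without spikes the gate falls back to the in-band
    spectral median.
    """
    if spikes is not None:
        f, ratio = synchrony_spectrum(spikes, t0=t0, f_min=f_min,
                                      f_max=f_max)
        return f if ratio >= peak_factor else None
    return dominant_frequency(population_rate, dt, f_min=f_min, f_max=f_max)


def stability_screen(osc: OscillatorNetwork, n_trials: int = 10,
                     threshold: float = 0.95, duration: float = 2000.0,
                     seeds: Optional[Sequence[int]] = None,
                     dt: float = DT_MS) -> StabilityReport:
    """Mean pairwise Pearson r of smoothed rates over cue-locked trials.

    Trials share the cue but start from independent initial conditions; a
    network is stable when the mean inter-trial correlation of its
    (20 ms-smoothed) population rate exceeds ``threshold``.
    """
    if n_trials < 2:
        raise ConfigurationError("need at least 2 trials")
    seeds = list(range(n_trials)) if seeds is None else list(seeds)
    if len(seeds) != n_trials:
        raise ConfigurationError("len(seeds) must equal n_trials")
    rates = []
    for s in seeds:
        _, tr = simulate_oscillator(osc, duration, dt=dt, seed=s)
        sm = smooth_rate(tr["rate"], dt)
        # score only the post-cue window where the oscillation lives
        i0 = int(round(osc.cue.t_stim / dt))
        rates.append(sm[i0:])
    rates = np.asarray(rates)
    n = len(rates)
    cs = []
    for a in range(n):
        for b in range(a + 1, n):
            sa, sb = rates[a], rates[b]
            if sa.std() == 0 or sb.std() == 0:
                cs.append(0.0)
            else:
                cs.append(float(np.corrcoef(sa, sb)[0, 1]))
    mean_c = float(np.mean(cs))
    return StabilityReport(trial_rates=rates, mean_correlation=mean_c,
                           stable=mean_c > threshold, threshold=threshold)


@dataclass
class ComposedModel:
    """Oscillator networks wired to a reservoir in one joint simulation.

    Neuron order: oscillator networks first (concatenated), reservoir
    last.  Cue step currents reach only the oscillator populations;
    oscillator spikes inject current pulses into the reservoir through M
    and, when feedback is enabled, reservoir spikes reach the oscillators
    through M'.
    """

    oscillators: List[OscillatorNetwork]
    srnn: core.Network
    population: core.NeuronPopulation
    W: core.SynapticMatrix
    current_synapses: tuple
    osc_slices: List[slice]
    srnn_slice: slice
    feedback: bool

    @property
    def exc_readout_indices(self) -> np.ndarray:
        off = self.srnn_slice.start
        return off + self.srnn.population.excitatory_indices

    def cue_drive(self, n_steps: int, dt: float,
                  cues: Optional[Sequence[CueInput]] = None
                  ) -> Tuple[np.ndarray, np.ndarray]:
        """Low-rank step-cue drive for all oscillator blocks."""
        cues = [o.cue for o in self.oscillators] if cues is None else cues
        Ms, Ss = [], []
        for osc, sl, cue in zip(self.oscillators, self.osc_slices, cues):
            targets = {
                "excitatory": sl.start + osc.population.excitatory_indices,
                "inhibitory": sl.start + osc.population.inhibitory_indices,
            }
            M, S = cue_lowrank(cue, n_steps, dt, targets,
                               self.population.size)
            Ms.append(M)
            Ss.append(S)
        return np.concatenate(Ms, axis=1), np.concatenate(Ss, axis=1)

    def simulate(self, duration: float, dt: float = DT_MS, seed: int = 0,
                 cue_on: bool = True,
                 cues: Optional[Sequence[CueInput]] = None,
                 record: Optional[core.RecordConfig] = None,
                 clamped: Optional[Sequence[int]] = None,
                 ) -> Tuple[core.SpikeTrain, dict]:
        n_steps = int(round(duration / dt))
        drive = self.cue_drive(n_steps, dt, cues) if cue_on else None
        return core.run(self.population, self.W, drive, duration, dt=dt,
                        record=record, seed=seed, clamped=clamped,
                        current_synapses=self.current_synapses)


def _concat_populations(pops: List[core.NeuronPopulation]
                        ) -> core.NeuronPopulation:
    import dataclasses

    arrays = {}
    for f in dataclasses.fields(core.NeuronPopulation):
        if f.name in ("size",):
            continue
        arrays[f.name] = np.concatenate([getattr(p, f.name) for p in pops])
    return core.NeuronPopulation(size=sum(p.size for p in pops), **arrays)


def compose_full_model(oscillators: Sequence[OscillatorNetwork],
                       srnn: core.Network, feedback: bool = True,
                       gamma_inp: float = 10.0, p_inp: float = 0.5,
                       gamma_fb: float = 0.5, p_fb: float = 0.5,
                       tau_projection: float = TAU_PROJECTION_MS,
                       seed: int = 0) -> ComposedModel:
    """Wire oscillator networks and a reservoir into one joint network.

    Cross-projections are signed current synapses: each oscillator spike
    injects an exponentially decaying current pulse (time constant
    ``tau_projection`` ms) of magnitude M[i, j] ~ N(0, sigma_inp) into
    reservoir neuron i, with sigma_inp = gamma_inp / sqrt(p_inp * N_osc);
    the optional feedback M' ~ N(0, sigma_fb), sigma_fb = gamma_fb /
    sqrt(p_fb * N_rnn), runs the other way.
    """
    oscillators = list(oscillators)
    if not oscillators:
        raise ConfigurationError("need at least one oscillator network")
    rng = np.random.default_rng(seed)
    pops = [o.population for o in oscillators] + [srnn.population]
    sizes = [p.size for p in pops]
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    n_total = int(offsets[-1])
    osc_slices = [slice(int(offsets[i]), int(offsets[i + 1]))
                  for i in range(len(oscillators))]
    srnn_slice = slice(int(offsets[-2]), n_total)

    population = _concat_populations(pops)

    blocks = [o.W.magnitudes for o in oscillators] + [srnn.W.magnitudes]
    W_big = sp.block_diag(blocks, format="csc")
    W = core.SynapticMatrix(magnitudes=W_big, density=float("nan"),
                            sigma=float("nan"), gain=float("nan"))

    # signed current cross-projections as one sparse matrix [post, pre]
    cross = sp.lil_matrix((n_total, n_total))
    n_rnn = srnn.population.size
    for osc, sl in zip(oscillators, osc_slices):
        n_osc = osc.population.size
        s_inp = sigma_inp(gamma_inp, p_inp, n_osc)
        mask = rng.random((n_rnn, n_osc)) < p_inp
        M = np.zeros((n_rnn, n_osc))
        M[mask] = rng.normal(0.0, s_inp, int(mask.sum()))
        cross[srnn_slice, sl] = M
        if feedback:
            s_fb = gamma_fb / np.sqrt(p_fb * n_rnn)
            mask_fb = rng.random((n_osc, n_rnn)) < p_fb
            Mfb = np.zeros((n_osc, n_rnn))
            Mfb[mask_fb] = rng.normal(0.0, s_fb, int(mask_fb.sum()))
            cross[sl, srnn_slice] = Mfb
    cross = cross.tocsc()
    current_synapses = (
        cross.indptr.astype(np.int64), cross.indices.astype(np.int64),
        cross.data.astype(float), float(tau_projection),
    )

    return ComposedModel(
        oscillators=list(oscillators), srnn=srnn, population=population,
        W=W, current_synapses=current_synapses, osc_slices=osc_slices,
        srnn_slice=srnn_slice, feedback=feedback,
    )
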