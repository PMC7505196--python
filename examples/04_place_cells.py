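"""Place-cell sequences: one-lap learning, theta replay and ripples.

A reservoir (CA1) driven by 20 theta-band oscillators (CA3) designates
ten excitatory neurons as place cells.  During a single 5 s lap each
cell receives a 600 ms depolarizing 10 Hz input at its field; bursts
gate a potentiation of the oscillator-to-cell weights toward the phase
configuration of that moment.  At test time the oscillators alone evoke
the sequence; compressing their periods by 0.15 evokes it at ripple
speed.
"""

import numpy as np

from oscmux import hippocampus as hc

model = hc.build_hippocampal_model(seed=1)
cfg = model.cfg
print(f"{cfg.n_place} place cells, fields every "
      f"{cfg.onsets()[1]:.0f} ms (~{cfg.onsets()[1]/cfg.ms_per_cm:.0f} cm "
      "on the virtual track)\n")

pre = hc.test_recall(model, model.M_input, seed=5)
n_pre = sum(pre["spikes"].for_neuron(int(c)).size
            for c in model.place_cells)
print(f"before training: {n_pre} place-cell spikes (silent)")

M, spikes, traces = hc.training_lap(model, seed=2)
print(f"training lap: {len(traces['burst_times'])} plasticity events "
      f"(bursts), weights within [0, {cfg.weight_bound}]")

prec = hc.phase_precession(spikes, model, traces["rate"])
print(f"phase precession: median circular-linear slope "
      f"{prec['median_slope']*1000:.2f} rad/s "
      "(negative = spikes drift to earlier theta phases)")

recall = hc.test_recall(model, M, seed=7)
counts = np.array([recall["spikes"].for_neuron(int(c)).size
                   for c in model.place_cells])
active = np.flatnonzero(counts)
print(f"\nrecall (drive only): {counts.sum()} place-cell spikes, "
      f"cells {active.tolist()} active")
print(f"  peak times (ms): "
      f"{np.round(recall['peak_times'][active]).tolist()} "
      "(order fidelity is limited; see docs/methods.md)")

rep = hc.replay(model, M, factor=0.15, seed=8)
print(f"compressed replay: dominant population frequency "
      f"{rep['dominant_frequency']:.1f} Hz (ripple band)")

rev = hc.replay(model, M, factor=0.15, reverse=True, seed=9)
n_rev = sum(rev["spikes"].for_neuron(int(c)).size
            for c in model.place_cells)
print(f"reversed ripple: {n_rev} place-cell spikes under the "
      "time-flipped compressed drive")
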