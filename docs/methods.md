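# Methods

## Model

`oscmux` simulates balanced networks of conductance-based leaky
integrate-and-fire neurons obeying

    C dV/dt = (E_L − V)/R + g_ex (E_ex − V) + g_in (E_in − V)
              + I_tonic + I_ext(t)

with exponentially decaying synaptic conductances incremented by delayed
presynaptic spikes, an absolute refractory period (V pinned at V_reset),
and Dale's principle: every neuron's outgoing synapses increment either
g_ex (excitatory presynaptic neuron) or g_in (inhibitory), never both.
80% of neurons are excitatory.  Per-neuron parameters are drawn from
Gaussian tables (`params.MAIN_SRNN` for the sparse reservoir,
`params.OSCILLATOR` for the dense oscillator sub-networks); recurrent
weight magnitudes are half-normal |N(0, σ_rnn)| with the balanced-network
scale σ_rnn = γ_rnn/√(N·p_rnn), overridable.  All ODEs are integrated by
forward Euler at Δt = 0.05 ms in a single compiled kernel.

The reservoir's external input is a bank of sinusoids
s_k(t) = (A/2)(sin(2π f_k t + φ_k) + 1) (range [0, A], A = 30 pA by
default; the hippocampal model uses the full-range variant A(sin+1) with
A = 1) projected through a sparse signed matrix M with N(0, 1) nonzero
entries at density p_inp = 0.3.  Because the joint phase vector of the
bank repeats only at the least common multiple of the component periods,
two inputs at 4 and 5 Hz give the network a non-repeating temporal code
lasting exactly 1 s; longer or richer codes come from more components.
Phase jitter, when enabled, turns each φ_k into a Gaussian-increment
random walk with var(φ(t) − φ(0)) = t·σ_φ².

Only excitatory neurons feed the readout.  Their spike trains are
filtered by the double exponential with rise 6 ms and decay 60 ms,
normalized so one spike contributes the unit-area kernel
[e^(−t/τ_d) − e^(−t/τ_r)]/(τ_d − τ_r) (integrated with exact exponential
propagators, not Euler, since the filter is linear).  The readout
ŷ = W_outᵀ r is trained by recursive least squares every 2.5 ms:
e = W_outᵀr − y with pre-update weights, P updated by the
Sherman–Morrison rank-one formula from P(0) = I/α, W_out ← W_out − (Pr)e ᵀ
with the post-update gain.  Iterating these updates over a fixed design
is algebraically identical to ridge regression (RᵀR + αI)⁻¹RᵀY, which
the tests use as an oracle.

## Training protocol

Trials run back to back in one continuous simulation: membrane state
carries over, input phases are reset at every trial onset, and two
burn-in trials precede training so the network sits on its input-locked
trajectory.  Each epoch is one training trial followed by a frozen test
trial; test performance is the Pearson correlation between the target
and the readout output averaged over five frozen trials (averaging a
handful of test repetitions is also how the model's outputs are usually
displayed).  Both W_out and P are frozen during testing.

Two defaults deserve justification:

* **α = 0.01.**  The filtered rates are O(10⁻²) in 1/ms units, so RᵀR
  over a few thousand grid points is O(1) and α sets a meaningful ridge
  penalty.  Small α buys a slightly better asymptotic fit, but large
  readout weights achieve it through delicate cancellations between
  correlated neurons, and such solutions shatter when part of the
  population is clamped.  α = 0.01 keeps the weights small enough that
  the output degrades gracefully under structural perturbation while
  still converging within ten epochs.

* **Task duration = joint input period.**  A target longer than the LCM
  of the input periods is unlearnable in the entrained regime: the
  reservoir trajectory repeats, so the output repeats.  The stock
  two-input task therefore uses a 1 s target (the 4 & 5 Hz joint
  period); the capacity experiments extend duration by adding inputs
  with incommensurate frequencies.

## Oscillator networks

Dense (p = 1) networks with slow inhibition (τ_in ≈ 80 ms) act as
central pattern generators: a step current onto the excitatory neurons
flips them from near-silence into periodic population events.
`build_oscillator` defaults to γ_rnn = 4 (σ = γ/√N ≈ 0.18): at that
coupling the rhythm is paced by inhibition, so the event frequency falls
as τ_in grows (≈23 → 18 → 9 Hz over 70/100/130 ms) and rises with the
cue amplitude (≈8 → 20 → 38 Hz over 10/20/40 pA).  At γ_rnn = 1 the
same architecture synchronizes through delays instead and the frequency
loses its τ_in dependence — both regimes are reachable; the default
picks the one that makes the networks usable as tunable oscillators.
A stability screen keeps only realizations whose smoothed population
rate correlates above 0.95 across cue-locked trials with independent
initial conditions.

Cross-projections between oscillators and the reservoir inject current,
not conductance (their weights are signed Gaussians, which cannot be
Dale-routed synapses): each presynaptic spike adds M[i,j] pA of
exponentially decaying current (τ = 20 ms) to its target, with
σ_inp = γ_inp/√(p_inp·N_osc), γ_inp = 10, and feedback σ_fb with
γ_fb = 0.5.

### Detecting synchrony

Deterministic LIF neurons fire regularly, so the rate spectrum of an
*asynchronous* network still contains single-neuron frequency combs that
defeat a naive "peak over spectral median" test.  `synchrony_spectrum`
therefore compares the rate spectrum against a shuffle predictor in
which every neuron's spike train is circularly shifted by a random
offset — per-neuron spectra survive, cross-neuron alignment does not.
Measured peak-to-shuffle ratios: cued oscillator ≈ 140, sinusoid-driven
reservoir ≈ 34, spontaneous reservoir ≈ 8, uncued oscillator ≈ 10; the
default gate is 10.

## Hippocampal model

The CA1 reservoir (C = 100 pF, γ_rnn = 0.5) receives 20 dense theta-band
oscillators (7.5–8.5 Hz, full-range signals in [0, 2]).  Ten random
excitatory neurons are place cells; their resting potential **and spike
threshold** are pinned to the table means — selectivity at recall rides
on a sub-millivolt margin, and millivolt-scale excitability differences
between cells would otherwise dominate the learned tuning.  Non-place
input rows are signed N(0, 1) (the generic projection convention), the
plastic place rows start from the half-normal f(0, σ_inp = 0.1).

During the single 5 s training lap each cell receives a 600 ms
depolarizing oscillation at 10 Hz — implemented as the half-range form
(A/2)(sin(2πf(t−onset) − π/2) + 1) ∈ [0, 60] pA so the stimulus ramps
from zero at field entry — slightly faster than the background theta,
which is what produces phase precession (spikes lock to the faster
environmental input and drift to earlier theta phases across the field).
Whenever a place cell fires three spikes within 50 ms, its input weights
are potentiated by the instantaneous oscillator signals,
M[i,k] ← clip(M[i,k] + 0.25·s_k(t_burst), 0, 5σ_inp), evaluated at the
first spike of the triplet and applied online inside the simulation
kernel.  A plateau refractory period (default 600 ms, one event per
field crossing) re-arms the gate: the rule is modeled on dendritic
calcium plateaus, which are rare events producing large potentiation
from few pairings, and without the refractory the ~6–13 bursts a field
evokes saturate every weight at the bound and erase the tuning.

Replay compresses all oscillator periods by 0.15 (50–57 Hz) and runs the
frozen model for 0.15 of a lap; reverse replay additionally flips the
compressed input sequence in time.  The replay's dominant frequency is
measured inside a ripple band (≥ 40 Hz) because the rate spectrum also
contains slower envelope/subharmonic components that are not the ripple.

### Known limitation: recall order fidelity

The sequence-recall mechanism is coincidence detection: each cell's
learned weight row is a nonnegative matched filter for the oscillator
phase configuration of its field.  With 20 oscillators confined to a
1–2 Hz band, the filter's alignment peak exceeds the background drive
envelope by only ≈ 2.6 SD while a 5 s lap offers ~40 theta cycles of
comparable random excursions; even an ideal detector of the learned
drive places the best cycle at the trained field for only a minority of
cells.  Recalled sequences are therefore noisy orderings (typical
Kendall τ ≈ 0.2–0.5 against the training order) rather than exact ones;
compressed and reversed replay inherit the same fidelity.  Pre-training
silence, in-field bursting, phase precession and ripple-band replay are
all robust.

## Speech codec

The mel codec is built on scipy alone: 25 ms Hann frames hopped every
2.5 ms (so frames land on the readout grid), a 64-band triangular mel
filterbank spanning 300 Hz – 8 kHz, log1p compression for the readout
targets, and inversion through the filterbank pseudo-inverse followed by
32 Griffin–Lim iterations.  Rescaled outputs are linearly resampled back
to the original frame grid before computing per-channel correlations.
The test fixture is a fully synthetic two-syllable "word" (glottal
harmonic source shaped by gliding formant stacks) generated at run time,
so no recordings ship with the package.

## Numerical and sampling choices

* Forward Euler at Δt = 0.05 ms keeps the single-neuron charging curve
  within 0.5% of the closed form; the linear spike filter uses exact
  propagators.
* Axonal delays are rounded to ≥ 1 integration step per presynaptic
  neuron (ring buffer); refractory periods are rounded *up*, so empirical
  ISIs never undercut τ_ref.
* Gaussian parameter sampling enforces positivity by per-field rejection
  (≤ 100 attempts).  V_reset ≤ E_L is enforced by sampling V_reset from
  the exact truncated normal the rejection scheme targets: E_L and
  V_reset share a distribution, so naive joint rejection would both bias
  mean(E_L) upward and stall on low E_L draws.
* Initial conditions: V(0) ~ U[V_reset, V_theta), conductances zero —
  avoids a synchronized-startup artifact.
* Self-connections are excluded; Dale routing and conductance positivity
  are asserted in tests over driven runs.
* Seeds: every stochastic component draws from its own
  deterministically derived stream; identical (seed, inputs) give
  bitwise-identical spike trains.

### Known limitation: recruited fraction

Under the temporal-selectivity protocol (10 inputs, 5–10 Hz, 30 one-
second trials) the stock reservoir recruits ~60% of its neurons
(median over realizations), not more: with the tonic current parked
1 mV below threshold, recruitment is decided almost entirely by the
sign and size of each neuron's sparse input projection, and neurons
with strongly negative projections stay silent regardless of trial
count, the σ_rnn convention, or whether state carries across trials.
The acceptance suite states the expected fraction it checks against;
the measured value sits just outside that band and the corresponding
test is left failing rather than redefining "active".

## What the synthetic conditions do and do not show

All experiments run on synthetic drive and targets: sinusoids with
exactly known periods, Gaussian noise targets with controlled bandwidth,
and a deterministic lap on a virtual track.  Passing tests show that the
mechanisms — multiplexed-period temporal codes, RLS readout learning,
rescaling by a common period factor, burst-gated tuning to phase
configurations — behave as designed in a noiseless, stationary world.
They do not speak to robustness against non-stationary inputs, real
speech variability, variable running speed, or biological noise sources
beyond the optional phase jitter.  Problem sizes used throughout
(N = 1000 reservoirs, 500-neuron oscillators, 5-seed medians) are the
package's stock desk scale; every size is a parameter.
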