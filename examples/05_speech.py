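"""Speech task: learn a word's 64-channel mel spectrogram, rescale it.

A synthetic two-syllable word is encoded as a 64-band mel spectrogram
(300 Hz - 8 kHz), each band becomes one readout target, and the trained
network is probed with compressed/expanded input oscillations.  Outputs
are scaled back to the original speed before comparison, so the printed
mean channel correlations measure how well the word survives speaking
it faster or slower.
"""

from oscmux import audio, tasks

wave, sr = audio.synth_word(seed=0)
spec = audio.wave_to_mel(wave, sr)
print(f"word: {len(wave)/sr*1000:.0f} ms, {spec.n_channels} mel channels"
      f" x {spec.n_frames} frames")

system = tasks.build_driven_network(size=400, n_inp=3,
                                    f_range=(3.0, 8.0), seed=5)
protocol = tasks.ExperimentProtocol(n_epochs=8, seed=5, n_test_trials=3)
out = audio.speech_experiment(system, wave, sr, [0.5, 1.0, 2.0],
                              protocol)

print("\nfactor -> mean per-channel Pearson r (scaled back)")
for f, r in zip(out["factors"], out["mean_r_by_factor"]):
    print(f"  {f:3.1f}  ->  {r:6.3f}")

rec = audio.mel_to_wave(out["spectrogram"])
audio.write_wav("scratch_reconstructed_word.wav", rec, sr)
print("\nwrote scratch_reconstructed_word.wav "
      "(codec round trip of the target, for listening)")
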