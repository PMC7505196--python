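"""Speech codec: waveform <-> 64-channel mel spectrogram, speech task.

A word waveform is analysed by a short-time Fourier transform (25 ms
frames, 2.5 ms hop so frames land on the readout grid), projected onto a
64-band mel filterbank spanning 300 Hz - 8 kHz, and log-compressed.  The
64 channels are the targets of 64 readout units.  Inversion goes through
the filterbank pseudo-inverse followed by Griffin-Lim phase
reconstruction, which is enough to make reconstructed words audible.

Rescaled utterances are produced by compressing/expanding the input
oscillator periods; outputs are time-scaled back to the original frame
grid before computing per-channel Pearson correlations with the target
spectrogram.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.signal import ShortTimeFFT, get_window

from . import readout as ro, tasks
from .params import ConfigurationError, GRID_MS
from .readout import TargetSignal

__all__ = [
    "MelSpectrogram", "wave_to_mel", "mel_to_wave", "speech_experiment",
    "mel_filterbank", "synth_word", "read_wav", "write_wav",
]

N_MELS = 64
F_MIN = 300.0
F_MAX = 8000.0
FRAME_MS = 25.0
HOP_MS = GRID_MS


@dataclass
class MelSpectrogram:
    """Nonnegative mel-band amplitudes, 64 channels x time frames."""

    values: np.ndarray
    frame_rate: float                       # frames per second
    f_range: Tuple[float, float] = (F_MIN, F_MAX)
    sample_rate: int = 16000

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def duration_ms(self) -> float:
        return 1000.0 * self.n_frames / self.frame_rate


def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, float) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, float) / 2595.0) - 1.0)


def mel_filterbank(sr: int, n_fft: int, n_mels: int = N_MELS,
                   fmin: float = F_MIN, fmax: float = F_MAX) -> np.ndarray:
    """Triangular mel filterbank, shape (n_mels, n_fft//2 + 1)."""
    mel_pts = np.linspace(_hz_to_mel(fmin), _hz_to_mel(fmax), n_mels + 2)
    hz_pts = _mel_to_hz(mel_pts)
    freqs = np.linspace(0.0, sr / 2.0, n_fft // 2 + 1)
    fb = np.zeros((n_mels, freqs.size))
    for m in range(n_mels):
        lo, ctr, hi = hz_pts[m], hz_pts[m + 1], hz_pts[m + 2]
        up = (freqs - lo) / max(ctr - lo, 1e-12)
        down = (hi - freqs) / max(hi - ctr, 1e-12)
        fb[m] = np.clip(np.minimum(up, down), 0.0, None)
    return fb


def _stft_obj(sr: int) -> ShortTimeFFT:
    nperseg = int(round(sr * FRAME_MS / 1000.0))
    hop = max(1, int(round(sr * HOP_MS / 1000.0)))
    win = get_window("hann", nperseg)
    return ShortTimeFFT(win, hop=hop, fs=sr)


def wave_to_mel(wave: np.ndarray, sr: int) -> MelSpectrogram:
    """Mono waveform -> 64-channel mel amplitude spectrogram."""
    wave = np.asarray(wave, dtype=float)
    if wave.ndim != 1:
        raise ConfigurationError("require a mono waveform (1-D array)")
    if sr < 16000:
        raise ConfigurationError("sample rate must be >= 16 kHz")
    stft = _stft_obj(sr)
    mag = np.abs(stft.stft(wave))
    fb = mel_filterbank(sr, stft.mfft)
    vals = fb @ mag
    return MelSpectrogram(values=vals, frame_rate=sr / stft.hop,
                          sample_rate=sr)


def mel_to_wave(spec: MelSpectrogram, n_iter: int = 32,
                seed: int = 0) -> np.ndarray:
    """Approximate inversion: filterbank pseudo-inverse + Griffin-Lim."""
    if np.any(spec.values < 0):
        raise ConfigurationError("mel values must be nonnegative")
    sr = spec.sample_rate
    stft = _stft_obj(sr)
    fb = mel_filterbank(sr, stft.mfft)
    mag = np.clip(np.linalg.pinv(fb) @ spec.values, 0.0, None)
    if not np.any(mag > 0):
        n = int(stft.hop * (spec.n_frames - 1) + stft.win.size)
        return np.zeros(max(n, 1))
    rng = np.random.default_rng(seed)
    phase = np.exp(2j * np.pi * rng.random(mag.shape))
    x = None
    for _ in range(n_iter):
        x = stft.istft(mag * phase)
        rec = stft.stft(x)
        if rec.shape[1] > mag.shape[1]:
            rec = rec[:, : mag.shape[1]]
        elif rec.shape[1] < mag.shape[1]:
            rec = np.pad(rec, ((0, 0), (0, mag.shape[1] - rec.shape[1])))
        phase = np.exp(1j * np.angle(rec))
    return x


def mel_target(spec: MelSpectrogram, grid: float = GRID_MS,
               log_compress: bool = True) -> TargetSignal:
    """Mel spectrogram as a readout target on the training grid."""
    vals = np.log1p(spec.values) if log_compress else spec.values
    frame_ms = 1000.0 / spec.frame_rate
    y = vals.T
    if abs(frame_ms - grid) > 1e-9:
        n_new = int(round(spec.duration_ms / grid))
        old = np.linspace(0, 1, y.shape[0])
        new = np.linspace(0, 1, n_new)
        y = np.column_stack([np.interp(new, old, y[:, k])
                             for k in range(y.shape[1])])
    return TargetSignal(y=np.ascontiguousarray(y), grid_ms=grid)


def target_to_mel(y: np.ndarray, frame_rate: float, sample_rate: int,
                  log_compress: bool = True) -> MelSpectrogram:
    """Invert ``mel_target`` scaling for readout outputs."""
    vals = np.clip(y.T, 0.0 if not log_compress else 0.0, None)
    if log_compress:
        vals = np.expm1(np.clip(y.T, 0.0, None))
    return MelSpectrogram(values=vals, frame_rate=frame_rate,
                          sample_rate=sample_rate)


def speech_experiment(system: "tasks.DrivenNetwork", wave: np.ndarray,
                      sr: int, factors: Sequence[float],
                      protocol: "tasks.ExperimentProtocol",
                      ) -> dict:
    """Train 64 readouts on a word spectrogram; test rescaled utterances.

    The trial duration is the word duration; per factor the input periods
    are multiplied by the factor, the frozen output is scaled back to the
    original frame grid, and the mean per-channel Pearson r against the
    target spectrogram is reported.
    """
    spec = wave_to_mel(wave, sr)
    target = mel_target(spec, grid=protocol.grid)
    dur = round(target.duration / protocol.grid) * protocol.grid
    proto = replace(protocol, trial_duration=dur)
    result = tasks.train_network(system, target, proto)
    resc = tasks.rescaling_experiment(result, factors, seed=protocol.seed)
    return {
        "result": result, "target": target, "spectrogram": spec,
        "factors": np.asarray(list(factors), float),
        "mean_r_by_factor": resc.r[0],
        "rescaling": resc,
    }


def synth_word(duration_s: float = 0.45, sr: int = 16000,
               seed: int = 0) -> Tuple[np.ndarray, int]:
    """Synthetic two-syllable multi-formant "word" (test fixture).

    Two voiced segments with distinct formant stacks and glides, a
    pitch contour and smooth amplitude envelopes; entirely generated, no
    recording involved.
    """
    rng = np.random.default_rng(seed)
    n = int(duration_s * sr)
    t = np.arange(n) / sr
    wave = np.zeros(n)
    segments = [
        (0.05, 0.45, 120.0, [(700, 500), (1200, 1000), (2600, 2400)]),
        (0.55, 0.95, 100.0, [(350, 450), (2000, 2300), (3000, 3000)]),
    ]
    for frac0, frac1, f0, formants in segments:
        i0, i1 = int(frac0 * n), int(frac1 * n)
        seg_t = t[i0:i1] - t[i0]
        seg_dur = seg_t[-1] if seg_t.size else 1.0
        # glottal source: harmonics of a gliding pitch
        pitch = f0 * (1.0 + 0.1 * seg_t / seg_dur)
        src = np.zeros_like(seg_t)
        phase = 2 * np.pi * np.cumsum(pitch) / sr
        for h in range(1, 30):
            src += np.sin(h * phase) / h
        # formant emphasis: sum of band-limited resonances
        out = np.zeros_like(seg_t)
        for (fa, fb) in formants:
            fc = fa + (fb - fa) * seg_t / seg_dur
            out += np.sin(2 * np.pi * np.cumsum(fc) / sr) * 0.3
        seg = src * 0.5 + out * 0.5
        env = np.sin(np.pi * seg_t / seg_dur) ** 2
        wave[i0:i1] += seg * env
    wave += rng.normal(0, 1e-4, n)
    wave /= np.max(np.abs(wave))
    return wave, sr


def read_wav(path) -> Tuple[np.ndarray, int]:
    """Mono float waveform in [-1, 1] from a PCM WAV file."""
    from scipy.io import wavfile

    sr, data = wavfile.read(path)
    if data.ndim != 1:
        raise ConfigurationError("require a mono WAV file")
    if np.issubdtype(data.dtype, np.integer):
        data = data / float(np.iinfo(data.dtype).max)
    return np.asarray(data, float), int(sr)


def write_wav(path, wave: np.ndarray, sr: int) -> None:
    from scipy.io import wavfile

    w = np.asarray(wave, float)
    peak = np.max(np.abs(w)) or 1.0
    wavfile.write(path, sr, (w / peak * 32767).astype(np.int16))
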