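"""Oscillatory external drive: sinusoid banks, projections, jitter, cues.

A bank of N_inp sinusoids with incommensurate periods produces a joint
phase vector whose repetition time is the least common multiple of the
component periods, giving the downstream network a temporal code far
longer than any single oscillation.  Two amplitude conventions exist:

``half_range``
    s_k(t) = (A/2) (sin(2 pi f_k t + phi_k) + 1), range [0, A] — the
    default for artificial drive.

``full_range``
    s_k(t) = A (sin(2 pi f_k t + phi_k) + 1), range [0, 2A] — used by the
    hippocampal model (with A = 1).

Phase jitter is a Gaussian-increment random walk per unit with increment
variance sigma_phi^2 * dt per bin, so var(phi_N - phi_0) = t * sigma_phi^2.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from fractions import Fraction
from math import gcd
from typing import Optional, Sequence, Tuple

import numpy as np

from .params import ConfigurationError

__all__ = [
    "OscillatorBank", "InputProjection", "PhaseJitterConfig", "CueInput",
    "sample_bank", "fixed_bank", "current_at", "signals", "jitter_phases",
    "sigma_deg", "build_projection", "cue_currents", "cue_lowrank",
    "rescale_bank", "reset_phases", "joint_period_ms", "sigma_inp",
]

VARIANTS = ("half_range", "full_range")


@dataclass(frozen=True)
class OscillatorBank:
    """Frequencies (Hz), initial phases (rad in [-pi, pi)) and amplitude."""

    f: np.ndarray
    phi0: np.ndarray
    A: float
    variant: str = "half_range"

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ConfigurationError(f"unknown variant {self.variant!r}")
        if np.any(self.f <= 0):
            raise ConfigurationError("frequencies must be positive")
        if self.A < 0:
            raise ConfigurationError("amplitude must be nonnegative")

    @property
    def n_inp(self) -> int:
        return len(self.f)

    @property
    def periods_ms(self) -> np.ndarray:
        return 1000.0 / self.f


@dataclass(frozen=True)
class InputProjection:
    """Signed sparse-in-expectation input weights M[post, input unit]."""

    M: np.ndarray
    density: float
    sigma: float

    @property
    def n_post(self) -> int:
        return self.M.shape[0]

    @property
    def n_inp(self) -> int:
        return self.M.shape[1]


@dataclass(frozen=True)
class PhaseJitterConfig:
    sigma_phi_sq: float   # rad^2 / ms
    dt: float             # ms
    seed: int = 0

    def __post_init__(self):
        if self.sigma_phi_sq < 0:
            raise ConfigurationError("sigma_phi_sq must be nonnegative")
        if self.dt <= 0:
            raise ConfigurationError("dt must be positive")


@dataclass(frozen=True)
class CueInput:
    """Step-current cue: excitatory pulse with a shorter inhibitory transient."""

    t_stim: float = 500.0
    t_end_ex: float = 2000.0
    t_end_in: float = 600.0
    A: float = 20.0
    W_in: float = 1.0

    def __post_init__(self):
        if not (self.t_end_ex > self.t_end_in >= self.t_stim):
            raise ConfigurationError(
                "cue requires t_end_ex > t_end_in >= t_stim"
            )


def sample_bank(n_inp: int, f_min: float, f_max: float, A: float = 30.0,
                variant: str = "half_range",
                seed: int = 0) -> OscillatorBank:
    """f ~ U(f_min, f_max), phi0 ~ U(-pi, pi), fixed per realization."""
    if n_inp < 1:
        raise ConfigurationError("n_inp must be >= 1")
    if not 0 < f_min <= f_max:
        raise ConfigurationError("need 0 < f_min <= f_max")
    rng = np.random.default_rng(seed)
    f = rng.uniform(f_min, f_max, n_inp)
    phi0 = rng.uniform(-np.pi, np.pi, n_inp)
    return OscillatorBank(f=f, phi0=phi0, A=A, variant=variant)


def fixed_bank(f: Sequence[float], phi0: Optional[Sequence[float]] = None,
               A: float = 30.0,
               variant: str = "half_range") -> OscillatorBank:
    """Bank with explicitly chosen frequencies (e.g. the 4 & 5 Hz pair)."""
    f = np.asarray(f, dtype=float)
    phi0 = np.zeros_like(f) if phi0 is None else np.asarray(phi0, float)
    return OscillatorBank(f=f, phi0=phi0, A=A, variant=variant)


def signals(bank: OscillatorBank, t_ms: np.ndarray,
            phases: Optional[np.ndarray] = None) -> np.ndarray:
    """Per-unit drive signals, shape (len(t_ms), n_inp).

    ``phases`` optionally overrides the static phi0 — either a vector
    (n_inp,) or a trajectory (len(t_ms), n_inp) from ``jitter_phases``.
    """
    t = np.asarray(t_ms, dtype=float)[:, None] / 1000.0  # s
    if phases is None:
        phi = bank.phi0[None, :]
    else:
        phi = np.asarray(phases, dtype=float)
        if phi.ndim == 1:
            phi = phi[None, :]
    raw = np.sin(2.0 * np.pi * bank.f[None, :] * t + phi) + 1.0
    if bank.variant == "half_range":
        return (bank.A / 2.0) * raw
    return bank.A * raw


def current_at(bank: OscillatorBank, M: InputProjection, t: float,
               phases_override: Optional[np.ndarray] = None) -> np.ndarray:
    """I_ext = M @ s(t), pA per postsynaptic neuron."""
    if M.n_inp != bank.n_inp:
        raise ConfigurationError("projection width != bank size")
    s = signals(bank, np.array([t]), phases_override)[0]
    return M.M @ s


def jitter_phases(bank: OscillatorBank, cfg: PhaseJitterConfig,
                  n_steps: int) -> np.ndarray:
    """Random-walk phase trajectories, shape (n_steps, n_inp); row 0 = phi0."""
    if n_steps < 0:
        raise ConfigurationError("n_steps must be >= 0")
    if n_steps == 0:
        return np.zeros((0, bank.n_inp))
    rng = np.random.default_rng(cfg.seed)
    eps = rng.normal(0.0, np.sqrt(cfg.sigma_phi_sq * cfg.dt),
                     size=(n_steps - 1, bank.n_inp)) \
        if n_steps > 1 and cfg.sigma_phi_sq > 0 \
        else np.zeros((max(n_steps - 1, 0), bank.n_inp))
    traj = np.empty((n_steps, bank.n_inp))
    traj[0] = bank.phi0
    np.cumsum(eps, axis=0, out=traj[1:]) if n_steps > 1 else None
    traj[1:] += bank.phi0[None, :]
    return traj


def sigma_deg(t_ms: float, sigma_phi_sq: float) -> float:
    """Accumulated phase SD after t ms, in degrees: sqrt(t sigma^2)*180/pi."""
    return float(np.sqrt(t_ms * sigma_phi_sq) * 180.0 / np.pi)


def sigma_inp(gamma_inp: float, p_inp: float, n_osc: int) -> float:
    """Input-projection weight scale gamma_inp / sqrt(p_inp * N_osc)."""
    return gamma_inp / np.sqrt(p_inp * n_osc)


def build_projection(n_post: int, n_inp: int, p_inp: float,
                     sigma: float = 1.0, seed: int = 0) -> InputProjection:
    """Bernoulli(p_inp) mask with Normal(0, sigma) nonzero entries."""
    if not 0.0 < p_inp <= 1.0:
        raise ConfigurationError("p_inp must lie in (0, 1]")
    if sigma < 0:
        raise ConfigurationError("sigma must be nonnegative")
    rng = np.random.default_rng(seed)
    mask = rng.random((n_post, n_inp)) < p_inp
    M = np.zeros((n_post, n_inp))
    M[mask] = rng.normal(0.0, sigma, int(mask.sum())) if sigma > 0 else 0.0
    return InputProjection(M=M, density=p_inp, sigma=sigma)


def cue_currents(cue: CueInput, t: float, targets: dict,
                 n: int) -> np.ndarray:
    """Per-neuron cue current at time t.

    ``targets`` maps 'excitatory'/'inhibitory' to index arrays; the
    excitatory pulse lasts [t_stim, t_end_ex], the inhibitory transient
    [t_stim, t_end_in].
    """
    out = np.zeros(n)
    if cue.t_stim <= t <= cue.t_end_ex:
        out[np.asarray(targets.get("excitatory", []), int)] = cue.A * cue.W_in
    if cue.t_stim <= t <= cue.t_end_in:
        out[np.asarray(targets.get("inhibitory", []), int)] = cue.A * cue.W_in
    return out


def cue_lowrank(cue: CueInput, n_steps: int, dt: float, targets: dict,
                n: int) -> Tuple[np.ndarray, np.ndarray]:
    """The same cue as a low-rank (M, S) drive for the simulation kernel."""
    t = np.arange(n_steps) * dt
    S = np.zeros((n_steps, 2))
    S[:, 0] = np.where((t >= cue.t_stim) & (t <= cue.t_end_ex),
                       cue.A * cue.W_in, 0.0)
    S[:, 1] = np.where((t >= cue.t_stim) & (t <= cue.t_end_in),
                       cue.A * cue.W_in, 0.0)
    M = np.zeros((n, 2))
    M[np.asarray(targets.get("excitatory", []), int), 0] = 1.0
    M[np.asarray(targets.get("inhibitory", []), int), 1] = 1.0
    return M, S


def rescale_bank(bank: OscillatorBank, factor: float) -> OscillatorBank:
    """Multiply every period by ``factor`` (frequencies divided by it)."""
    if factor <= 0:
        raise ConfigurationError("rescaling factor must be positive")
    return replace(bank, f=bank.f / factor)


def reset_phases(bank: OscillatorBank,
                 phi0: Optional[np.ndarray] = None) -> OscillatorBank:
    """Return a bank with phases set to ``phi0`` (default: unchanged)."""
    if phi0 is None:
        return bank
    return replace(bank, phi0=np.asarray(phi0, dtype=float))


def joint_period_ms(bank_or_periods) -> float:
    """Exact LCM of the component periods (ms) for rational period ratios.

    Periods are rationalized with limit_denominator(10**6), so e.g. the
    200 ms + 250 ms pair yields exactly 1000 ms.
    """
    if isinstance(bank_or_periods, OscillatorBank):
        periods = bank_or_periods.periods_ms
    else:
        periods = np.asarray(bank_or_periods, dtype=float)
    fracs = [Fraction(float(p)).limit_denominator(10 ** 6) for p in periods]
    num = 1
    den = 0  # gcd(0, d) = d seeds the accumulator
    for fr in fracs:
        num = num * fr.numerator // gcd(num, fr.numerator)
        den = gcd(den, fr.denominator)
    return float(Fraction(num, den))
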