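"""Electrophysiological parameter tables for the two network classes.

Each neuron-level parameter is described by a (mean, sd) pair of a Gaussian
from which per-neuron values are drawn.  Two stock tables are provided:

``MAIN_SRNN``
    The sparse reservoir network (N = 1000, p_rnn = 0.1) that projects to
    the trainable readout.

``OSCILLATOR``
    The densely connected (p_rnn = 1) sub-networks used as endogenous
    oscillators; slower inhibition (tau_in ~ 80 ms) makes them synchronize
    into periodic population events under a step current.

Units: potentials mV, currents pA, capacitance pF, resistance MOhm,
conductance increments pS, times ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Tuple


class ConfigurationError(ValueError):
    """Raised when a parameter table or experiment config is invalid."""


#: neuron-level fields every table must define
NEURON_FIELDS = (
    "R", "C", "E_L", "V_theta", "V_reset", "I_tonic",
    "T_delay", "tau_ref", "G_ex", "G_in", "tau_ex", "tau_in",
    "E_ex", "E_in",
)


@dataclass(frozen=True)
class ParameterTable:
    """Gaussian (mu, sigma) per neuron-level field plus network constants."""

    fields: Dict[str, Tuple[float, float]]
    N: int = 1000
    p_rnn: float = 0.1
    p_inp: float = 0.3
    gamma_rnn: float = 1.0

    def __post_init__(self) -> None:
        missing = [f for f in NEURON_FIELDS if f not in self.fields]
        if missing:
            raise ConfigurationError(
                f"parameter table is missing field(s): {', '.join(missing)}"
            )
        for name, (mu, sd) in self.fields.items():
            if not (abs(mu) < float("inf")) or not (sd >= 0.0):
                raise ConfigurationError(
                    f"field {name!r} must have finite mean and sd >= 0"
                )

    def with_overrides(self, *, N: int | None = None,
                       p_rnn: float | None = None,
                       p_inp: float | None = None,
                       gamma_rnn: float | None = None,
                       **neuron_fields: Tuple[float, float]) -> "ParameterTable":
        """Return a copy with selected entries replaced.

        ``neuron_fields`` maps a field name to a new (mu, sigma) pair.
        """
        unknown = [k for k in neuron_fields if k not in self.fields]
        if unknown:
            raise ConfigurationError(f"unknown field(s): {', '.join(unknown)}")
        new_fields = dict(self.fields)
        new_fields.update(neuron_fields)
        kw = {}
        if N is not None:
            kw["N"] = N
        if p_rnn is not None:
            kw["p_rnn"] = p_rnn
        if p_inp is not None:
            kw["p_inp"] = p_inp
        if gamma_rnn is not None:
            kw["gamma_rnn"] = gamma_rnn
        return replace(self, fields=new_fields, **kw)


MAIN_SRNN = ParameterTable(
    fields={
        "R": (100.0, 0.0),           # MOhm
        "C": (200.0, 0.0),           # pF
        "E_L": (-60.0, 1.2),         # mV
        "V_theta": (-50.0, 0.5),     # mV
        "V_reset": (-60.0, 1.2),     # mV
        "I_tonic": (90.0, 0.0),      # pA
        "T_delay": (1.0, 0.02),      # ms
        "tau_ref": (2.0, 0.04),      # ms
        "G_ex": (20.0, 0.4),         # pS
        "G_in": (160.0, 3.2),        # pS
        "tau_ex": (20.0, 0.4),       # ms
        "tau_in": (20.0, 0.4),       # ms
        "E_ex": (0.0, 0.0),          # mV
        "E_in": (-80.0, 0.0),        # mV
    },
    N=1000, p_rnn=0.1, p_inp=0.3, gamma_rnn=1.0,
)

OSCILLATOR = ParameterTable(
    fields={
        "R": (100.0, 0.0),
        "C": (200.0, 0.0),
        "E_L": (-60.0, 0.6),
        "V_theta": (-50.0, 0.5),
        "V_reset": (-60.0, 0.6),
        "I_tonic": (90.0, 0.0),
        "T_delay": (1.0, 0.01),
        "tau_ref": (2.0, 0.02),
        "G_ex": (30.0, 0.03),
        "G_in": (140.0, 1.4),
        "tau_ex": (20.0, 0.2),
        "tau_in": (80.0, 0.8),
        "E_ex": (0.0, 0.0),
        "E_in": (-80.0, 0.0),
    },
    N=500, p_rnn=1.0, p_inp=1.0, gamma_rnn=1.0,
)

#: integration step used throughout (ms)
DT_MS = 0.05
#: readout / analysis sampling grid (ms)
GRID_MS = 2.5
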