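"""Shared fixtures: small deterministic networks for fast tests."""

import numpy as np
import pytest

from oscmux import drive, srnn_core as core
from oscmux.params import MAIN_SRNN, OSCILLATOR


@pytest.fixture(scope="session")
def zero_sigma_table():
    """Main parameter table with all per-neuron variability removed."""
    return MAIN_SRNN.with_overrides(
        **{k: (v[0], 0.0) for k, v in MAIN_SRNN.fields.items()}
    )


@pytest.fixture(scope="session")
def tiny_population():
    return core.sample_population(MAIN_SRNN, 100, seed=11)


@pytest.fixture(scope="session")
def tiny_weights():
    return core.build_recurrent_weights(100, 0.1, 1.0, seed=12)


@pytest.fixture(scope="session")
def tiny_driven_run(tiny_population, tiny_weights):
    """A 500 ms driven run of the tiny network, shared across tests."""
    bank = drive.fixed_bank([4.0, 5.0], phi0=[0.5, -1.0], A=30.0)
    proj = drive.build_projection(100, 2, 0.3, 1.0, seed=13)
    n_steps = int(500.0 / 0.05)
    S = drive.signals(bank, np.arange(n_steps) * 0.05)
    spikes, traces = core.run(
        tiny_population, tiny_weights, (proj.M, S), 500.0, seed=14,
        record=core.RecordConfig(every_ms=2.5, record_traces=True),
    )
    return dict(spikes=spikes, traces=traces, bank=bank, proj=proj)
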