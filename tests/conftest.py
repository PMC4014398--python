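"""Shared fixtures.

The two protocol ensembles and the diameter-scaling study are expensive
(minutes of stochastic cable integration), so they are session-scoped and
shared between the statistical tests and the acceptance suite.  Scales
follow the desk-scale study conditions: a 2 mm, 0.2 µm interneuron axon
driven by the printed noise stimulus until ≥300 APs over ≥10 s for the
spike train, 100 single-AP trials, and 60 trials per diameter for the
squid scaling study.
"""

import numpy as np
import pytest

import axonoise as ax
from axonoise.experiments import scaling_experiment
from axonoise.protocols import run_single_ap_protocol, run_spike_train_protocol


@pytest.fixture(scope="session")
def spike_train_result():
    spec = ax.preset("rat_interneuron", diameter=0.2, axon_length=2000.0,
                     compartment_length=20.0, **ax.SPIKE_TRAIN_PASSIVE)
    return run_spike_train_protocol(
        spec, duration=10_000.0, target_aps=310, max_duration=60_000.0,
        seed=101, dt=0.005, positions=(0.45, 0.95))


@pytest.fixture(scope="session")
def train_distal_events(spike_train_result):
    return [e for e in spike_train_result.events_by_position[0.95]
            if not e.truncated]


@pytest.fixture(scope="session")
def single_ap_result():
    spec = ax.preset("rat_interneuron", diameter=0.2, axon_length=2000.0,
                     compartment_length=20.0)
    return run_single_ap_protocol(spec, n_trials=100, seed=55, dt=0.005,
                                  positions=(0.45, 0.95))


@pytest.fixture(scope="session")
def squid_single_ap_events():
    """Distal single-AP ensemble of a 0.2 µm squid axon (the configuration
    whose waveform-variability profile the structural checks refer to)."""
    spec = ax.preset("squid_hh", diameter=0.2, axon_length=2000.0,
                     compartment_length=10.0)
    res = run_single_ap_protocol(spec, n_trials=60, seed=13, dt=0.005,
                                 positions=(0.45, 0.95))
    return [e for e in res.events_by_position[0.95] if not e.truncated]


@pytest.fixture(scope="session")
def scaling_result():
    return scaling_experiment(diameters=(0.2, 0.5, 1.0), n_trials=60, seed=7,
                              compartment_length=10.0, dt=0.005)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
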