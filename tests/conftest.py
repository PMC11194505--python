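"""Shared fixtures: small trained networks reused across test modules.

Training runs are session-scoped because they are the expensive part of the
suite; every test that needs a trained network shares the same artifacts.
"""

import numpy as np
import pytest

import synhebb as sh


@pytest.fixture(scope="session")
def fig1_competitive_run():
    """Single-neuron circuit trained with competitive plasticity on both
    synapse types (2000 gratings)."""
    cfg = sh.get_preset("fig1_competitive", seed=1)
    return cfg, sh.run_experiment(cfg)


@pytest.fixture(scope="session")
def fig1_classic_run():
    """Single-neuron circuit trained with the classic target-rate inhibitory
    rule and competitive excitatory plasticity."""
    cfg = sh.get_preset("fig1_classic", seed=1, protocol=dict(
        stimulus_duration=200.0, n_stimuli=8000, contrast=1.0))
    return cfg, sh.run_experiment(cfg)


@pytest.fixture(scope="session")
def pca_fixture_run():
    """Linear single neuron trained on the anisotropic two-channel ensemble."""
    cfg, ens = sh.make_fixture("two_channel_pca", seed=2)
    return cfg, ens, sh.run_experiment(cfg, ensemble=ens)


@pytest.fixture(scope="session")
def paired_ei_run():
    """Linear neuron with paired E/I input streams (balanced-PCA fixture)."""
    cfg, ens = sh.make_fixture("paired_ei_pca", seed=3)
    return cfg, ens, sh.run_experiment(cfg, ensemble=ens)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
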