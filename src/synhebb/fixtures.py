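"""Miniature, analytically tractable experiment fixtures.

Each fixture is a seconds-scale configuration with known structure, used to
validate the learning dynamics against linear-algebra oracles:

two_channel_pca
    One linear neuron, two excitatory input channels driven by an
    anisotropic (4:1 variance) Gaussian ensemble rectified to nonnegative
    rates.  Competitive Hebbian learning should align the weight vector with
    the principal eigenvector of the input second-moment matrix.
paired_ei_pca
    Same ensemble feeding two excitatory/inhibitory input pairs with
    identical activities; excitatory and inhibitory weights should converge
    to proportional vectors on the principal component (balanced PCA).
toy_recurrent
    A small linear recurrent E-I network driven by one-hot channel patterns
    of graded amplitude (distinct mode variances); used to probe the
    collapse-prevention condition in both regimes.
tiny_center_surround
    A reduced two-region network with static tuned feedforward weights.
"""

from __future__ import annotations

import numpy as np

from .config import ExperimentConfig, config_from_dict, get_preset
from .network import BLOCKS
from .theory import InputEnsemble

__all__ = ["make_fixture", "FIXTURE_KINDS"]

FIXTURE_KINDS = ("two_channel_pca", "paired_ei_pca", "toy_recurrent",
                 "tiny_center_surround")

#: construction axis of the two-channel ensembles (degrees in weight space)
PCA_AXIS_DEG = 30.0
#: standard deviations along / against the axis (4:1 variance anisotropy)
PCA_SIGMAS = (2.0, 1.0)


def _two_channel_ensemble(n_patterns: int, rng: np.random.Generator) -> InputEnsemble:
    """Anisotropic Gaussian rates along a known axis, rectified to >= 0.

    The on-axis coordinate is folded to its absolute value so patterns lie in
    the positive quadrant up to the (small) off-axis spread; remaining
    negative entries are clipped at zero.
    """
    phi = np.deg2rad(PCA_AXIS_DEG)
    v = np.array([np.cos(phi), np.sin(phi)])
    v_perp = np.array([-np.sin(phi), np.cos(phi)])
    z1 = np.abs(rng.normal(0.0, PCA_SIGMAS[0], size=n_patterns))
    z2 = rng.normal(0.0, PCA_SIGMAS[1], size=n_patterns)
    pats = np.maximum(z1[:, None] * v + z2[:, None] * v_perp, 0.0)
    return InputEnsemble(pats)


def _linear_single_neuron(name: str, NI: int, norms: dict, rates: dict,
                          plastic: dict, n_stimuli: int, mirror: bool) -> dict:
    return dict(
        name=name,
        dimensions=dict(NE=1, NI=NI, NF=2),
        activation=dict(a=1.0, b=0.0, n=1.0),
        dynamics=dict(tau_E=1.0, tau_I=1.0, dt=1.0),
        init=dict(mu_W=0.5, sigma_W=0.25),
        plasticity=dict(rates=rates, norms=norms, plastic=plastic),
        input=dict(kind="ensemble", mirror_inputs=mirror),
        protocol=dict(stimulus_duration=1.0, n_stimuli=n_stimuli, contrast=1.0),
        run=dict(snapshot_every=500),
    )


def make_fixture(kind: str, seed: int = 0, **overrides):
    """Build a named fixture; returns ``(ExperimentConfig, InputEnsemble | None)``."""
    rng = np.random.default_rng(seed)

    if kind == "two_channel_pca":
        d = _linear_single_neuron(
            "two_channel_pca", NI=0,
            norms=dict(W_EE=1.0),
            rates=dict(eps_EF=5e-3),
            plastic=dict(EE=False, EF=True, EI=False, IE=False, II=False, IF=False),
            n_stimuli=5000, mirror=False,
        )
        d.update(overrides)
        d["seed"] = seed
        return config_from_dict(d), _two_channel_ensemble(d["protocol"]["n_stimuli"], rng)

    if kind == "paired_ei_pca":
        # two E/I input pairs with identical activities: the I population is
        # clamped to the feedforward stream (NI == NF), so y_I == y_E always
        d = _linear_single_neuron(
            "paired_ei_pca", NI=2,
            norms=dict(W_EE=2.0, W_EI=1.0),
            rates=dict(eps_EF=5e-3, eps_EI=5e-3),
            plastic=dict(EE=False, EF=True, EI=True, IE=False, II=False, IF=False),
            n_stimuli=5000, mirror=True,
        )
        d.update(overrides)
        d["seed"] = seed
        return config_from_dict(d), _two_channel_ensemble(d["protocol"]["n_stimuli"], rng)

    if kind == "toy_recurrent":
        # twice as many I as E neurons, with a larger input budget, keeps the
        # network deep inside the collapse-prevented regime (N_I var_I well
        # above N_E var_E) so the distributed outcome is robust across seeds
        d = dict(
            name="toy_recurrent",
            dimensions=dict(NE=4, NI=8, NF=4),
            activation=dict(a=1.0, b=0.0, n=1.0),
            dynamics=dict(tau_E=1.0, tau_I=1.0, dt=1.0),
            init=dict(mu_W=0.5, sigma_W=0.25, zero_recurrent_E=False),
            plasticity=dict(
                rates={f"eps_{b}": 2e-4 for b in BLOCKS},
                norms=dict(W_EE=1.0, W_IE=2.0, W_EI=0.8, W_II=0.3),
                plastic={b: True for b in BLOCKS},
            ),
            input=dict(kind="ensemble"),
            protocol=dict(stimulus_duration=8.0, n_stimuli=4000, contrast=1.0),
            run=dict(snapshot_every=500),
        )
        d.update(overrides)
        d["seed"] = seed
        cfg = config_from_dict(d)
        # graded but close amplitudes: a mild dominance ordering (so the
        # uninhibited network has a well-defined collapse target) without a
        # repulsion gradient steep enough to funnel all neurons onto the
        # weakest mode in the inhibited network
        amplitudes = np.array([1.9, 1.8, 1.7, 1.6])[: cfg.dims.NF]
        channels = rng.integers(0, cfg.dims.NF, size=cfg.protocol.n_stimuli)
        pats = np.zeros((cfg.protocol.n_stimuli, cfg.dims.NF))
        pats[np.arange(len(channels)), channels] = amplitudes[channels]
        return cfg, InputEnsemble(pats)

    if kind == "tiny_center_surround":
        cfg = get_preset(
            "fig5_cs_correlated", seed=seed,
            name="tiny_center_surround",
            dimensions=dict(NE=24, NI=8, NF=24),
            plasticity=dict(
                rates=dict(eps_EE=2.0e-8, eps_IE=3.0e-8, eps_EI=4.0e-8, eps_II=5.0e-8),
                norms=dict(W_EE=3.51, W_IE=3.35, W_EI=1.84, W_II=1.44,
                           W_EF=1.4, W_IF=1.4),
                plastic=dict(EE=True, IE=True, EI=True, II=True, EF=False, IF=False),
            ),
            protocol=dict(stimulus_duration=200.0, n_stimuli=1000, contrast=0.5),
            **overrides,
        )
        return cfg, None

    raise ValueError(f"unknown fixture kind {kind!r}; available: {FIXTURE_KINDS}")
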