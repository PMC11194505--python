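"""Oriented-grating inputs and training protocols.

Feedforward input neurons are orientation tuned: a grating of orientation
theta and contrast c drives input neuron j at rate

    rF_j = c * A_F * exp(-d(theta, thetaF_j)^2 / (2 sigma_F^2)),

where d is the angular distance on the 180-degree orientation circle.
Training streams present gratings of uniformly random orientation, each held
for a fixed duration.  A center/surround variant splits the input channels
(and the neurons reading them out) into two regions that are stimulated
either with identical orientations (correlated statistics) or one region at
a time (independent statistics).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "InputTuning",
    "GratingStimulus",
    "TrainingProtocol",
    "CenterSurroundLayout",
    "RegionStimulus",
    "circular_distance",
    "grating_response",
    "sample_training_stream",
    "static_feedforward_weights",
    "compose_stimuli",
    "center_surround_stream",
    "stream_to_records",
    "evenly_spaced_orientations",
]


def evenly_spaced_orientations(n: int) -> np.ndarray:
    """n preferred orientations evenly distributed over [0, 180) degrees."""
    return np.arange(n) * (180.0 / n)


@dataclass(frozen=True)
class InputTuning:
    """Tuning of the feedforward population: preferred orientations thetaF
    (degrees), shared width sigma_F (degrees) and peak rate A_F."""

    thetaF: np.ndarray
    sigma_F: float
    A_F: float

    def __post_init__(self):
        object.__setattr__(self, "thetaF", np.asarray(self.thetaF, dtype=float))
        if self.sigma_F <= 0 or self.A_F <= 0:
            raise ValueError("sigma_F and A_F must be positive")

    @classmethod
    def evenly_spaced(cls, n: int, sigma_F: float, A_F: float) -> "InputTuning":
        return cls(evenly_spaced_orientations(n), sigma_F, A_F)

    def __len__(self) -> int:
        return len(self.thetaF)


@dataclass(frozen=True)
class GratingStimulus:
    """A single oriented grating: orientation theta (degrees) and contrast c."""

    theta: float
    c: float

    def __post_init__(self):
        if self.c < 0:
            raise ValueError("contrast must be nonnegative")


@dataclass(frozen=True)
class TrainingProtocol:
    """Stimulus presentation schedule: each grating is held for
    ``stimulus_duration`` ms; orientations are uniform on [0, 180)."""

    stimulus_duration: float = 200.0
    n_stimuli: int = 1000
    contrast: float = 1.0

    def __post_init__(self):
        if self.stimulus_duration <= 0 or self.n_stimuli < 0 or self.contrast < 0:
            raise ValueError("invalid training protocol")


def circular_distance(t1, t2):
    """Shortest distance between two orientations on the 180-degree circle.

    Scalar or elementwise on arrays; result lies in [0, 90].
    """
    d = np.abs(np.asarray(t1, dtype=float) - np.asarray(t2, dtype=float)) % 180.0
    return np.minimum(d, 180.0 - d)


def grating_response(stim: GratingStimulus, tuning: InputTuning) -> np.ndarray:
    """Input-population rates for one grating: Gaussian in angular distance,
    peaking at c * A_F for a channel whose preference matches the grating."""
    d = circular_distance(stim.theta, tuning.thetaF)
    return stim.c * tuning.A_F * np.exp(-(d**2) / (2.0 * tuning.sigma_F**2))


def compose_stimuli(stims, tuning: InputTuning) -> np.ndarray:
    """Input rates for simultaneously presented gratings (e.g. a plaid).

    Components superpose additively at the input stage, so a single grating
    is recovered exactly and any sublinearity of the *network* response to a
    plaid is attributable to recurrent dynamics.
    """
    if len(stims) == 0:
        raise ValueError("compose_stimuli requires at least one stimulus")
    out = np.zeros(len(tuning))
    for s in stims:
        out += grating_response(s, tuning)
    return out


def sample_training_stream(p: TrainingProtocol, rng: np.random.Generator):
    """Draw the full sequence of training gratings (reproducible per rng)."""
    thetas = rng.uniform(0.0, 180.0, size=p.n_stimuli)
    return [GratingStimulus(float(t), p.contrast) for t in thetas]


def static_feedforward_weights(
    theta_hat: np.ndarray,
    tuning: InputTuning,
    sigma_theta: float,
    norm: float,
) -> np.ndarray:
    """Fixed, orientation-tuned feedforward weights.

    Row i connects a neuron with assigned preferred orientation theta_hat[i]
    to the input channels through a Gaussian profile of width sigma_theta;
    each row is then scaled to sum to ``norm``.
    """
    theta_hat = np.asarray(theta_hat, dtype=float)
    d = circular_distance(theta_hat[:, None], tuning.thetaF[None, :])
    W = np.exp(-(d**2) / (2.0 * sigma_theta**2))
    return norm * W / W.sum(axis=1, keepdims=True)


@dataclass(frozen=True)
class CenterSurroundLayout:
    """Two-region input layout: disjoint center and surround channel blocks.

    ``center_channels`` / ``surround_channels`` index into the full
    feedforward vector and together cover it.  Each region has its own
    tuning.  ``mode`` selects the training statistics: in ``correlated`` mode
    both regions always see the same orientation; in ``independent`` mode one
    region, chosen uniformly at random per trial, sees a grating while the
    other is silent.
    """

    center_channels: np.ndarray
    surround_channels: np.ndarray
    center_tuning: InputTuning
    surround_tuning: InputTuning
    mode: str = "correlated"

    def __post_init__(self):
        object.__setattr__(self, "center_channels", np.asarray(self.center_channels, dtype=int))
        object.__setattr__(self, "surround_channels", np.asarray(self.surround_channels, dtype=int))
        if self.mode not in ("correlated", "independent"):
            raise ValueError(f"unknown center/surround mode {self.mode!r}")
        overlap = np.intersect1d(self.center_channels, self.surround_channels)
        if overlap.size:
            raise ValueError("center and surround channel sets must be disjoint")
        if len(self.center_tuning) != len(self.center_channels) or len(
            self.surround_tuning
        ) != len(self.surround_channels):
            raise ValueError("region tuning length must match its channel count")

    @property
    def n_channels(self) -> int:
        return len(self.center_channels) + len(self.surround_channels)

    def input_vector(self, center: GratingStimulus | None,
                     surround: GratingStimulus | None) -> np.ndarray:
        """Assemble the full feedforward rate vector from per-region gratings
        (``None`` = region unstimulated)."""
        rF = np.zeros(self.n_channels)
        if center is not None:
            rF[self.center_channels] = grating_response(center, self.center_tuning)
        if surround is not None:
            rF[self.surround_channels] = grating_response(surround, self.surround_tuning)
        return rF


@dataclass(frozen=True)
class RegionStimulus:
    """One center/surround training trial (``None`` = region silent)."""

    center: GratingStimulus | None
    surround: GratingStimulus | None


def stream_to_records(trials):
    """Flatten a training stream to records for audit export.

    Accepts a list of :class:`GratingStimulus` (single-region streams) or of
    :class:`RegionStimulus`; yields dicts with keys trial, region, theta,
    contrast (silent regions are omitted).
    """
    records = []
    for k, t in enumerate(trials):
        if isinstance(t, GratingStimulus):
            records.append(dict(trial=k, region="full", theta=t.theta, c=t.c))
        else:
            for name, g in (("center", t.center), ("surround", t.surround)):
                if g is not None:
                    records.append(dict(trial=k, region=name, theta=g.theta, c=g.c))
    return records


def center_surround_stream(
    layout: CenterSurroundLayout,
    p: TrainingProtocol,
    rng: np.random.Generator,
):
    """Per-trial region stimuli under the layout's training statistics."""
    trials = []
    for _ in range(p.n_stimuli):
        theta = float(rng.uniform(0.0, 180.0))
        g = GratingStimulus(theta, p.contrast)
        if layout.mode == "correlated":
            trials.append(RegionStimulus(center=g, surround=g))
        else:
            if rng.uniform() < 0.5:
                trials.append(RegionStimulus(center=g, surround=None))
            else:
                trials.append(RegionStimulus(center=None, surround=g))
    return trials
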