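"""Analysis measures for trained networks.

Covers: tuning uniformity (normalized entropy of the feedforward output-weight
distribution), preferred-orientation maps from steady-state probe responses,
connectivity as a function of preferred-orientation difference, the
excitatory/inhibitory input decomposition of single neurons, and the probe
protocols for surround suppression and masked contrast-response curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import (ActivationParams, DynamicsParams, NetworkState,
                      WeightSet, run_to_steady_state)
from .stimuli import (CenterSurroundLayout, GratingStimulus, InputTuning,
                      compose_stimuli, grating_response)

__all__ = [
    "output_weight_share",
    "tuning_uniformity",
    "PreferredOrientationMap",
    "preferred_orientations",
    "ConnectivityProfile",
    "connectivity_vs_delta_theta",
    "EIDecomposition",
    "ei_input_decomposition",
    "SuppressionCurve",
    "suppression_curves",
    "ContrastResponse",
    "contrast_response",
    "semi_saturation_contrast",
    "probe_response",
]

DEFAULT_SETTLE_TAUS = 20.0


def output_weight_share(W_AF: np.ndarray) -> np.ndarray:
    """Normalized total synaptic output weight of each input neuron onto the
    population: column sums of W_AF divided by the grand total."""
    W = np.asarray(W_AF, dtype=float)
    if W.size == 0 or W.min() < 0:
        raise ValueError("weight matrix must be nonempty and nonnegative")
    total = W.sum()
    if total <= 0:
        raise ValueError("tuning uniformity is undefined for an all-zero matrix")
    return W.sum(axis=0) / total


def tuning_uniformity(W_AF: np.ndarray) -> float:
    """Normalized Shannon entropy of the output-weight shares, in [0, 1].

    1 when every input neuron carries equal total weight onto the population;
    0 when all weight concentrates on a single input neuron.  0*log(0) = 0.
    """
    p = output_weight_share(W_AF)
    nz = p[p > 0]
    H = -(nz * np.log(nz)).sum()
    return float(H / np.log(p.size))


def probe_response(
    w: WeightSet,
    rF: np.ndarray,
    dyn: DynamicsParams,
    act: ActivationParams,
    *,
    settle_taus: float = DEFAULT_SETTLE_TAUS,
    mirror_inputs: bool = False,
) -> NetworkState:
    """Steady-state response to a constant input vector, from rest."""
    state = NetworkState.zeros(w.dims, act)
    duration = settle_taus * max(dyn.tau_E, dyn.tau_I)
    return run_to_steady_state(state, w, rF, dyn, act, duration,
                               mirror_inputs=mirror_inputs)


@dataclass
class PreferredOrientationMap:
    """Per-neuron preferred orientations theta_hat (argmax of the steady-state
    response over the probe grid; ties break to the smallest angle)."""

    grid: np.ndarray
    contrast: float
    theta_hat_E: np.ndarray
    theta_hat_I: np.ndarray
    responses_E: np.ndarray  # (n_grid, NE)
    responses_I: np.ndarray  # (n_grid, NI)


def preferred_orientations(
    w: WeightSet,
    tuning: InputTuning,
    dyn: DynamicsParams,
    act: ActivationParams,
    grid: np.ndarray | None = None,
    *,
    contrast: float = 1.0,
    settle_taus: float = DEFAULT_SETTLE_TAUS,
    mirror_inputs: bool = False,
) -> PreferredOrientationMap:
    """Probe the network with gratings over an orientation grid and record the
    orientation of each neuron's peak steady-state response."""
    if grid is None:
        grid = np.arange(0.0, 180.0, 1.0)
    grid = np.asarray(grid, dtype=float)
    rE = np.empty((grid.size, w.dims.NE))
    rI = np.empty((grid.size, w.dims.NI))
    for k, theta in enumerate(grid):
        rF = grating_response(GratingStimulus(float(theta), contrast), tuning)
        s = probe_response(w, rF, dyn, act, settle_taus=settle_taus,
                           mirror_inputs=mirror_inputs)
        rE[k] = s.r_E
        rI[k] = s.r_I
    def _argmax_smallest_angle(resp: np.ndarray) -> np.ndarray:
        # ties (within fp tolerance of the max) resolve to the smallest angle
        if resp.shape[1] == 0:
            return np.empty(0)
        peak = resp.max(axis=0)
        tied = resp >= peak[None, :] * (1.0 - 1e-12) - 1e-300
        return grid[tied.argmax(axis=0)]

    th_E = _argmax_smallest_angle(rE)
    th_I = _argmax_smallest_angle(rI)
    return PreferredOrientationMap(grid=grid, contrast=contrast,
                                   theta_hat_E=th_E, theta_hat_I=th_I,
                                   responses_E=rE, responses_I=rI)


@dataclass
class ConnectivityProfile:
    """Mean normalized weight per signed preferred-orientation-difference bin.

    Bins partition [-90, 90); weights are normalized by the block maximum.
    Empty bins are recorded as NaN (missing), not zero.
    """

    bin_centers: np.ndarray
    mean_weight: np.ndarray


def connectivity_vs_delta_theta(
    W: np.ndarray,
    theta_hat_pre: np.ndarray,
    theta_hat_post: np.ndarray,
    n_bins: int = 18,
) -> ConnectivityProfile:
    """Average weight as a function of Delta theta_hat = theta_post - theta_pre,
    the signed circular difference on the orientation circle."""
    W = np.asarray(W, dtype=float)
    pre = np.asarray(theta_hat_pre, dtype=float)
    post = np.asarray(theta_hat_post, dtype=float)
    # signed difference in [-90, 90)
    d = (post[:, None] - pre[None, :] + 90.0) % 180.0 - 90.0
    edges = np.linspace(-90.0, 90.0, n_bins + 1)
    idx = np.clip(np.digitize(d.ravel(), edges) - 1, 0, n_bins - 1)
    wmax = W.max()
    vals = (W / wmax if wmax > 0 else W).ravel()
    mean = np.full(n_bins, np.nan)
    for b in range(n_bins):
        sel = idx == b
        if np.any(sel):
            mean[b] = vals[sel].mean()
    centers = 0.5 * (edges[:-1] + edges[1:])
    return ConnectivityProfile(bin_centers=centers, mean_weight=mean)


@dataclass
class EIDecomposition:
    """Per-excitatory-neuron input currents: feedforward and recurrent
    excitation (both nonnegative) and inhibition."""

    feedforward: np.ndarray
    recurrent_exc: np.ndarray
    inhibitory: np.ndarray

    @property
    def excitatory(self) -> np.ndarray:
        return self.feedforward + self.recurrent_exc

    @property
    def net(self) -> np.ndarray:
        """E minus I drive; equals u_E at a steady state of the dynamics."""
        return self.excitatory - self.inhibitory


def ei_input_decomposition(s: NetworkState, w: WeightSet, rF: np.ndarray) -> EIDecomposition:
    """Decompose the synaptic drive onto each excitatory neuron."""
    rF = np.asarray(rF, dtype=float)
    return EIDecomposition(
        feedforward=w.W_EF @ rF,
        recurrent_exc=w.W_EE @ s.r_E,
        inhibitory=w.W_EI @ s.r_I,
    )


@dataclass
class SuppressionCurve:
    """Mean steady-state rate of the center-tuned excitatory population as a
    function of surround contrast, for an iso- or cross-oriented surround."""

    surround_contrasts: np.ndarray
    response: np.ndarray
    condition: str  # "iso" | "cross"


def suppression_curves(
    w: WeightSet,
    layout: CenterSurroundLayout,
    center_E_mask: np.ndarray,
    dyn: DynamicsParams,
    act: ActivationParams,
    *,
    center_theta: float = 90.0,
    center_contrast: float = 1.0,
    surround_contrasts=(0.0, 0.2, 0.4, 0.6, 0.8, 1.0),
    condition: str = "iso",
    settle_taus: float = DEFAULT_SETTLE_TAUS,
) -> SuppressionCurve:
    """Probe surround suppression: a fixed full-contrast center grating plus a
    surround grating of increasing contrast, iso- or cross-oriented."""
    if condition not in ("iso", "cross"):
        raise ValueError("condition must be 'iso' or 'cross'")
    surround_theta = center_theta if condition == "iso" else (center_theta + 90.0) % 180.0
    contrasts = np.asarray(surround_contrasts, dtype=float)
    if np.any(np.diff(contrasts) < 0) or np.any(contrasts < 0):
        raise ValueError("surround contrasts must be nonnegative and increasing")
    center_E_mask = np.asarray(center_E_mask, dtype=bool)
    resp = np.empty(contrasts.size)
    for k, cs in enumerate(contrasts):
        rF = layout.input_vector(
            GratingStimulus(center_theta, center_contrast),
            GratingStimulus(surround_theta, float(cs)) if cs > 0 else None,
        )
        s = probe_response(w, rF, dyn, act, settle_taus=settle_taus)
        resp[k] = s.r_E[center_E_mask].mean()
    return SuppressionCurve(surround_contrasts=contrasts, response=resp,
                            condition=condition)


@dataclass
class ContrastResponse:
    """Steady-state response of one neuron across test contrasts, one curve per
    mask contrast."""

    test_contrasts: np.ndarray
    mask_contrasts: np.ndarray
    response: np.ndarray  # (n_mask, n_test)
    neuron: int


def contrast_response(
    w: WeightSet,
    tuning: InputTuning,
    dyn: DynamicsParams,
    act: ActivationParams,
    neuron: int,
    *,
    test_theta: float = 45.0,
    mask_theta: float = 135.0,
    test_contrasts=(0.0, 0.06, 0.12, 0.25, 0.5, 1.0),
    mask_contrasts=(0.0, 0.25, 0.5, 1.0),
    settle_taus: float = DEFAULT_SETTLE_TAUS,
) -> ContrastResponse:
    """Contrast-response family of a single excitatory neuron under a
    superposed mask grating (plaid) of varying contrast."""
    tc = np.asarray(test_contrasts, dtype=float)
    mc = np.asarray(mask_contrasts, dtype=float)
    out = np.empty((mc.size, tc.size))
    for i, cm in enumerate(mc):
        for j, ct in enumerate(tc):
            stims = []
            if ct > 0:
                stims.append(GratingStimulus(test_theta, float(ct)))
            if cm > 0:
                stims.append(GratingStimulus(mask_theta, float(cm)))
            rF = compose_stimuli(stims, tuning) if stims else np.zeros(len(tuning))
            s = probe_response(w, rF, dyn, act, settle_taus=settle_taus)
            out[i, j] = s.r_E[neuron]
    return ContrastResponse(test_contrasts=tc, mask_contrasts=mc,
                            response=out, neuron=neuron)


def semi_saturation_contrast(test_contrasts: np.ndarray, response: np.ndarray) -> float:
    """Contrast at half the curve's dynamic range, interpolated on log contrast.

    The half-response level is (min + max) / 2 of the given curve; the
    crossing is located by linear interpolation of the response against
    log contrast between the bracketing grid points.
    """
    c = np.asarray(test_contrasts, dtype=float)
    r = np.asarray(response, dtype=float)
    half = 0.5 * (r.min() + r.max())
    above = np.nonzero(r >= half)[0]
    if above.size == 0:
        return float("nan")
    k = above[0]
    if k == 0 or r[k] == r[k - 1]:
        return float(c[k])
    if c[k - 1] <= 0:
        # cannot interpolate on log axis below zero contrast; fall back to linear
        frac = (half - r[k - 1]) / (r[k] - r[k - 1])
        return float(c[k - 1] + frac * (c[k] - c[k - 1]))
    frac = (half - r[k - 1]) / (r[k] - r[k - 1])
    return float(np.exp(np.log(c[k - 1]) + frac * (np.log(c[k]) - np.log(c[k - 1]))))
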