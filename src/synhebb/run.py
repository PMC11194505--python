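"""Config-driven training runs: network assembly, the stimulus/dynamics/
plasticity loop, snapshots with exact resume, and post-training rate
statistics.

A run is driven by a single seeded random generator that serves weight
initialization first and stimulus sampling afterwards, in a fixed order, so
(config, seed) reproduces a run bit for bit.  Snapshots store the weights,
the network state, and the generator state, so a run can be resumed from any
snapshot and reproduces the remainder exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import ExperimentConfig
from .metrics import tuning_uniformity
from .network import (BLOCKS, DivergenceError, NetworkState, WeightSet,
                      euler_step, initialize_weights)
from .plasticity import (classic_inhibitory_step, competitive_plasticity_step,
                         normalize_all)
from .stimuli import (GratingStimulus, evenly_spaced_orientations,
                      grating_response, static_feedforward_weights)

__all__ = [
    "Snapshot",
    "RunArtifacts",
    "RunDivergence",
    "assemble_network",
    "run_experiment",
    "resume_run",
    "measure_rate_statistics",
]


@dataclass
class Snapshot:
    """Full run checkpoint: trial index, weights, network state, RNG state."""

    trial: int
    weights: WeightSet
    state: NetworkState
    rng_state: dict


@dataclass
class RunArtifacts:
    """Everything a training run produces."""

    config: ExperimentConfig
    weights: WeightSet
    state: NetworkState
    initial_weights: WeightSet
    snapshots: list = field(default_factory=list)
    uniformity_trace: list = field(default_factory=list)  # (trial, U_E, U_I)
    n_trials_run: int = 0
    converged: bool = False
    log: list = field(default_factory=list)

    def uniformity_at(self, fraction: float):
        """(U_E, U_I) at the recorded time closest to a fraction of the run."""
        if not self.uniformity_trace:
            raise ValueError("no uniformity trace was recorded")
        target = fraction * self.n_trials_run
        trial, uE, uI = min(self.uniformity_trace, key=lambda t: abs(t[0] - target))
        return uE, uI


class RunDivergence(RuntimeError):
    """Training diverged; carries the last stable snapshot and partial artifacts."""

    def __init__(self, trial: int, step: int, artifacts: RunArtifacts):
        self.trial = trial
        self.step = step
        self.artifacts = artifacts
        super().__init__(
            f"run diverged during trial {trial} (integration step {step}); "
            f"{len(artifacts.snapshots)} stable snapshot(s) retained"
        )


# ---------------------------------------------------------------------------
# network assembly
# ---------------------------------------------------------------------------


def _static_ff_matrices(cfg: ExperimentConfig):
    """Static tuned feedforward matrices (or None) for both populations."""
    if cfg.input.sigma_theta is None:
        return None, None
    st = cfg.input.sigma_theta
    if cfg.input.kind == "center_surround":
        layout = cfg.center_surround_layout()
        nf = len(layout.center_channels)

        def block_diag(n_post):
            half = n_post // 2
            th = evenly_spaced_orientations(half)
            Wr = static_feedforward_weights(th, layout.center_tuning, st, 1.0)
            W = np.zeros((n_post, 2 * nf))
            W[:half, :nf] = Wr
            W[half:, nf:] = Wr
            return W

        return block_diag(cfg.dims.NE), block_diag(cfg.dims.NI)

    tuning = cfg.input_tuning()
    W_EF = static_feedforward_weights(
        evenly_spaced_orientations(cfg.dims.NE), tuning, st, 1.0) if cfg.dims.NE else None
    W_IF = static_feedforward_weights(
        evenly_spaced_orientations(cfg.dims.NI), tuning, st, 1.0) if cfg.dims.NI else None
    return W_EF, W_IF


def assemble_network(cfg: ExperimentConfig, rng: np.random.Generator):
    """Build the initial WeightSet plus per-neuron plasticity masks and gains.

    Returns ``(weights, plastic_rows, gain_E, gain_I)`` where plastic_rows is
    None unless some neurons are static lateral projectors, and the gains are
    None unless those projectors use a different gain.
    """
    static_EF, static_IF = _static_ff_matrices(cfg)
    w = initialize_weights(
        cfg.dims, cfg.init, cfg.norms,
        rng=rng,
        plastic=cfg.plastic,
        exclude_autapses=cfg.run.exclude_autapses,
        static_W_EF=static_EF,
        static_W_IF=static_IF,
    )

    if cfg.input.tuned_init_sigma_theta is not None:
        tuning = cfg.input_tuning()
        for A, n_post in (("E", cfg.dims.NE), ("I", cfg.dims.NI)):
            if n_post and w.plastic[A + "F"]:
                th = evenly_spaced_orientations(n_post)
                w.set_block(A + "F", static_feedforward_weights(th, tuning, cfg.input.tuned_init_sigma_theta, 1.0))
        normalize_all(w, cfg.norms)

    plastic_rows = None
    gain_E = gain_I = None
    sl = cfg.static_lateral
    if sl is not None:
        n_static = len(sl.theta_hat)
        n_pop = cfg.dims.NE if sl.population == "E" else cfg.dims.NI
        if n_static > n_pop:
            raise ValueError("more static lateral neurons than population members")
        mask = np.ones(n_pop, dtype=bool)
        mask[n_pop - n_static:] = False  # static neurons occupy the last rows
        plastic_rows = {"E": None, "I": None}
        plastic_rows[sl.population] = mask

        tuning = cfg.input_tuning()
        W_ff = static_feedforward_weights(np.asarray(sl.theta_hat), tuning,
                                          sl.sigma_theta, sl.ff_norm)
        A = sl.population
        blk = w.block(A + "F")
        blk[~mask] = W_ff
        # static projectors receive no recurrent input
        for pre in ("E", "I"):
            w.block(A + pre)[~mask] = 0.0

        gains = np.full(n_pop, cfg.act.a)
        gains[~mask] = sl.gain
        if A == "E":
            gain_E = gains
        else:
            gain_I = gains

    return w, plastic_rows, gain_E, gain_I


# ---------------------------------------------------------------------------
# stimulus sampling (one rng draw order, fixed)
# ---------------------------------------------------------------------------


def _next_input(cfg: ExperimentConfig, rng: np.random.Generator, trial: int,
                ensemble=None) -> np.ndarray:
    kind = cfg.input.kind
    if kind == "ensemble":
        if ensemble is None:
            raise ValueError("config requires an input ensemble")
        pats = ensemble.patterns if hasattr(ensemble, "patterns") else np.asarray(ensemble)
        return pats[trial % pats.shape[0]]
    if kind == "gratings":
        theta = float(rng.uniform(0.0, 180.0))
        return grating_response(GratingStimulus(theta, cfg.protocol.contrast),
                                cfg.input_tuning())
    # center_surround
    layout = cfg.center_surround_layout()
    theta = float(rng.uniform(0.0, 180.0))
    g = GratingStimulus(theta, cfg.protocol.contrast)
    if layout.mode == "correlated":
        return layout.input_vector(g, g)
    if rng.uniform() < 0.5:
        return layout.input_vector(g, None)
    return layout.input_vector(None, g)


# ---------------------------------------------------------------------------
# the training loop
# ---------------------------------------------------------------------------


def _record_uniformity(cfg, w, trial, trace):
    uE = tuning_uniformity(w.W_EF) if (w.plastic["EF"] and cfg.dims.NE and w.W_EF.sum() > 0) else np.nan
    uI = tuning_uniformity(w.W_IF) if (w.plastic["IF"] and cfg.dims.NI and w.W_IF.sum() > 0) else np.nan
    trace.append((trial, uE, uI))


def _plasticity(cfg, state, rF, w, plastic_rows):
    competitive_plasticity_step(state, rF, w, cfg.rates, cfg.norms, cfg.dyn.dt,
                                plastic_rows=plastic_rows)
    if cfg.rule == "classic_inhibitory":
        w.set_block("EI", classic_inhibitory_step(state.r_E, state.r_I, w.W_EI,
                                                  cfg.classic, cfg.dyn.dt))


def _run_loop(cfg, w, state, rng, start_trial, ensemble, artifacts):
    dyn, act = cfg.dyn, cfg.act
    mirror = cfg.input.mirror_inputs
    steps_per_stim = max(1, int(round(cfg.protocol.stimulus_duration / dyn.dt)))
    every = cfg.run.snapshot_every
    tol = cfg.run.convergence_tol
    norm_scale = max((v for v in (cfg.norms.W_EE, cfg.norms.W_IE, cfg.norms.W_EI,
                                  cfg.norms.W_II) if v is not None), default=1.0)
    plastic_rows = artifacts._plastic_rows
    gain_E, gain_I = artifacts._gain_E, artifacts._gain_I

    prev_check = {b: w.block(b).copy() for b in BLOCKS if w.plastic[b]}
    step_counter = start_trial * steps_per_stim
    trial = start_trial
    try:
        for trial in range(start_trial, cfg.protocol.n_stimuli):
            rF = _next_input(cfg, rng, trial, ensemble)
            for _ in range(steps_per_stim):
                step_counter += 1
                if cfg.update_order == "plasticity_first":
                    _plasticity(cfg, state, rF, w, plastic_rows)
                    state = euler_step(state, w, rF, dyn, act, mirror_inputs=mirror,
                                       gain_E=gain_E, gain_I=gain_I)
                else:
                    state = euler_step(state, w, rF, dyn, act, mirror_inputs=mirror,
                                       gain_E=gain_E, gain_I=gain_I)
                    _plasticity(cfg, state, rF, w, plastic_rows)
                for u in (state.u_E, state.u_I):
                    # `not (m < limit)` also catches NaN
                    if u.size and not (np.abs(u).max() < 1e6):
                        raise DivergenceError(step_counter)

            if (trial + 1) % every == 0 or trial + 1 == cfg.protocol.n_stimuli:
                _record_uniformity(cfg, w, trial + 1, artifacts.uniformity_trace)
                artifacts.snapshots.append(Snapshot(
                    trial=trial + 1,
                    weights=w.copy(),
                    state=state.copy(),
                    rng_state=rng.bit_generator.state,
                ))
                if tol is not None:
                    delta = max(np.max(np.abs(w.block(b) - prev_check[b]), initial=0.0)
                                for b in prev_check)
                    prev_check = {b: w.block(b).copy() for b in prev_check}
                    if delta < tol * norm_scale:
                        artifacts.converged = True
                        artifacts.log.append(
                            f"converged at trial {trial + 1}: max weight change "
                            f"{delta:.3e} < {tol:g} * {norm_scale:g}")
                        break
    except DivergenceError as e:
        artifacts.weights = w
        artifacts.state = state
        artifacts.n_trials_run = trial
        artifacts.log.append(f"diverged at trial {trial}, step {e.step}")
        raise RunDivergence(trial, e.step, artifacts) from e

    artifacts.weights = w
    artifacts.state = state
    artifacts.n_trials_run = trial + 1 if cfg.protocol.n_stimuli else 0
    return artifacts


def run_experiment(cfg: ExperimentConfig, *, ensemble=None,
                   initial_weights: WeightSet | None = None) -> RunArtifacts:
    """Run a full training experiment from a config.

    ``ensemble`` supplies the input patterns for ``input.kind == "ensemble"``
    configs.  ``initial_weights`` overrides the random initialization (the
    RNG then serves stimulus sampling only), used e.g. for equivariance
    checks with hand-permuted initial conditions.
    """
    rng = np.random.default_rng(cfg.seed)
    if initial_weights is not None:
        w, plastic_rows, gain_E, gain_I = initial_weights.copy(), None, None, None
    else:
        w, plastic_rows, gain_E, gain_I = assemble_network(cfg, rng)
    state = NetworkState.zeros(cfg.dims, cfg.act)

    artifacts = RunArtifacts(config=cfg, weights=w, state=state,
                             initial_weights=w.copy())
    artifacts._plastic_rows = plastic_rows
    artifacts._gain_E = gain_E
    artifacts._gain_I = gain_I
    _record_uniformity(cfg, w, 0, artifacts.uniformity_trace)
    return _run_loop(cfg, w, state, rng, 0, ensemble, artifacts)


def resume_run(cfg: ExperimentConfig, snapshot: Snapshot, *,
               ensemble=None) -> RunArtifacts:
    """Continue a run from a snapshot; reproduces the remainder exactly."""
    rng = np.random.default_rng()
    rng.bit_generator.state = snapshot.rng_state
    w = snapshot.weights.copy()
    state = snapshot.state.copy()
    artifacts = RunArtifacts(config=cfg, weights=w, state=state,
                             initial_weights=w.copy())
    # resumed runs have no static-lateral bookkeeping to rebuild beyond masks
    _, plastic_rows, gain_E, gain_I = (None, None, None, None)
    if cfg.static_lateral is not None or cfg.input.sigma_theta is not None:
        tmp_rng = np.random.default_rng(cfg.seed)
        _, plastic_rows, gain_E, gain_I = assemble_network(cfg, tmp_rng)
    artifacts._plastic_rows = plastic_rows
    artifacts._gain_E = gain_E
    artifacts._gain_I = gain_I
    return _run_loop(cfg, w, state, rng, snapshot.trial, ensemble, artifacts)


def measure_rate_statistics(cfg: ExperimentConfig, w: WeightSet, *,
                            n_stimuli: int = 200, seed: int = 12345,
                            ensemble=None):
    """Per-neuron mean and variance of end-of-stimulus firing rates under the
    training stimulus distribution, with plasticity off.

    Returns ``(mean_E, var_E, mean_I, var_I)``; one sample per stimulus,
    taken after the presentation interval.
    """
    rng = np.random.default_rng(seed)
    state = NetworkState.zeros(cfg.dims, cfg.act)
    steps = max(1, int(round(cfg.protocol.stimulus_duration / cfg.dyn.dt)))
    samples_E, samples_I = [], []
    for trial in range(n_stimuli):
        rF = _next_input(cfg, rng, trial, ensemble)
        for _ in range(steps):
            state = euler_step(state, w, rF, cfg.dyn, cfg.act,
                               mirror_inputs=cfg.input.mirror_inputs)
        samples_E.append(state.r_E.copy())
        samples_I.append(state.r_I.copy())
    E = np.array(samples_E)
    I = np.array(samples_I)
    return E.mean(axis=0), E.var(axis=0), I.mean(axis=0), I.var(axis=0)
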