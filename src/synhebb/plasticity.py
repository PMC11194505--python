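"""Hebbian plasticity with synapse-type-specific competitive normalization.

Every plastic weight matrix grows by a plain Hebbian rule,
dW_AB/dt = eps_AB * r_A r_B^T, and is then rescaled so that each postsynaptic
neuron's *total* synaptic weight of each type stays constant: excitatory
inputs (recurrent E plus plastic feedforward F, pooled) are divisively
normalized to one budget, inhibitory inputs to a separate budget.  Synapses
of one type therefore compete for a limited resource pool without any
homeostatic set point on the firing rate.

The classic alternative, inhibitory plasticity toward a target rate
(dw_EI/dt = eps (r_E - r0) r_I, unnormalized), is provided as a baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .network import BLOCKS, NetworkState, WeightSet

__all__ = [
    "LearningRates",
    "WeightNorms",
    "ClassicInhibParams",
    "hebbian_delta",
    "normalize_excitatory_pool",
    "normalize_inhibitory",
    "normalize_all",
    "competitive_plasticity_step",
    "classic_inhibitory_step",
]


@dataclass(frozen=True)
class LearningRates:
    """Per-block Hebbian learning rates (ms^-1); 0 freezes the block."""

    eps_EE: float = 0.0
    eps_EI: float = 0.0
    eps_EF: float = 0.0
    eps_IE: float = 0.0
    eps_II: float = 0.0
    eps_IF: float = 0.0

    def __post_init__(self):
        for b in BLOCKS:
            if getattr(self, f"eps_{b}") < 0:
                raise ValueError(f"eps_{b} must be nonnegative")


@dataclass(frozen=True)
class WeightNorms:
    """Per-neuron synaptic resource budgets (L1 row norms).

    W_EE / W_IE : total excitatory weight onto each E / I neuron.  The budget
    covers the recurrent E block and the feedforward block *pooled*, whenever
    the feedforward block is itself plastic; a static feedforward block is
    normalized once to W_EF / W_IF at setup and excluded from the pool.
    W_EI / W_II : total inhibitory weight onto each E / I neuron.
    ``None`` marks a block that is not normalized (unused, or governed by the
    classic unnormalized rule).
    """

    W_EE: float | None = None
    W_IE: float | None = None
    W_EI: float | None = None
    W_II: float | None = None
    W_EF: float | None = None
    W_IF: float | None = None

    def __post_init__(self):
        for b in BLOCKS:
            v = getattr(self, f"W_{b}")
            if v is not None and v <= 0:
                raise ValueError(f"norm W_{b} must be positive")


@dataclass(frozen=True)
class ClassicInhibParams:
    """Target-rate inhibitory plasticity: r0 target rate, eps_EI rate (ms^-1)."""

    r0: float
    eps_EI: float

    def __post_init__(self):
        if self.r0 < 0:
            raise ValueError("target rate r0 must be nonnegative")


def hebbian_delta(r_post: np.ndarray, r_pre: np.ndarray, eps: float, dt: float) -> np.ndarray:
    """Discrete Hebbian increment dt * eps * outer(r_post, r_pre) (rank <= 1)."""
    return dt * eps * np.outer(r_post, r_pre)


def _scale_rows(sums: np.ndarray, norm: float, context: str) -> np.ndarray:
    """Row scale factors norm / sums, with zero-sum rows left unscaled."""
    if (sums > 0.0).all():
        return norm / sums
    zero = sums <= 0.0
    # constant message so the default warning filter deduplicates it; rows
    # can legitimately stay at zero until their neuron first fires
    warnings.warn(
        f"{context}: rows with zero total weight were left unnormalized",
        RuntimeWarning,
        stacklevel=3,
    )
    safe = np.where(zero, 1.0, sums)
    return np.where(zero, 1.0, norm / safe)


def normalize_excitatory_pool(W_AE: np.ndarray, W_AF: np.ndarray, norm: float):
    """Rescale each postsynaptic row so its pooled excitatory sum equals ``norm``.

    The pool is the recurrent excitatory row plus the plastic feedforward row;
    relative proportions within a row are unchanged (divisive normalization).
    Returns the two rescaled matrices.
    """
    sums = W_AE.sum(axis=1) + W_AF.sum(axis=1)
    scale = _scale_rows(sums, norm, "excitatory pool normalization")[:, None]
    return W_AE * scale, W_AF * scale


def normalize_inhibitory(W_AI: np.ndarray, norm: float) -> np.ndarray:
    """Rescale each row of the inhibitory block so its sum equals ``norm``."""
    sums = W_AI.sum(axis=1)
    scale = _scale_rows(sums, norm, "inhibitory normalization")[:, None]
    return W_AI * scale


def _apply_rows(w: WeightSet, block: str, new: np.ndarray, rows: np.ndarray | None) -> None:
    if rows is None:
        w.set_block(block, new)
    else:
        W = w.block(block)
        W[rows] = new[rows]


def normalize_all(
    w: WeightSet,
    norms: WeightNorms,
    *,
    include_static_ff: bool = False,
    plastic_rows: dict | None = None,
) -> None:
    """Impose all synapse-type-specific norms on a weight set, in place.

    For each postsynaptic population A: the plastic excitatory blocks (W_AE
    and, if plastic, W_AF) are pooled and normalized to norms.W_AE; the
    inhibitory block W_AI is normalized to norms.W_AI.  Norms set to ``None``
    are skipped.  ``include_static_ff`` additionally normalizes static
    feedforward blocks to norms.W_AF — done once at setup only.
    ``plastic_rows`` optionally restricts normalization to a boolean subset of
    postsynaptic neurons per population (static lateral neurons keep the
    incoming weights they were assigned).
    """
    for A in ("E", "I"):
        n_post = w.block(A + "E").shape[0]
        if n_post == 0:
            continue
        rows = None if plastic_rows is None else plastic_rows.get(A)

        pool_norm = getattr(norms, f"W_{A}E")
        if pool_norm is not None:
            W_AE, W_AF = w.block(A + "E"), w.block(A + "F")
            if w.plastic[A + "F"]:
                if rows is None:
                    scale = _scale_rows(W_AE.sum(axis=1) + W_AF.sum(axis=1),
                                        pool_norm, "excitatory pool normalization")[:, None]
                    W_AE *= scale
                    W_AF *= scale
                else:
                    new_AE, new_AF = normalize_excitatory_pool(W_AE, W_AF, pool_norm)
                    _apply_rows(w, A + "E", new_AE, rows)
                    _apply_rows(w, A + "F", new_AF, rows)
            elif w.plastic[A + "E"]:
                if rows is None:
                    W_AE *= _scale_rows(W_AE.sum(axis=1), pool_norm,
                                        "excitatory pool normalization")[:, None]
                else:
                    new_AE, _ = normalize_excitatory_pool(
                        W_AE, np.zeros((n_post, 0)), pool_norm)
                    _apply_rows(w, A + "E", new_AE, rows)

        ff_norm = getattr(norms, f"W_{A}F")
        if include_static_ff and ff_norm is not None and not w.plastic[A + "F"]:
            w.set_block(A + "F", normalize_inhibitory(w.block(A + "F"), ff_norm))

        inh_norm = getattr(norms, f"W_{A}I")
        # include_static_ff marks the one-time setup pass, where the initial
        # norm is imposed even on blocks that the competitive rule won't touch
        if inh_norm is not None and (w.plastic[A + "I"] or include_static_ff):
            W_AI = w.block(A + "I")
            if rows is None:
                W_AI *= _scale_rows(W_AI.sum(axis=1), inh_norm,
                                    "inhibitory normalization")[:, None]
            else:
                _apply_rows(w, A + "I", normalize_inhibitory(W_AI, inh_norm), rows)


def competitive_plasticity_step(
    s: NetworkState,
    rF: np.ndarray,
    w: WeightSet,
    rates: LearningRates,
    norms: WeightNorms,
    dt: float,
    *,
    plastic_rows: dict | None = None,
) -> None:
    """One Hebbian-update-plus-normalization step, in place.

    Every plastic block with a nonzero learning rate receives its Hebbian
    increment (using the current state's rates), autapse diagonals are
    re-zeroed, and all norms are re-imposed.  Static blocks are untouched.
    """
    r = {"E": s.r_E, "I": s.r_I, "F": np.asarray(rF, dtype=float)}
    for b in BLOCKS:
        if not w.plastic[b]:
            continue
        eps = getattr(rates, f"eps_{b}")
        if eps == 0.0:
            continue
        if plastic_rows is not None and plastic_rows.get(b[0]) is not None:
            delta = hebbian_delta(r[b[0]], r[b[1]], eps, dt)
            w.block(b)[...] += delta * plastic_rows[b[0]][:, None]
        else:
            # scale the (small) postsynaptic vector before the outer product
            w.block(b)[...] += np.outer((dt * eps) * r[b[0]], r[b[1]])
    w.zero_autapses()
    normalize_all(w, norms, plastic_rows=plastic_rows)


def classic_inhibitory_step(
    rE: np.ndarray,
    rI: np.ndarray,
    W_EI: np.ndarray,
    p: ClassicInhibParams,
    dt: float,
) -> np.ndarray:
    """Target-rate inhibitory update: W_EI + dt * eps * outer(rE - r0, rI).

    No normalization is applied; entries are clipped at zero from below
    (Dale's law), a regime the rule itself does not constrain.
    """
    W = W_EI + dt * p.eps_EI * np.outer(rE - p.r0, rI)
    return np.maximum(W, 0.0)
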