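"""Recurrent excitatory-inhibitory rate network: data model and forward dynamics.

The circuit consists of an excitatory population (E), an inhibitory population
(I), and a feedforward input population (F).  Membrane potentials evolve by
leaky integration of the synaptic drive,

    tau_A du_A/dt = -u_A + W_AF r_F + W_AE r_E - W_AI r_I ,   A in {E, I},

integrated with the explicit Euler method, and firing rates follow a
rectified power-law transfer function r = a [u - b]_+^n.  All synaptic
weights are nonnegative; the sign of a projection is carried by the network
structure (Dale's law by construction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NetworkDimensions",
    "ActivationParams",
    "DynamicsParams",
    "InitSpec",
    "WeightSet",
    "NetworkState",
    "DivergenceError",
    "rectified_power_activation",
    "euler_step",
    "run_to_steady_state",
    "initialize_weights",
]

#: membrane potentials beyond this magnitude abort the simulation
DIVERGENCE_LIMIT = 1e6

# weight blocks, keyed (postsynaptic, presynaptic)
BLOCKS = ("EE", "EI", "EF", "IE", "II", "IF")


class DivergenceError(RuntimeError):
    """Raised when recurrent excitation runs away (non-finite or huge potentials)."""

    def __init__(self, step: int, message: str = ""):
        self.step = step
        super().__init__(
            message or f"network diverged at integration step {step}: "
            f"|u| exceeded {DIVERGENCE_LIMIT:g} or became non-finite"
        )


@dataclass(frozen=True)
class NetworkDimensions:
    """Population sizes: NE excitatory, NI inhibitory, NF feedforward inputs."""

    NE: int
    NI: int
    NF: int

    def __post_init__(self):
        if self.NE < 0 or self.NI < 0 or self.NF < 1:
            raise ValueError(f"invalid dimensions NE={self.NE}, NI={self.NI}, NF={self.NF}")
        if self.NE + self.NI < 1:
            raise ValueError("network must contain at least one neuron")


@dataclass(frozen=True)
class ActivationParams:
    """Rectified power-law transfer function r = a [u - b]_+^n.

    a : gain (dimensionless), b : threshold (potential units),
    n : exponent; n = 2 gives the supralinear regime used throughout,
    n = 1 with b = 0 gives a linear (rectified) neuron.
    """

    a: float = 1.0
    b: float = 0.0
    n: float = 2.0

    def __post_init__(self):
        if self.a <= 0 or self.n <= 0:
            raise ValueError(f"activation requires a > 0 and n > 0 (got a={self.a}, n={self.n})")


@dataclass(frozen=True)
class DynamicsParams:
    """Integration constants: membrane time constants (ms) and Euler step (ms)."""

    tau_E: float
    tau_I: float
    dt: float

    def __post_init__(self):
        if self.tau_E <= 0 or self.tau_I <= 0 or self.dt <= 0:
            raise ValueError("tau_E, tau_I and dt must all be positive")


@dataclass(frozen=True)
class InitSpec:
    """Random weight initialization: entries ~ N(mu_W, sigma_W), negatives folded
    to their absolute value.  ``zero_recurrent_E`` clears recurrently projecting
    excitatory blocks (W_EE, and W_IE unless ``zero_W_IE`` is False) before the
    initial normalization, so the network starts feedforward-dominated."""

    mu_W: float = 0.1
    sigma_W: float = 0.05
    zero_recurrent_E: bool = True
    zero_W_IE: bool = True
    seed: int | None = None

    def __post_init__(self):
        if self.sigma_W < 0:
            raise ValueError("sigma_W must be nonnegative")


def rectified_power_activation(u: np.ndarray, p: ActivationParams,
                               gain: np.ndarray | None = None) -> np.ndarray:
    """Elementwise a * max(0, u - b)**n.

    ``gain`` optionally overrides the scalar gain per neuron (used for static
    lateral neurons that operate at a different gain than the plastic ones).
    """
    a = p.a if gain is None else gain
    return a * np.maximum(np.asarray(u, dtype=float) - p.b, 0.0) ** p.n


@dataclass
class WeightSet:
    """The six nonnegative weight matrices W_AB, A in {E, I}, B in {E, I, F}.

    ``plastic`` flags each block; static blocks are never touched by learning.
    ``exclude_autapses`` holds the diagonals of W_EE and W_II at zero.
    """

    W_EE: np.ndarray
    W_EI: np.ndarray
    W_EF: np.ndarray
    W_IE: np.ndarray
    W_II: np.ndarray
    W_IF: np.ndarray
    plastic: dict = field(default_factory=lambda: {b: True for b in BLOCKS})
    exclude_autapses: bool = True

    def __post_init__(self):
        for b in BLOCKS:
            setattr(self, f"W_{b}", np.asarray(getattr(self, f"W_{b}"), dtype=float))
        self.validate()

    @property
    def dims(self) -> NetworkDimensions:
        return NetworkDimensions(self.W_EE.shape[0], self.W_II.shape[0], self.W_EF.shape[1])

    def block(self, name: str) -> np.ndarray:
        return getattr(self, f"W_{name}")

    def set_block(self, name: str, value: np.ndarray) -> None:
        setattr(self, f"W_{name}", np.asarray(value, dtype=float))

    def zero_autapses(self) -> None:
        if self.exclude_autapses:
            np.fill_diagonal(self.W_EE, 0.0)
            np.fill_diagonal(self.W_II, 0.0)

    def validate(self) -> None:
        NE, NI, NF = self.W_EE.shape[0], self.W_II.shape[0], self.W_EF.shape[1]
        expected = {
            "EE": (NE, NE), "EI": (NE, NI), "EF": (NE, NF),
            "IE": (NI, NE), "II": (NI, NI), "IF": (NI, NF),
        }
        for b, shape in expected.items():
            W = self.block(b)
            if W.shape != shape:
                raise ValueError(f"W_{b} has shape {W.shape}, expected {shape}")
            if W.size and W.min() < 0:
                raise ValueError(f"W_{b} contains negative entries")

    def copy(self) -> "WeightSet":
        return WeightSet(
            *(self.block(b).copy() for b in BLOCKS),
            plastic=dict(self.plastic),
            exclude_autapses=self.exclude_autapses,
        )


@dataclass
class NetworkState:
    """Membrane potentials and firing rates of both populations at one time step."""

    u_E: np.ndarray
    u_I: np.ndarray
    r_E: np.ndarray
    r_I: np.ndarray

    @classmethod
    def zeros(cls, dims: NetworkDimensions, act: ActivationParams) -> "NetworkState":
        uE = np.zeros(dims.NE)
        uI = np.zeros(dims.NI)
        return cls(uE, uI, rectified_power_activation(uE, act),
                   rectified_power_activation(uI, act))

    def copy(self) -> "NetworkState":
        return NetworkState(self.u_E.copy(), self.u_I.copy(),
                            self.r_E.copy(), self.r_I.copy())


def euler_step(
    s: NetworkState,
    w: WeightSet,
    rF: np.ndarray,
    dyn: DynamicsParams,
    act: ActivationParams,
    *,
    mirror_inputs: bool = False,
    gain_E: np.ndarray | None = None,
    gain_I: np.ndarray | None = None,
) -> NetworkState:
    """One explicit Euler step of the membrane dynamics.

    The synaptic drive uses the rates of the incoming state (explicit scheme);
    the returned state carries rates recomputed from the new potentials.

    With ``mirror_inputs`` the inhibitory population is not integrated:
    its rates are clamped to the feedforward rates (r_I = r_F), the
    configuration used when inhibitory inputs are assumed to be exactly as
    stimulus-selective as the excitatory inputs.
    """
    rF = np.asarray(rF, dtype=float)
    if rF.shape != (w.W_EF.shape[1],):
        raise ValueError(f"rF has shape {rF.shape}, expected ({w.W_EF.shape[1]},)")

    # clamped inhibitory inputs are input neurons: they carry the *current*
    # stimulus, like the feedforward term, rather than an integrated state
    r_I_drive = rF if mirror_inputs else s.r_I
    drive_E = w.W_EF @ rF + w.W_EE @ s.r_E - w.W_EI @ r_I_drive
    u_E = s.u_E + (dyn.dt / dyn.tau_E) * (-s.u_E + drive_E)
    r_E = rectified_power_activation(u_E, act, gain_E)

    if mirror_inputs:
        if w.W_EI.shape[1] != rF.shape[0]:
            raise ValueError("mirror_inputs requires NI == NF")
        u_I = s.u_I
        r_I = rF.copy()
    else:
        drive_I = w.W_IF @ rF + w.W_IE @ s.r_E - w.W_II @ s.r_I
        u_I = s.u_I + (dyn.dt / dyn.tau_I) * (-s.u_I + drive_I)
        r_I = rectified_power_activation(u_I, act, gain_I)

    return NetworkState(u_E, u_I, r_E, r_I)


def _check_finite(s: NetworkState, step: int) -> None:
    for u in (s.u_E, s.u_I):
        if u.size and (not np.all(np.isfinite(u)) or np.max(np.abs(u)) > DIVERGENCE_LIMIT):
            raise DivergenceError(step)


def run_to_steady_state(
    s: NetworkState,
    w: WeightSet,
    rF: np.ndarray,
    dyn: DynamicsParams,
    act: ActivationParams,
    duration: float,
    *,
    mirror_inputs: bool = False,
    gain_E: np.ndarray | None = None,
    gain_I: np.ndarray | None = None,
    record: bool = False,
):
    """Integrate for ``duration`` ms under a constant input drive.

    Returns the final state, or ``(state, (r_E trace, r_I trace))`` when
    ``record`` is set.  Raises :class:`DivergenceError` (naming the step) if
    the potentials blow up.
    """
    if duration < dyn.dt:
        raise ValueError("duration must be at least one Euler step dt")
    n_steps = int(duration // dyn.dt)
    traces = ([], []) if record else None
    state = s
    for k in range(n_steps):
        state = euler_step(state, w, rF, dyn, act, mirror_inputs=mirror_inputs,
                           gain_E=gain_E, gain_I=gain_I)
        _check_finite(state, k)
        if record:
            traces[0].append(state.r_E.copy())
            traces[1].append(state.r_I.copy())
    if record:
        return state, (np.array(traces[0]), np.array(traces[1]))
    return state


def initialize_weights(
    dims: NetworkDimensions,
    spec: InitSpec,
    norms,
    *,
    rng: np.random.Generator | None = None,
    plastic: dict | None = None,
    exclude_autapses: bool = True,
    static_W_EF: np.ndarray | None = None,
    static_W_IF: np.ndarray | None = None,
) -> WeightSet:
    """Draw initial weights and apply the normalization once.

    Entries are drawn from N(mu_W, sigma_W) and negatives folded to their
    absolute value, which for mu_W = 2 sigma_W yields mainly positive draws.
    Recurrent excitatory blocks are optionally zeroed, autapse diagonals are
    cleared, and the synapse-type-specific norms are imposed before the first
    stimulus.  ``static_W_EF`` / ``static_W_IF`` install precomputed (tuned)
    feedforward matrices and mark those blocks static; static feedforward
    blocks are normalized separately to their own norm and excluded from the
    recurrent excitatory pool thereafter.

    Deterministic given ``rng`` (or ``spec.seed``).
    """
    from .plasticity import normalize_all  # local import to avoid a cycle

    if rng is None:
        rng = np.random.default_rng(spec.seed)

    shapes = {
        "EE": (dims.NE, dims.NE), "EI": (dims.NE, dims.NI), "EF": (dims.NE, dims.NF),
        "IE": (dims.NI, dims.NE), "II": (dims.NI, dims.NI), "IF": (dims.NI, dims.NF),
    }
    mats = {}
    for b in BLOCKS:
        mats[b] = np.abs(rng.normal(spec.mu_W, spec.sigma_W, size=shapes[b]))

    plastic = dict(plastic) if plastic is not None else {b: True for b in BLOCKS}
    if static_W_EF is not None:
        mats["EF"] = np.asarray(static_W_EF, dtype=float).copy()
        plastic["EF"] = False
    if static_W_IF is not None:
        mats["IF"] = np.asarray(static_W_IF, dtype=float).copy()
        plastic["IF"] = False

    if spec.zero_recurrent_E:
        mats["EE"] = np.zeros_like(mats["EE"])
        if spec.zero_W_IE:
            mats["IE"] = np.zeros_like(mats["IE"])

    w = WeightSet(mats["EE"], mats["EI"], mats["EF"], mats["IE"], mats["II"], mats["IF"],
                  plastic=plastic, exclude_autapses=exclude_autapses)
    w.zero_autapses()
    with warnings.catch_warnings():
        # freshly zeroed recurrent blocks legitimately have all-zero rows
        warnings.simplefilter("ignore")
        normalize_all(w, norms, include_static_ff=True)
    return w
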