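"""Linear fixed-point theory of competitive Hebbian learning.

For a linear neuron the expected feedforward weight drift under Hebbian
growth with divisive normalization is <dw_E/dt> ~ C w_E - gamma w_E, with
C the (uncentered) input second-moment matrix, so fixed points are
eigenvectors of C and the neuron performs principal component analysis of
its inputs.  With plastic inhibitory weights, the joint drift of the stacked
vector w = (w_E; w_I) is governed by a modified covariance matrix whose
inhibitory blocks enter with a minus sign; when the inhibitory input stream
mirrors the excitatory one, co-aligned eigenvector weights (w_E ~ w_I) are
fixed points — the balanced-PCA solution.

In recurrent networks, neurons tuned to the same input mode form an
"eigencircuit".  Its members shift the mode's effective attraction:
each excitatory member adds its rate variance, each inhibitory member
subtracts it,

    lambda_eff = lambda_ff + sum_i var(r_E,i) - sum_j var(r_I,j),

and a collapse of all tunings onto a single mode is prevented when
N_E * mean var(r_E) < N_I * mean var(r_I).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "InputEnsemble",
    "ModifiedCovariance",
    "EigencircuitSummary",
    "StabilityCheck",
    "second_moment",
    "modified_covariance",
    "expected_drift",
    "effective_attraction",
    "collapse_predicted",
    "principal_eigenvector",
]


@dataclass(frozen=True)
class InputEnsemble:
    """A set of input patterns, one pattern per row.

    ``patterns_I`` optionally holds a distinct inhibitory input stream; when
    absent (``mirrored=True`` semantics) the inhibitory stream is taken to be
    identical to the excitatory one.
    """

    patterns: np.ndarray
    patterns_I: np.ndarray | None = None

    def __post_init__(self):
        P = np.asarray(self.patterns, dtype=float)
        object.__setattr__(self, "patterns", P)
        if P.ndim != 2 or P.shape[0] < 2:
            raise ValueError("ensemble requires at least 2 patterns (rows)")
        if not np.all(np.isfinite(P)):
            raise ValueError("ensemble contains non-finite entries")
        if self.patterns_I is not None:
            Q = np.asarray(self.patterns_I, dtype=float)
            object.__setattr__(self, "patterns_I", Q)
            if Q.shape[0] != P.shape[0]:
                raise ValueError("excitatory and inhibitory ensembles must have "
                                 "equal pattern counts")

    @property
    def mirrored(self) -> bool:
        return self.patterns_I is None

    @property
    def inhibitory(self) -> np.ndarray:
        return self.patterns if self.patterns_I is None else self.patterns_I

    @classmethod
    def from_csv(cls, path) -> "InputEnsemble":
        return cls(np.loadtxt(path, delimiter=","))


def second_moment(ensemble: InputEnsemble | np.ndarray) -> np.ndarray:
    """Uncentered second-moment matrix <y y^T>, averaged over patterns.

    This is the "covariance" of the linear theory: the temporal average of
    outer products, *not* mean-subtracted.  Center the ensemble first if a
    centered statistic is wanted.
    """
    Y = ensemble.patterns if isinstance(ensemble, InputEnsemble) else np.asarray(ensemble, float)
    return Y.T @ Y / Y.shape[0]


@dataclass(frozen=True)
class ModifiedCovariance:
    """Block matrix governing the joint (w_E; w_I) drift:

    [[ <yE yE^T>, -<yE yI^T>],
     [ <yI yE^T>, -<yI yI^T>]]

    The inhibitory column blocks carry a minus sign because inhibitory input
    enters the postsynaptic rate with negative sign while its own Hebbian
    growth is still positive in r_I.
    """

    C_EE: np.ndarray
    C_EI: np.ndarray
    C_IE: np.ndarray
    C_II: np.ndarray

    @property
    def matrix(self) -> np.ndarray:
        return np.block([[self.C_EE, -self.C_EI], [self.C_IE, -self.C_II]])

    @property
    def nE(self) -> int:
        return self.C_EE.shape[0]

    @property
    def nI(self) -> int:
        return self.C_II.shape[0]


def modified_covariance(ensemble_E: np.ndarray, ensemble_I: np.ndarray) -> ModifiedCovariance:
    """Cross second moments of the excitatory and inhibitory input streams."""
    YE = np.asarray(ensemble_E, dtype=float)
    YI = np.asarray(ensemble_I, dtype=float)
    if YE.shape[0] != YI.shape[0]:
        raise ValueError("pattern counts differ between streams")
    n = YE.shape[0]
    return ModifiedCovariance(
        C_EE=YE.T @ YE / n,
        C_EI=YE.T @ YI / n,
        C_IE=YI.T @ YE / n,
        C_II=YI.T @ YI / n,
    )


def expected_drift(wE: np.ndarray, wI: np.ndarray, mc: ModifiedCovariance) -> np.ndarray:
    """Expected drift of the stacked weight vector under normalized Hebbian flow.

    Computes Cbar @ (wE; wI) minus the normalization terms (gamma * wE;
    rho * wI), with gamma and rho chosen block-wise so that the summed drift
    over the excitatory components and over the inhibitory components each
    vanish — the unique scalars consistent with conservation of the L1 norms
    that the divisive normalization maintains.
    """
    wE = np.asarray(wE, dtype=float)
    wI = np.asarray(wI, dtype=float)
    w = np.concatenate([wE, wI])
    g = mc.matrix @ w
    gE, gI = g[: mc.nE], g[mc.nE:]
    gamma = gE.sum() / wE.sum() if wE.sum() != 0 else 0.0
    rho = gI.sum() / wI.sum() if wI.sum() != 0 else 0.0
    return np.concatenate([gE - gamma * wE, gI - rho * wI])


@dataclass(frozen=True)
class EigencircuitSummary:
    """Effective attraction of one input mode.

    lambda_ff : attraction of the isolated feedforward mode;
    var_E / var_I : firing-rate variances of the eigencircuit's members;
    lambda_eig : their net contribution; lambda_eff = lambda_ff + lambda_eig.
    """

    lambda_ff: float
    var_E: tuple
    var_I: tuple
    lambda_eig: float = field(init=False)
    lambda_eff: float = field(init=False)

    def __post_init__(self):
        vE = np.asarray(self.var_E, dtype=float)
        vI = np.asarray(self.var_I, dtype=float)
        if (vE.size and vE.min() < 0) or (vI.size and vI.min() < 0):
            raise ValueError("rate variances must be nonnegative")
        object.__setattr__(self, "var_E", tuple(vE))
        object.__setattr__(self, "var_I", tuple(vI))
        object.__setattr__(self, "lambda_eig", float(vE.sum() - vI.sum()))
        object.__setattr__(self, "lambda_eff", float(self.lambda_ff + self.lambda_eig))


def effective_attraction(lambda_ff: float, var_E, var_I) -> EigencircuitSummary:
    """Effective attraction of an input mode hosting an eigencircuit:
    excitatory members add their rate variance, inhibitory members subtract."""
    return EigencircuitSummary(lambda_ff=float(lambda_ff), var_E=tuple(var_E),
                               var_I=tuple(var_I))


@dataclass(frozen=True)
class StabilityCheck:
    """Collapse condition: tuning-curve collapse onto a single input mode is
    prevented iff N_E * mean var(r_E) < N_I * mean var(r_I) (strict)."""

    NE: int
    NI: int
    mean_var_E: float
    mean_var_I: float

    @property
    def collapse_prevented(self) -> bool:
        return self.NE * self.mean_var_E < self.NI * self.mean_var_I


def collapse_predicted(NE: int, NI: int, mean_var_E: float, mean_var_I: float) -> StabilityCheck:
    """Evaluate the collapse-prevention inequality (strict; equality does not
    prevent collapse)."""
    if NE < 0 or NI < 0 or mean_var_E < 0 or mean_var_I < 0:
        raise ValueError("counts and variances must be nonnegative")
    return StabilityCheck(NE=NE, NI=NI, mean_var_E=float(mean_var_E),
                          mean_var_I=float(mean_var_I))


def principal_eigenvector(matrix: np.ndarray, *, degenerate_tol: float = 1e-10):
    """Unit-norm eigenvector of the largest eigenvalue of a symmetric matrix.

    The sign is fixed so the largest-magnitude component is positive.
    Returns ``(vector, degenerate)`` where ``degenerate`` flags a (numerically)
    repeated leading eigenvalue, in which case the returned direction is one
    representative of the leading eigenspace.
    """
    A = np.asarray(matrix, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1] or not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("principal_eigenvector requires a symmetric matrix")
    vals, vecs = np.linalg.eigh(A)
    v = vecs[:, -1]
    scale = max(abs(vals[-1]), 1.0)
    degenerate = A.shape[0] > 1 and (vals[-1] - vals[-2]) <= degenerate_tol * scale
    i = int(np.argmax(np.abs(v)))
    if v[i] < 0:
        v = -v
    return v, bool(degenerate)
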