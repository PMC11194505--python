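"""Forward dynamics of the E-I rate network."""

import numpy as np
import pytest

from synhebb.network import (ActivationParams, DivergenceError, DynamicsParams,
                             InitSpec, NetworkDimensions, NetworkState,
                             WeightSet, euler_step, initialize_weights,
                             rectified_power_activation, run_to_steady_state)
from synhebb.plasticity import WeightNorms


def make_weights(NE=2, NI=2, NF=3, fill=0.0, **kw):
    return WeightSet(
        np.full((NE, NE), fill), np.full((NE, NI), fill), np.full((NE, NF), fill),
        np.full((NI, NE), fill), np.full((NI, NI), fill), np.full((NI, NF), fill),
        **kw,
    )


class TestActivation:
    @pytest.mark.parametrize("u,params,expected", [
        (-1.0, dict(a=0.04, b=0.0, n=2.0), 0.0),     # below threshold
        (0.7, dict(a=3.0, b=0.7, n=2.0), 0.0),       # exactly at threshold
        (5.0, dict(a=0.04, b=0.0, n=2.0), 1.0),      # 0.04 * 25
        (1.25, dict(a=1.0, b=0.25, n=2.0), 1.0),     # 1 * 1^2
    ])
    def test_pointwise_values(self, u, params, expected):
        p = ActivationParams(**params)
        assert rectified_power_activation(np.array([u]), p)[0] == pytest.approx(expected)

    def test_nonnegative_everywhere(self, rng):
        p = ActivationParams(a=0.5, b=-1.0, n=2.0)
        u = rng.normal(size=100) * 10
        assert (rectified_power_activation(u, p) >= 0).all()

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            ActivationParams(a=0.0)
        with pytest.raises(ValueError):
            ActivationParams(n=-1.0)


class TestEulerStep:
    dyn = DynamicsParams(tau_E=20.0, tau_I=10.0, dt=5.0)
    act = ActivationParams(a=1.0, b=0.0, n=1.0)

    def test_zero_weights_zero_input_is_fixed_point(self):
        w = make_weights()
        s = NetworkState.zeros(w.dims, self.act)
        out = euler_step(s, w, np.zeros(3), self.dyn, self.act)
        assert (out.u_E == 0).all() and (out.u_I == 0).all()
        assert (out.r_E == 0).all() and (out.r_I == 0).all()

    def test_dt_equal_tau_replaces_potential_by_drive(self):
        # with dt = tau and no recurrence the potential becomes W_EF rF exactly
        dyn = DynamicsParams(tau_E=200.0, tau_I=200.0, dt=200.0)
        w = make_weights()
        w.W_EF[...] = [[1.0, 2.0, 0.5], [0.0, 1.0, 1.0]]
        rF = np.array([1.0, 0.5, 2.0])
        s = NetworkState.zeros(w.dims, self.act)
        out = euler_step(s, w, rF, dyn, self.act)
        np.testing.assert_allclose(out.u_E, w.W_EF @ rF)

    def test_matches_closed_form_exponential_relaxation(self):
        # single linear neuron under constant drive: u(t) = d (1 - exp(-t/tau))
        dyn = DynamicsParams(tau_E=20.0, tau_I=20.0, dt=0.1)
        w = make_weights(NE=1, NI=0, NF=1)
        w.W_EF[...] = 1.0
        d = 3.0
        s = NetworkState.zeros(w.dims, self.act)
        for _ in range(400):  # 40 ms = 2 tau
            s = euler_step(s, w, np.array([d]), dyn, self.act)
        exact = d * (1 - np.exp(-40.0 / 20.0))
        assert s.u_E[0] == pytest.approx(exact, abs=5e-3)
        # iterate to effective convergence at the fixed point u* = d
        for _ in range(4000):
            s = euler_step(s, w, np.array([d]), dyn, self.act)
        assert s.u_E[0] == pytest.approx(d, rel=1e-9)

    def test_shape_mismatch_raises(self):
        w = make_weights()
        s = NetworkState.zeros(w.dims, self.act)
        with pytest.raises(ValueError, match="shape"):
            euler_step(s, w, np.zeros(5), self.dyn, self.act)


class TestRunToSteadyState:
    act = ActivationParams(a=1.0, b=0.0, n=1.0)
    dyn = DynamicsParams(tau_E=10.0, tau_I=10.0, dt=1.0)

    def _stable_random_network(self, rng):
        w = make_weights(NE=3, NI=3, NF=4)
        w.W_EE[...] = rng.uniform(0, 0.1, (3, 3))
        w.W_EI[...] = rng.uniform(0, 0.3, (3, 3))
        w.W_EF[...] = rng.uniform(0, 1, (3, 4))
        w.W_IE[...] = rng.uniform(0, 0.3, (3, 3))
        w.W_II[...] = rng.uniform(0, 0.1, (3, 3))
        w.W_IF[...] = rng.uniform(0, 1, (3, 4))
        return w

    def test_duration_dt_equals_single_step(self):
        w = make_weights()
        w.W_EF[...] = 0.3
        rF = np.array([1.0, 2.0, 0.0])
        s0 = NetworkState.zeros(w.dims, self.act)
        one = euler_step(s0, w, rF, self.dyn, self.act)
        out = run_to_steady_state(s0, w, rF, self.dyn, self.act, duration=self.dyn.dt)
        np.testing.assert_array_equal(out.u_E, one.u_E)

    def test_linear_steady_state_matches_direct_solve(self, rng):
        # for linear f the fixed point solves (I - Wtilde) u = feedforward drive,
        # with Wtilde the signed recurrent matrix acting on (u_E, u_I)
        w = self._stable_random_network(rng)
        rF = rng.uniform(0, 1, 4)
        Wt = np.block([[w.W_EE, -w.W_EI], [w.W_IE, -w.W_II]])
        drive = np.concatenate([w.W_EF @ rF, w.W_IF @ rF])
        u_exact = np.linalg.solve(np.eye(6) - Wt, drive)
        assert (u_exact >= 0).all(), "oracle assumes rectification inactive"
        s = NetworkState.zeros(w.dims, self.act)
        out = run_to_steady_state(s, w, rF, self.dyn, self.act, duration=400.0)
        np.testing.assert_allclose(np.concatenate([out.u_E, out.u_I]), u_exact,
                                   rtol=1e-6, atol=1e-9)

    def test_zero_input_decays_to_rest(self, rng):
        w = self._stable_random_network(rng)
        s = NetworkState(np.ones(3), np.ones(3), np.ones(3), np.ones(3))
        out = run_to_steady_state(s, w, np.zeros(4), self.dyn, self.act, duration=400.0)
        np.testing.assert_allclose(out.r_E, 0.0, atol=1e-10)
        np.testing.assert_allclose(out.r_I, 0.0, atol=1e-10)

    def test_runaway_excitation_raises_divergence_error(self):
        w = make_weights(NE=2, NI=0, NF=1)
        w.W_EE[...] = 5.0  # strong mutual excitation, no inhibition
        w.exclude_autapses = True
        w.zero_autapses()
        w.W_EF[...] = 1.0
        s = NetworkState.zeros(w.dims, self.act)
        with pytest.raises(DivergenceError, match="step"):
            run_to_steady_state(s, w, np.array([1.0]), self.dyn, self.act,
                                duration=10000.0)

    def test_records_trace_when_asked(self):
        w = make_weights()
        s = NetworkState.zeros(w.dims, self.act)
        _, (trE, trI) = run_to_steady_state(s, w, np.zeros(3), self.dyn, self.act,
                                            duration=10.0, record=True)
        assert trE.shape == (10, 2) and trI.shape == (10, 2)


class TestInitializeWeights:
    dims = NetworkDimensions(NE=3, NI=2, NF=4)
    norms = WeightNorms(W_EE=2.0, W_IE=1.5, W_EI=0.8, W_II=0.5)

    def test_zero_sigma_gives_constant_entries_up_to_normalization(self):
        spec = InitSpec(mu_W=0.1, sigma_W=0.0, zero_recurrent_E=False, seed=0)
        w = initialize_weights(self.dims, spec, self.norms)
        # W_EI rows were constant, so normalization makes each entry norm / NI
        np.testing.assert_allclose(w.W_EI, 0.8 / 2)
        np.testing.assert_allclose(w.W_IF + 0, w.W_IF)  # shape sanity

    def test_same_seed_reproduces_weights_exactly(self):
        spec = InitSpec(mu_W=0.1, sigma_W=0.05, seed=7)
        w1 = initialize_weights(self.dims, spec, self.norms)
        w2 = initialize_weights(self.dims, spec, self.norms)
        for b in ("EE", "EI", "EF", "IE", "II", "IF"):
            np.testing.assert_array_equal(w1.block(b), w2.block(b))

    def test_row_norms_imposed_after_initialization(self):
        spec = InitSpec(mu_W=0.2, sigma_W=0.1, zero_recurrent_E=False, seed=3)
        w = initialize_weights(self.dims, spec, self.norms)
        np.testing.assert_allclose(w.W_EE.sum(1) + w.W_EF.sum(1), 2.0, rtol=1e-12)
        np.testing.assert_allclose(w.W_IE.sum(1) + w.W_IF.sum(1), 1.5, rtol=1e-12)
        np.testing.assert_allclose(w.W_EI.sum(1), 0.8, rtol=1e-12)
        np.testing.assert_allclose(w.W_II.sum(1), 0.5, rtol=1e-12)

    def test_zero_recurrent_E_clears_both_E_originating_blocks(self):
        spec = InitSpec(mu_W=0.2, sigma_W=0.1, zero_recurrent_E=True, seed=3)
        w = initialize_weights(self.dims, spec, self.norms)
        assert (w.W_EE == 0).all() and (w.W_IE == 0).all()
        assert (w.W_EF > 0).all()

    def test_autapse_diagonals_held_at_zero(self):
        spec = InitSpec(mu_W=0.2, sigma_W=0.1, zero_recurrent_E=False, seed=3)
        w = initialize_weights(self.dims, spec, self.norms)
        assert (np.diag(w.W_EE) == 0).all() and (np.diag(w.W_II) == 0).all()

    def test_negative_entries_rejected_by_weightset(self):
        with pytest.raises(ValueError, match="negative"):
            make_weights(fill=-0.1)


class TestDimensions:
    def test_invalid_dimensions_rejected(self):
        with pytest.raises(ValueError):
            NetworkDimensions(NE=0, NI=0, NF=4)
        with pytest.raises(ValueError):
            NetworkDimensions(NE=1, NI=1, NF=0)

    def test_nonnegative_rates_after_any_step(self, rng):
        act = ActivationParams(a=0.04, b=0.0, n=2.0)
        dyn = DynamicsParams(tau_E=20.0, tau_I=17.0, dt=10.0)
        w = make_weights(NE=3, NI=3, NF=4)
        for b in ("EE", "EI", "EF", "IE", "II", "IF"):
            w.block(b)[...] = rng.uniform(0, 0.5, w.block(b).shape)
        s = NetworkState.zeros(w.dims, act)
        for _ in range(50):
            s = euler_step(s, w, rng.uniform(0, 2, 4), dyn, act)
            assert (s.r_E >= 0).all() and (s.r_I >= 0).all()
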