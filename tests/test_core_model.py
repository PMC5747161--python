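"""Unit and property tests for the redox-switch ODE core."""

import math

import numpy as np
import pytest

from appa_ppsr.core_model import (
    DEFAULT_FIT_PARAMS,
    ModelParams,
    ModelState,
    anaerobic_start,
    jacobian_reduced,
    rhs,
    rhs_reduced,
    simulate,
    steady_state,
)
from appa_ppsr.errors import DomainError

from conftest import random_state


def random_params(rng) -> ModelParams:
    return ModelParams(I=rng.uniform(0.001, 1.0),
                       alpha=rng.uniform(0.5, 10.0),
                       beta=rng.uniform(1.0, 50.0),
                       gamma=rng.uniform(0.5, 3.0),
                       delta=rng.uniform(0.1, 2.0),
                       K_eq=math.inf if rng.random() < 0.5
                       else rng.uniform(1.0, 100.0))


class TestRHS:
    def test_conservation_exact(self, rng):
        """Both conservation laws hold identically for the time derivative."""
        for _ in range(50):
            params = random_params(rng)
            state = random_state(rng, params.gamma)
            O = rng.uniform(0, 30)
            da, db, dp, dr, dc = rhs(params, O, state)
            assert da + db + dc == pytest.approx(0.0, abs=1e-12)
            assert dp + dr + 2 * dc == pytest.approx(0.0, abs=1e-12)

    def test_anaerobic_complex_formation_only(self):
        """At O=0 with all AppA and PpsR reduced, only the complex-formation
        flux delta*a*r^2 is active."""
        params = ModelParams(I=0.5, alpha=6, beta=500, gamma=2.1)
        state = ModelState(a=2.1, b=0.0, p=0.0, r=1.0, c=0.0)
        da, db, dp, dr, dc = rhs(params, 0.0, state)
        assert dp == 0.0
        assert db == 0.0
        assert dc == pytest.approx(2.1)
        assert da == pytest.approx(-2.1)
        assert dr == pytest.approx(-4.2)

    def test_matches_integrated_derivative(self, rng):
        """rhs agrees with the central-difference time derivative of a
        high-accuracy short integration."""
        for _ in range(5):
            params = random_params(rng)
            state = random_state(rng, params.gamma)
            O = rng.uniform(0, 20)
            dt = 1e-6
            _, traj = simulate(params, O, state, 2 * dt, reltol=1e-12,
                               abstol=1e-14, n_out=3)
            deriv = rhs(params, O, traj[1])
            num = (traj[2].as_array() - traj[0].as_array()) / (2 * dt)
            scale = max(1.0, float(np.max(np.abs(deriv))))
            assert np.allclose(num, deriv, atol=1e-5 * scale)

    def test_domain_errors(self, default_params):
        bad = ModelState(a=-0.1, b=2.2, p=0.0, r=1.0, c=0.0)
        with pytest.raises(DomainError):
            rhs(default_params, 1.0, bad)
        good = anaerobic_start(default_params)
        with pytest.raises(DomainError):
            rhs(default_params, -1.0, good)
        with pytest.raises(DomainError):
            rhs(default_params, math.nan, good)

    def test_irreversible_sentinel_matches_large_keq(self, rng):
        """K_eq = inf equals the limit of a very large finite K_eq."""
        base = dict(I=0.01, alpha=6, beta=500, gamma=2.1)
        state = random_state(rng, 2.1)
        f_inf = rhs(ModelParams(K_eq=math.inf, **base), 5.0, state)
        f_big = rhs(ModelParams(K_eq=1e12, **base), 5.0, state)
        assert np.allclose(f_inf, f_big, atol=1e-8)


class TestSimulate:
    def test_zero_time_is_identity(self, default_params):
        s0 = anaerobic_start(default_params)
        times, states = simulate(default_params, 5.0, s0, 0.0)
        assert list(times) == [0.0]
        assert states == [s0]

    def test_oxidized_ppsr_decays_anaerobically(self, default_params, rng):
        """At O=0 production of oxidized PpsR is impossible, so p -> 0."""
        s0 = random_state(rng, default_params.gamma)
        _, states = simulate(default_params, 0.0, s0, 2000.0)
        assert states[-1].p <= 1e-6

    def test_conservation_drift(self, default_params):
        s0 = anaerobic_start(default_params)
        _, states = simulate(default_params, 10.0, s0, 100.0)
        for s in states:
            assert abs(s.a + s.b + s.c - default_params.gamma) < 1e-7
            assert abs(s.p + s.r + 2 * s.c - 1.0) < 1e-7


class TestSteadyState:
    def test_anaerobic_has_no_oxidized_ppsr(self, rng):
        for _ in range(5):
            params = random_params(rng)
            ss = steady_state(params, 0.0, strict_stability=False)
            assert ss.state.p <= 1e-10

    def test_free_reduced_ppsr_negligible_at_fit(self, default_params):
        """At the recommended fit and O=10 free reduced PpsR is < 5% of
        total, the basis for the case-i simplification."""
        ss = steady_state(default_params, 10.0, strict_stability=False)
        assert ss.state.r < 0.05

    def test_agrees_with_long_integration(self, default_params):
        # the slowest relaxation mode at O=5 has |Re λ| ≈ 1e-3, so the
        # integration horizon must cover several of those e-folding times
        ss = steady_state(default_params, 5.0, strict_stability=False)
        _, states = simulate(default_params, 5.0,
                             anaerobic_start(default_params), 3e4)
        assert np.allclose(ss.state.as_array(), states[-1].as_array(),
                           atol=1e-6)

    def test_residual_and_conservation(self, default_params):
        for O in (0.0, 2.0, 7.5, 30.0):
            ss = steady_state(default_params, O, strict_stability=False)
            assert ss.residual_norm < 1e-10
            ss.state.validate(gamma=default_params.gamma, tol=1e-9)

    def test_random_inits_reach_same_attractor(self, rng):
        """In a monostable regime the steady state is the long-time limit of
        the flow from arbitrary admissible initial conditions."""
        for _ in range(5):
            params = ModelParams(I=rng.uniform(0.01, 0.5),
                                 alpha=rng.uniform(1, 8),
                                 beta=rng.uniform(5, 50),
                                 gamma=rng.uniform(1.0, 2.5))
            O = rng.uniform(5.0, 20.0)
            ref = steady_state(params, O, strict_stability=False,
                               ensure_stable=True)
            for _ in range(4):
                s0 = random_state(rng, params.gamma)
                _, states = simulate(params, O, s0, 5e3)
                assert np.allclose(states[-1].as_array(),
                                   ref.state.as_array(), atol=1e-5)


class TestJacobian:
    def test_decoupled_appa_eigenvalue(self):
        """With the PpsR couplings switched off the AppA redox cycle has the
        closed-form relaxation rate 1 + O."""
        O = 3.0
        params = ModelParams(I=0.5, alpha=6, beta=1e-12, gamma=2.1,
                             delta=1e-12)
        x = np.array([1.0, 0.4, 0.1])
        eig = np.linalg.eigvals(jacobian_reduced(params, O, x))
        assert min(abs(e.real + (1 + O)) for e in eig) < 1e-6

    def test_matches_finite_difference(self, rng):
        for _ in range(10):
            params = random_params(rng)
            x = random_state(rng, params.gamma).reduced()
            O = rng.uniform(0, 20)
            J = jacobian_reduced(params, O, x)
            Jfd = np.empty_like(J)
            for j in range(3):
                h = 1e-7 * max(1.0, abs(x[j]))
                e = np.zeros(3)
                e[j] = h
                Jfd[:, j] = (rhs_reduced(params, O, x + e)
                             - rhs_reduced(params, O, x - e)) / (2 * h)
            scale = max(1.0, float(np.max(np.abs(J))))
            assert np.allclose(J, Jfd, atol=1e-5 * scale)

    def test_fit_regime_is_linearly_stable(self, default_params):
        ss = steady_state(default_params, 10.0, strict_stability=False)
        assert all(e.real < 0 for e in ss.eigenvalues)
        assert ss.stable


class TestSteadyStateProperties:
    @pytest.mark.parametrize("O", [1.0, 5.0, 10.0, 20.0, 30.0])
    def test_delta_independence(self, O):
        """The complex-kinetics timescale delta cancels from the
        steady-state equations."""
        states = []
        for delta in (0.1, 1.0, 100.0):
            p = ModelParams(I=0.001, alpha=6, beta=500, gamma=2.1,
                            delta=delta)
            init = steady_state(
                ModelParams(I=0.001, alpha=6, beta=500, gamma=2.1), 1.0,
                strict_stability=False).state if O > 3 else None
            states.append(steady_state(p, O, init=init,
                                       strict_stability=False,
                                       ensure_stable=True).state.as_array())
        for other in states[1:]:
            assert np.allclose(states[0], other, atol=1e-8)

    def test_nonmonotone_beta_effect(self):
        """Raising the PpsR-reduction speed first depletes then (via complex
        sequestration of the reduced form) restores oxidized PpsR at fixed
        intermediate oxygen."""
        def p_star(beta):
            params = ModelParams(I=0.001, alpha=6, beta=beta, gamma=2.1)
            prev = None
            for O in np.arange(0.0, 10.5, 0.5):
                prev = steady_state(params, O, init=prev,
                                    strict_stability=False,
                                    ensure_stable=True).state
            return prev.p

        p10, p100, p500 = p_star(10.0), p_star(100.0), p_star(500.0)
        assert p100 < p10
        assert p500 > p100

    def test_oxidation_monotone_in_oxygen(self, default_params):
        """Along the anaerobic-continued branch the oxidized fraction never
        decreases with oxygen."""
        prev, ps = None, []
        for O in np.linspace(0.0, 30.0, 31):
            prev = steady_state(default_params, O, init=prev,
                                strict_stability=False,
                                ensure_stable=True).state
            ps.append(prev.p)
        assert np.all(np.diff(ps) >= -1e-9)


class TestParamsValidation:
    @pytest.mark.parametrize("kwargs", [
        dict(I=-0.1, alpha=6, beta=500, gamma=2.1),
        dict(I=0.1, alpha=0, beta=500, gamma=2.1),
        dict(I=0.1, alpha=6, beta=-5, gamma=2.1),
        dict(I=0.1, alpha=6, beta=500, gamma=2.1, K_eq=-1),
        dict(I=math.nan, alpha=6, beta=500, gamma=2.1),
    ])
    def test_rejects_invalid(self, kwargs):
        with pytest.raises(DomainError):
            ModelParams(**kwargs)

    def test_state_invariant_check(self):
        with pytest.raises(DomainError):
            ModelState(a=1.0, b=1.0, p=0.5, r=0.5, c=0.5).validate(gamma=2.1)
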