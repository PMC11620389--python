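"""Compartment model: closed forms, ODE agreement, threshold behavior."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lexepi.model_core import (
    ModelParams,
    ModelState,
    equilibrium_user_fraction,
    herd_immunity_threshold,
    intrinsic_growth_rate,
    logistic_solution,
    r0_from_params,
    simulate_ode,
    thresholds_from_params,
)


class TestParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(beta=0, gamma=0, mu=1),
            dict(beta=-1, gamma=0, mu=1),
            dict(beta=1, gamma=-0.1, mu=1),
            dict(beta=1, gamma=0, mu=0),
            dict(beta=float("inf"), gamma=0, mu=1),
        ],
    )
    def test_invalid_rates_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ModelParams(**kwargs)

    def test_state_conservation_enforced(self):
        with pytest.raises(ValueError):
            ModelState(u=0.5, n=0.6, t=0.0)


class TestR0:
    @pytest.mark.parametrize(
        "beta, gamma, mu, expected",
        [(4, 0, 1, 4.0), (1, 0, 1, 1.0), (0.1, 0.5, 0.5, 0.1), (6, 0.5, 0.5, 6.0)],
    )
    def test_ratio(self, beta, gamma, mu, expected):
        assert r0_from_params(ModelParams(beta, gamma, mu)) == pytest.approx(expected)


class TestEquilibrium:
    def test_supercritical_matches_long_time_ode(self):
        params = ModelParams(beta=4, gamma=0, mu=1)
        u_star = equilibrium_user_fraction(params)
        assert u_star == pytest.approx(0.75)
        states = simulate_ode(params, u0=0.1, t_grid=np.linspace(0, 50, 20))
        assert states[-1].u == pytest.approx(u_star, abs=1e-6)

    @pytest.mark.parametrize("beta", [1.0, 0.1])
    def test_at_or_below_criticality_clamps_to_zero(self, beta):
        assert equilibrium_user_fraction(ModelParams(beta, 0, 1)) == 0.0


class TestSimulateOde:
    def test_starts_at_equilibrium_stays_constant(self):
        params = ModelParams(beta=4, gamma=0, mu=1)
        states = simulate_ode(params, u0=0.75, t_grid=np.linspace(0, 10, 11))
        assert all(s.u == pytest.approx(0.75, abs=1e-7) for s in states)

    def test_word_free_state_is_absorbing(self):
        states = simulate_ode(ModelParams(4, 0, 1), u0=0.0, t_grid=np.linspace(0, 10, 5))
        assert all(s.u == 0.0 for s in states)

    def test_conservation_along_solution(self):
        states = simulate_ode(ModelParams(3, 0.2, 0.5), 0.3, np.linspace(0, 20, 50))
        assert all(abs(s.u + s.n - 1) <= 1e-9 for s in states)

    def test_nonmonotone_grid_rejected(self):
        with pytest.raises(ValueError):
            simulate_ode(ModelParams(4, 0, 1), 0.5, np.array([0.0, 2.0, 1.0]))


class TestLogisticSolution:
    def test_initial_condition(self):
        assert logistic_solution(0.25, 0.75, 3.0, 0.0) == pytest.approx(0.25)

    @pytest.mark.parametrize("r", [-1.0, 0.0, 2.0])
    @pytest.mark.parametrize("t", [0.0, 1.5, 10.0])
    def test_equilibrium_is_fixed_point(self, r, t):
        assert logistic_solution(0.5, 0.5, r, t) == pytest.approx(0.5)

    def test_matches_ode_at_t5(self):
        # beta=4, gamma+mu=1 -> u_star=0.75, r=3
        closed = logistic_solution(0.25, 0.75, 3.0, 5.0)
        states = simulate_ode(ModelParams(4, 0, 1), 0.25, np.array([0.0, 5.0]))
        assert closed == pytest.approx(states[-1].u, rel=1e-6)

    def test_zero_start_rejected(self):
        with pytest.raises(ValueError):
            logistic_solution(0.0, 0.75, 3.0, 1.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        r0=st.floats(1.1, 20),
        mu=st.floats(0.05, 1.0),
        u0_frac=st.floats(0.01, 0.99),
        gamma=st.floats(0, 0.5),
    )
    def test_closed_form_equals_ode(self, r0, mu, u0_frac, gamma):
        """Analytic logistic solution tracks the numerical ODE solution."""
        params = ModelParams(beta=r0 * (gamma + mu), gamma=gamma, mu=mu)
        u_star = equilibrium_user_fraction(params)
        r = intrinsic_growth_rate(params)
        u0 = u0_frac * u_star
        t_grid = np.linspace(0, 30 / max(abs(r), 0.1), 12)
        states = simulate_ode(params, u0, t_grid, rtol=1e-11, atol=1e-12)
        closed = logistic_solution(u0, u_star, r, t_grid)
        ode = np.array([s.u for s in states])
        assert np.allclose(closed, ode, rtol=1e-6, atol=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(r0=st.floats(1.2, 15), below=st.booleans())
    def test_monotone_approach_to_equilibrium(self, r0, below):
        """Starting below (above) the carrying capacity the solution rises
        (falls) strictly toward it."""
        u_star = 1 - 1 / r0
        u0 = 0.2 * u_star if below else min(0.99, 1.6 * u_star)
        r = (r0 - 1) * 0.2
        t = np.linspace(0, 20 / r, 30)
        u = logistic_solution(u0, u_star, r, t)
        diffs = np.diff(u)
        assert np.all(diffs > 0) if below else np.all(diffs < 0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(r0=st.floats(0.2, 5), mu=st.floats(0.1, 1.0))
    def test_threshold_dichotomy(self, r0, mu):
        """Subcritical items die out; supercritical ones settle at 1 - 1/R0."""
        if abs(r0 - 1) < 0.05:
            return  # neighbourhood of criticality: arbitrarily slow dynamics
        params = ModelParams(beta=r0 * mu, gamma=0, mu=mu)
        r = intrinsic_growth_rate(params)
        t_end = 50 / abs(r)
        states = simulate_ode(params, 0.2, np.array([0.0, t_end]))
        target = 0.0 if r0 < 1 else 1 - 1 / r0
        assert states[-1].u == pytest.approx(target, abs=1e-4)


class TestHerdImmunity:
    @pytest.mark.parametrize(
        "r0, expected", [(6, 5 / 6), (1, 0.0), (2, 0.5), (0.5, 0.0), (17, 16 / 17)]
    )
    def test_threshold(self, r0, expected):
        assert herd_immunity_threshold(r0) == pytest.approx(expected)

    def test_nonpositive_r0_rejected(self):
        with pytest.raises(ValueError):
            herd_immunity_threshold(0.0)

    def test_threshold_equals_equilibrium_prevalence(self):
        th = thresholds_from_params(ModelParams(4, 0, 1))
        assert th.h == pytest.approx(th.u_star)
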