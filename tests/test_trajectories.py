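"""Trajectory reconstruction, trend/stability statistics, logistic fit."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from lexepi.trajectories import (
    Trajectory,
    fit_logistic,
    normalize_frequency,
    prevalence_trajectory,
    reconstruct_and_filter,
    spearman_increase_test,
    stability,
)


def _traj(values, times=None, kind="frequency", item_id="w"):
    values = np.asarray(values, dtype=float)
    if times is None:
        times = np.arange(len(values), dtype=float)
    return Trajectory(item_id, times, values, kind=kind)


def _avg_ranks(x):
    """Independent average-rank oracle (sorting-based, handles ties)."""
    x = np.asarray(x, dtype=float)
    order = np.argsort(x, kind="stable")
    ranks = np.empty(len(x))
    i = 0
    pos = 1
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        avg = (pos + pos + (j - i)) / 2
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        pos += j - i + 1
        i = j + 1
    return ranks


def _brute_spearman(t, v):
    """Pearson correlation of average ranks, computed from scratch."""
    rt, rv = _avg_ranks(t), _avg_ranks(v)
    rt = rt - rt.mean()
    rv = rv - rv.mean()
    return float(rt @ rv / np.sqrt((rt @ rt) * (rv @ rv)))


class TestNormalize:
    @pytest.mark.parametrize(
        "values, expected",
        [([1, 2, 4], [0.25, 0.5, 1.0]), ([5, 5, 5], [1, 1, 1]), ([0.25, 0.5, 1.0], [0.25, 0.5, 1.0])],
    )
    def test_examples(self, values, expected):
        out = normalize_frequency(_traj(values))
        np.testing.assert_allclose(out.values, expected)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            normalize_frequency(_traj([0, 0, 0]))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(scale=st.floats(1e-8, 1e6), seed=st.integers(0, 10_000))
    def test_scale_invariance(self, scale, seed):
        rng = np.random.default_rng(seed)
        v = rng.uniform(0.1, 5.0, 8)
        a = normalize_frequency(_traj(v))
        b = normalize_frequency(_traj(scale * v))
        np.testing.assert_allclose(a.values, b.values, rtol=1e-12)


class TestPrevalenceTrajectory:
    def test_scaling(self):
        out = prevalence_trajectory(_traj([0.25, 0.5, 1.0]), p_u=0.4)
        np.testing.assert_allclose(out.values, [0.1, 0.2, 0.4])
        assert out.kind == "prevalence"

    @pytest.mark.parametrize("p_u", [0.0, 1.0, -0.2])
    def test_degenerate_prevalence_rejected(self, p_u):
        with pytest.raises(ValueError):
            prevalence_trajectory(_traj([1, 2, 3]), p_u)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(p_u=st.floats(0.01, 0.94), seed=st.integers(0, 1000))
    def test_peak_equals_survey_prevalence(self, p_u, seed):
        rng = np.random.default_rng(seed)
        out = prevalence_trajectory(_traj(rng.uniform(0.1, 3.0, 10)), p_u)
        assert np.max(out.values) == pytest.approx(p_u)


class TestSpearmanIncrease:
    def test_perfect_increase(self):
        rho, p, sig = spearman_increase_test(_traj(np.arange(10) + 1.0))
        assert rho == pytest.approx(1.0)
        assert sig

    def test_decrease_is_not_an_increase(self):
        rho, p, sig = spearman_increase_test(_traj(np.arange(10, 0, -1.0)))
        assert rho == pytest.approx(-1.0)
        assert not sig

    def test_constant_series_convention(self):
        assert spearman_increase_test(_traj([2, 2, 2, 2.0])) == (0.0, 1.0, False)

    def test_rho_matches_rank_oracle_over_all_orderings(self):
        """rho agrees with a from-scratch rank correlation for every
        permutation of a small series, including tied values."""
        t = np.arange(5, dtype=float)
        for base in ([1.0, 2.0, 3.0, 4.0, 5.0], [1.0, 1.0, 2.0, 3.0, 3.0]):
            for perm in set(itertools.permutations(base)):
                v = np.array(perm)
                if np.ptp(v) == 0:
                    continue
                rho, _, _ = spearman_increase_test(_traj(v, t))
                assert rho == pytest.approx(_brute_spearman(t, v), abs=1e-12)


class TestStability:
    def test_linear_increase_in_window_gives_zero(self):
        traj = _traj(np.arange(11.0), times=np.arange(1950, 2005, 5.0))
        assert stability(traj).s == pytest.approx(0.0)

    def test_constant_series_is_maximally_stable(self):
        traj = _traj([3, 3, 3, 3, 3.0], times=np.arange(1950, 2000, 10.0))
        assert stability(traj).s == pytest.approx(1.0)

    def test_matches_brute_force_rho(self):
        times = np.arange(1950, 2001, 10.0)
        values = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 6.0])
        score = stability(_traj(values, times))
        assert score.rho_abs == pytest.approx(abs(_brute_spearman(times, values)))
        assert score.s == pytest.approx(1 - score.rho_abs)

    def test_only_window_points_used(self):
        times = np.array([1800.0, 1900.0, 1950.0, 1970.0, 1990.0])
        inside = stability(_traj([9, 0.5, 1, 2, 3.0], times))
        assert inside.s == pytest.approx(0.0)  # increasing inside the window

    def test_too_few_points_in_window(self):
        with pytest.raises(ValueError):
            stability(_traj([1, 2, 3.0], times=np.array([1700.0, 1800.0, 1960.0])))


class TestFitLogistic:
    def test_recovers_generating_parameters(self):
        times = np.arange(1820, 2001, 10.0)
        tau = times - times[0]
        u = 0.8 / (1 + 9 * np.exp(-0.05 * tau))
        fit = fit_logistic(_traj(u, times, kind="prevalence"))
        assert fit.converged
        assert fit.a == pytest.approx(0.8, rel=1e-2)
        assert fit.b == pytest.approx(9.0, rel=1e-2)
        assert fit.r == pytest.approx(0.05, rel=1e-2)
        assert fit.r2 >= 0.9999

    def test_perfect_fit_r2_is_one(self):
        times = np.arange(1900, 2001, 10.0)
        u = 0.6 / (1 + 4 * np.exp(-0.08 * (times - 1900)))
        fit = fit_logistic(_traj(u, times, kind="prevalence"))
        assert fit.r2 == pytest.approx(1.0, abs=1e-9)

    def test_constant_series_not_identifiable(self):
        fit = fit_logistic(_traj([0.3] * 8, np.arange(8.0), kind="prevalence"))
        assert not fit.converged

    def test_inflection_point_is_half_capacity_crossing(self):
        times = np.arange(1820, 2001, 10.0)
        u = 0.7 / (1 + 50 * np.exp(-0.06 * (times - times[0])))
        fit = fit_logistic(_traj(u, times, kind="prevalence"))
        crossing = brentq(lambda t: fit.predict(t) - fit.a / 2, 1820, 2000)
        assert abs(fit.t_infl - crossing) < 0.1

    def test_declining_trajectory_gets_negative_rate(self):
        times = np.arange(1820, 2001, 10.0)
        u = 0.5 / (1 + 0.2 * np.exp(0.04 * (times - times[0])))
        fit = fit_logistic(_traj(u, times, kind="prevalence"))
        assert fit.converged and fit.r < 0


class TestReconstructAndFilter:
    def test_fixture_exclusion_reasons(self, worked_example):
        norms = {
            row.item_id: row.prevalence for row in worked_example.norms.itertuples()
        }
        out = reconstruct_and_filter(
            worked_example.trajectories, norms, stability_window=(0.0, 4.0)
        )
        assert out["core"].reason == "core_lexicon"
        assert out["declining"].reason == "no_significant_increase"
        assert out["stable"].reason == "no_significant_increase"
        assert out["growing"].included

    def test_missing_trajectory_reason(self):
        out = reconstruct_and_filter({}, {"w": 0.5})
        assert out["w"].reason == "no_trajectory"

    def test_every_item_reported_once(self, small_lexicon):
        norms = {
            row.item_id: row.prevalence for row in small_lexicon.norms.itertuples()
        }
        out = reconstruct_and_filter(small_lexicon.trajectories, norms)
        assert set(out) == set(norms)
        for res in out.values():
            assert res.included == (res.reason is None)

    def test_noise_free_lexicon_passes_exactly_the_growing_items(self):
        from lexepi.synthetic_data import GeneratorConfig, generate_lexicon

        lex = generate_lexicon(
            GeneratorConfig(n_items=100, frac_growing=0.5, seed=5).noise_free()
        )
        norms = {row.item_id: row.prevalence for row in lex.norms.itertuples()}
        out = reconstruct_and_filter(lex.trajectories, norms)
        truth = lex.truth.set_index("item_id")
        for item_id, res in out.items():
            expect = bool(
                truth.loc[item_id, "is_growing"]
                and norms[item_id] < 0.95
            )
            assert res.included == expect, (item_id, res.reason)

    def test_growth_rate_recovery_under_binomial_noise(self):
        """Median relative error of the fitted rate stays below 5% when
        trajectories are observed as binomial proportions at N_p=300."""
        from lexepi.model_core import logistic_solution

        rng = np.random.default_rng(12)
        times = np.arange(1820, 2001, 10.0)
        errs = []
        for _ in range(200):
            u_star = rng.uniform(0.3, 0.9)
            r = rng.uniform(0.04, 0.12)
            mid = rng.uniform(1880, 1960)
            u = u_star / (1 + np.exp(-r * (times - mid)))
            obs = rng.binomial(300, u) / 300
            fit = fit_logistic(_traj(obs, times, kind="prevalence"))
            if fit.converged:
                errs.append((fit.r - r) / r)
        assert abs(float(np.median(errs))) < 0.05
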