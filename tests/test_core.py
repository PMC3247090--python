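"""Core estimator: weights, augmented system, LP solution."""

import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given, settings, strategies as st

from ladafl import (
    AugmentedLADProblem,
    CGHProfile,
    PenaltyWeights,
    TuningParams,
    adaptive_weights,
    build_augmented_problem,
    fit_lad_afl,
    initial_estimates,
    objective,
    solve_lad,
)

from conftest import lad_vertex_oracle


def make_profile(values):
    return CGHProfile(values=np.asarray(values, dtype=float))


class TestInitialEstimates:
    @pytest.mark.parametrize(
        "y, beta0, u0",
        [
            ([1, 1, 3], [1, 1, 3], [1, 0, 2]),
            ([0, 0], [0, 0], [0, 0]),
            ([0.5, -0.5, -0.5, 0], [0.5, -0.5, -0.5, 0], [0.5, -1, 0, 0.5]),
        ],
    )
    def test_marker_wise_lad_and_differences(self, y, beta0, u0):
        b, u = initial_estimates(make_profile(y))
        np.testing.assert_allclose(b, beta0)
        np.testing.assert_allclose(u, u0)


class TestAdaptiveWeights:
    def test_reciprocal_magnitudes(self):
        w = adaptive_weights(np.array([2.0, 0.5]), np.array([2.0, -1.5]))
        np.testing.assert_allclose(w.a, [0.5, 2.0])
        np.testing.assert_allclose(w.b, [0.5, 2.0 / 3.0])

    def test_zero_denominators_map_to_cap(self):
        w = adaptive_weights(np.array([0.0, 1.0]), np.array([0.0, 1.0]), cap=1e6)
        np.testing.assert_allclose(w.a, [1e6, 1.0])
        np.testing.assert_allclose(w.b, [1e6, 1.0])

    def test_first_weights_agree_from_initial_estimates(self):
        # u0_1 = beta0_1 so a_1 = b_1 and the split first-column
        # penalty halves recombine exactly
        b0, u0 = initial_estimates(make_profile([0.7, 0.2, -0.4]))
        w = adaptive_weights(b0, u0)
        assert w.a[0] == w.b[0]

    def test_nonpositive_cap_rejected(self):
        with pytest.raises(ValueError):
            adaptive_weights(np.ones(2), np.ones(2), cap=0.0)

    def test_unit_mode_ignores_data(self):
        w = PenaltyWeights.unit(4)
        np.testing.assert_allclose(w.a, 1.0)
        np.testing.assert_allclose(w.b, 1.0)


class TestAugmentedProblem:
    def test_block_structure_n2(self):
        profile = make_profile([1.0, -1.0])
        weights = PenaltyWeights(a=np.ones(2), b=np.ones(2))
        problem = build_augmented_problem(profile, weights, TuningParams(1.0, 1.0))
        dense = problem.design.toarray()
        np.testing.assert_allclose(dense[:2], np.eye(2))           # data
        np.testing.assert_allclose(dense[2:4], [[0.5, 0], [0, 1]])  # sparsity
        np.testing.assert_allclose(dense[4:], [[0.5, 0], [-1, 1]])  # fusion
        np.testing.assert_allclose(problem.response, [1, -1, 0, 0, 0, 0])
        beta = np.array([1.0, -1.0])
        direct = abs(1 - 1) + abs(-1 + 1) + (1 + 1) + abs(-1 - 1)
        assert problem.l1_residual(beta) == pytest.approx(direct)

    def test_zero_penalties_reduce_to_plain_loss(self):
        profile = make_profile([0.3, -0.2, 0.9])
        weights = PenaltyWeights.unit(3)
        problem = build_augmented_problem(profile, weights, TuningParams(0.0, 0.0))
        assert np.all(problem.design.toarray()[3:] == 0)
        beta = np.array([0.1, 0.1, 0.1])
        assert problem.l1_residual(beta) == pytest.approx(
            np.abs(profile.values - beta).sum()
        )

    @settings(max_examples=60, deadline=None)
    @given(st.integers(min_value=2, max_value=8), st.integers(min_value=0, max_value=2**31 - 1))
    def test_l1_residual_equals_criterion(self, n, seed):
        """The augmented system is an exact rewriting of the criterion."""
        r = np.random.default_rng(seed)
        profile = make_profile(r.normal(0, 1, n))
        weights = PenaltyWeights(a=r.uniform(0.1, 5, n), b=r.uniform(0.1, 5, n))
        tuning = TuningParams(r.uniform(0, 3), r.uniform(0, 3))
        beta = r.normal(0, 1, n)
        # the identity needs a_1 = b_1 (shared split of the beta_1 term)
        weights_matched = PenaltyWeights(
            a=np.concatenate([[weights.b[0]], weights.a[1:]]), b=weights.b
        )
        problem = build_augmented_problem(profile, weights_matched, tuning)
        assert problem.l1_residual(beta) == pytest.approx(
            objective(profile, beta, weights_matched, tuning), abs=1e-10
        )


class TestObjective:
    @pytest.mark.parametrize(
        "y, beta, lam, expected",
        [
            ([1, 1], [1, 1], (0, 0), 0.0),
            ([1, 0], [0, 0], (2, 3), 1.0),
            ([1, 0], [1, 0], (2, 3), 5.0),
        ],
    )
    def test_hand_values(self, y, beta, lam, expected):
        profile = make_profile(y)
        weights = PenaltyWeights.unit(len(y))
        assert objective(
            profile, np.asarray(beta, float), weights, TuningParams(*lam)
        ) == pytest.approx(expected)


class TestSolveLad:
    def test_identity_design_returns_data(self):
        y = np.array([3.0, -1.0, 4.0])
        problem = AugmentedLADProblem(
            response=y.copy(), design=sp.identity(3, format="csr"), n=3
        )
        np.testing.assert_allclose(solve_lad(problem), y, atol=1e-8)

    @pytest.mark.parametrize("lam, expected", [(0.5, 1.0), (2.0, 0.0)])
    def test_soft_threshold_one_dimensional(self, lam, expected):
        """|1 - b| + lam |b| is minimized at 1 (lam < 1) or 0 (lam > 1)."""
        design = sp.csr_matrix(np.array([[1.0], [lam]]))
        problem = AugmentedLADProblem(
            response=np.array([1.0, 0.0]), design=design, n=1
        )
        beta = solve_lad(problem)
        obj = problem.l1_residual(beta)
        assert obj == pytest.approx(abs(1 - expected) + lam * expected, abs=1e-8)

    def test_matches_vertex_oracle_small_instances(self, rng):
        for _ in range(25):
            n = int(rng.integers(2, 5))
            profile = make_profile(rng.normal(0, 1, n))
            weights = adaptive_weights(*initial_estimates(profile))
            tuning = TuningParams(rng.uniform(0, 2), rng.uniform(0, 2))
            problem = build_augmented_problem(profile, weights, tuning)
            beta = solve_lad(problem)
            oracle = lad_vertex_oracle(problem.design.toarray(), problem.response)
            assert problem.l1_residual(beta) == pytest.approx(oracle, abs=1e-6)


class TestFit:
    def test_zero_penalties_return_data_exactly(self, rng):
        profile = make_profile(rng.normal(0, 1, 30))
        fit = fit_lad_afl(profile, TuningParams(0.0, 0.0))
        np.testing.assert_array_equal(fit.beta_hat, profile.values)

    def test_huge_lambda1_returns_zero(self, rng):
        profile = make_profile(rng.normal(0, 0.1, 30))
        fit = fit_lad_afl(profile, TuningParams(1e4, 0.0))
        np.testing.assert_array_equal(fit.beta_hat, 0.0)

    def test_step_signal_single_jump(self, noisy_step_profile):
        fit = fit_lad_afl(noisy_step_profile, TuningParams(0.001, 0.5))
        nonzero_jumps = np.flatnonzero(fit.u_hat[1:]) + 2  # 1-based
        assert list(nonzero_jumps) == [4]

    def test_jumps_are_first_differences(self, noisy_step_profile):
        fit = fit_lad_afl(noisy_step_profile, TuningParams(0.01, 0.3))
        np.testing.assert_array_equal(
            fit.u_hat, np.diff(fit.beta_hat, prepend=0.0)
        )
        assert fit.u_hat[0] == fit.beta_hat[0]

    def test_piecewise_constancy_matches_jump_count(self, rng):
        profile = make_profile(
            np.repeat([0.0, 0.8, 0.0], 10) + rng.normal(0, 0.02, 30)
        )
        fit = fit_lad_afl(profile, TuningParams(0.01, 0.8))
        distinct_runs = 1 + int(np.sum(np.diff(fit.beta_hat) != 0))
        assert distinct_runs == 1 + int(np.sum(fit.u_hat[1:] != 0))

    def test_fitted_objective_no_worse_than_data(self, rng):
        profile = make_profile(rng.normal(0, 0.3, 40))
        weights = adaptive_weights(*initial_estimates(profile))
        tuning = TuningParams(0.05, 0.5)
        fit = fit_lad_afl(profile, tuning, weights=weights)
        assert fit.objective <= objective(
            profile, profile.values, weights, tuning
        ) + 1e-8

    def test_loss_scale_equivariance(self, rng):
        y = rng.normal(0, 1, 12)
        fit1 = fit_lad_afl(make_profile(y), TuningParams(0.0, 0.0))
        fit2 = fit_lad_afl(make_profile(3.0 * y), TuningParams(0.0, 0.0))
        np.testing.assert_allclose(fit2.beta_hat, 3.0 * fit1.beta_hat)
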