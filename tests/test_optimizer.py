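import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import multida as mda
from multida.data import BlockGraph
from multida.optimizer import (
    FitOptions,
    auto_lambda_grid,
    deflate,
    fit,
    fit_rank,
    inner_component,
    normalize_loading,
    objective_value,
    select_lambda_cv,
    ust_update,
)


def soft_threshold_oracle(g, lam):
    """Element-wise proximal minimizer of 0.5*a^2 - g*a + lam*|a|.

    Independent of the sign/positive-part shortcut: enumerate the three
    stationary candidates of the piecewise-quadratic objective and pick
    the one with the smallest objective value.
    """

    def obj(a, gi):
        return 0.5 * a * a - gi * a + lam * abs(a)

    out = np.empty_like(g)
    for i, gi in enumerate(g):
        candidates = [0.0, gi - lam, gi + lam]
        out[i] = min(candidates, key=lambda a: obj(a, gi))
    return out


class TestUstUpdate:
    def test_hand_evaluated_thresholding(self):
        # X'upsilon = [2, -0.5, 1.2] with threshold 1
        X = np.eye(3)
        upsilon = np.array([2.0, -0.5, 1.2])
        np.testing.assert_allclose(ust_update(X, upsilon, 1.0), [1.0, 0.0, 0.2])

    def test_zero_threshold_is_identity_on_gradient(self, rng):
        X = rng.standard_normal((12, 5))
        upsilon = rng.standard_normal(12)
        np.testing.assert_allclose(ust_update(X, upsilon, 0.0), X.T @ upsilon)

    def test_full_shrinkage_gives_zero_vector(self, rng):
        X = rng.standard_normal((12, 5))
        upsilon = rng.standard_normal(12)
        lam = np.abs(X.T @ upsilon).max() + 1.0
        assert not np.any(ust_update(X, upsilon, lam))

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            ust_update(np.eye(2), np.ones(2), -0.1)

    def test_matches_proximal_oracle(self, rng):
        for _ in range(20):
            g = rng.standard_normal(10) * 3
            lam = rng.uniform(0, 2)
            expected = soft_threshold_oracle(g, lam)
            got = ust_update(np.eye(10), g, lam)
            np.testing.assert_allclose(got, expected, atol=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_support_size_nonincreasing_in_threshold(self, seed):
        rng = np.random.default_rng(seed)
        g = rng.standard_normal(15)
        lams = np.sort(rng.uniform(0, 2, size=5))
        sizes = [int(np.count_nonzero(ust_update(np.eye(15), g, l))) for l in lams]
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))


class TestObjectiveValue:
    def test_zero_loadings_give_zero(self, random_multiblock, graph):
        data = random_multiblock(0)
        loadings = [np.zeros(b.shape[1]) for b in data.blocks]
        assert objective_value(data, graph, loadings) == 0.0

    def test_two_identical_blocks_reach_n_squared_per_ordered_pair(self):
        # chi_1 alpha_1 = chi_2 alpha_2 with ||v||^2 = N gives
        # d * (v'v)^2 = N^2 for each of the two ordered pairs
        rng = np.random.default_rng(3)
        n = 16
        v = rng.standard_normal(n)
        v *= np.sqrt(n) / np.linalg.norm(v)
        data = mda.MultiblockData(
            blocks=[v[:, None], v[:, None]],
            sample_ids=[str(i) for i in range(n)],
            feature_names=[["a"], ["b"]],
            block_names=["A", "B"],
        )
        g = BlockGraph(C=np.array([[0, 1], [1, 0]]), D=np.array([[0, 1], [1, 0]]))
        obj = objective_value(data, g, [np.ones(1), np.ones(1)])
        np.testing.assert_allclose(obj, 2 * n**2)

    def test_matches_brute_force_triple_loop(self, random_multiblock, graph):
        data = random_multiblock(7, n=8, widths=(3, 3, 3, 3))
        rng = np.random.default_rng(5)
        loadings = [rng.standard_normal(b.shape[1]) for b in data.blocks]
        expected = 0.0
        for j in range(5):
            for k in range(5):
                if j == k:
                    continue
                cov = loadings[j] @ data.blocks[j].T @ data.blocks[k] @ loadings[k]
                expected += graph.D[j, k] * cov**2
        got = objective_value(data, graph, loadings)
        np.testing.assert_allclose(got, expected, rtol=1e-10)


class TestInnerComponent:
    def test_unconnected_block_gets_zero_vector(self, random_multiblock):
        data = random_multiblock(1)
        C = np.zeros((5, 5))
        C[0, 1] = C[1, 0] = 1  # block 3 (index 2) unconnected
        g = BlockGraph(C=C, D=C)
        rng = np.random.default_rng(0)
        loadings = [rng.standard_normal(b.shape[1]) for b in data.blocks]
        np.testing.assert_array_equal(
            inner_component(2, data, g, loadings), np.zeros(data.n_samples)
        )

    def test_single_neighbour_is_scaled_latent(self, random_multiblock):
        data = random_multiblock(2)
        C = np.zeros((5, 5))
        C[0, 1] = C[1, 0] = 1
        g = BlockGraph(C=C, D=C)
        rng = np.random.default_rng(0)
        loadings = [rng.standard_normal(b.shape[1]) for b in data.blocks]
        v0 = data.blocks[0] @ loadings[0]
        v1 = data.blocks[1] @ loadings[1]
        expected = (v0 @ v1) * v1
        np.testing.assert_allclose(inner_component(0, data, g, loadings), expected)

    def test_matches_naive_loop_accumulation(self, random_multiblock, graph):
        data = random_multiblock(3, n=6)
        rng = np.random.default_rng(9)
        loadings = [rng.standard_normal(b.shape[1]) for b in data.blocks]
        scores = [b @ a for b, a in zip(data.blocks, loadings)]
        j = 3  # the expression block has three neighbours plus the class
        expected = np.zeros(6)
        for k in range(5):
            if k != j and graph.D[j, k] != 0:
                expected += graph.D[j, k] * (scores[j] @ scores[k]) * scores[k]
        np.testing.assert_allclose(
            inner_component(j, data, graph, loadings), expected, rtol=1e-10
        )


class TestNormalizeLoading:
    def test_latent_norm_contract(self, rng):
        chi = rng.standard_normal((30, 6))
        alpha = rng.standard_normal(6)
        out, degenerate = normalize_loading(alpha, chi)
        assert not degenerate
        np.testing.assert_allclose(np.linalg.norm(chi @ out) ** 2, 30.0, atol=1e-8)

    def test_scale_invariance(self, rng):
        chi = rng.standard_normal((30, 6))
        alpha = rng.standard_normal(6)
        out1, _ = normalize_loading(alpha, chi)
        out2, _ = normalize_loading(7.0 * alpha, chi)
        np.testing.assert_allclose(out1, out2, atol=1e-12)

    def test_zero_loading_flagged_not_divided(self):
        out, degenerate = normalize_loading(np.zeros(4), np.ones((5, 4)))
        assert degenerate
        np.testing.assert_array_equal(out, np.zeros(4))

    def test_unit_convention(self, rng):
        chi = rng.standard_normal((30, 6))
        out, _ = normalize_loading(rng.standard_normal(6), chi, convention="unit")
        np.testing.assert_allclose(np.linalg.norm(chi @ out), 1.0, atol=1e-10)

    def test_sparsity_pattern_unchanged(self, rng):
        chi = rng.standard_normal((20, 5))
        alpha = np.array([0.0, 2.0, 0.0, -1.0, 0.0])
        out, _ = normalize_loading(alpha, chi)
        np.testing.assert_array_equal(out == 0, alpha == 0)


class TestSelectLambdaCV:
    def test_single_element_grid_returned(self, rng):
        X = rng.standard_normal((20, 4))
        lam = select_lambda_cv(X, rng.standard_normal(20), 5, [0.37], rng)
        assert lam == 0.37

    def test_empty_grid_rejected(self, rng):
        with pytest.raises(ValueError):
            select_lambda_cv(np.eye(4), np.ones(4), 2, [], rng)

    def test_identical_errors_break_toward_larger(self, rng):
        # a zero target makes every candidate predict zero identically
        X = rng.standard_normal((20, 4))
        lam = select_lambda_cv(X, np.zeros(20), 5, [0.1, 0.5, 0.9], rng)
        assert lam == 0.9

    def test_noise_free_recovery_keeps_true_columns(self, rng):
        # columns with disjoint row support are orthogonal on every fold
        n, p = 40, 4
        X = np.zeros((n, p))
        for j in range(p):
            X[j * 10 : (j + 1) * 10, j] = rng.standard_normal(10)
        beta = np.array([2.0, -1.5, 1.0, 0.5])
        upsilon = X @ beta
        lam = select_lambda_cv(X, upsilon, 5, auto_lambda_grid(), rng)
        coef = ust_update(X, upsilon, lam * np.abs(X.T @ upsilon).max())
        assert np.all(coef != 0), "all true columns must be retained"
        assert lam == 0.0  # zero held-out error only without shrinkage bias


class TestFitRank:
    def test_collinear_blocks_reach_analytic_maximum(self):
        # X2 = X1 and no shrinkage: the squared covariance attains its
        # Cauchy-Schwarz bound N^2 per ordered pair
        rng = np.random.default_rng(8)
        n = 24
        X = rng.standard_normal((n, 4))
        X -= X.mean(axis=0)
        data = mda.MultiblockData(
            blocks=[X, X.copy()],
            sample_ids=[str(i) for i in range(n)],
            feature_names=[[f"a{i}" for i in range(4)], [f"b{i}" for i in range(4)]],
            block_names=["A", "B"],
        )
        g = BlockGraph(C=np.array([[0, 1], [1, 0]]), D=np.array([[0, 1], [1, 0]]))
        options = FitOptions(seed=1, discriminant=False, lambda_grid=[0.0], max_iter=200)
        result = fit_rank(data, g, options, np.random.default_rng(1))
        np.testing.assert_allclose(result.trace[-1], 2 * n**2, rtol=1e-6)

    def test_infinite_tolerance_performs_one_sweep(self, small_dataset, graph):
        data, _ = small_dataset
        options = FitOptions(seed=3, tol=np.inf)
        result = fit_rank(data, graph, options, np.random.default_rng(3))
        assert result.n_sweeps == 1
        assert len(result.trace) == 1

    def test_seeded_runs_are_bit_identical(self, small_dataset, graph):
        data, _ = small_dataset
        options = FitOptions(seed=5)
        r1 = fit_rank(data, graph, options, np.random.default_rng(5))
        r2 = fit_rank(data, graph, options, np.random.default_rng(5))
        for a, b in zip(r1.loadings, r2.loadings):
            np.testing.assert_array_equal(a, b)

    def test_objective_trace_non_decreasing(self, random_multiblock, graph):
        for seed in range(5):
            data = random_multiblock(seed + 100)
            options = FitOptions(seed=seed)
            result = fit_rank(data, graph, options, np.random.default_rng(seed))
            diffs = np.diff(result.trace)
            assert np.all(diffs >= -1e-9), f"seed {seed}: trace decreased"

    def test_normalization_holds_for_fitted_loadings(self, small_dataset, graph):
        data, _ = small_dataset
        result = fit_rank(data, graph, FitOptions(seed=2), np.random.default_rng(2))
        for j, (alpha, score) in enumerate(zip(result.loadings, result.scores)):
            if np.any(alpha):
                np.testing.assert_allclose(
                    np.linalg.norm(score) ** 2, data.n_samples, atol=1e-8
                )


class TestDeflate:
    def test_deflated_columns_orthogonal_to_score(self, small_dataset, graph):
        data, _ = small_dataset
        rank = fit_rank(data, graph, FitOptions(seed=4), np.random.default_rng(4))
        out = deflate(data, rank)
        for j in range(data.n_blocks - 1):
            v = data.blocks[j] @ rank.loadings[j]
            if np.any(rank.loadings[j]):
                assert np.abs(v @ out.blocks[j]).max() < 1e-8

    def test_idempotent_projection(self, rng):
        data = mda.prepare([rng.standard_normal((20, 5))], [0, 1] * 10)
        alpha = rng.standard_normal(5)
        once = deflate(data, [alpha, np.zeros(1)])
        twice = deflate(once, [alpha, np.zeros(1)])
        # deflating again with the same original score leaves it unchanged
        np.testing.assert_allclose(once.blocks[0], twice.blocks[0], atol=1e-10)

    def test_rank_one_block_becomes_zero(self, rng):
        base = rng.standard_normal(20)
        X = np.outer(base, rng.standard_normal(4))  # all columns proportional
        X -= X.mean(axis=0)
        data = mda.MultiblockData(
            blocks=[X, np.ones((20, 1))],
            sample_ids=[str(i) for i in range(20)],
            feature_names=[["a", "b", "c", "d"], ["y"]],
            block_names=["A", "CLASS"],
        )
        out = deflate(data, [np.array([1.0, 0, 0, 0]), np.zeros(1)])
        assert np.abs(out.blocks[0]).max() < 1e-8

    def test_zero_loading_passes_block_through(self, small_dataset):
        data, _ = small_dataset
        out = deflate(data, [np.zeros(b.shape[1]) for b in data.blocks])
        for a, b in zip(data.blocks, out.blocks):
            np.testing.assert_array_equal(a, b)


class TestFit:
    def test_single_rank_equals_fit_rank(self, small_dataset, graph):
        data, _ = small_dataset
        options = FitOptions(seed=6, n_ranks=1)
        full = fit(data, graph, options)
        single = fit_rank(data, graph, options, np.random.default_rng(6))
        assert full.n_ranks == 1
        for a, b in zip(full.loadings[0], single.loadings):
            np.testing.assert_array_equal(a, b)

    def test_full_shrinkage_stops_with_zero_effective_ranks(self, random_multiblock, graph):
        data = random_multiblock(55)
        options = FitOptions(seed=1, lambda_grid=[1.5])  # threshold above max|g|
        result = fit(data, graph, options)
        assert result.n_ranks == 0

    def test_reduction_to_sgcca_with_slack_off_and_binary_weights(
        self, small_dataset, graph
    ):
        data, _ = small_dataset
        binary = BlockGraph(C=graph.C, D=graph.C)
        a = fit(data, binary, FitOptions(seed=9, discriminant=False))
        b = fit(data, binary, FitOptions(seed=9, sgcca_mode=True))
        assert a.n_ranks == b.n_ranks
        for r in range(a.n_ranks):
            for x, y in zip(a.loadings[r], b.loadings[r]):
                np.testing.assert_allclose(x, y, atol=1e-10)

    def test_frozen_slack_keeps_margins_at_zero(self, small_dataset, graph):
        data, _ = small_dataset
        result = fit(data, graph, FitOptions(seed=9, freeze_slack_at_zero=True))
        for slack in result.slacks:
            assert slack is not None
            np.testing.assert_array_equal(slack.m, 0.0)

    def test_loading_set_serialization_shapes(self, small_dataset, graph):
        data, _ = small_dataset
        result = fit(data, graph, FitOptions(seed=10, n_ranks=2))
        assert result.n_blocks == 5
        for j in range(5):
            assert result.block_loadings(j).shape == (
                result.n_ranks,
                data.blocks[j].shape[1],
            )


class TestFitOptionsValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_ranks": 0},
            {"tol": 0.0},
            {"cv_folds": 1},
            {"lambda_grid": []},
            {"lambda_grid": [-0.1]},
            {"norm_convention": "bogus"},
        ],
    )
    def test_invalid_options_rejected(self, kwargs):
        with pytest.raises(ValueError):
            FitOptions(**kwargs)

    def test_round_trips_through_dict(self):
        options = FitOptions(seed=4, lambda_grid=[0.1, 0.5], sgcca_mode=True)
        assert FitOptions.from_dict(options.to_dict()) == options
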