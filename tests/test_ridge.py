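"""Banded ridge: closed-form solve, CV folds, two-stage search.

Independent oracles: scipy generic minimisation of the penalised
objective, scikit-learn Ridge for the equal-penalty reduction, ordinary
least squares for the vanishing-penalty limit, and exhaustive grid
search for the single-band hyperparameter problem.
"""

import numpy as np
import pytest
from scipy.optimize import minimize
from sklearn.linear_model import Ridge

from timescales.ridge import (
    HyperparameterSet,
    build_design,
    gradient_refine,
    make_cv_folds,
    random_search,
    solve_banded_ridge,
)
from timescales.stimulus import RunLayout


def toy_problem(rng, n=20, dims=(2, 2), v=3):
    bands = [rng.standard_normal((n, d)) for d in dims]
    design = build_design(bands)
    Y = rng.standard_normal((n, v))
    return design, Y


def hypers_for(design, penalties):
    return HyperparameterSet(
        penalties=np.asarray(penalties, float),
        groups=design.reg_groups,
        group_names=design.reg_group_names,
    )


class TestSolve:
    def test_equal_penalties_match_standard_ridge(self, rng):
        design, Y = toy_problem(rng, n=30, dims=(3, 4), v=2)
        lam = 2.5
        model = solve_banded_ridge(design.F, Y, hypers_for(design, [lam, lam]))
        oracle = Ridge(alpha=lam, fit_intercept=False).fit(design.F, Y)
        np.testing.assert_allclose(model.weights, oracle.coef_, atol=1e-10)

    def test_vanishing_penalty_recovers_ols(self, rng):
        design, Y = toy_problem(rng, n=50, dims=(2, 3), v=2)
        model = solve_banded_ridge(design.F, Y, hypers_for(design, [1e-12, 1e-12]))
        ols, *_ = np.linalg.lstsq(design.F, Y, rcond=None)
        np.testing.assert_allclose(model.weights, ols.T, atol=1e-6)

    def test_matches_generic_numerical_minimiser(self, rng):
        design, Y = toy_problem(rng, n=20, dims=(2, 2), v=1)
        penalties = np.array([1.0, 100.0])
        model = solve_banded_ridge(design.F, Y, hypers_for(design, penalties))
        col_pen = np.concatenate([np.full(2, 1.0), np.full(2, 100.0)])

        def objective(w):
            resid = Y[:, 0] - design.F @ w
            return resid @ resid + (col_pen * w**2).sum()

        res = minimize(objective, np.zeros(4), method="BFGS", tol=1e-14)
        np.testing.assert_allclose(model.weights[0], res.x, atol=1e-6)

    def test_per_voxel_penalties_differ(self, rng):
        design, Y = toy_problem(rng, n=30, dims=(2, 2), v=2)
        pen = np.array([[0.1, 10.0], [10.0, 0.1]])
        model = solve_banded_ridge(design.F, Y, hypers_for(design, pen))
        single0 = solve_banded_ridge(design.F, Y[:, :1], hypers_for(design, pen[0]))
        np.testing.assert_allclose(model.weights[0], single0.weights[0], atol=1e-12)

    def test_dual_path_matches_primal(self, rng):
        # wide problem (D > n) exercises the kernel formulation
        design, Y = toy_problem(rng, n=15, dims=(10, 12), v=2)
        pen = [3.0, 0.7]
        model = solve_banded_ridge(design.F, Y, hypers_for(design, pen))
        col_pen = np.concatenate([np.full(10, 3.0), np.full(12, 0.7)])
        direct = np.linalg.solve(
            design.F.T @ design.F + np.diag(col_pen), design.F.T @ Y
        )
        np.testing.assert_allclose(model.weights, direct.T, atol=1e-8)

    def test_scaling_covariance(self, rng):
        """Scaling one band by s and its penalty by s^2 fixes predictions."""
        design, Y = toy_problem(rng, n=25, dims=(2, 3), v=2)
        s = 7.0
        model1 = solve_banded_ridge(design.F, Y, hypers_for(design, [2.0, 5.0]))
        F2 = design.F.copy()
        F2[:, :2] *= s
        model2 = solve_banded_ridge(F2, Y, hypers_for(design, [2.0 * s**2, 5.0]))
        np.testing.assert_allclose(F2 @ model2.weights.T, design.F @ model1.weights.T,
                                   atol=1e-8)

    def test_nonfinite_inputs_rejected(self, rng):
        design, Y = toy_problem(rng)
        Y[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            solve_banded_ridge(design.F, Y, hypers_for(design, [1.0, 1.0]))

    def test_nonpositive_penalty_rejected(self, rng):
        design, _ = toy_problem(rng)
        with pytest.raises(ValueError, match="positive"):
            hypers_for(design, [1.0, 0.0])


class TestFolds:
    def test_ten_runs_give_ten_single_run_folds(self):
        layout = RunLayout((50,) * 10, 50, tr=2.0, trim_count=5)
        folds = make_cv_folds(layout)
        assert len(folds) == 10
        lengths = layout.trimmed_lengths(layout.train_run_lengths)
        assert all(len(val) == lengths[i] for i, (_, val) in enumerate(folds))

    def test_folds_partition_the_time_axis(self):
        layout = RunLayout((40, 40, 40), 40, tr=2.0, trim_count=5)
        folds = make_cv_folds(layout, n_folds=3)
        vals = np.concatenate([val for _, val in folds])
        assert np.array_equal(np.sort(vals), np.arange(90))
        for train, val in folds:
            assert np.intersect1d(train, val).size == 0

    def test_more_folds_than_runs_rejected(self):
        layout = RunLayout((40, 40), 40, tr=2.0, trim_count=5)
        with pytest.raises(ValueError, match="folds"):
            make_cv_folds(layout, n_folds=5)


def cv_loss_for_penalty(F, Y, folds, lam):
    """Exhaustive oracle: summed validation SSE of plain ridge at lam."""
    loss = np.zeros(Y.shape[1])
    for train, val in folds:
        W = np.linalg.solve(
            F[train].T @ F[train] + lam * np.eye(F.shape[1]), F[train].T @ Y[train]
        )
        loss += ((F[val] @ W - Y[val]) ** 2).sum(axis=0)
    return loss


@pytest.fixture()
def search_problem(rng):
    layout = RunLayout((30, 30, 30), 30, tr=2.0, trim_count=5)
    folds = make_cv_folds(layout)
    n = sum(layout.trimmed_lengths(layout.train_run_lengths))
    F = rng.standard_normal((n, 4))
    W_true = rng.standard_normal((4, 3))
    Y = F @ W_true + 0.5 * rng.standard_normal((n, 3))
    return layout, folds, F, Y


class TestRandomSearch:
    def test_single_band_matches_exhaustive_grid(self, search_problem):
        _, folds, F, Y = search_problem
        groups = [np.arange(4)]
        hypers = random_search(F, Y, groups, folds, n_candidates=5, n_scales=10, seed=0)
        scales = np.geomspace(1e-5, 1e5, 10)
        grid_losses = np.stack([cv_loss_for_penalty(F, Y, folds, lam) for lam in scales])
        best = scales[grid_losses.argmin(axis=0)]
        np.testing.assert_allclose(hypers.penalties[:, 0], best, rtol=1e-8)
        np.testing.assert_allclose(hypers.cv_loss, grid_losses.min(axis=0), rtol=1e-8)

    def test_deterministic_under_seed(self, search_problem):
        _, folds, F, Y = search_problem
        groups = [np.arange(2), np.arange(2, 4)]
        a = random_search(F, Y, groups, folds, n_candidates=20, seed=3)
        b = random_search(F, Y, groups, folds, n_candidates=20, seed=3)
        np.testing.assert_array_equal(a.penalties, b.penalties)

    def test_null_response_loss_bounded_by_variance(self, search_problem, rng):
        _, folds, F, _ = search_problem
        Y = rng.standard_normal((F.shape[0], 4))  # independent of features
        groups = [np.arange(2), np.arange(2, 4)]
        hypers = random_search(F, Y, groups, folds, n_candidates=50, seed=1)
        total_ss = (Y**2).sum(axis=0)
        # CV loss cannot be much below the (uncentred) variance of Y
        assert np.all(hypers.cv_loss >= 0.8 * total_ss)

    def test_invalid_scale_range_rejected(self, search_problem):
        _, folds, F, Y = search_problem
        with pytest.raises(ValueError, match="scale_range"):
            random_search(F, Y, [np.arange(4)], folds, scale_range=(0.0, 1.0))


class TestGradientRefine:
    def test_refined_loss_never_worse(self, search_problem):
        _, folds, F, Y = search_problem
        groups = [np.arange(2), np.arange(2, 4)]
        stage1 = random_search(F, Y, groups, folds, n_candidates=15, seed=2)
        stage2 = gradient_refine(F, Y, groups, folds, stage1, top_frac=1.0, n_iter=50)
        assert np.all(stage2.cv_loss <= stage1.cv_loss + 1e-12)
        assert stage2.stage == "gradient_refine"

    def test_stationary_at_dense_grid_optimum(self, search_problem):
        """Refinement from a dense 1-D optimum barely moves the loss."""
        _, folds, F, Y = search_problem
        groups = [np.arange(4)]
        lams = np.geomspace(1e-4, 1e4, 200)
        losses = np.stack([cv_loss_for_penalty(F, Y, folds, lam) for lam in lams])
        best_lam = lams[losses.argmin(axis=0)]
        start = HyperparameterSet(
            penalties=best_lam[:, None], groups=groups, group_names=["g"],
            cv_loss=losses.min(axis=0),
        )
        refined = gradient_refine(F, Y, groups, folds, start, top_frac=1.0, n_iter=100)
        rel_gain = (start.cv_loss - refined.cv_loss) / start.cv_loss
        assert np.all(rel_gain >= -1e-12)
        assert np.all(rel_gain < 1e-3)

    def test_refined_penalty_near_grid_optimum(self, search_problem):
        """Starting from a coarse grid, refinement lands within 10% of the
        dense-grid CV optimum of a single-penalty problem."""
        _, folds, F, Y = search_problem
        groups = [np.arange(4)]
        stage1 = random_search(F, Y, groups, folds, n_candidates=1, n_scales=4,
                               scale_range=(1e-3, 1e3), seed=0)
        refined = gradient_refine(F, Y, groups, folds, stage1, top_frac=1.0, n_iter=300)
        lams = np.geomspace(1e-4, 1e4, 2000)
        losses = np.stack([cv_loss_for_penalty(F, Y, folds, lam) for lam in lams])
        for vox in range(Y.shape[1]):
            dense_best_loss = losses[:, vox].min()
            assert refined.cv_loss[vox] <= dense_best_loss * 1.10

    def test_untouched_voxels_keep_stage1_penalties(self, search_problem):
        _, folds, F, Y = search_problem
        groups = [np.arange(2), np.arange(2, 4)]
        stage1 = random_search(F, Y, groups, folds, n_candidates=10, seed=5)
        stage2 = gradient_refine(F, Y, groups, folds, stage1, top_frac=0.34, n_iter=20)
        worst = np.argsort(stage1.cv_loss)[-1]
        np.testing.assert_array_equal(stage2.penalties[worst], stage1.penalties[worst])
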