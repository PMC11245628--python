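"""Banded ridge regression with two-stage hyperparameter search.

The encoding model maps a concatenated design F' (n x D, several feature
spaces side by side) to voxel responses Y (n x v).  Unlike standard
ridge, banded ridge assigns one regularization hyperparameter per
feature-space group (and per voxel), minimising

    ||Y - F'B||^2 + sum_g pen_g ||B_g||^2 ,

which prevents feature spaces with different scales or dimensionalities
from biasing each other's weights.  With per-group penalties ``pen_g``
the problem reduces to standard ridge on a column-rescaled design:
scaling group g's columns by ``1/sqrt(pen_g)`` and solving ridge with
unit penalty gives the banded solution after unscaling.

Hyperparameters are selected per voxel by leave-one-run-out
cross-validation in two stages: (1) random search over simplex-sampled
group weightings (Dirichlet) crossed with log-spaced overall scales;
(2) backtracking gradient descent on the log-penalties of the
best-predicted voxels, guaranteed never to increase the CV loss.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .stimulus import RunLayout

logger = logging.getLogger(__name__)

_LOG_PEN_MIN, _LOG_PEN_MAX = np.log(1e-10), np.log(1e12)


@dataclass
class BandedDesign:
    """Concatenated design matrix with feature-space bookkeeping.

    ``band_cols[i]`` are the columns of feature space i (used for the
    split-prediction decomposition); ``reg_groups`` partition the columns
    for regularization, equal to ``band_cols`` unless delays are treated
    as separate groups.
    """

    F: np.ndarray
    band_names: list[str]
    band_cols: list[np.ndarray]
    reg_groups: list[np.ndarray]
    reg_group_names: list[str]

    @property
    def n_bands(self) -> int:
        return len(self.band_cols)

    @property
    def n_groups(self) -> int:
        return len(self.reg_groups)

    def column_group(self) -> np.ndarray:
        """Map column index -> regularization group index."""
        col_group = np.empty(self.F.shape[1], dtype=int)
        for g, cols in enumerate(self.reg_groups):
            col_group[cols] = g
        return col_group


def build_design(
    band_features: list[np.ndarray],
    band_names: list[str] | None = None,
    delay_tags: list[np.ndarray] | None = None,
    group_delays: bool = False,
) -> BandedDesign:
    """Concatenate per-band feature matrices into a banded design.

    ``group_delays=False`` (default) makes each feature space one
    regularization group; ``group_delays=True`` splits every (space,
    FIR delay) combination into its own group, which requires
    ``delay_tags`` (one tag vector per band, as returned by
    :func:`timescales.alignment.add_fir_delays`).
    """
    if not band_features:
        raise ValueError("at least one feature space required")
    n = band_features[0].shape[0]
    if any(f.shape[0] != n for f in band_features):
        raise ValueError("all feature spaces must share the time axis")
    if band_names is None:
        band_names = [f"band{i}" for i in range(len(band_features))]
    F = np.concatenate(band_features, axis=1)
    if not np.all(np.isfinite(F)):
        raise ValueError("design matrix contains non-finite values")
    offsets = np.cumsum([0] + [f.shape[1] for f in band_features])
    band_cols = [np.arange(a, b) for a, b in zip(offsets[:-1], offsets[1:])]

    if not group_delays:
        reg_groups = [c.copy() for c in band_cols]
        reg_names = list(band_names)
    else:
        if delay_tags is None:
            raise ValueError("group_delays=True requires delay_tags")
        reg_groups, reg_names = [], []
        for name, cols, tags in zip(band_names, band_cols, delay_tags):
            for d in np.unique(tags):
                reg_groups.append(cols[np.asarray(tags) == d])
                reg_names.append(f"{name}|delay{d}")
    return BandedDesign(F, list(band_names), band_cols, reg_groups, reg_names)


@dataclass
class HyperparameterSet:
    """Per-voxel, per-group regularization penalties with provenance.

    ``penalties`` has shape (v, m) (or (m,) to share across voxels); all
    entries are positive and finite.  ``cv_loss`` is the summed
    validation squared error of the selected combination, per voxel.
    """

    penalties: np.ndarray
    groups: list[np.ndarray]
    group_names: list[str]
    cv_loss: np.ndarray | None = None
    stage: str = "manual"

    def __post_init__(self) -> None:
        pen = np.asarray(self.penalties, dtype=float)
        if not np.all(np.isfinite(pen)) or np.any(pen <= 0):
            raise ValueError("all regularization penalties must be positive and finite")
        if pen.ndim == 1:
            pen = pen[np.newaxis, :]
        if pen.shape[1] != len(self.groups):
            raise ValueError("penalty columns must match the number of groups")
        self.penalties = pen

    def for_voxels(self, n_voxels: int) -> np.ndarray:
        """Penalties broadcast to shape (n_voxels, m)."""
        if self.penalties.shape[0] == n_voxels:
            return self.penalties
        if self.penalties.shape[0] == 1:
            return np.broadcast_to(self.penalties, (n_voxels, self.penalties.shape[1]))
        raise ValueError("penalty rows match neither 1 nor the number of voxels")


@dataclass
class EncodingModel:
    """Fitted banded-ridge weights plus the group partition used."""

    weights: np.ndarray  # (v, D)
    design_groups: list[np.ndarray]
    hypers: HyperparameterSet
    band_cols: list[np.ndarray] | None = None
    band_names: list[str] | None = None


def _column_penalties(penalties_row: np.ndarray, groups: list[np.ndarray], n_cols: int) -> np.ndarray:
    col_pen = np.empty(n_cols)
    for g, cols in enumerate(groups):
        col_pen[cols] = penalties_row[g]
    return col_pen


def _ridge_solve_scaled(Xs: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Unit-penalty ridge on an already-scaled design; primal or dual."""
    n, D = Xs.shape
    if D <= n:
        A = Xs.T @ Xs + np.eye(D)
        return cho_solve(cho_factor(A, lower=True), Xs.T @ Y)
    K = Xs @ Xs.T + np.eye(n)
    return Xs.T @ cho_solve(cho_factor(K, lower=True), Y)


def solve_banded_ridge(F: np.ndarray, Y: np.ndarray, hypers: HyperparameterSet) -> EncodingModel:
    """Closed-form banded ridge solve for all voxels.

    Per voxel, minimises ``||y - F w||^2 + sum_g pen_g ||w_g||^2`` via
    column rescaling plus unit-penalty ridge.  Voxels sharing a penalty
    row are solved in one batch.
    """
    F = np.asarray(F, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] != F.shape[0]:
        raise ValueError("design and responses must share the time axis")
    if not (np.all(np.isfinite(F)) and np.all(np.isfinite(Y))):
        raise ValueError("design or responses contain non-finite values")
    n, D = F.shape
    v = Y.shape[1]
    pen = hypers.for_voxels(v)

    weights = np.empty((v, D))
    unique_rows, inverse = np.unique(pen, axis=0, return_inverse=True)
    for u, row in enumerate(unique_rows):
        vox = np.flatnonzero(inverse == u)
        col_pen = _column_penalties(row, hypers.groups, D)
        scale = 1.0 / np.sqrt(col_pen)
        W_scaled = _ridge_solve_scaled(F * scale, Y[:, vox])
        weights[vox] = (W_scaled * scale[:, None]).T
    return EncodingModel(weights=weights, design_groups=hypers.groups, hypers=hypers)


def make_cv_folds(layout: RunLayout, n_folds: int | None = None) -> list[tuple[np.ndarray, np.ndarray]]:
    """Leave-one-run-out folds over the trimmed training time axis.

    Each fold's validation set is exactly one training run; folds are
    disjoint and cover all runs, so ``n_folds`` (default: the number of
    training runs) must equal the run count.
    """
    n_runs = layout.n_train_runs
    if n_folds is None:
        n_folds = n_runs
    if n_folds > n_runs:
        raise ValueError(f"cannot make {n_folds} one-run folds from {n_runs} runs")
    if n_folds != n_runs:
        raise ValueError(
            "folds validate exactly one run each and must cover all runs; "
            f"n_folds={n_folds} != {n_runs} training runs"
        )
    lengths = layout.trimmed_lengths(layout.train_run_lengths)
    slices = layout.run_slices(lengths)
    all_idx = np.arange(sum(lengths))
    folds = []
    for sl in slices:
        val = all_idx[sl]
        train = np.concatenate([all_idx[s] for s in slices if s != sl])
        folds.append((train, val))
    return folds


def _cv_losses_for_candidates(
    F: np.ndarray,
    Y: np.ndarray,
    col_group: np.ndarray,
    gammas: np.ndarray,
    scales: np.ndarray,
    folds: list[tuple[np.ndarray, np.ndarray]],
) -> np.ndarray:
    """Summed validation SSE, shape (n_candidates, n_scales, v).

    For one Dirichlet candidate the scaled design is fixed, so a single
    eigendecomposition of the scaled Gram matrix per fold serves every
    overall scale via the spectral filter ``1 / (eig + scale)``.
    """
    n_cand, n_scales, v = gammas.shape[0], scales.size, Y.shape[1]
    loss = np.zeros((n_cand, n_scales, v))
    cache = [
        (F[train].T @ F[train], F[train].T @ Y[train], F[val], Y[val])
        for train, val in folds
    ]
    for XtX, XtY, Xval, Yval in cache:
        for c in range(n_cand):
            s = np.sqrt(gammas[c][col_group])
            evals, V = np.linalg.eigh(XtX * np.outer(s, s))
            evals = np.maximum(evals, 0.0)
            z = V.T @ (s[:, None] * XtY)
            XvV = (Xval * s) @ V
            for k, lam in enumerate(scales):
                pred = XvV @ (z / (evals + lam)[:, None])
                loss[c, k] += ((pred - Yval) ** 2).sum(axis=0)
    return loss


def random_search(
    F: np.ndarray,
    Y: np.ndarray,
    groups: list[np.ndarray],
    folds: list[tuple[np.ndarray, np.ndarray]],
    group_names: list[str] | None = None,
    n_candidates: int = 1000,
    n_scales: int = 10,
    scale_range: tuple[float, float] = (1e-5, 1e5),
    dirichlet_alpha: float = 1.0,
    seed: int = 0,
) -> HyperparameterSet:
    """Stage 1: random hyperparameter search.

    Samples ``n_candidates`` group weightings from a Dirichlet
    distribution on the simplex, crosses each with ``n_scales``
    log-spaced overall scales, and keeps, per voxel, the combination with
    the minimum summed validation squared error across folds.  A group
    weighting gamma at overall scale ``lam`` corresponds to per-group
    penalties ``lam / gamma_g``.
    """
    if scale_range[0] <= 0 or scale_range[1] <= 0:
        raise ValueError("scale_range must be positive")
    F = np.asarray(F, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    m = len(groups)
    if m == 0:
        raise ValueError("at least one group required")
    if group_names is None:
        group_names = [f"group{g}" for g in range(m)]
    rng = np.random.default_rng(seed)
    if m == 1:
        gammas = np.ones((1, 1))
    else:
        gammas = rng.dirichlet(np.full(m, float(dirichlet_alpha)), size=n_candidates)
        gammas = np.maximum(gammas, 1e-10)
    scales = np.geomspace(scale_range[0], scale_range[1], n_scales)

    col_group = np.empty(F.shape[1], dtype=int)
    for g, cols in enumerate(groups):
        col_group[cols] = g

    loss = _cv_losses_for_candidates(F, Y, col_group, gammas, scales, folds)
    v = Y.shape[1]
    flat = loss.reshape(-1, v)
    best = flat.argmin(axis=0)
    c_best, k_best = np.unravel_index(best, loss.shape[:2])
    penalties = scales[k_best][:, None] / gammas[c_best]
    return HyperparameterSet(
        penalties=penalties,
        groups=[np.asarray(g) for g in groups],
        group_names=list(group_names),
        cv_loss=flat[best, np.arange(v)],
        stage="random_search",
    )


def _voxel_cv_loss_and_grad(
    log_pen: np.ndarray,
    fold_cache: list[tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]],
    col_group: np.ndarray,
    m: int,
    with_grad: bool = True,
) -> tuple[float, np.ndarray | None]:
    """CV loss of one voxel at log-penalties, with analytic gradient.

    For each fold, with A = Xtr'Xtr + diag(pen) and w = A^-1 Xtr'y, the
    gradient of the validation SSE wrt pen_j is -2 (A^-1 Xval'r)_j w_j
    summed over each group's columns and chain-ruled to log-penalties.
    """
    pen = np.exp(log_pen)
    col_pen = pen[col_group]
    loss = 0.0
    grad = np.zeros(m) if with_grad else None
    for XtX, Xty, Xval, yval in fold_cache:
        A = XtX + np.diag(col_pen)
        factor = cho_factor(A, lower=True, check_finite=False)
        w = cho_solve(factor, Xty, check_finite=False)
        r = Xval @ w - yval
        loss += float(r @ r)
        if with_grad:
            u = cho_solve(factor, Xval.T @ r, check_finite=False)
            per_col = -2.0 * u * w
            np.add.at(grad, col_group, per_col)
    if with_grad:
        grad *= pen  # d/d log pen
    return loss, grad


def gradient_refine(
    F: np.ndarray,
    Y: np.ndarray,
    groups: list[np.ndarray],
    folds: list[tuple[np.ndarray, np.ndarray]],
    start: HyperparameterSet,
    top_frac: float = 0.2,
    n_iter: int = 1000,
    step: float = 0.5,
    tol: float = 1e-6,
) -> HyperparameterSet:
    """Stage 2: gradient descent on log-penalties of the best voxels.

    Refines the voxels in the lowest ``top_frac`` of stage-1 CV loss by
    backtracking gradient descent on the leave-one-run-out loss; a step
    is accepted only if it does not increase the loss (halved otherwise),
    so every refined voxel's final CV loss is <= its stage-1 loss.
    Other voxels keep their stage-1 penalties.  Iteration stops once the
    relative loss improvement drops below ``tol`` (stationarity).
    """
    F = np.asarray(F, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    v = Y.shape[1]
    if start.cv_loss is None:
        raise ValueError("start must carry stage-1 CV losses")
    m = len(groups)
    col_group = np.empty(F.shape[1], dtype=int)
    for g, cols in enumerate(groups):
        col_group[cols] = g

    n_refine = max(1, int(np.ceil(top_frac * v)))
    order = np.argsort(start.cv_loss, kind="stable")
    refine_idx = order[:n_refine]

    base = [(F[tr].T @ F[tr], F[tr].T, F[va], Y[va]) for tr, va in folds]
    penalties = start.for_voxels(v).copy()
    cv_loss = start.cv_loss.copy()

    for vox in refine_idx:
        fold_cache = [
            (XtX, XtrT @ Y[folds[i][0], vox], Xval, Yval[:, vox])
            for i, (XtX, XtrT, Xval, Yval) in enumerate(base)
        ]
        log_pen = np.clip(np.log(penalties[vox]), _LOG_PEN_MIN, _LOG_PEN_MAX)
        loss, grad = _voxel_cv_loss_and_grad(log_pen, fold_cache, col_group, m)
        step_v = step
        for _ in range(n_iter):
            if np.linalg.norm(grad) <= tol * max(1.0, loss):
                break
            accepted = False
            while step_v > 1e-12:
                trial = np.clip(log_pen - step_v * grad, _LOG_PEN_MIN, _LOG_PEN_MAX)
                trial_loss, trial_grad = _voxel_cv_loss_and_grad(
                    trial, fold_cache, col_group, m
                )
                if trial_loss <= loss:
                    accepted = True
                    break
                step_v *= 0.5
            if not accepted:
                break
            improvement = loss - trial_loss
            log_pen, loss, grad = trial, trial_loss, trial_grad
            step_v = min(step_v * 1.5, 10.0)
            if improvement <= tol * max(1.0, loss):
                break
        penalties[vox] = np.exp(log_pen)
        cv_loss[vox] = loss

    return HyperparameterSet(
        penalties=penalties,
        groups=[np.asarray(g) for g in groups],
        group_names=list(start.group_names),
        cv_loss=cv_loss,
        stage="gradient_refine",
    )
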