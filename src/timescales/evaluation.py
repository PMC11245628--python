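"""Model evaluation: joint/split prediction performance and significance.

Joint prediction performance r is the Pearson correlation between the
predicted and recorded responses on the held-out test run.  Because the
joint prediction is the sum of per-feature-space predictions, r can be
decomposed into per-space contributions: the split-prediction
performance

    r~_i = sum_t Yhat_i[t] Y[t] / sqrt(sum_t Yhat[t]^2 * sum_t Y[t]^2)

(signals mean-centred per voxel), with the *joint* prediction in the
denominator so that sum_i r~_i = r exactly.  Negative contributions are
retained.

Language-selective voxels are those whose summed contribution of the
eight timescale feature spaces (r~_all) is significant under a one-sided
blockwise permutation test (test-response timecourse shuffled in blocks
of 10 TRs to respect autocorrelation), FDR-corrected (Benjamini-
Hochberg) within participant and condition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

from .ridge import EncodingModel

N_LANGUAGE_BANDS = 8


@dataclass
class VoxelScores:
    """Per-voxel evaluation results.

    ``split`` is (n_bands, v); ``r_all`` sums the language-band rows.
    ``flags`` marks voxels with zero-variance predictions (scored 0).
    """

    r: np.ndarray
    split: np.ndarray
    r_all: np.ndarray
    p: np.ndarray | None = None
    q: np.ndarray | None = None
    selective: np.ndarray | None = None
    flags: np.ndarray | None = None
    band_names: list[str] | None = None


def predict(model: EncodingModel, F_test: np.ndarray, band_cols: list[np.ndarray]) -> tuple[list[np.ndarray], np.ndarray]:
    """Per-feature-space and joint predictions on a test design.

    ``Yhat_i`` uses only feature space i's columns of the weights; the
    joint prediction is their exact sum.  Test features must have been
    z-scored with the training statistics.
    """
    F_test = np.asarray(F_test, dtype=float)
    if F_test.shape[1] != model.weights.shape[1]:
        raise ValueError(
            f"test design has {F_test.shape[1]} columns, model expects {model.weights.shape[1]}"
        )
    yhat_bands = [F_test[:, cols] @ model.weights[:, cols].T for cols in band_cols]
    return yhat_bands, np.sum(yhat_bands, axis=0)


def joint_r(yhat: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson correlation per voxel column; returns (r, zero-variance flags)."""
    yhat = np.atleast_2d(np.asarray(yhat, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if yhat.shape != y.shape:
        raise ValueError("prediction and response shapes differ")
    if yhat.shape[0] < 3:
        raise ValueError("need at least 3 time points")
    yc = y - y.mean(axis=0)
    pc = yhat - yhat.mean(axis=0)
    ny = np.sqrt((yc**2).sum(axis=0))
    np_ = np.sqrt((pc**2).sum(axis=0))
    flags = (ny <= 1e-300) | (np_ <= 1e-300)
    denom = np.where(flags, 1.0, ny * np_)
    r = np.where(flags, 0.0, (pc * yc).sum(axis=0) / denom)
    return r, flags


def split_r(
    yhat_bands: list[np.ndarray], yhat: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Split-prediction performance r~_i per band per voxel.

    Returns ``(split, flags)`` with ``split`` of shape (n_bands, v);
    ``sum_i split[i] = joint r`` holds exactly on centred signals.
    Voxels with a zero-norm joint prediction or response score 0 and are
    flagged.
    """
    yhat = np.atleast_2d(np.asarray(yhat, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    yc = y - y.mean(axis=0)
    phc = yhat - yhat.mean(axis=0)
    denom2 = (phc**2).sum(axis=0) * (yc**2).sum(axis=0)
    flags = denom2 <= 1e-300
    denom = np.sqrt(np.where(flags, 1.0, denom2))
    out = np.empty((len(yhat_bands), y.shape[1]))
    for i, yh in enumerate(yhat_bands):
        yhc = yh - yh.mean(axis=0)
        out[i] = np.where(flags, 0.0, (yhc * yc).sum(axis=0) / denom)
    return out, flags


def r_all_timescales(
    split: np.ndarray, language_bands: np.ndarray | list[int] | None = None
) -> np.ndarray:
    """Summed split performance of the eight language bands, per voxel.

    ``language_bands`` selects the timescale rows of ``split`` when
    nuisance (sensory) bands are present; by default all rows are taken
    and must number exactly eight.
    """
    split = np.asarray(split, dtype=float)
    idx = np.arange(split.shape[0]) if language_bands is None else np.asarray(language_bands)
    if idx.size != N_LANGUAGE_BANDS:
        raise ValueError(
            f"r_all requires exactly {N_LANGUAGE_BANDS} language bands, got {idx.size}"
        )
    return split[idx].sum(axis=0)


def block_permutation_indices(n: int, block: int, rng: np.random.Generator) -> np.ndarray:
    """Random reordering of consecutive blocks of ``block`` time points.

    The final short block (if ``n`` is not a multiple of ``block``) is
    kept intact and shuffled as a unit.
    """
    starts = np.arange(0, n, block)
    order = rng.permutation(len(starts))
    return np.concatenate([np.arange(starts[b], min(starts[b] + block, n)) for b in order])


def blockwise_permutation_test(
    yhat_lang: np.ndarray,
    yhat: np.ndarray,
    y: np.ndarray,
    n_perm: int = 1000,
    block: int = 10,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided blockwise permutation test of r~_all per voxel.

    The test-response timecourse is reordered in blocks of ``block`` TRs
    ``n_perm`` times; each reordering yields a null r~_all.  The add-one
    estimator ``p = (1 + #{null >= observed}) / (1 + n_perm)`` guarantees
    p in (0, 1].  Returns ``(p, observed_r_all)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    y = np.atleast_2d(np.asarray(y, dtype=float))
    n = y.shape[0]
    if n < 2 * block:
        raise ValueError(f"test run ({n} TRs) must span at least two {block}-TR blocks")
    yc = y - y.mean(axis=0)
    lc = yhat_lang - yhat_lang.mean(axis=0)
    jc = yhat - yhat.mean(axis=0)
    denom2 = (jc**2).sum(axis=0) * (yc**2).sum(axis=0)
    denom = np.sqrt(np.where(denom2 <= 1e-300, 1.0, denom2))
    observed = np.where(denom2 <= 1e-300, 0.0, (lc * yc).sum(axis=0) / denom)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(y.shape[1], dtype=int)
    for _ in range(n_perm):
        idx = block_permutation_indices(n, block, rng)
        yp = yc[idx]
        yp = yp - yp.mean(axis=0)  # identical values; mean unchanged, kept for clarity
        null = np.einsum("tv,tv->v", lc, yp) / denom
        exceed += null >= observed
    p = (1.0 + exceed) / (1.0 + n_perm)
    return p, observed


def fdr_correct(p: np.ndarray, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up; returns ``(q, selective_mask)``.

    ``selective_mask = q < alpha``, applied within one participant and
    condition.  Empty input yields empty outputs.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return np.empty(0), np.empty(0, dtype=bool)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, q < alpha


def score_voxels(
    model: EncodingModel,
    F_test: np.ndarray,
    y_test: np.ndarray,
    band_cols: list[np.ndarray],
    language_bands: np.ndarray | list[int] | None = None,
    n_perm: int = 1000,
    block: int = 10,
    alpha: float = 0.05,
    seed: int = 0,
    band_names: list[str] | None = None,
) -> VoxelScores:
    """Full evaluation: predict, score, permutation-test, FDR-correct."""
    yhat_bands, yhat = predict(model, F_test, band_cols)
    r, r_flags = joint_r(yhat, y_test)
    split, s_flags = split_r(yhat_bands, yhat, y_test)
    idx = (
        np.arange(len(yhat_bands)) if language_bands is None else np.asarray(language_bands)
    )
    r_all = r_all_timescales(split, idx)
    yhat_lang = np.sum([yhat_bands[i] for i in idx], axis=0)
    p, _ = blockwise_permutation_test(yhat_lang, yhat, y_test, n_perm, block, seed)
    q, selective = fdr_correct(p, alpha)
    return VoxelScores(
        r=r,
        split=split,
        r_all=r_all,
        p=p,
        q=q,
        selective=selective,
        flags=r_flags | s_flags,
        band_names=band_names,
    )
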