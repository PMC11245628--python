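"""Timescale selectivity: per-voxel profiles, the scalar T-bar, and
cross-condition comparison.

The timescale selectivity profile r~' rectifies the eight split-
prediction performances and normalises them to proportions:

    r~'_i = max(0, r~_i) / sum_j max(0, r~_j) .

Voxels whose split performances are all non-positive have no defined
profile and are excluded (flagged).  Timescale selectivity is the
profile-weighted geometric mean of the nominal band timescales,

    T-bar = 2 ^ ( sum_i r~'_i log2(t_i) )   (words),

so one-hot profiles recover their band's nominal timescale and T-bar
always lies between the shortest and longest nominal timescale.

Cross-condition comparison correlates T-bar (or per-band selectivity, or
whole profiles) between two conditions across voxels selective in both;
significance comes from blockwise shuffling of each condition's test
responses, recomputing null selectivities, and correlating the null
values between conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evaluation import block_permutation_indices


@dataclass
class SelectivityResult:
    """Profiles (v x 8, rows summing to 1 where defined) and T-bar (words)."""

    profile: np.ndarray
    tbar: np.ndarray
    timescales: np.ndarray
    defined: np.ndarray


@dataclass
class ComparisonResult:
    """Cross-condition comparison statistics."""

    r: float
    p: float
    null: np.ndarray


def selectivity_profile(split_lang: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rectified, sum-to-one selectivity profile per voxel.

    ``split_lang`` is (n_bands, v) or (v, n_bands); the band axis is
    taken as the first.  Returns ``(profile, defined)`` with ``profile``
    of shape (v, n_bands); undefined rows (all split performances <= 0)
    are NaN and ``defined`` False.
    """
    split_lang = np.asarray(split_lang, dtype=float)
    clipped = np.clip(split_lang, 0.0, None)  # (bands, v)
    totals = clipped.sum(axis=0)
    defined = totals > 0
    profile = np.full(clipped.T.shape, np.nan)
    profile[defined] = (clipped[:, defined] / totals[defined]).T
    return profile, defined


def timescale_selectivity(profile: np.ndarray, timescales: np.ndarray) -> np.ndarray:
    """T-bar: 2^(sum_i profile_i * log2 t_i), NaN where the profile is undefined."""
    timescales = np.asarray(timescales, dtype=float)
    if np.any(timescales <= 0):
        raise ValueError("timescales must be strictly positive")
    profile = np.atleast_2d(np.asarray(profile, dtype=float))
    with np.errstate(invalid="ignore"):
        return np.exp2(profile @ np.log2(timescales))


def compute_selectivity(split_lang: np.ndarray, timescales: np.ndarray) -> SelectivityResult:
    """Profile + T-bar from the language-band split performances."""
    profile, defined = selectivity_profile(split_lang)
    tbar = timescale_selectivity(profile, timescales)
    return SelectivityResult(
        profile=profile, tbar=tbar, timescales=np.asarray(timescales, float), defined=defined
    )


def _null_selectivity(
    yhat_bands_lang: np.ndarray,
    yhat: np.ndarray,
    y: np.ndarray,
    timescales: np.ndarray,
    perm_idx: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Null (profile, tbar) from one blockwise shuffle of the responses.

    ``yhat_bands_lang`` is the centred stack (8, n, v); ``yhat`` the
    centred joint prediction; ``y`` the centred responses.
    """
    yp = y[perm_idx]
    denom2 = (yhat**2).sum(axis=0) * (yp**2).sum(axis=0)
    denom = np.sqrt(np.where(denom2 <= 1e-300, 1.0, denom2))
    split = np.einsum("btv,tv->bv", yhat_bands_lang, yp) / denom
    profile, _ = selectivity_profile(split)
    return profile, timescale_selectivity(profile, timescales)


class _NullInputs:
    """Pre-centred per-condition inputs for permutation nulls."""

    def __init__(self, yhat_bands_lang: list[np.ndarray], yhat: np.ndarray, y: np.ndarray):
        stack = np.stack([yh - yh.mean(axis=0) for yh in yhat_bands_lang])
        self.bands = stack
        self.yhat = yhat - yhat.mean(axis=0)
        self.y = y - y.mean(axis=0)
        self.n = y.shape[0]


def compare_selectivity(
    tbar_a: np.ndarray,
    tbar_b: np.ndarray,
    mask: np.ndarray,
    null_a: tuple[list[np.ndarray], np.ndarray, np.ndarray] | None = None,
    null_b: tuple[list[np.ndarray], np.ndarray, np.ndarray] | None = None,
    timescales: np.ndarray | None = None,
    n_perm: int = 1000,
    block: int = 10,
    seed: int = 0,
    log_domain: bool = False,
) -> ComparisonResult:
    """Correlate T-bar between two conditions over jointly selective voxels.

    ``null_a``/``null_b`` are ``(yhat_bands_lang, yhat_joint, y_test)``
    for each condition; per iteration each condition's test responses
    are independently blockwise-shuffled, null T-bars recomputed, and
    the null T-bars correlated between conditions, giving a one-sided
    permutation p.  With ``null_a=None`` no p-value is computed (p=NaN).
    Correlations use raw T-bar values by default; ``log_domain=True``
    correlates log2 T-bar instead (timescales are ratio-scaled).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 3:
        raise ValueError("mask must select at least 3 voxels")
    a = np.asarray(tbar_a, float)[mask]
    b = np.asarray(tbar_b, float)[mask]
    if log_domain:
        a, b = np.log2(a), np.log2(b)
    observed = _pearson(a, b)

    if null_a is None or null_b is None:
        return ComparisonResult(r=observed, p=np.nan, null=np.empty(0))
    if timescales is None:
        raise ValueError("timescales required to build permutation nulls")

    rng = np.random.default_rng(seed)
    ca, cb = _NullInputs(*null_a), _NullInputs(*null_b)
    null = np.empty(n_perm)
    for i in range(n_perm):
        _, ta = _null_selectivity(
            ca.bands, ca.yhat, ca.y, timescales, block_permutation_indices(ca.n, block, rng)
        )
        _, tb = _null_selectivity(
            cb.bands, cb.yhat, cb.y, timescales, block_permutation_indices(cb.n, block, rng)
        )
        va, vb = ta[mask], tb[mask]
        if log_domain:
            with np.errstate(invalid="ignore"):
                va, vb = np.log2(va), np.log2(vb)
        null[i] = _pearson_nan(va, vb)
    p = (1.0 + np.sum(null >= observed)) / (1.0 + n_perm)
    return ComparisonResult(r=observed, p=float(p), null=null)


def per_band_comparison(
    profile_a: np.ndarray,
    profile_b: np.ndarray,
    mask: np.ndarray,
    null_a: tuple[list[np.ndarray], np.ndarray, np.ndarray] | None = None,
    null_b: tuple[list[np.ndarray], np.ndarray, np.ndarray] | None = None,
    timescales: np.ndarray | None = None,
    n_perm: int = 1000,
    block: int = 10,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-band correlation of selectivity between conditions.

    For each band, correlates that band's profile entry between the two
    conditions across masked voxels; permutation nulls (if null inputs
    are given) are built from blockwise-shuffled responses as in
    :func:`compare_selectivity`.  Returns ``(r_per_band, p_per_band)``.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 3:
        raise ValueError("mask must select at least 3 voxels")
    pa = np.asarray(profile_a, float)[mask]
    pb = np.asarray(profile_b, float)[mask]
    n_bands = pa.shape[1]
    observed = np.array([_pearson_nan(pa[:, i], pb[:, i]) for i in range(n_bands)])
    if null_a is None or null_b is None:
        return observed, np.full(n_bands, np.nan)
    if timescales is None:
        raise ValueError("timescales required to build permutation nulls")
    rng = np.random.default_rng(seed)
    ca, cb = _NullInputs(*null_a), _NullInputs(*null_b)
    exceed = np.zeros(n_bands, dtype=int)
    for _ in range(n_perm):
        prof_a, _ = _null_selectivity(
            ca.bands, ca.yhat, ca.y, timescales, block_permutation_indices(ca.n, block, rng)
        )
        prof_b, _ = _null_selectivity(
            cb.bands, cb.yhat, cb.y, timescales, block_permutation_indices(cb.n, block, rng)
        )
        for i in range(n_bands):
            exceed[i] += _pearson_nan(prof_a[mask, i], prof_b[mask, i]) >= observed[i]
    p = (1.0 + exceed) / (1.0 + n_perm)
    return observed, p


def profile_correlation(
    profile_a: np.ndarray, profile_b: np.ndarray, mask: np.ndarray | None = None
) -> np.ndarray:
    """Per-voxel Pearson correlation of the 8-band profiles between conditions.

    Voxels outside ``mask``, with undefined profiles, or with constant
    profiles (zero variance across bands) are NaN.
    """
    pa = np.asarray(profile_a, float)
    pb = np.asarray(profile_b, float)
    if pa.shape != pb.shape:
        raise ValueError("profile shapes differ")
    v = pa.shape[0]
    out = np.full(v, np.nan)
    sel = np.ones(v, dtype=bool) if mask is None else np.asarray(mask, bool)
    for i in np.flatnonzero(sel):
        a, b = pa[i], pb[i]
        if np.any(np.isnan(a)) or np.any(np.isnan(b)):
            continue
        if a.std() <= 1e-12 or b.std() <= 1e-12:
            continue
        out[i] = _pearson(a, b)
    return out


def group_aggregate(
    values: np.ndarray,
    masks: np.ndarray,
    min_fraction: float = 1.0 / 3.0,
    log_domain: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Cross-subject aggregation on a shared vertex grid.

    ``values``/``masks`` are (n_subjects, n_vertices); per vertex the
    group value is the mean over subjects whose mask includes it (raw
    values by default, geometric mean with ``log_domain=True``), and the
    group mask requires selectivity in at least
    ``ceil(min_fraction * n_subjects)`` subjects.  Unselected vertices
    are NaN.
    """
    values = np.asarray(values, dtype=float)
    masks = np.asarray(masks, dtype=bool)
    if values.shape != masks.shape:
        raise ValueError("values and masks must share the (subjects x vertices) grid")
    n_subjects = values.shape[0]
    counts = masks.sum(axis=0)
    group_mask = counts >= int(np.ceil(min_fraction * n_subjects))
    vals = np.log2(values) if log_domain else values
    with np.errstate(invalid="ignore"):
        sums = np.where(masks, vals, 0.0).sum(axis=0)
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    if log_domain:
        mean = np.exp2(mean)
    mean = np.where(counts > 0, mean, np.nan)
    return mean, group_mask


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a**2).sum() * (b**2).sum())
    if denom <= 1e-300:
        return np.nan
    return float((a * b).sum() / denom)


def _pearson_nan(a: np.ndarray, b: np.ndarray) -> float:
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        return np.nan
    return _pearson(a[ok], b[ok])
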