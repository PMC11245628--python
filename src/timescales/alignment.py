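"""Temporal alignment of word-rate features to TR-rate BOLD recordings.

Word-rate filtered embeddings are sampled once per word, at irregular
times; BOLD responses are sampled once per TR.  Downsampling the word
stream directly would confound slow embedding components with the
(variable) word presentation rate, so alignment proceeds in two steps:

1. normalised Gaussian RBF interpolation of the word-rate signal onto a
   uniform grid of 25 samples per TR, anchored at word midpoint times;
2. anti-aliasing 3-lobe Lanczos resampling (cut-off at the fMRI Nyquist
   rate, 0.25 Hz) onto the middle time point of each TR.

TR-rate features and responses are then truncated (10 TRs per run edge),
z-scored (feature statistics from training runs only), and features are
FIR-delayed by 1-4 TRs (~2-8 s) to absorb the hemodynamic lag.  Feature
spaces already sampled at TR rate (e.g. sensory nuisance spaces) skip the
interpolation but share trimming, z-scoring and delays.

All TR-rate arrays are time-major: shape (n_trs, n_channels).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .stimulus import RunLayout, WordSequence

logger = logging.getLogger(__name__)


@dataclass
class FeatureMatrix:
    """TR-rate feature matrix with channel bookkeeping.

    ``values`` is (n_trs, n_channels); ``band`` names the feature space
    ("2-4 words", ..., or "concatenated"); ``delays[j]`` is the FIR delay
    (TRs) of channel j (0 = undelayed); ``mean``/``std`` are the training
    statistics used for z-scoring, if applied.
    """

    values: np.ndarray
    band: str = ""
    delays: np.ndarray | None = None
    mean: np.ndarray | None = None
    std: np.ndarray | None = None
    flags: np.ndarray | None = None

    @property
    def n_trs(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]


def tr_midpoints(n_trs: int, tr: float) -> np.ndarray:
    """Middle time point of each TR of a run starting at t=0."""
    return (np.arange(n_trs) + 0.5) * tr


def dense_grid(n_trs: int, tr: float, samples_per_tr: int = 25) -> np.ndarray:
    """Uniform grid of ``samples_per_tr`` sample times per TR."""
    n = n_trs * samples_per_tr
    return (np.arange(n) + 0.5) * (tr / samples_per_tr)


def rbf_interpolate(
    values: np.ndarray,
    word_times: np.ndarray,
    n_trs: int,
    tr: float,
    samples_per_tr: int = 25,
    sigma: float | None = None,
) -> np.ndarray:
    """Interpolate a word-rate signal onto a dense uniform grid.

    Normalised Gaussian-kernel (Nadaraya-Watson) interpolation:
    ``s(t) = sum_k x_k K(t - t_k) / sum_k K(t - t_k)`` with Gaussian K of
    width ``sigma`` and t_k the word anchor (midpoint) times.  The
    normalisation makes the interpolant an exact partition of unity, so a
    constant word signal maps to the same constant, and silent gaps decay
    toward local averages rather than zero.

    Parameters
    ----------
    values
        Word-rate signal, shape (p, w) or (w,).
    word_times
        Anchor time of each word (seconds, run-relative).
    n_trs, tr
        Length of the run (TRs) and TR duration (s).
    sigma
        Kernel width in seconds; default = mean inter-word interval of
        the run (one word spacing).
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    word_times = np.asarray(word_times, dtype=float)
    grid = dense_grid(n_trs, tr, samples_per_tr)
    if word_times.size == 0:
        logger.warning("run has zero words; interpolated signal set to zeros")
        return np.zeros((values.shape[0], grid.size))
    if word_times.min() < 0 or word_times.max() > n_trs * tr:
        raise ValueError("word times fall outside the run's time span")
    if sigma is None:
        sigma = float(np.mean(np.diff(word_times))) if word_times.size > 1 else tr
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    # (n_grid, w) kernel; subtract row max before exp for numerical range
    d2 = (grid[:, None] - word_times[None, :]) ** 2 / (2.0 * sigma**2)
    log_k = -d2
    log_k -= log_k.max(axis=1, keepdims=True)
    kernel = np.exp(log_k)
    kernel /= kernel.sum(axis=1, keepdims=True)
    return values @ kernel.T


def lanczos_kernel(x: np.ndarray, lobes: int = 3) -> np.ndarray:
    """Lanczos window: sinc(x)·sinc(x/a) for |x| < a, else 0 (x in cut-off periods)."""
    out = np.sinc(x) * np.sinc(x / lobes)
    out[np.abs(x) >= lobes] = 0.0
    return out


def lanczos_downsample(
    dense: np.ndarray,
    n_trs: int,
    tr: float,
    samples_per_tr: int = 25,
    cutoff: float = 0.25,
    lobes: int = 3,
) -> np.ndarray:
    """Resample a dense signal to the middle time point of each TR.

    Applies a ``lobes``-lobe Lanczos kernel with the given cut-off
    frequency (Hz); weights are renormalised to sum to one per output
    sample so the DC gain is exactly 1.

    ``dense`` has shape (p, n_trs * samples_per_tr) (or 1-D).
    """
    if cutoff <= 0:
        raise ValueError("cutoff frequency must be positive")
    dense = np.atleast_2d(np.asarray(dense, dtype=float))
    if dense.shape[-1] != n_trs * samples_per_tr:
        raise ValueError(
            f"dense signal length {dense.shape[-1]} != n_trs*samples_per_tr = {n_trs * samples_per_tr}"
        )
    t_dense = dense_grid(n_trs, tr, samples_per_tr)
    t_out = tr_midpoints(n_trs, tr)
    # x in units of the cut-off period: x = 2*cutoff*(t_k - t_j)
    x = 2.0 * cutoff * (t_dense[None, :] - t_out[:, None])
    weights = lanczos_kernel(x, lobes=lobes)
    weights /= weights.sum(axis=1, keepdims=True)
    return dense @ weights.T


def resample_run(
    filtered: np.ndarray,
    seq: WordSequence,
    n_trs: int,
    tr: float,
    samples_per_tr: int = 25,
    sigma: float | None = None,
    cutoff: float = 0.25,
    lobes: int = 3,
) -> np.ndarray:
    """RBF-interpolate then Lanczos-downsample one run; returns (n_trs, p)."""
    dense = rbf_interpolate(filtered, seq.midpoints, n_trs, tr, samples_per_tr, sigma)
    return lanczos_downsample(dense, n_trs, tr, samples_per_tr, cutoff, lobes).T


def trim_runs(matrix: np.ndarray, run_lengths: tuple[int, ...], trim: int = 10) -> np.ndarray:
    """Drop ``trim`` TRs from both ends of every run (time-major matrix)."""
    matrix = np.asarray(matrix)
    if matrix.shape[0] != sum(run_lengths):
        raise ValueError(
            f"time axis {matrix.shape[0]} != sum of run lengths {sum(run_lengths)}"
        )
    if trim == 0:
        return matrix
    parts = []
    start = 0
    for i, n in enumerate(run_lengths):
        if n <= 2 * trim:
            raise ValueError(f"run {i} ({n} TRs) too short to trim {trim} TRs per edge")
        parts.append(matrix[start + trim : start + n - trim])
        start += n
    return np.concatenate(parts, axis=0)


def zscore_features(
    values: np.ndarray, train_mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Z-score channels using statistics from training rows only.

    Returns ``(z, mean, std, zero_variance_flags)``.  Statistics are
    computed on rows where ``train_mask`` is True and applied everywhere
    (no test-set leakage); zero-variance channels are set to 0 and
    flagged rather than raising.
    """
    values = np.asarray(values, dtype=float)
    train_mask = np.asarray(train_mask, dtype=bool)
    train = values[train_mask]
    mean = train.mean(axis=0)
    std = train.std(axis=0)
    flags = std <= 1e-12
    safe_std = np.where(flags, 1.0, std)
    z = (values - mean) / safe_std
    z[:, flags] = 0.0
    if flags.any():
        logger.warning("%d zero-variance feature channels set to 0", int(flags.sum()))
    return z, mean, std, flags


def add_fir_delays(
    values: np.ndarray,
    run_lengths: tuple[int, ...],
    delays: tuple[int, ...] = (1, 2, 3, 4),
) -> tuple[np.ndarray, np.ndarray]:
    """Concatenate copies of the features delayed by whole TRs.

    Each delay shifts channels forward in time within each run,
    zero-filling the first ``delay`` TRs; shifts never cross run
    boundaries.  Returns ``(delayed, tags)`` where ``delayed`` has shape
    (n, len(delays) * d) (delay-major blocks) and ``tags[j]`` is the
    delay of output channel j.
    """
    values = np.asarray(values, dtype=float)
    if any(d < 1 or int(d) != d for d in delays):
        raise ValueError("delays must be positive integers (TRs)")
    if max(delays) >= min(run_lengths):
        raise ValueError(
            f"delay {max(delays)} >= shortest run ({min(run_lengths)} TRs)"
        )
    if values.shape[0] != sum(run_lengths):
        raise ValueError("time axis must equal the sum of run lengths")
    n, d = values.shape
    blocks = []
    for delay in delays:
        shifted = np.zeros_like(values)
        start = 0
        for length in run_lengths:
            shifted[start + delay : start + length] = values[start : start + length - delay]
            start += length
        blocks.append(shifted)
    tags = np.repeat(np.asarray(delays, dtype=int), d)
    return np.concatenate(blocks, axis=1), tags


def savgol_window_trs(tr: float, window_seconds: float = 120.0) -> int:
    """Nearest odd TR count to ``window_seconds`` / TR."""
    w = window_seconds / tr
    lower = int(np.floor(w))
    if lower % 2 == 0:
        lower -= 1
    lower = max(lower, 5)
    return lower if abs(lower - w) <= abs(lower + 2 - w) else lower + 2


def preprocess_bold(
    raw: np.ndarray,
    run_lengths: tuple[int, ...],
    tr: float,
    detrend: bool = True,
    window_seconds: float = 120.0,
    polyorder: int = 3,
) -> np.ndarray:
    """Per-run BOLD preprocessing: drift removal then voxelwise z-scoring.

    Drift removal subtracts a third-order Savitzky-Golay smooth with a
    ~120 s window (nearest odd TR count) from each voxel timecourse; runs
    shorter than the window skip detrending with a warning.  Each run's
    voxel columns are then z-scored across time.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.shape[0] != sum(run_lengths):
        raise ValueError("time axis must equal the sum of run lengths")
    window = savgol_window_trs(tr, window_seconds)
    out = np.empty_like(raw)
    start = 0
    for i, length in enumerate(run_lengths):
        block = raw[start : start + length]
        if detrend:
            if length <= window:
                warnings.warn(
                    f"run {i} ({length} TRs) shorter than the Savitzky-Golay window "
                    f"({window} TRs); drift removal skipped for this run",
                    stacklevel=2,
                )
            else:
                block = block - savgol_filter(block, window, polyorder, axis=0)
        mean = block.mean(axis=0)
        std = block.std(axis=0)
        std = np.where(std <= 1e-12, 1.0, std)
        out[start : start + length] = (block - mean) / std
        start += length
    return out


def average_test_repeats(*repeats: np.ndarray) -> np.ndarray:
    """Elementwise mean of repeated test-run responses (equal shapes)."""
    if not repeats:
        raise ValueError("at least one repeat required")
    shapes = {r.shape for r in repeats}
    if len(shapes) > 1:
        raise ValueError(f"repeat shapes differ: {sorted(shapes)}")
    return np.mean(np.stack(repeats), axis=0)
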