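"""Synthetic stimulus and response generator with known ground truth.

Emulates the structure of a narrative fMRI experiment — several ~10-min
training runs and one test run presented twice — so every stage of the
pipeline can be validated by parameter recovery at desk scale:

* word sequences with naturalistic (log-normal) inter-word intervals;
* embedding streams whose spectral content per dimension is known by
  construction (each dimension is a sinusoid in word index with period
  drawn inside an assigned timescale band, plus white noise);
* voxel responses that are linear in timescale-band features with a
  known per-voxel band weighting, plus slow cosine drift (periods above
  120 s, the removable target of the Savitzky-Golay detrend) and
  Gaussian noise.

The generator does not attempt realistic transformer-embedding geometry,
hemodynamic nonlinearity, or spatial voxel correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .embedding import StimulusEmbedding
from .filterbank import BandSpec
from .stimulus import RunLayout, WordSequence

_CONSONANTS = "bcdfghjklmnpqrstvwz"
_VOWELS = "aeiou"


def _pseudo_word(rng: np.random.Generator) -> str:
    n_syll = int(rng.integers(1, 4))
    return "".join(
        _CONSONANTS[rng.integers(len(_CONSONANTS))] + _VOWELS[rng.integers(len(_VOWELS))]
        for _ in range(n_syll)
    )


def generate_word_sequence(
    n_words: int,
    mean_interval: float = 0.4,
    jitter: float = 0.3,
    sentence_len_mean: float = 12.0,
    seed: int = 0,
    start_time: float = 0.0,
) -> WordSequence:
    """Word sequence with log-normal inter-word intervals.

    Intervals have mean ``mean_interval`` seconds and coefficient of
    variation ``jitter`` (log-normal: positive and right-skewed, like
    natural narration); ``jitter=0`` gives exactly arithmetic onsets.
    Word durations are 80% of the gap to the next onset.  Sentences are
    contiguous blocks with mean length ``sentence_len_mean`` words.
    """
    if n_words < 0:
        raise ValueError("n_words must be non-negative")
    if mean_interval <= 0:
        raise ValueError("mean_interval must be positive")
    if not 0 <= jitter < 1:
        raise ValueError("jitter must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    if n_words == 0:
        empty = np.empty(0)
        return WordSequence((), empty, empty, np.empty(0, dtype=int))

    if jitter == 0:
        intervals = np.full(n_words, mean_interval)
    else:
        sigma2 = np.log1p(jitter**2)
        mu = np.log(mean_interval) - 0.5 * sigma2
        intervals = rng.lognormal(mu, np.sqrt(sigma2), size=n_words)
    onsets = start_time + np.concatenate([[0.0], np.cumsum(intervals[:-1])])
    gaps = np.concatenate([np.diff(onsets), [mean_interval]])
    offsets = onsets + 0.8 * gaps

    words = tuple(_pseudo_word(rng) for _ in range(n_words))
    sentence_ids = np.empty(n_words, dtype=int)
    i, sid = 0, 0
    while i < n_words:
        length = 1 + int(rng.poisson(max(sentence_len_mean - 1.0, 0.0)))
        sentence_ids[i : i + length] = sid
        i += length
        sid += 1
    return WordSequence(words, onsets, offsets, sentence_ids)


def generate_band_limited_embedding(
    seq: WordSequence,
    bands: list[BandSpec],
    dims_per_band: int = 2,
    amp: float = 1.0,
    noise: float = 0.0,
    seed: int = 0,
) -> tuple[StimulusEmbedding, np.ndarray]:
    """Embedding whose per-dimension spectral content is known.

    Dimension d is assigned to band ``d // dims_per_band`` (band-major
    order) and is a sinusoid in word index with period drawn uniformly
    inside that band's period range, amplitude ``amp``, random phase,
    plus white Gaussian noise of s.d. ``noise``.  Returns the embedding
    and the per-dimension band assignment.
    """
    if not bands:
        raise ValueError("band list must be non-empty")
    if dims_per_band < 1:
        raise ValueError("dims_per_band must be >= 1")
    rng = np.random.default_rng(seed)
    w = len(seq)
    p = len(bands) * dims_per_band
    assignment = np.repeat(np.arange(len(bands)), dims_per_band)
    n = np.arange(w)
    matrix = np.empty((p, w))
    for d, band_idx in enumerate(assignment):
        band = bands[band_idx]
        period = rng.uniform(band.p_low, band.p_high)
        phase = rng.uniform(0.0, 2 * np.pi)
        matrix[d] = amp * np.cos(2 * np.pi * n / period + phase)
        if noise > 0:
            matrix[d] += noise * rng.standard_normal(w)
    emb = StimulusEmbedding(matrix=matrix, layer_slices=((0, p),), context_mode="sentence",
                            layers_used="synthetic")
    return emb, assignment


@dataclass(frozen=True)
class SyntheticGroundTruth:
    """Per-voxel band weights and the implied true timescale.

    ``band_weights`` is (v, n_bands), non-negative with at least one
    positive entry per row; ``true_timescale`` (words) is the
    row-normalised weighted geometric mean of the nominal band
    timescales, i.e. exactly the quantity T-bar estimates.
    """

    band_weights: np.ndarray
    timescales: np.ndarray
    noise_sigma: float = 1.0
    drift_amplitude: float = 0.5
    seed: int = 0
    true_timescale: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        weights = np.asarray(self.band_weights, dtype=float)
        ts = np.asarray(self.timescales, dtype=float)
        if weights.ndim != 2 or weights.shape[1] != ts.size:
            raise ValueError("band_weights must be (v, n_bands) matching timescales")
        if np.any(weights < 0):
            raise ValueError("band weights must be non-negative")
        row_sums = weights.sum(axis=1)
        if np.any(row_sums <= 0):
            bad = int(np.argmax(row_sums <= 0))
            raise ValueError(f"voxel {bad} has an all-zero band weight row")
        if self.noise_sigma < 0 or self.drift_amplitude < 0:
            raise ValueError("noise_sigma and drift_amplitude must be non-negative")
        norm = weights / row_sums[:, None]
        object.__setattr__(self, "band_weights", weights)
        object.__setattr__(self, "timescales", ts)
        object.__setattr__(self, "true_timescale", np.exp2(norm @ np.log2(ts)))

    @property
    def n_voxels(self) -> int:
        return self.band_weights.shape[0]

    @property
    def dominant_band(self) -> np.ndarray:
        return self.band_weights.argmax(axis=1)


def one_hot_truth(
    n_voxels: int,
    timescales: np.ndarray,
    noise_sigma: float = 1.0,
    drift_amplitude: float = 0.5,
    seed: int = 0,
) -> SyntheticGroundTruth:
    """One-hot band truth cycling voxels through all bands."""
    n_bands = len(timescales)
    weights = np.zeros((n_voxels, n_bands))
    weights[np.arange(n_voxels), np.arange(n_voxels) % n_bands] = 1.0
    return SyntheticGroundTruth(weights, np.asarray(timescales, float),
                                noise_sigma, drift_amplitude, seed)


@dataclass
class SyntheticResponses:
    """Generated BOLD-like responses plus the ground truth used."""

    train: np.ndarray  # (n_train_trs, v)
    test_repeats: list[np.ndarray]  # test_repeats x (n_test_trs, v)
    truth: SyntheticGroundTruth


def _drift(n_trs: int, tr: float, amplitude: float, n_voxels: int,
           rng: np.random.Generator, min_period: float = 120.0) -> np.ndarray:
    """Sum of low-order cosines with periods > ``min_period`` seconds."""
    if amplitude == 0:
        return np.zeros((n_trs, n_voxels))
    duration = n_trs * tr
    t = (np.arange(n_trs) + 0.5) * tr
    out = np.zeros((n_trs, n_voxels))
    k = 1
    while duration / k > min_period and k <= 4:
        phase = rng.uniform(0, 2 * np.pi, size=n_voxels)
        out += np.cos(2 * np.pi * k * t[:, None] / duration + phase[None, :])
        k += 1
    scale = out.std(axis=0)
    scale[scale <= 1e-12] = 1.0
    return amplitude * out / scale


def generate_voxel_responses(
    band_features: list[np.ndarray],
    truth: SyntheticGroundTruth,
    layout: RunLayout,
    generative_delay: int = 2,
    noise_seed: int | None = None,
) -> SyntheticResponses:
    """Linear responses from band features plus drift and noise.

    ``band_features[i]`` is the TR-rate feature matrix of band i over
    all runs concatenated (training runs then the test run, untrimmed).
    Each voxel's noiseless signal is the sum over bands of the band
    features (delayed by ``generative_delay`` TRs within runs, emulating
    hemodynamic lag) projected onto a random unit vector, scaled by the
    voxel's band weight; the signal is standardised per voxel on the
    training portion, then slow drift and white noise of s.d.
    ``truth.noise_sigma`` are added per run.  The test run is produced
    ``layout.test_repeats`` times with independent drift and noise.

    The projection vectors (a voxel's identity) are drawn from
    ``truth.seed``, so two stimulus realisations generated under the
    same truth share voxel tuning; drift and noise are drawn from
    ``noise_seed`` (default: ``truth.seed``).
    """
    n_total = sum(layout.all_run_lengths)
    if any(f.shape[0] != n_total for f in band_features):
        raise ValueError("band feature time axis must equal the sum of all run lengths")
    if len(band_features) != truth.band_weights.shape[1]:
        raise ValueError("band count mismatch between features and truth weights")

    rng_proj = np.random.default_rng(truth.seed)
    rng = np.random.default_rng(truth.seed if noise_seed is None else noise_seed)
    v = truth.n_voxels
    signal = np.zeros((n_total, v))
    for i, feats in enumerate(band_features):
        shifted = _delay_within_runs(feats, layout.all_run_lengths, generative_delay)
        d = feats.shape[1]
        proj = rng_proj.standard_normal((d, v)) / np.sqrt(d)
        signal += shifted @ (proj * truth.band_weights[:, i][None, :])

    n_train = layout.n_train_trs
    sd = signal[:n_train].std(axis=0)
    sd[sd <= 1e-12] = 1.0
    signal /= sd[None, :]

    train = signal[:n_train].copy()
    start = 0
    for length in layout.train_run_lengths:
        train[start : start + length] += _drift(length, layout.tr, truth.drift_amplitude, v, rng)
        start += length
    train += truth.noise_sigma * rng.standard_normal(train.shape)

    test_signal = signal[n_train:]
    test_repeats = []
    for _ in range(layout.test_repeats):
        rep = test_signal + _drift(layout.test_run_length, layout.tr,
                                   truth.drift_amplitude, v, rng)
        rep = rep + truth.noise_sigma * rng.standard_normal(rep.shape)
        test_repeats.append(rep)
    return SyntheticResponses(train=train, test_repeats=test_repeats, truth=truth)


def _delay_within_runs(values: np.ndarray, run_lengths: tuple[int, ...], delay: int) -> np.ndarray:
    if delay == 0:
        return values
    out = np.zeros_like(values)
    start = 0
    for length in run_lengths:
        out[start + delay : start + length] = values[start : start + length - delay]
        start += length
    return out
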