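"""Stimulus timing containers.

A narrative stimulus is an ordered sequence of words with presentation
times (seconds, run-relative).  Word timing is the clock that links the
word-rate embedding stream to the TR-rate BOLD recordings: every word has
an onset and an offset, and words are grouped into sentences (used as the
input context for contextual embedding extraction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class WordSequence:
    """Ordered words with onset/offset times and sentence grouping.

    Parameters
    ----------
    words
        Token strings, one per presented word.
    onsets
        Word onset times in seconds, strictly increasing.
    offsets
        Word offset times in seconds; ``offsets[k] >= onsets[k]`` and
        ``offsets[k] <= onsets[k + 1]`` (words do not overlap).
    sentence_ids
        Non-negative, non-decreasing integers partitioning the words into
        contiguous sentences.
    """

    words: tuple[str, ...]
    onsets: np.ndarray
    offsets: np.ndarray
    sentence_ids: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "words", tuple(self.words))
        onsets = np.asarray(self.onsets, dtype=float)
        offsets = np.asarray(self.offsets, dtype=float)
        sids = np.asarray(self.sentence_ids, dtype=int)
        n = len(self.words)
        if not (len(onsets) == len(offsets) == len(sids) == n):
            raise ValueError("words, onsets, offsets, sentence_ids must have equal length")
        if n:
            if np.any(np.diff(onsets) <= 0):
                k = int(np.argmax(np.diff(onsets) <= 0))
                raise ValueError(f"onsets must be strictly increasing (violated at word {k + 1})")
            if np.any(offsets < onsets):
                raise ValueError("offsets must be >= onsets")
            if np.any(offsets[:-1] > onsets[1:]):
                raise ValueError("words overlap: offsets[k] must be <= onsets[k+1]")
            if np.any(sids < 0) or np.any(np.diff(sids) < 0):
                raise ValueError("sentence_ids must be non-negative and non-decreasing")
        object.__setattr__(self, "onsets", onsets)
        object.__setattr__(self, "offsets", offsets)
        object.__setattr__(self, "sentence_ids", sids)

    def __len__(self) -> int:
        return len(self.words)

    @property
    def n_words(self) -> int:
        return len(self.words)

    @property
    def midpoints(self) -> np.ndarray:
        """Anchor time of each word: the midpoint of (onset, offset)."""
        return 0.5 * (self.onsets + self.offsets)

    def sentences(self) -> list[tuple[int, int]]:
        """Half-open ``(start, stop)`` word-index ranges, one per sentence."""
        if not len(self):
            return []
        bounds = np.flatnonzero(np.diff(self.sentence_ids)) + 1
        starts = np.concatenate([[0], bounds])
        stops = np.concatenate([bounds, [len(self)]])
        return list(zip(starts.tolist(), stops.tolist()))


@dataclass(frozen=True)
class RunLayout:
    """Scanning-session layout: run lengths, TR, trimming and test repeats.

    ``train_run_lengths`` are the model-estimation runs (one narrative per
    run); the single test narrative of length ``test_run_length`` TRs is
    presented ``test_repeats`` times and the repeats averaged before model
    evaluation.  ``trim_count`` TRs are truncated from both ends of every
    run to discard the silent padding and onset/offset transients.
    """

    train_run_lengths: tuple[int, ...]
    test_run_length: int
    tr: float = 2.0045
    trim_count: int = 10
    test_repeats: int = 2

    def __post_init__(self) -> None:
        object.__setattr__(self, "train_run_lengths", tuple(int(v) for v in self.train_run_lengths))
        if self.tr <= 0:
            raise ValueError("TR must be positive")
        if self.trim_count < 0:
            raise ValueError("trim_count must be non-negative")
        for i, n in enumerate((*self.train_run_lengths, self.test_run_length)):
            if n <= 2 * self.trim_count:
                raise ValueError(
                    f"run {i} has {n} TRs, not more than 2 x trim_count = {2 * self.trim_count}"
                )
        if self.test_repeats < 1:
            raise ValueError("test_repeats must be >= 1")

    @property
    def n_train_runs(self) -> int:
        return len(self.train_run_lengths)

    @property
    def all_run_lengths(self) -> tuple[int, ...]:
        return (*self.train_run_lengths, self.test_run_length)

    @property
    def n_train_trs(self) -> int:
        return int(sum(self.train_run_lengths))

    def trimmed_lengths(self, lengths: tuple[int, ...] | None = None) -> tuple[int, ...]:
        lengths = self.all_run_lengths if lengths is None else lengths
        return tuple(n - 2 * self.trim_count for n in lengths)

    def run_slices(self, lengths: tuple[int, ...]) -> list[slice]:
        """Slices into a time axis formed by concatenating runs of ``lengths``."""
        edges = np.concatenate([[0], np.cumsum(lengths)])
        return [slice(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])]
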