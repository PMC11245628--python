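"""Contextual word-embedding extraction.

The stimulus embedding M(X) is a p x w matrix: one column per presented
word, rows stacking the unit activations of a contextual language model
(the input-embedding layer plus every transformer layer; for a BERT-base
style model, p = 13 x 768 = 9984).  Words are fed to the model one
sentence at a time (matching the model's pretraining input format) or,
optionally, in fixed rolling windows of words.  Sub-word tokens are
pooled back to one activation per word.

The model itself sits behind a small adapter protocol so the pipeline is
model-agnostic; :class:`MockAdapter` is a deterministic, hash-seeded
stand-in used throughout the test-suite, and :class:`HuggingFaceAdapter`
wraps a real pretrained transformer when one is installed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Protocol

import numpy as np

from .stimulus import WordSequence


class EmbeddingAdapter(Protocol):
    """Contract an embedding model must satisfy.

    ``encode(words)`` runs the model on one input context (a list of
    words) and returns ``(activations, word_ids)`` where ``activations``
    is a list with one ``(n_tokens, width)`` array per layer (input
    embeddings first) and ``word_ids[t]`` is the index into ``words`` of
    the word token ``t`` belongs to.  Every word must receive >= 1 token.
    """

    n_layers: int
    width: int

    def encode(self, words: list[str]) -> tuple[list[np.ndarray], list[int]]: ...


class AlignmentError(ValueError):
    """A word gained no tokens (or tokens map outside the input words)."""


@dataclass(frozen=True)
class StimulusEmbedding:
    """p x w per-word embedding with layer bookkeeping.

    ``layer_slices[k]`` is the row range occupied by layer ``k``;
    ``context_mode`` records how input contexts were formed ("sentence"
    or "rolling"); ``layers_used`` is "all" or "single:<k>".
    """

    matrix: np.ndarray
    layer_slices: tuple[tuple[int, int], ...]
    context_mode: str = "sentence"
    layers_used: str = "all"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2:
            raise ValueError("embedding matrix must be 2-D (p x w)")
        if not np.all(np.isfinite(m)):
            raise ValueError("embedding matrix contains non-finite values")
        if sum(b - a for a, b in self.layer_slices) != m.shape[0]:
            raise ValueError("layer slices must tile the p rows exactly")
        object.__setattr__(self, "matrix", m)

    @property
    def p(self) -> int:
        return self.matrix.shape[0]

    @property
    def w(self) -> int:
        return self.matrix.shape[1]


def pool_subword_tokens(
    token_activations: np.ndarray,
    word_ids: list[int],
    n_words: int,
    policy: str = "mean",
) -> np.ndarray:
    """Pool per-token activations to one activation per word.

    ``policy`` is one of ``mean`` (default), ``first`` or ``last``.
    Raises :class:`AlignmentError` naming the first word that received no
    tokens.
    """
    if policy not in ("mean", "first", "last"):
        raise ValueError(f"unknown pooling policy {policy!r}")
    token_activations = np.asarray(token_activations, dtype=float)
    word_ids_arr = np.asarray(word_ids, dtype=int)
    out = np.empty((n_words, token_activations.shape[1]))
    for w in range(n_words):
        rows = np.flatnonzero(word_ids_arr == w)
        if rows.size == 0:
            raise AlignmentError(f"word {w} received no tokens during tokenization")
        if policy == "mean":
            out[w] = token_activations[rows].mean(axis=0)
        elif policy == "first":
            out[w] = token_activations[rows[0]]
        else:
            out[w] = token_activations[rows[-1]]
    return out


def extract_embeddings(
    seq: WordSequence,
    adapter: EmbeddingAdapter,
    context_mode: str = "sentence",
    layers_used: str = "all",
    pooling: str = "mean",
    rolling_window: int = 64,
) -> StimulusEmbedding:
    """Build the p x w stimulus embedding M(X) for a word sequence.

    With ``context_mode="sentence"`` each sentence (per ``sentence_ids``)
    is one input context.  With ``context_mode="rolling"`` the context of
    word j is the ``rolling_window`` words ending at j (sentence
    boundaries ignored) and only the final word's activation is kept.

    ``layers_used`` is ``"all"`` (stack the input-embedding layer and all
    transformer layers; p = n_layers x width) or ``"single:<k>"`` (keep
    layer k only; p = width).
    """
    if context_mode not in ("sentence", "rolling"):
        raise ValueError(f"unknown context_mode {context_mode!r}")
    layer_pick = _parse_layers(layers_used, adapter.n_layers)

    w = len(seq)
    n_kept = len(layer_pick)
    p = n_kept * adapter.width
    matrix = np.empty((p, w))

    if context_mode == "sentence":
        for start, stop in seq.sentences():
            words = list(seq.words[start:stop])
            cols = _encode_context(adapter, words, layer_pick, pooling)
            matrix[:, start:stop] = cols
    else:
        for j in range(w):
            lo = max(0, j - rolling_window + 1)
            words = list(seq.words[lo : j + 1])
            cols = _encode_context(adapter, words, layer_pick, pooling)
            matrix[:, j] = cols[:, -1]

    slices = tuple(
        (i * adapter.width, (i + 1) * adapter.width) for i in range(n_kept)
    )
    return StimulusEmbedding(
        matrix=matrix, layer_slices=slices, context_mode=context_mode, layers_used=layers_used
    )


def _parse_layers(layers_used: str, n_layers: int) -> list[int]:
    if layers_used == "all":
        return list(range(n_layers))
    if layers_used.startswith("single:"):
        k = int(layers_used.split(":", 1)[1])
        if not 0 <= k < n_layers:
            raise ValueError(f"layer {k} out of range for a {n_layers}-layer adapter")
        return [k]
    raise ValueError(f"layers_used must be 'all' or 'single:<k>', got {layers_used!r}")


def _encode_context(
    adapter: EmbeddingAdapter, words: list[str], layer_pick: list[int], pooling: str
) -> np.ndarray:
    activations, word_ids = adapter.encode(words)
    if len(activations) != adapter.n_layers:
        raise AlignmentError(
            f"adapter returned {len(activations)} layers, declared {adapter.n_layers}"
        )
    per_layer = [
        pool_subword_tokens(activations[k], word_ids, len(words), pooling) for k in layer_pick
    ]
    return np.concatenate(per_layer, axis=1).T  # (p, n_words)


class MockAdapter:
    """Deterministic stand-in embedding model for tests and simulations.

    Each token's activation is a hash-seeded pseudo-random vector that
    depends only on (token string, position in context, layer), so
    repeated calls are bit-identical.  Long words (> 6 characters) are
    split into two sub-word tokens to exercise pooling.
    """

    def __init__(self, n_layers: int = 3, width: int = 8, split_long_words: bool = True):
        self.n_layers = int(n_layers)
        self.width = int(width)
        self.split_long_words = bool(split_long_words)

    def _tokenize(self, words: list[str]) -> tuple[list[str], list[int]]:
        tokens, word_ids = [], []
        for i, word in enumerate(words):
            if self.split_long_words and len(word) > 6:
                cut = len(word) // 2
                pieces = [word[:cut], "##" + word[cut:]]
            else:
                pieces = [word]
            tokens.extend(pieces)
            word_ids.extend([i] * len(pieces))
        return tokens, word_ids

    def _token_vector(self, token: str, position: int, layer: int) -> np.ndarray:
        key = f"{token}|{position}|{layer}".encode()
        seed = int.from_bytes(hashlib.sha256(key).digest()[:4], "little")
        rng = np.random.default_rng(seed)
        return rng.standard_normal(self.width)

    def encode(self, words: list[str]) -> tuple[list[np.ndarray], list[int]]:
        tokens, word_ids = self._tokenize(words)
        layers = [
            np.stack([self._token_vector(tok, pos, k) for pos, tok in enumerate(tokens)])
            for k in range(self.n_layers)
        ]
        return layers, word_ids


class ConstantAdapter:
    """Adapter returning a constant activation everywhere (degenerate tests)."""

    def __init__(self, n_layers: int = 2, width: int = 4, value: float = 1.0):
        self.n_layers = int(n_layers)
        self.width = int(width)
        self.value = float(value)

    def encode(self, words: list[str]) -> tuple[list[np.ndarray], list[int]]:
        acts = np.full((len(words), self.width), self.value)
        return [acts.copy() for _ in range(self.n_layers)], list(range(len(words)))


class HuggingFaceAdapter:
    """Adapter around a pretrained transformer (requires ``transformers``).

    Exposes the input-embedding layer plus every transformer layer of an
    encoder model such as ``bert-base-uncased`` (13 layers x 768 units).
    Imported lazily; nothing in the package or its tests requires it.
    """

    def __init__(self, model_name: str = "bert-base-uncased"):
        try:  # pragma: no cover - optional heavy dependency
            import torch
            from transformers import AutoModel, AutoTokenizer
        except ImportError as exc:  # pragma: no cover
            raise ImportError(
                "HuggingFaceAdapter requires the 'transformers' and 'torch' packages"
            ) from exc
        self._torch = torch
        self._tokenizer = AutoTokenizer.from_pretrained(model_name)
        self._model = AutoModel.from_pretrained(model_name, output_hidden_states=True)
        self._model.eval()
        self.n_layers = self._model.config.num_hidden_layers + 1
        self.width = self._model.config.hidden_size

    def encode(self, words: list[str]) -> tuple[list[np.ndarray], list[int]]:  # pragma: no cover
        enc = self._tokenizer(words, is_split_into_words=True, return_tensors="pt")
        with self._torch.no_grad():
            out = self._model(**enc)
        word_ids_full = enc.word_ids(0)
        keep = [t for t, wid in enumerate(word_ids_full) if wid is not None]
        word_ids = [word_ids_full[t] for t in keep]
        layers = [h[0, keep].numpy() for h in out.hidden_states]
        return layers, word_ids
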