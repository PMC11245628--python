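"""Readers and writers: word-timing TSV, HDF5 arrays, results tables."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .embedding import StimulusEmbedding
from .evaluation import VoxelScores
from .ridge import EncodingModel, HyperparameterSet
from .selectivity import SelectivityResult
from .stimulus import WordSequence

_WORD_COLUMNS = ["word", "onset", "offset", "sentence_id"]


def read_word_timing(path: str | Path) -> WordSequence:
    """Read a word-timing TSV (columns word/onset/offset/sentence_id).

    Malformed rows are reported with their (1-based, header-exclusive)
    line numbers; non-monotone onsets raise naming the first violation.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _WORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    for col in ("onset", "offset"):
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            raise ValueError(f"{path}: non-numeric {col} at row {bad[0] + 1}")
    onsets = df["onset"].to_numpy(float)
    if len(onsets) > 1:
        viol = np.flatnonzero(np.diff(onsets) <= 0)
        if viol.size:
            raise ValueError(
                f"{path}: onsets not strictly increasing at row {viol[0] + 2}"
            )
    return WordSequence(
        words=tuple(str(w) for w in df["word"]),
        onsets=onsets,
        offsets=df["offset"].to_numpy(float),
        sentence_ids=df["sentence_id"].to_numpy(int),
    )


def write_word_timing(seq: WordSequence, path: str | Path) -> None:
    pd.DataFrame(
        {
            "word": list(seq.words),
            "onset": seq.onsets,
            "offset": seq.offsets,
            "sentence_id": seq.sentence_ids,
        }
    ).to_csv(path, sep="\t", index=False)


def write_embedding_h5(emb: StimulusEmbedding, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("M", data=emb.matrix)
        f.attrs["layer_slices"] = np.asarray(emb.layer_slices)
        f.attrs["context_mode"] = emb.context_mode
        f.attrs["layers_used"] = emb.layers_used


def read_embedding_h5(path: str | Path) -> StimulusEmbedding:
    with h5py.File(path, "r") as f:
        return StimulusEmbedding(
            matrix=f["M"][()],
            layer_slices=tuple(tuple(int(v) for v in row) for row in f.attrs["layer_slices"]),
            context_mode=str(f.attrs["context_mode"]),
            layers_used=str(f.attrs["layers_used"]),
        )


def write_array_h5(path: str | Path, name: str, array: np.ndarray, **attrs) -> None:
    with h5py.File(path, "a") as f:
        if name in f:
            del f[name]
        ds = f.create_dataset(name, data=array)
        for key, value in attrs.items():
            ds.attrs[key] = value


def read_array_h5(path: str | Path, name: str) -> tuple[np.ndarray, dict]:
    with h5py.File(path, "r") as f:
        ds = f[name]
        return ds[()], dict(ds.attrs)


def write_model_h5(model: EncodingModel, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("weights", data=model.weights)
        f.create_dataset("penalties", data=model.hypers.penalties)
        col_group = np.empty(model.weights.shape[1], dtype=np.int64)
        for g, cols in enumerate(model.design_groups):
            col_group[cols] = g
        f.create_dataset("column_group", data=col_group)
        f.attrs["group_names"] = [str(n) for n in model.hypers.group_names]
        f.attrs["stage"] = model.hypers.stage
        if model.hypers.cv_loss is not None:
            f.create_dataset("cv_loss", data=model.hypers.cv_loss)
        if model.band_cols is not None:
            col_band = np.empty(model.weights.shape[1], dtype=np.int64)
            for b, cols in enumerate(model.band_cols):
                col_band[cols] = b
            f.create_dataset("column_band", data=col_band)
            f.attrs["band_names"] = [str(n) for n in (model.band_names or [])]


def read_model_h5(path: str | Path) -> EncodingModel:
    with h5py.File(path, "r") as f:
        col_group = f["column_group"][()]
        groups = [np.flatnonzero(col_group == g) for g in range(col_group.max() + 1)]
        hypers = HyperparameterSet(
            penalties=f["penalties"][()],
            groups=groups,
            group_names=[str(n) for n in f.attrs["group_names"]],
            cv_loss=f["cv_loss"][()] if "cv_loss" in f else None,
            stage=str(f.attrs["stage"]),
        )
        band_cols = band_names = None
        if "column_band" in f:
            col_band = f["column_band"][()]
            band_cols = [np.flatnonzero(col_band == b) for b in range(col_band.max() + 1)]
            band_names = [str(n) for n in f.attrs.get("band_names", [])]
        return EncodingModel(
            weights=f["weights"][()],
            design_groups=groups,
            hypers=hypers,
            band_cols=band_cols,
            band_names=band_names,
        )


def scores_frame(scores: VoxelScores) -> pd.DataFrame:
    names = scores.band_names or [f"band{i + 1}" for i in range(scores.split.shape[0])]
    data = {"voxel": np.arange(scores.r.size), "r": scores.r}
    for i, name in enumerate(names):
        data[f"r_split[{name}]"] = scores.split[i]
    data["r_all"] = scores.r_all
    if scores.p is not None:
        data["p"] = scores.p
        data["q"] = scores.q
        data["selective"] = scores.selective.astype(int)
    return pd.DataFrame(data)


def write_scores_tsv(scores: VoxelScores, path: str | Path) -> None:
    scores_frame(scores).to_csv(path, sep="\t", index=False, float_format="%.10g")


def selectivity_frame(result: SelectivityResult) -> pd.DataFrame:
    data = {"voxel": np.arange(result.tbar.size), "tbar": result.tbar,
            "defined": result.defined.astype(int)}
    for i in range(result.profile.shape[1]):
        data[f"profile[{i + 1}]"] = result.profile[:, i]
    return pd.DataFrame(data)


def write_selectivity_tsv(result: SelectivityResult, path: str | Path) -> None:
    selectivity_frame(result).to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_filter_taps_tsv(taps: np.ndarray, band_names: list[str], path: str | Path) -> None:
    pd.DataFrame(taps.T, columns=band_names).to_csv(path, sep="\t", index=False)
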