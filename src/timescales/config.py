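"""Structured pipeline configuration with YAML round-trip."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """Every tunable constant of the pipeline, with validated defaults.

    Filtering
    ---------
    band_edges : period-range edges in words (9 edges -> 8 bands).
    n_taps : FIR length in words (odd).
    filter_center : "arithmetic" or "geometric" cosine centre frequency.

    Temporal alignment
    ------------------
    samples_per_tr : dense interpolation grid density.
    rbf_sigma : Gaussian kernel width in seconds (None = mean inter-word
        interval of each run).
    trim : TRs truncated from each run edge.
    delays : FIR delays in TRs.
    detrend : remove slow drift from responses (Savitzky-Golay).

    Hyperparameter search
    ---------------------
    n_candidates x n_scales combinations; scale_range log-spaced;
    dirichlet_alpha concentration; top_frac of voxels refined for up to
    refine_iters gradient steps; group_delays treats each (space, delay)
    pair as its own regularization group.

    Evaluation
    ----------
    n_perm blockwise permutations in blocks of ``block`` TRs; FDR at
    ``alpha``.

    Synthetic data
    --------------
    Scan layout, word statistics, embedding dimensionality and response
    noise of the simulated experiment.
    """

    # filter bank
    band_edges: tuple[float, ...] = (2, 4, 8, 16, 32, 64, 128, 256, 512)
    n_taps: int = 2049
    filter_center: str = "arithmetic"
    # temporal alignment
    samples_per_tr: int = 25
    rbf_sigma: float | None = None
    trim: int = 10
    delays: tuple[int, ...] = (1, 2, 3, 4)
    detrend: bool = True
    # hyperparameter search
    n_candidates: int = 1000
    n_scales: int = 10
    scale_range: tuple[float, float] = (1e-5, 1e5)
    dirichlet_alpha: float = 1.0
    top_frac: float = 0.2
    refine_iters: int = 1000
    group_delays: bool = False
    # evaluation
    n_perm: int = 1000
    block: int = 10
    alpha: float = 0.05
    # synthetic experiment
    n_train_runs: int = 6
    train_run_len: int = 300
    test_run_len: int = 300
    tr: float = 2.0045
    test_repeats: int = 2
    silence_seconds: float = 10.0
    mean_interval: float = 0.4
    jitter: float = 0.3
    sentence_len_mean: float = 12.0
    dims_per_band: int = 2
    embed_amp: float = 1.0
    embed_noise: float = 0.1
    n_voxels: int = 200
    noise_sigma: float = 1.0
    drift_amplitude: float = 0.5
    allow_nonstandard_bands: bool = False

    def __post_init__(self) -> None:
        self.band_edges = tuple(float(e) for e in self.band_edges)
        self.delays = tuple(int(d) for d in self.delays)
        self.scale_range = tuple(float(s) for s in self.scale_range)
        if len(self.band_edges) != 9 and not self.allow_nonstandard_bands:
            raise ValueError(
                f"{len(self.band_edges) - 1} bands configured; the selectivity analysis "
                "requires exactly 8 language bands (set allow_nonstandard_bands to override)"
            )
        positive = {
            "n_taps": self.n_taps, "samples_per_tr": self.samples_per_tr,
            "n_candidates": self.n_candidates, "n_scales": self.n_scales,
            "n_perm": self.n_perm, "block": self.block, "alpha": self.alpha,
            "n_train_runs": self.n_train_runs, "train_run_len": self.train_run_len,
            "test_run_len": self.test_run_len, "tr": self.tr,
            "mean_interval": self.mean_interval, "n_voxels": self.n_voxels,
            "dims_per_band": self.dims_per_band, "test_repeats": self.test_repeats,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if not 0 < self.top_frac <= 1:
            raise ValueError("top_frac must lie in (0, 1]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.trim < 0 or self.refine_iters < 0:
            raise ValueError("trim and refine_iters must be non-negative")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("band_edges", "delays", "scale_range"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
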