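"""End-to-end pipeline driver.

Chains the stages — synthetic stimulus generation (or supplied data),
timescale filtering, temporal alignment, banded-ridge fitting,
evaluation, selectivity estimation and cross-condition comparison — with
one seed controlling every source of randomness, so any run is exactly
reproducible.

The synthetic experiment mirrors a full narrative-fMRI design at desk scale:
several training runs plus one test run presented twice per condition,
two "conditions" (e.g. reading vs listening) sharing the same per-voxel
ground-truth band weights but realised with independent stimuli and
noise.  Parameter recovery across that pair validates every stage
jointly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import io as tio
from .alignment import (
    add_fir_delays,
    average_test_repeats,
    preprocess_bold,
    resample_run,
    trim_runs,
    zscore_features,
)
from .config import PipelineConfig
from .evaluation import VoxelScores, predict, score_voxels
from .filterbank import BandSpec, FilterBank, apply_filter_bank, design_filter_bank
from .ridge import (
    BandedDesign,
    EncodingModel,
    build_design,
    gradient_refine,
    make_cv_folds,
    random_search,
    solve_banded_ridge,
)
from .selectivity import (
    ComparisonResult,
    SelectivityResult,
    compare_selectivity,
    compute_selectivity,
    per_band_comparison,
    profile_correlation,
)
from .stimulus import RunLayout, WordSequence
from .synthetic import (
    SyntheticGroundTruth,
    SyntheticResponses,
    generate_band_limited_embedding,
    generate_voxel_responses,
    generate_word_sequence,
    one_hot_truth,
)

logger = logging.getLogger(__name__)


def config_bands(cfg: PipelineConfig) -> list[BandSpec]:
    edges = cfg.band_edges
    return [BandSpec(lo, hi) for lo, hi in zip(edges[:-1], edges[1:])]


def make_layout(cfg: PipelineConfig) -> RunLayout:
    return RunLayout(
        train_run_lengths=(cfg.train_run_len,) * cfg.n_train_runs,
        test_run_length=cfg.test_run_len,
        tr=cfg.tr,
        trim_count=cfg.trim,
        test_repeats=cfg.test_repeats,
    )


@dataclass
class SyntheticDataset:
    """One condition's simulated stimuli, features and responses."""

    layout: RunLayout
    sequences: list[WordSequence]  # training runs then the test run
    bank: FilterBank
    band_assignment: np.ndarray
    band_features: list[np.ndarray]  # per band, (sum of all run lengths, p)
    responses: SyntheticResponses
    truth: SyntheticGroundTruth


def simulate_condition(
    cfg: PipelineConfig,
    truth: SyntheticGroundTruth,
    stim_seed: int,
    noise_seed: int,
    bank: FilterBank | None = None,
) -> SyntheticDataset:
    """Simulate one condition's stimuli and responses for a given truth.

    Each run gets its own word sequence and band-limited embedding (the
    dimension-to-band assignment is fixed across runs); embeddings are
    filtered into the eight timescale bands and aligned to TR rate, and
    voxel responses are generated from the band features under
    ``truth``.
    """
    layout = make_layout(cfg)
    bands = config_bands(cfg)
    if bank is None:
        bank = design_filter_bank(bands, cfg.n_taps, cfg.filter_center)
    rng = np.random.default_rng(stim_seed)

    sequences: list[WordSequence] = []
    per_run_features: list[list[np.ndarray]] = []  # run -> band -> (n_trs, p)
    assignment = None
    for n_trs in layout.all_run_lengths:
        duration = n_trs * layout.tr
        n_words = int((duration - 2 * cfg.silence_seconds) / cfg.mean_interval)
        seq = generate_word_sequence(
            n_words,
            mean_interval=cfg.mean_interval,
            jitter=cfg.jitter,
            sentence_len_mean=cfg.sentence_len_mean,
            seed=int(rng.integers(2**31 - 1)),
            start_time=cfg.silence_seconds,
        )
        emb, assignment = generate_band_limited_embedding(
            seq,
            bands,
            dims_per_band=cfg.dims_per_band,
            amp=cfg.embed_amp,
            noise=cfg.embed_noise,
            seed=int(rng.integers(2**31 - 1)),
        )
        filtered = apply_filter_bank(emb.matrix, bank)
        # one RBF kernel per run serves all bands: stack, resample, split
        stacked = np.concatenate(filtered, axis=0)
        tr_rate = resample_run(stacked, seq, n_trs, layout.tr, cfg.samples_per_tr, cfg.rbf_sigma)
        p = emb.matrix.shape[0]
        per_run_features.append(
            [tr_rate[:, b * p : (b + 1) * p] for b in range(len(bands))]
        )
        sequences.append(seq)

    band_features = [
        np.concatenate([run[b] for run in per_run_features], axis=0)
        for b in range(len(bands))
    ]
    responses = generate_voxel_responses(band_features, truth, layout, noise_seed=noise_seed)
    return SyntheticDataset(
        layout=layout,
        sequences=sequences,
        bank=bank,
        band_assignment=assignment,
        band_features=band_features,
        responses=responses,
        truth=truth,
    )


@dataclass
class PreparedData:
    """Trimmed, z-scored, delayed design plus preprocessed responses."""

    design: BandedDesign
    F_train: np.ndarray
    F_test: np.ndarray
    Y_train: np.ndarray
    Y_test: np.ndarray
    layout: RunLayout
    band_names: list[str]


def prepare_data(dataset: SyntheticDataset, cfg: PipelineConfig) -> PreparedData:
    """Align features and responses for model fitting.

    Features: trim -> z-score (training statistics only) -> FIR delays.
    Responses: trim -> optional drift removal -> per-run z-scoring; the
    test repeats are each preprocessed then averaged.
    """
    layout = dataset.layout
    all_lengths = layout.all_run_lengths
    trimmed_all = layout.trimmed_lengths()
    trimmed_train = layout.trimmed_lengths(layout.train_run_lengths)
    n_train = sum(trimmed_train)
    train_mask = np.zeros(sum(trimmed_all), dtype=bool)
    train_mask[:n_train] = True

    band_names = [str(b) for b in dataset.bank.bands]
    delayed_bands, tags = [], []
    for feats in dataset.band_features:
        trimmed = trim_runs(feats, all_lengths, layout.trim_count)
        z, *_ = zscore_features(trimmed, train_mask)
        delayed, tag = add_fir_delays(z, trimmed_all, cfg.delays)
        delayed_bands.append(delayed)
        tags.append(tag)
    design = build_design(delayed_bands, band_names, tags, group_delays=cfg.group_delays)

    resp = dataset.responses
    y_train = trim_runs(resp.train, layout.train_run_lengths, layout.trim_count)
    y_train = preprocess_bold(y_train, trimmed_train, layout.tr, detrend=cfg.detrend)
    test_len = layout.trimmed_lengths((layout.test_run_length,))
    reps = [
        preprocess_bold(
            trim_runs(rep, (layout.test_run_length,), layout.trim_count),
            test_len,
            layout.tr,
            detrend=cfg.detrend,
        )
        for rep in resp.test_repeats
    ]
    y_test = average_test_repeats(*reps)

    return PreparedData(
        design=design,
        F_train=design.F[:n_train],
        F_test=design.F[n_train:],
        Y_train=y_train,
        Y_test=y_test,
        layout=layout,
        band_names=band_names,
    )


def fit_encoding_model(prep: PreparedData, cfg: PipelineConfig, seed: int) -> EncodingModel:
    """Two-stage hyperparameter search plus the final banded-ridge solve."""
    folds = make_cv_folds(prep.layout)
    logger.info(
        "random search: %d candidates x %d scales over %d groups",
        cfg.n_candidates, cfg.n_scales, prep.design.n_groups,
    )
    hypers = random_search(
        prep.F_train,
        prep.Y_train,
        prep.design.reg_groups,
        folds,
        group_names=prep.design.reg_group_names,
        n_candidates=cfg.n_candidates,
        n_scales=cfg.n_scales,
        scale_range=cfg.scale_range,
        dirichlet_alpha=cfg.dirichlet_alpha,
        seed=seed,
    )
    if cfg.refine_iters > 0:
        logger.info("gradient refinement of the best %.0f%% voxels", 100 * cfg.top_frac)
        hypers = gradient_refine(
            prep.F_train,
            prep.Y_train,
            prep.design.reg_groups,
            folds,
            hypers,
            top_frac=cfg.top_frac,
            n_iter=cfg.refine_iters,
        )
    model = solve_banded_ridge(prep.F_train, prep.Y_train, hypers)
    model.band_cols = prep.design.band_cols
    model.band_names = prep.band_names
    return model


@dataclass
class ConditionResult:
    """Everything computed for one condition."""

    dataset: SyntheticDataset
    prep: PreparedData
    model: EncodingModel
    scores: VoxelScores
    selectivity: SelectivityResult

    def null_inputs(self) -> tuple[list[np.ndarray], np.ndarray, np.ndarray]:
        """(language-band predictions, joint prediction, test responses)."""
        yhat_bands, yhat = predict(self.model, self.prep.F_test, self.model.band_cols)
        return yhat_bands[:8], yhat, self.prep.Y_test


def run_condition(
    cfg: PipelineConfig,
    truth: SyntheticGroundTruth,
    stim_seed: int,
    noise_seed: int,
    search_seed: int,
    perm_seed: int,
    bank: FilterBank | None = None,
) -> ConditionResult:
    """Simulate, fit, evaluate and estimate selectivity for one condition."""
    logger.info("simulating condition (stim_seed=%d)", stim_seed)
    dataset = simulate_condition(cfg, truth, stim_seed, noise_seed, bank=bank)
    prep = prepare_data(dataset, cfg)
    logger.info("fitting encoding model (%d x %d design)", *prep.F_train.shape)
    model = fit_encoding_model(prep, cfg, search_seed)
    logger.info("evaluating on the held-out test run")
    scores = score_voxels(
        model,
        prep.F_test,
        prep.Y_test,
        model.band_cols,
        language_bands=np.arange(8),
        n_perm=cfg.n_perm,
        block=cfg.block,
        alpha=cfg.alpha,
        seed=perm_seed,
        band_names=prep.band_names,
    )
    sel = compute_selectivity(scores.split[:8], dataset.bank.timescales[:8])
    return ConditionResult(dataset=dataset, prep=prep, model=model, scores=scores,
                           selectivity=sel)


@dataclass
class PipelineResult:
    """Bundle of both conditions and their comparison."""

    condition_a: ConditionResult
    condition_b: ConditionResult
    joint_mask: np.ndarray
    comparison: ComparisonResult
    per_band_r: np.ndarray
    per_band_p: np.ndarray
    profile_r: np.ndarray
    truth: SyntheticGroundTruth
    config: PipelineConfig


def derive_seeds(seed: int, n: int = 10) -> np.ndarray:
    """Deterministic per-stage sub-seeds from one master seed."""
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


def shuffled_truth(truth: SyntheticGroundTruth, seed: int) -> SyntheticGroundTruth:
    """Permute the band-weight rows across voxels (null truth sharing)."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(truth.n_voxels)
    return SyntheticGroundTruth(
        band_weights=truth.band_weights[perm],
        timescales=truth.timescales,
        noise_sigma=truth.noise_sigma,
        drift_amplitude=truth.drift_amplitude,
        seed=truth.seed,
    )


def run_pipeline(
    cfg: PipelineConfig,
    seed: int = 0,
    out_dir: str | Path | None = None,
    truth_b: SyntheticGroundTruth | None = None,
    comparison_perms: int | None = None,
) -> PipelineResult:
    """Full synthetic experiment: two conditions sharing ground truth.

    Both conditions use the same per-voxel band weights (``truth_b``
    overrides condition B's truth, e.g. for a shuffled-truth null) but
    independent stimuli and noise.  Selectivity is compared across
    voxels selective in both conditions.  With ``out_dir`` set, all
    stage artifacts (config, models, score and selectivity tables,
    comparison report) are written as they are produced.
    """
    seeds = derive_seeds(seed)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        cfg.to_yaml(out / "config.yaml")

    bands = config_bands(cfg)
    bank = design_filter_bank(bands, cfg.n_taps, cfg.filter_center)
    timescales = bank.timescales[:8]
    truth = one_hot_truth(
        cfg.n_voxels, timescales, cfg.noise_sigma, cfg.drift_amplitude, seed=int(seeds[0])
    )

    results: list[ConditionResult] = []
    for label, cond_truth, k in (("a", truth, 1), ("b", truth_b or truth, 2)):
        res = run_condition(
            cfg,
            cond_truth,
            stim_seed=int(seeds[2 * k]),
            noise_seed=int(seeds[2 * k + 1]),
            search_seed=int(seeds[6]) + k,
            perm_seed=int(seeds[7]) + k,
            bank=bank,
        )
        results.append(res)
        if out is not None:
            tio.write_model_h5(res.model, out / f"model_{label}.h5")
            tio.write_scores_tsv(res.scores, out / f"scores_{label}.tsv")
            tio.write_selectivity_tsv(res.selectivity, out / f"selectivity_{label}.tsv")
    res_a, res_b = results

    mask = (
        res_a.scores.selective
        & res_b.scores.selective
        & res_a.selectivity.defined
        & res_b.selectivity.defined
    )
    logger.info("comparing selectivity over %d jointly selective voxels", int(mask.sum()))
    n_perm = cfg.n_perm if comparison_perms is None else comparison_perms
    if mask.sum() >= 3:
        comparison = compare_selectivity(
            res_a.selectivity.tbar,
            res_b.selectivity.tbar,
            mask,
            null_a=res_a.null_inputs(),
            null_b=res_b.null_inputs(),
            timescales=timescales,
            n_perm=n_perm,
            block=cfg.block,
            seed=int(seeds[8]),
        )
        band_r, band_p = per_band_comparison(
            res_a.selectivity.profile,
            res_b.selectivity.profile,
            mask,
            null_a=res_a.null_inputs(),
            null_b=res_b.null_inputs(),
            timescales=timescales,
            n_perm=n_perm,
            block=cfg.block,
            seed=int(seeds[9]),
        )
        prof_r = profile_correlation(
            res_a.selectivity.profile, res_b.selectivity.profile, mask
        )
    else:
        logger.warning("fewer than 3 jointly selective voxels; comparison undefined")
        comparison = ComparisonResult(r=np.nan, p=np.nan, null=np.empty(0))
        band_r = band_p = np.full(8, np.nan)
        prof_r = np.full(cfg.n_voxels, np.nan)

    result = PipelineResult(
        condition_a=res_a,
        condition_b=res_b,
        joint_mask=mask,
        comparison=comparison,
        per_band_r=band_r,
        per_band_p=band_p,
        profile_r=prof_r,
        truth=truth,
        config=cfg,
    )
    if out is not None:
        _write_comparison(result, out / "comparison.tsv")
    return result


@dataclass
class RecoveryReport:
    """Parameter-recovery metrics of the synthetic two-condition experiment."""

    adjacent_fraction: float
    spearman_log_timescale: float
    shared_truth_r: float
    shared_truth_p: float
    shuffled_truth_r: float
    n_selective_a: int
    n_joint_shared: int
    n_joint_shuffled: int


def recovery_config(**overrides) -> PipelineConfig:
    """Desk-scale parameter-recovery configuration.

    Six 300-TR training runs, one 300-TR test run presented twice, 200
    voxels with one-hot band truth cycling through all eight bands at
    response SNR 1.0; the hyperparameter search is reduced to 100
    Dirichlet candidates x 10 scales with capped gradient refinement to
    keep a full two-condition experiment tractable on one CPU.
    """
    base = dict(
        n_train_runs=6, train_run_len=300, test_run_len=300, n_voxels=200,
        noise_sigma=1.0, n_candidates=100, n_scales=10, refine_iters=30,
        n_perm=500,
    )
    base.update(overrides)
    return PipelineConfig(**base)


def run_recovery_experiment(cfg: PipelineConfig, seed: int = 0) -> tuple[RecoveryReport, PipelineResult]:
    """Three-condition recovery experiment: shared truth and shuffled null.

    Runs condition pair (A, B) under the same ground truth and a third
    condition C whose band weights are shuffled across voxels, then
    measures: (a) how often the profile argmax of a selective voxel hits
    the true or an adjacent band, (b) the Spearman correlation between
    true and estimated log timescale, (c) the cross-condition T-bar
    correlation for shared truth (expected high) and shuffled truth
    (expected near zero).
    """
    from scipy.stats import spearmanr

    result = run_pipeline(cfg, seed=seed)
    res_a = result.condition_a
    truth = result.truth

    sel = res_a.scores.selective & res_a.selectivity.defined
    profile = res_a.selectivity.profile
    est_band = np.nanargmax(np.where(np.isnan(profile), -np.inf, profile), axis=1)
    adjacent = np.abs(est_band - truth.dominant_band) <= 1
    adjacent_fraction = float(adjacent[sel].mean()) if sel.any() else np.nan
    spearman = (
        float(
            spearmanr(
                np.log(truth.true_timescale[sel]), np.log(res_a.selectivity.tbar[sel])
            ).statistic
        )
        if sel.sum() >= 3
        else np.nan
    )

    # condition C: same experiment but band weights shuffled across voxels
    seeds = derive_seeds(seed)
    truth_c = shuffled_truth(truth, seed=int(seeds[9]) + 1)
    res_c = run_condition(
        cfg,
        truth_c,
        stim_seed=int(seeds[4]) + 7,
        noise_seed=int(seeds[5]) + 7,
        search_seed=int(seeds[6]) + 7,
        perm_seed=int(seeds[7]) + 7,
        bank=res_a.dataset.bank,
    )
    mask_c = (
        res_a.scores.selective
        & res_c.scores.selective
        & res_a.selectivity.defined
        & res_c.selectivity.defined
    )
    if mask_c.sum() >= 3:
        shuffled_cmp = compare_selectivity(
            res_a.selectivity.tbar, res_c.selectivity.tbar, mask_c
        )
        shuffled_r = shuffled_cmp.r
    else:
        shuffled_r = np.nan

    report = RecoveryReport(
        adjacent_fraction=adjacent_fraction,
        spearman_log_timescale=spearman,
        shared_truth_r=result.comparison.r,
        shared_truth_p=result.comparison.p,
        shuffled_truth_r=shuffled_r,
        n_selective_a=int(sel.sum()),
        n_joint_shared=int(result.joint_mask.sum()),
        n_joint_shuffled=int(mask_c.sum()),
    )
    return report, result


def _write_comparison(result: PipelineResult, path: Path) -> None:
    import pandas as pd

    rows = [{"statistic": "tbar_correlation", "value": result.comparison.r,
             "p": result.comparison.p}]
    for i, (r, p) in enumerate(zip(result.per_band_r, result.per_band_p)):
        rows.append({"statistic": f"band{i + 1}_correlation", "value": r, "p": p})
    rows.append({"statistic": "n_joint_selective", "value": int(result.joint_mask.sum()),
                 "p": np.nan})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")
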