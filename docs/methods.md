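# Methods

`timescales` estimates, for every fMRI voxel, the *language timescale*
it is selective for — the characteristic period, measured in words, of
the stimulus information that drives its BOLD response — and compares
that selectivity between stimulus conditions (e.g. reading vs
listening the same narratives).  This note documents the model, the
numerical choices, and what the synthetic validation does and does not
establish.

## Model

### Timescale-specific feature spaces

A narrative stimulus of `w` words is embedded by a contextual language
model into a `p × w` matrix `M(X)` (one column per word; with a
BERT-base-style encoder and all layers retained, `p = 13 × 768 =
9984`).  A language timescale is operationalised spectrally: the
components of `M(X)` whose period in *word index* falls in one of
eight octave ranges — 2–4, 4–8, 8–16, 16–32, 32–64, 64–128, 128–256
and 256+ words.  Each band `i` is extracted by an FIR filter `b_i`
designed by the window method: a cosine at the band-centre frequency
`f_i = 1/t_i` cycles/word multiplied by a Blackman window, normalised
to unit peak gain.  The nominal timescale is the arithmetic centre
`t_i = (p_low + p_high)/2`, giving `t = (3, 6, 12, 24, 48, 96, 192,
384)` words.  Convolving `M(X)` with each filter (centred, so zero
phase; mirror-padded at both ends) yields eight filtered embeddings
`M_i(X)` of the same shape.

The open-ended top band ("256+ words") is closed at 512 words by
octave continuation, giving `t_8 = 384`; the scalar selectivity
(below) needs a finite `t_8`, and any choice above the run length is
unidentifiable anyway.  Both the closure and the choice of arithmetic
vs geometric band centres are configurable.

### Temporal alignment

Words arrive at a variable rate, so the word-rate streams are aligned
to the scanner clock in two steps.  First, normalised Gaussian-RBF
(Nadaraya–Watson) interpolation evaluates each channel on a uniform
grid of 25 samples per TR, anchored at word midpoint times; the
normalisation is a partition of unity, so constants are reproduced
exactly and silent gaps decay to local averages rather than to zero.
The kernel width defaults to the run's mean inter-word interval.
Second, an anti-aliasing 3-lobe Lanczos filter with cut-off at the
fMRI Nyquist rate (0.25 Hz) resamples the dense signal to the middle
time point of each TR; weights are renormalised per output sample so
DC gain is exactly 1.

Per run, the first and last 10 TRs are truncated (silence padding,
onset/offset transients).  Features are z-scored per channel with
statistics computed on the *training* runs only, mirroring the
z-scoring of the MRI data without test-set leakage; zero-variance
channels are zeroed and flagged.  Finally each channel is duplicated
at FIR delays of 1–4 TRs (≈2–8 s, absorbing the hemodynamic lag);
shifts zero-fill at run starts and never cross run boundaries.
Ordering: responses are trimmed, then (optionally) detrended by
subtracting a third-order Savitzky–Golay smooth with a ~120-s window
(nearest odd TR count, 59 at TR ≈ 2 s), then z-scored per run; the
twice-presented test run is preprocessed per repeat and the repeats
averaged.  Features are trimmed → z-scored → delayed.  Feature spaces
already sampled at TR rate (sensory nuisance regressors) skip
interpolation but share trimming, z-scoring and delays.

### Banded ridge regression

The concatenated design `F'` (all bands, all delays) maps to voxel
responses `Y` by per-voxel weights minimising
`‖y − F'w‖² + Σ_g pen_g ‖w_g‖²`, one penalty per feature-space group
`g`.  A single overall penalty would bias weights when feature spaces
differ in scale or dimensionality; per-group penalties also act as
soft feature selection.  The solver rescales group `g`'s columns by
`pen_g^{-1/2}` and solves unit-penalty ridge (primal when `D ≤ n`,
dual otherwise), which is algebraically exact.

Penalties are chosen per voxel by leave-one-run-out cross-validation
(each fold validates on exactly one training run) in two stages:

1. **Random search.**  `n_candidates` group weightings `γ` are drawn
   from a Dirichlet distribution (concentration α = 1, uniform on the
   simplex) and crossed with 10 log-spaced overall scales in
   [1e−5, 1e5]; a candidate (γ, λ) corresponds to penalties `λ/γ_g`.
   Every (candidate, scale) pair is scored by summed validation
   squared error; for each candidate the scaled Gram matrix is
   eigendecomposed once per fold, so all scales share one spectral
   filter.  Each voxel keeps its loss-minimising combination.
2. **Gradient refinement.**  The voxels in the lowest 20% of stage-1
   CV loss are refined by backtracking gradient descent on the
   log-penalties, using the analytic gradient of the leave-one-run-out
   loss (`∂SSE/∂pen_j = −2 (A⁻¹X_v'r)_j w_j` with `A = X'X +
   diag(pen)`).  Steps that would increase the loss are halved, so the
   refined loss is never worse than stage 1; iteration stops at
   stationarity (relative improvement < 1e-6) or after `n_iter` steps.

The regularization grouping defaults to one group per feature space
(delays concatenated within a space), the standard banded-ridge
practice; a finer space × delay grouping is available
(`group_delays=True`) for users who want independent penalties per
delay, at the cost of a much higher-dimensional simplex for the random
search to cover.

### Evaluation and selectivity

On the held-out test run, per-band predictions `Ŷ_i` use only band
`i`'s weight columns, and the joint prediction is their exact sum.
Joint performance `r` is the per-voxel Pearson correlation; the
split-prediction performance

    r̃_i = Σ_t Ŷ_i[t]·Y[t] / sqrt(Σ_t Ŷ[t]² · Σ_t Y[t]²)

(signals mean-centred per voxel; note the *joint* prediction in the
denominator) decomposes it exactly: `Σ_i r̃_i = r`.  Negative
contributions are retained.  `r̃_all` sums the eight language bands,
excluding nuisance spaces.

Language-selective voxels: the test-response timecourse is reordered
in blocks of 10 TRs (preserving short-range autocorrelation; the final
short block is kept intact) 1000 times; each reordering yields a null
`r̃_all`, and `p = (1 + #{null ≥ observed}) / (1 + n_perm)` (one-sided,
add-one smoothed so p > 0).  Benjamini–Hochberg FDR is applied within
participant × condition; the selective set is `q < 0.05`.

The timescale selectivity profile rectifies and normalises the split
performances, `r̃'_i = max(0, r̃_i) / Σ_j max(0, r̃_j)`; voxels with no
positive split performance have an undefined profile and are excluded
(flagged) rather than assigned an arbitrary value.  The scalar
timescale selectivity is the profile-weighted geometric mean of the
nominal timescales, `T̄ = 2^(Σ_i r̃'_i log₂ t_i)`, bounded by `t_1` and
`t_8`.

### Cross-condition comparison

Across voxels selective (and defined) in both conditions, T̄ is
compared by Pearson correlation of the raw values (a log-domain option
exists; raw is the default because T̄ is reported in words).  The
permutation null shuffles each condition's test responses blockwise,
recomputes null T̄ per condition, and correlates the null values
between conditions — so the null preserves each condition's
prediction structure while destroying the temporal match.  Per-band
selectivity and per-voxel profile correlations are compared the same
way.  Group-level aggregation (for subjects on a shared vertex grid)
averages values over the subjects in which a vertex is selective and
keeps vertices selective in at least one-third of subjects (ceiling).

## Synthetic data and what the tests show

The generator emulates the structure of a narrative fMRI experiment:

* **word timing** — log-normal inter-word intervals (mean 0.4 s, CV
  0.3; positive and right-skewed like natural narration), contiguous
  sentences of mean length 12 words, 10 s of silence per run edge;
* **embeddings** — each dimension a sinusoid in word index with period
  drawn uniformly inside an assigned band (2 dimensions per band by
  default) plus white noise (s.d. 0.1), so the spectral content per
  dimension is known by construction;
* **responses** — linear in the TR-rate band features (delayed 2 TRs
  to emulate hemodynamic lag) through per-voxel random projections
  scaled by the voxel's band weights; signal standardised per voxel,
  then slow cosine drift (periods > 120 s — the removable target of
  the Savitzky–Golay detrend; amplitude 0.5) and white noise added.
  Response SNR defaults to 1.0 (noise s.d. 1 per unit signal s.d.).
  Two conditions generated under the same truth share their projection
  vectors (same voxel tuning) but use independent stimuli and noise.

The recovery experiment uses 6 training runs × 300 TRs, one test run
presented twice, TR = 2.0045 s, and 200 voxels with one-hot band truth
cycling through all eight bands; the hyperparameter search is reduced
to 100 candidates × 10 scales with at most 30 refinement iterations
and 500 permutations, sizes chosen so a full three-condition
experiment (shared truth, shared truth replicate, shuffled-truth null)
completes in minutes on one CPU.

Passing recovery shows the pipeline is *internally consistent*: when
responses really are linear in band-limited embedding features, the
estimated profiles and T̄ recover the generating band (or an adjacent
band — adjacent confusion is expected because band-edge periods leak
into neighbouring filters), T̄ ranks voxels correctly, and the
cross-condition comparison separates shared from unshared tuning.  It
does **not** show that real BOLD responses are linear in embedding
features, that transformer embedding geometry resembles band-limited
sinusoids, or anything about spatial structure (no hemodynamic
nonlinearity, no voxel correlation, no real tokenizer).  One
systematic feature of the synthetic results mirrors a physical limit:
the two shortest bands (periods 2–8 words ≈ 0.8–3.2 s at this word
rate) lie above the fMRI Nyquist frequency, so their features barely
survive Lanczos downsampling and voxels generated from them are
rarely language-selective; they are excluded by the selectivity mask
rather than mis-assigned.

## Numerical choices

* Filter length defaults to 2049 taps: the longest band (centre period
  384 words) then keeps its DC gain below 1% of peak (1.3e-3); at 1025
  taps the DC lobe of that band reaches 1.04e-2.  The minimum enforced
  is `n_taps ≥ 2 × longest period`, odd.
* Mirror padding uses symmetric reflection including the edge sample,
  repeat-mirrored when the pad exceeds the signal length.
* Zero-variance channels/predictions score 0 with a flag instead of
  propagating NaN; undefined selectivity profiles are NaN and masked.
* Penalties are clipped to `[1e-10, 1e12]` during refinement; Dirichlet
  weights are floored at 1e-10 before inversion.
* Stage-1 losses are aggregated across folds by sum (equivalent to the
  mean for fixed folds).
* The permutation estimator uses add-one smoothing; the FDR step uses
  `q < α` (strict) for the selective mask.
* All randomness flows from explicit integer seeds; per-stage
  sub-seeds are derived from one master seed, so every pipeline output
  is bit-reproducible.

## Known limitations

* The profile `r̃'` is noisier than T̄ (rectification discards negative
  evidence); per-band comparisons are accordingly less stable than T̄
  comparisons.
* Timescales above ~360 words interact with the drift-removal filter:
  the Savitzky–Golay high-pass attenuates response components whose
  period in seconds exceeds the window, biasing the longest band
  downward when word rate is slow.
* The blockwise permutation reorders blocks (rather than circularly
  shifting); with few blocks the null is coarse, and the add-one
  estimator's minimum p is `1/(n_perm + 1)`.
* An entropy-based profile-uniformity helper is deliberately not
  provided: a defensible uniformity metric depends on analysis goals,
  and the profile itself is exported for users who need one.
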