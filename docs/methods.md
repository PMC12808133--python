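# Methods

## Problem and data model

The package predicts the next motor-UPDRS score of a Parkinson's disease
patient from a history window of at-home telemonitoring assessments. The
raw data model is the UCI telemonitoring table dialect: one row per voice
assessment with subject id, age, sex (0 = male, 1 = female), `test_time`
in days since recruitment, motor and total UPDRS, and 16 precomputed
acoustic dysphonia measures (jitter and shimmer families, NHR/HNR, RPDE,
DFA, PPE). Stage labels use the grid Early = [0, 20], Moderate = (20, 40],
Advanced = (40, inf); the half-open convention extends the printed integer
grid (0-20 / 21-40 / 41+) gaplessly to continuous per-patient means.
Monitoring duration is converted at 30.44 days per mean Gregorian month.
Cohort-level acoustic summaries average within patient first, then across
patients, so long records do not dominate.

## Synthetic cohort

`dcan.synthetic` draws cohorts whose structure matches a six-month
telemonitoring study: 42 patients by default, 120-150 visits each at
irregular uniform times over 180 days, age ~ N(64.4, 9.2) truncated to
[40, 90], two-thirds male. Each patient's latent severity is
`s(t) = baseline + slope * t` with baseline ~ U(8, 35) points and slope ~
N(0.02, 0.015) points/day; observed motor UPDRS adds AR(1) visit noise
(rho = 0.7, innovation sd 1.0 points) and is clipped to [0, 60], which
keeps the default cohort in the early-to-moderate regime (essentially no
advanced-stage patients). The AR(1) choice, rather than iid noise, makes
rolling and lag features carry real signal. Each acoustic measure is
`intercept + loading * s(t) + scale * LogNormal(0, 0.5)`; loadings are
positive for the jitter/shimmer/NHR family and negative for HNR, with
intercepts placed so a mid-severity cohort lands near the published
telemonitoring marginals (HNR ~ 21.7 dB, Jitter(%) ~ 0.006, Shimmer ~
0.034).

What the generator does *not* emulate: medication cycles or diurnal
fluctuation, measurement dropout, heteroscedastic noise across severity,
floor effects in individual acoustic measures, or any nonlinearity in the
severity trajectory. Tests passing on this cohort therefore demonstrate
that the pipeline's plumbing, leakage guarantees, optimization and
evaluation behave as designed - not that the model's accuracy transfers
to real telemonitoring data.

## Feature engineering

Four per-visit blocks, aligned to the visit axis:

* **Voice (146 columns).** Each of the 16 base measures expands into raw,
  Savitzky-Golay denoised (window 5, order 2, polynomial boundary
  extrapolation), velocity and acceleration (backward differences over
  actual day gaps, first element 0), trailing rolling mean and sample sd
  (3 visits, min_periods 1), within-patient z-score
  ((x - mean)/(sd + 0.01), clipped to +-5), and trailing rolling skewness
  and excess kurtosis (5 visits); plus a voice-instability index (mean of
  patient-wise min-max-normalized jitter and shimmer) and the voice
  quality ratio HNR/(NHR + 1e-6). Trailing windows are used for all
  rolling statistics so no future visit leaks in; the centered denoiser
  does use up to two later visits of *acoustic* data within the window (a
  documented caveat; `causal_denoise=True` switches to a one-sided fit).
* **Clinical (9 columns), lagged-UPDRS only.** days since first visit,
  visit number, inter-visit interval, lag-1 and lag-2 motor UPDRS, their
  difference, its trailing 3-visit mean, the stage code of the lag-1
  score, and a progression-rate code (worsening/stable/improving at a
  +-0.5-point threshold - below measurement noise, configurable). Head-of-
  series lags are imputed with the first observed score; the window mask
  records which steps are real.
* **Meta (3 columns).** age, sex code, test_time.
* **Text (768 columns).** The patient's narrative embedding (below) tiled
  across timesteps.

Supervised windows take the trailing T = 10 visits ending at each target
visit (every visit index >= 2 is a target; an optional stride subsamples
targets), left-padded with zeros plus a validity mask. T = 10 spans about
six weeks of twice-weekly recordings and is configurable. By construction
no feature cell in the voice/clinical/meta blocks depends on motor UPDRS
at the target visit or later; this is enforced by perturbation tests.

## Narrative context

Per-patient longitudinal statistics (UPDRS mean/sd and per-visit OLS
slope, jitter/shimmer/HNR means and trends, monitoring cadence) fill a
fixed clinical-summary template; the rendered text is encoded to a
768-dim vector and tiled across the window. Label thresholds: severity
mild <= 20 / moderate <= 40 / severe > 40 on the mean score (mirroring the
stage grid); progression pattern from the slope with a +-0.05
points/visit dead-band; variability high iff sd > 5 points; voice trend
"increasing" iff the fitted change over the record exceeds 5% of the
feature's mean; impairment significant if jitter >= 0.01 or shimmer >=
0.06, mild if jitter < 0.004 and shimmer < 0.02, else moderate (common
clinical-voice norm ranges; all configurable).

Two statistic modes: `full_history` (default) computes them over the
complete record, so a window's text block can reflect visits after its
target. Patient-level cross-validation keeps this from contaminating
train/test splits, but within-patient it is future information -
`causal` mode restricts statistics to visits up to each target.

Encoders are pluggable behind a text -> 768-dim contract. The default
backend is a seeded feature-hashing projector (word and bigram tokens
hashed into 768 signed buckets, L2-normalized): fully offline and
deterministic, identical texts map to identical vectors, disjoint
vocabularies are nearly orthogonal, and the template's numeric tokens
shift the vector so different patients get distinct embeddings. The
pretrained `all-mpnet-base-v2` sentence encoder is available as an
optional backend; it produces semantically richer embeddings but requires
the optional dependency and a model download.

## Architecture

All branches map to hidden width h_d = 256 (default):

* voice: two stacked bidirectional LSTM layers (h_d/2 units per
  direction) -> 4-head self-attention (d_k = h_d/4) -> dropout, residual
  add, layer norm;
* clinical / meta / text: two position-wise dense layers with exact GELU
  (x * Phi(x), via erf) -> layer norm;
* **dynamic fusion**: per-modality 4-head self-attention; each attended
  stream is mean-pooled over valid timesteps; the pooled vectors
  concatenate into a context vector h_context in R^{4 h_d}; alpha =
  softmax(W_c h_context + b_c) gives one convex weight per modality; the
  fused sequence is sum_m alpha_m * A_m applied to the *full* attended
  sequences, preserving the T x h_d shape for the temporal block (the
  pooled vectors drive only the weighting). With modalities ablated away,
  the softmax renormalizes over those remaining. alpha is exposed per
  sample for inspection;
* temporal block: two bidirectional LSTM layers with per-layer residual
  connections (a config switch moves the residual around the pair), then
  self-attention under a strictly causal mask (position i attends to
  j <= i only), residual, layer norm. Bidirectional recurrence *within*
  the historical window is intentional: leakage prevention lives in the
  windowing (only past visits enter) and the causal attention mask;
* head: three dense layers (h_d, h_d/2, h_d/4) with GELU and dropout
  0.15, layer norm, linear output neuron on the final-timestep
  representation - one scalar UPDRS prediction per window (per-timestep
  supervision is available behind a flag).

Padded timesteps are zeroed at the input, excluded from attention keys
and from pooling; fully masked attention rows output zeros rather than
NaN so short histories cannot poison gradients. Predictions are exactly
invariant to values stored at padded positions.

Dropout rates: 0.15 on attention/residual paths, 0.2 in dense encoders,
0.3 in the temporal block, 0.15 in the head. L2 penalty lambda = 3e-4 on
dense and recurrent kernels. The ablation preset reduces the model to
hidden 128, dropout 0.2 everywhere, lambda 5e-4, 4 heads.

## Training protocol

Mean Huber loss with delta = 2.0 UPDRS points (quadratic inside the
elbow, linear outside; C1 at the elbow), plus the L2 kernel penalty.
AdamW with decoupled weight decay 0.005 (biases and norm gains excluded),
global gradient-norm clipping at 1.0 applied to the combined gradient,
batch size 16, up to 150 epochs. Learning rate: 3e-4 constant for 10
epochs, 5% decays at epochs 10/20/30, a 10% decay at epoch 60, 15% decays
every 30 epochs from 90 on; on top of the schedule, a plateau callback
halves the rate after 10 non-improving validation epochs (floor 1e-6).
Early stopping (patience 25; 10 in the reduced preset) restores the best
validation weights. The validation holdout is 15% of training *patients*,
never windows, for consistency with the patient-wise evaluation stance.

Scaling is fitted on training data only: voice, meta and numeric clinical
columns are centered at the median and scaled by the IQR (columns with
IQR < 1e-9 get scale 1) with post-scaling clipping to [-5, 5]; the two
categorical clinical codes pass through; text embeddings are mean-
centered only (full standardization behind a flag). Internally the
regression target is standardized with the Huber elbow transformed to
delta/sigma - exactly equivalent to the raw-scale objective (the losses
differ by the constant factor sigma^2) but far better conditioned at the
published learning rate; predictions are mapped back to UPDRS points.

The whole stack is implemented on a compact reverse-mode autodiff core
(`dcan.nn`) over NumPy arrays, with fused primitives (one graph node per
LSTM layer, in-node backpropagation-through-time; masked softmax; layer
norm; Huber loss) so that full training runs are single-CPU-friendly.
Network compute uses float32 (the autodiff core preserves storage dtype;
gradient checks run in float64).
Every primitive's gradient is verified against central finite differences
in the test suite. With fixed seeds, training is bit-reproducible.

## Evaluation

Repeated k-fold cross-validation at the patient level: each repetition
reshuffles patients (seed + repetition index, so partitions differ across
repetitions) into k disjoint folds of size floor(n/k) or ceil(n/k); with
n = 42, k = 5 and 8 repetitions every patient is tested exactly 8 times
across 40 folds. Scalers are fitted per fold on training-side patients
only. Fold metrics (MAE, MSE, RMSE, R^2 on pooled test-window
predictions) aggregate into mean, sample sd, min/max/range, a t-based 95%
CI (mean +- t_{0.975, n-1} sd/sqrt(n); the CI method is a package choice)
and the coefficient of variation. Paired two-sided t-tests compare
fold-wise metrics between models; exact ties are flagged. Agreement is
summarized by Bland-Altman bias and 1.96-sd limits. Ablations rerun the
pipeline over modality subsets (clinical-only, text-only, clinical+text,
clinical+meta, clinical+voice+meta, full) with identical fold assignments
and the reduced preset, reporting % RMSE change against clinical-only and
the fold-wise rank concordance of configurations as Kendall's W (with tie
correction). Classical baselines (ridge, gradient-boosted trees, random
forest from scikit-learn, and a small single-layer LSTM regressor built
on the package's nn core) run under the same folds on flattened
final-timestep features (text optional, excluded by default).

## Problem sizes used in the shipped experiments

The acceptance test and `scripts/acceptance.py` run the default
42-patient cohort with supervised-window stride 6 (about 22 windows per
patient, ~950 total), the reduced hyperparameter preset, one repetition
of 5-fold patient-level CV, and an ablation subset (clinical-only,
text-only, full); the baseline harness uses 50 random-forest trees and
15 LSTM-baseline epochs. Stride matters beyond data volume: it sets the
optimizer-step count per epoch, and too-aggressive subsampling leaves
the fused model undertrained inside the 50-epoch preset; stride 6 is the
coarsest setting we found that converges reliably, and the full-scale
protocol (stride 1, 8 repetitions, all six configurations, 150-epoch
budget) is available through the same APIs and the CLI. At desk scale
the clinical-only configuration can match or beat the full fusion model
on mean RMSE - recovering the published ordering among the strong
configurations requires the full-scale protocol - whereas the text-only
degradation is large and robust at any scale.

## Numerical choices and edge cases

* Savitzky-Golay on series shorter than the window returns the input
  unchanged (no full window exists).
* Rolling sd/skewness/kurtosis are 0 where undefined (fewer than 2/3/4
  points); sd is the sample (n-1) estimate, skewness adjusted
  Fisher-Pearson, kurtosis bias-corrected excess.
* Derivatives divide by actual day gaps; zero or negative gaps are
  rejected as degenerate input.
* The z-score epsilon (0.01) guards constant traces; clipping at +-5
  bounds outliers.
* Min-max normalization of a constant trace maps to 0 (instability index).
* A patient series of length 1 or 2 produces fully finite blocks; lags
  fall back to the first observed score with the mask carrying validity.
* Attention logits use exact -inf masking; fully masked rows output zero.
* Fold RNG: repetition r shuffles with seed base + r.
* Ridge/forest/boosting baselines use scikit-learn defaults except where
  the harness exposes size knobs.

## Known limitations

* The default `full_history` narrative mode reuses future same-patient
  data inside the text block; patient-level CV keeps evaluation honest,
  but per-window deployment should use `causal` mode.
* The centered denoiser sees up to two future acoustic (not UPDRS)
  samples inside the window unless `causal_denoise` is set.
* The hashing text encoder captures lexical, not semantic, similarity;
  conclusions about the value of narrative embeddings are weaker than
  with a pretrained sentence encoder.
* Synthetic-cohort results do not establish real-data accuracy (see
  above); the pipeline accepts the real UCI table via `telemon` whenever
  it is available locally.
* No mixed-precision or parallel training; the implementation targets
  small clinical cohorts, not large-scale pretraining.
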