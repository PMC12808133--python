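# dcan

Multi-modal dynamic attention fusion for longitudinal prediction of
Parkinson's disease motor-UPDRS scores from voice telemonitoring data.

## The problem

In early-to-moderate Parkinson's disease, motor symptom severity (the
motor subscale of the Unified Parkinson's Disease Rating Scale, 0-108
points, higher = worse) evolves slowly and heterogeneously. At-home
telemonitoring produces long, irregularly spaced series of voice
recordings with paired UPDRS assessments; forecasting the next motor
score from that history supports timely medication adjustment without
extra clinic visits. This package is for researchers working with
telemonitoring tables in the UCI "Parkinsons Telemonitoring" dialect
(42 patients, ~5,875 recordings over six months in the original study)
or with synthetic cohorts of the same shape.

## The model

Each prediction uses a trailing window of T visits, split into four
modality streams: engineered voice biomarkers **X**_v ∈ ℝ^{T×146}
(jitter/shimmer/HNR families expanded with Savitzky–Golay denoising,
velocities, rolling moments, within-patient z-scores), clinical
progression features **X**_c ∈ ℝ^{T×9} built from *lagged* UPDRS only,
demographic metadata **X**_m ∈ ℝ^{T×3}, and a patient narrative
embedding **X**_t ∈ ℝ^{T×768} (a templated clinical summary encoded to a
dense vector and tiled over the window).

Branch encoders map every stream to a common width h_d (BiLSTM stacks +
self-attention for voice; position-wise GELU layers for the rest):

    Attention(Q, K, V) = softmax(QKᵀ / √d_k) V

A dynamic fusion layer attends within each modality, mean-pools each
attended stream **A**_m into **h**_m, concatenates
**h**_context = [**h**_v; **h**_c; **h**_m; **h**_t], and computes convex
modality weights

    α = softmax(W_c · h_context + b_c),   Σ_m α_m = 1,

which weight the full attended sequences: **H**_f[t] = Σ_m α_m **A**_m[t].
A temporal block (BiLSTM layers with residuals, then self-attention under
a strictly causal mask A_ij = −∞ for j > i) feeds a GELU head that emits
the motor-UPDRS prediction ŷ for the target visit. Training minimizes
Huber loss (δ = 2 points) with AdamW, gradient clipping, a piecewise
learning-rate schedule and patient-level early stopping; evaluation is
repeated k-fold cross-validation *at the patient level*, with modality
ablations and classical baselines under identical folds. The network and
its training loop run on a small reverse-mode autodiff core over NumPy —
no deep-learning framework required.

## Worked example

```python
import numpy as np
from dcan import (SyntheticCohortConfig, generate_cohort, cohort_summary,
                  CVSpec, ModelConfig, TrainConfig, run_cv)

cohort = generate_cohort(SyntheticCohortConfig(rng_seed=0))   # 42 patients
summ = cohort_summary(cohort)
print(f"{summ.n_patients} patients, {summ.n_records} visits, "
      f"age {summ.age_mean:.1f}±{summ.age_sd:.1f}, stages {summ.stage_counts}")

report = run_cv(
    cohort,
    ModelConfig(seed=0).ablation_preset(),      # hidden 128 preset
    TrainConfig(rng_seed=0).ablation_preset(),  # ≤50 epochs, patience 10
    CVSpec(k=5, repeats=1, seed=0, window_stride=6),
)
print(report.summary.round(4))
```

which prints (exact numbers vary with the seed):

```
42 patients, 5620 visits, age 64.8±9.3, stages {'Early': 12, 'Moderate': 30, 'Advanced': 0}
        mean      sd     min     max   range  ci_low  ci_high   cv_pct
mae   1.5222  0.4794  1.1344  2.1713  1.0369  0.9269   2.1174  31.4944
mse   4.3714  3.0832  1.9652  8.7124  6.7472  0.5432   8.1997  70.5303
rmse  1.9902  0.7165  1.4019  2.9517  1.5498  1.1005   2.8798  36.0038
r2    0.9227  0.0276  0.8842  0.9548  0.0706  0.8884   0.9571   2.9945
```

Read: across five patient-disjoint test folds the fused model predicts
the next motor-UPDRS score with a mean absolute error of ≈1.5 points —
well under the 3–5 point minimal clinically important difference — and
explains ≈92% of the variance in held-out patients' scores. `report`
also carries the per-fold results and pooled test predictions, and the
fitted model exposes its per-sample modality weights α.

The same pipeline is scriptable from the shell:

```bash
dcan simulate --out cohort.csv --seed 0
dcan summarize cohort.csv
dcan evaluate cohort.csv --out cv/ --repeats 1 --folds 5 --window-stride 6
dcan ablate cohort.csv --out ablation/ --window-stride 6
```

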