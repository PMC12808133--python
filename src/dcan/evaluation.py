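"""Metrics, repeated patient-level cross-validation, ablations, baselines.

The evaluation protocol is repeated k-fold cross-validation *at the
patient level*: every repetition reshuffles the patients into k disjoint
folds, so with k=5 and 8 repetitions each patient is tested exactly 8
times across 40 folds and no window of a test patient is ever seen in
training. Fold-wise MAE / MSE / RMSE / R^2 are aggregated into mean, sd,
min/max/range, a t-based 95% CI and the coefficient of variation.

Modality ablations rerun the pipeline with identical fold assignments and
a reduced hyperparameter preset, dropping branches from the fusion stack
(the softmax weighting renormalizes over the remaining modalities), and
summarize rank concordance across folds with Kendall's W. The baseline
harness fits classical comparators (ridge, gradient-boosted trees, random
forest, a small single-layer LSTM regressor) on flattened windows under
the same folds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import nn
from .errors import ConfigError, DomainError
from .features import FeatureConfig, build_patient_blocks, make_supervised_windows
from .model import EnhancedDCAN, ModelConfig
from .narrative import HashingTextEncoder, patient_embedding
from .telemon import PatientSeries
from .training import (
    TrainConfig,
    apply_scalers,
    fit_scalers,
    predict_updrs,
    split_patients_for_validation,
    train_model,
)

ABLATION_CONFIGS: dict[str, tuple[str, ...]] = {
    "clinical_only": ("clinical",),
    "text_only": ("text",),
    "clinical_text": ("clinical", "text"),
    "clinical_meta": ("clinical", "meta"),
    "clinical_voice_meta": ("clinical", "voice", "meta"),
    "full": ("voice", "clinical", "meta", "text"),
}


# ---------------------------------------------------------------------------
# metrics and statistics


def regression_metrics(y, y_hat) -> tuple[float, float, float, float]:
    """(MAE, MSE, RMSE, R^2); R^2 is NaN-flagged for zero-variance targets."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.size == 0 or y.size != y_hat.size:
        raise DomainError("metrics need equal-length nonempty arrays")
    err = y_hat - y
    mae = float(np.mean(np.abs(err)))
    mse = float(np.mean(err**2))
    rmse = float(np.sqrt(mse))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(err**2)) / ss_tot if ss_tot > 0 else float("nan")
    return mae, mse, rmse, r2


def paired_t_test(metric_a, metric_b) -> tuple[float, float]:
    """Two-sided paired t on fold-wise differences.

    Identical samples give (0.0, 1.0); a zero-variance nonzero difference
    is an exact tie-break and returns (+-inf, 0.0).
    """
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if a.size != b.size or a.size < 2:
        raise DomainError("paired t-test needs equal-length samples, n >= 2")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d.mean(), 0.0):
            return 0.0, 1.0
        return float(np.sign(d.mean()) * np.inf), 0.0
    res = sps.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


def kendalls_w(ranks: np.ndarray) -> float:
    """Kendall's coefficient of concordance with tie correction.

    ``ranks`` is (m raters, k items) of within-rater ranks (mid-ranks for
    ties). W = 12 S / (m^2 (k^3 - k) - m T) with S the squared deviation of
    item rank sums and T the tie correction.
    """
    ranks = np.asarray(ranks, dtype=float)
    if ranks.ndim != 2 or ranks.shape[0] < 2 or ranks.shape[1] < 2:
        raise DomainError("need >= 2 raters and >= 2 items")
    m, k = ranks.shape
    rank_sums = ranks.sum(axis=0)
    s = float(np.sum((rank_sums - rank_sums.mean()) ** 2))
    tie_term = 0.0
    for row in ranks:
        _, counts = np.unique(row, return_counts=True)
        tie_term += float(np.sum(counts**3 - counts))
    denom = m**2 * (k**3 - k) - m * tie_term
    if denom <= 0:
        return 1.0  # all raters fully tied on everything
    return 12.0 * s / denom


def bland_altman(y, y_hat) -> tuple[float, float, float]:
    """(bias, lower LoA, upper LoA): mean difference +- 1.96 sd."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.size != y_hat.size or y.size < 2:
        raise DomainError("Bland-Altman needs equal-length arrays, n >= 2")
    d = y_hat - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


# ---------------------------------------------------------------------------
# fold bookkeeping


def repeated_patient_kfold(patient_ids, k: int = 5, repeats: int = 8,
                           seed: int = 0) -> pd.DataFrame:
    """Assignment table: one row per (repetition, fold, test patient).

    Each repetition r reshuffles all patients with seed ``seed + r`` and
    partitions them into k folds of size floor(n/k) or ceil(n/k); every
    patient is tested exactly once per repetition.
    """
    ids = sorted(set(patient_ids), key=str)
    n = len(ids)
    if k > n:
        raise DomainError(f"cannot make {k} folds from {n} patients")
    rows = []
    for rep in range(1, repeats + 1):
        rng = np.random.default_rng(seed + rep)
        order = [ids[i] for i in rng.permutation(n)]
        splits = np.array_split(order, k)
        for fold, test_ids in enumerate(splits, start=1):
            for sid in test_ids:
                rows.append({"repetition": rep, "fold": fold, "subject_id": sid})
    return pd.DataFrame(rows)


@dataclass
class FoldResult:
    repetition: int
    fold: int
    test_patients: tuple[str, ...]
    mae: float
    mse: float
    rmse: float
    r2: float

    def __post_init__(self) -> None:
        assert abs(self.rmse**2 - self.mse) <= 1e-9 * max(1.0, self.mse)


@dataclass
class CVReport:
    folds: list[FoldResult]
    summary: pd.DataFrame  # per-metric aggregates
    predictions: pd.DataFrame | None = None  # pooled test predictions

    def metric(self, name: str) -> np.ndarray:
        return np.array([getattr(f, name) for f in self.folds])


def aggregate_fold_metrics(values) -> dict[str, float]:
    """mean, sd, min, max, range, t-based 95% CI, CV% over fold metrics."""
    v = np.asarray(values, dtype=float)
    n = v.size
    mean = float(v.mean())
    sd = float(v.std(ddof=1)) if n > 1 else 0.0
    half = float(sps.t.ppf(0.975, n - 1) * sd / np.sqrt(n)) if n > 1 else 0.0
    return {
        "mean": mean,
        "sd": sd,
        "min": float(v.min()),
        "max": float(v.max()),
        "range": float(v.max() - v.min()),
        "ci_low": mean - half,
        "ci_high": mean + half,
        "cv_pct": sd / mean * 100.0 if mean != 0 else float("nan"),
    }


def summarize_folds(folds: list[FoldResult]) -> pd.DataFrame:
    rows = {}
    for name in ("mae", "mse", "rmse", "r2"):
        rows[name] = aggregate_fold_metrics([getattr(f, name) for f in folds])
    return pd.DataFrame(rows).T


# ---------------------------------------------------------------------------
# the cross-validation driver


@dataclass
class CVSpec:
    """How to run the repeated patient-level cross-validation."""

    k: int = 5
    repeats: int = 8
    seed: int = 0
    window_stride: int = 1
    narrative_mode: str = "full_history"
    encoder: object | None = None  # defaults to the offline hashing encoder

    def get_encoder(self):
        return self.encoder if self.encoder is not None else HashingTextEncoder(self.seed)


def prepare_windows(
    cohort: list[PatientSeries],
    feature_config: FeatureConfig,
    spec: CVSpec,
) -> dict[str, list]:
    """Per-patient unscaled supervised windows (features are fold-free)."""
    encoder = spec.get_encoder()
    windows: dict[str, list] = {}
    for series in cohort:
        if spec.narrative_mode == "full_history":
            emb = patient_embedding(series, encoder, mode="full_history").vector
            blocks = build_patient_blocks(series, feature_config, emb)
            samples = make_supervised_windows(blocks, feature_config, stride=spec.window_stride)
        else:
            blocks = build_patient_blocks(series, feature_config, None)
            samples = make_supervised_windows(blocks, feature_config, stride=spec.window_stride)
            for s in samples:  # causal: embed history up to each target
                e = patient_embedding(series, encoder, mode="causal",
                                      upto=s.target_visit_index).vector
                s.X_t = np.tile(e.reshape(1, -1), (s.X_t.shape[0], 1)) * s.mask[:, None]
        windows[series.subject_id] = samples
    return windows


def _train_eval_fold(windows, train_ids, test_ids, model_config, train_config):
    train_pool = [s for sid in train_ids for s in windows[sid]]
    test_samples = [s for sid in test_ids for s in windows[sid]]
    assert not (set(train_ids) & set(test_ids))
    rng = np.random.default_rng(train_config.rng_seed)
    fit_part, val_part = split_patients_for_validation(
        train_pool, train_config.val_fraction, rng)
    scalers = fit_scalers(fit_part)
    fit_scaled = apply_scalers(fit_part, scalers)
    val_scaled = apply_scalers(val_part, scalers)
    test_scaled = apply_scalers(test_samples, scalers)
    model = EnhancedDCAN(model_config)
    model, history = train_model(model, fit_scaled, train_config, val_samples=val_scaled)
    y_hat = predict_updrs(model, test_scaled)
    y = np.array([s.y for s in test_samples])
    return y, y_hat, history


def run_cv(
    cohort: list[PatientSeries],
    model_config: ModelConfig,
    train_config: TrainConfig,
    spec: CVSpec,
    feature_config: FeatureConfig | None = None,
    windows: dict[str, list] | None = None,
    collect_predictions: bool = False,
) -> CVReport:
    """Full repeated patient-level CV of the fusion model."""
    feature_config = feature_config or FeatureConfig(
        sequence_length=model_config.sequence_length)
    if windows is None:
        windows = prepare_windows(cohort, feature_config, spec)
    assignments = repeated_patient_kfold(
        list(windows), k=spec.k, repeats=spec.repeats, seed=spec.seed)
    all_ids = set(windows)
    folds: list[FoldResult] = []
    pred_rows = []
    for (rep, fold), grp in assignments.groupby(["repetition", "fold"], sort=True):
        rep, fold = int(rep), int(fold)
        test_ids = sorted(grp["subject_id"])
        train_ids = sorted(all_ids - set(test_ids))
        y, y_hat, _ = _train_eval_fold(
            windows, train_ids, test_ids, model_config, train_config)
        mae, mse, rmse, r2 = regression_metrics(y, y_hat)
        folds.append(FoldResult(rep, fold, tuple(test_ids), mae, mse, rmse, r2))
        if collect_predictions:
            pred_rows.append(pd.DataFrame(
                {"repetition": rep, "fold": fold, "y": y, "y_hat": y_hat}))
    preds = pd.concat(pred_rows, ignore_index=True) if pred_rows else None
    return CVReport(folds=folds, summary=summarize_folds(folds), predictions=preds)


# ---------------------------------------------------------------------------
# ablations


def ablation_runner(
    cohort: list[PatientSeries],
    spec: CVSpec,
    base_model_config: ModelConfig | None = None,
    base_train_config: TrainConfig | None = None,
    configurations: dict[str, tuple[str, ...]] | None = None,
    feature_config: FeatureConfig | None = None,
    windows: dict[str, list] | None = None,
    collect_predictions_for: tuple[str, ...] = (),
) -> tuple[pd.DataFrame, dict[str, CVReport]]:
    """Run the modality-ablation grid under identical fold assignments.

    Every configuration uses the reduced hyperparameter preset; absent
    modalities are removed from the fusion stack so the dynamic weighting
    renormalizes over those remaining. Returns the summary table (RMSE and
    R^2 per configuration with % RMSE change vs the clinical-only
    baseline, fold-rank concordance) and the per-configuration reports.
    """
    configurations = configurations or ABLATION_CONFIGS
    unknown = set(configurations) - set(ABLATION_CONFIGS)
    if unknown:
        raise ConfigError(f"unknown ablation configurations: {sorted(unknown)}")
    base_model_config = base_model_config or ModelConfig()
    base_train_config = base_train_config or TrainConfig()
    feature_config = feature_config or FeatureConfig(
        sequence_length=base_model_config.sequence_length)
    if windows is None:
        windows = prepare_windows(cohort, feature_config, spec)

    reports: dict[str, CVReport] = {}
    for name, mods in configurations.items():
        mcfg = base_model_config.ablation_preset(modalities=mods)
        tcfg = base_train_config.ablation_preset()
        reports[name] = run_cv(
            cohort, mcfg, tcfg, spec, feature_config=feature_config, windows=windows,
            collect_predictions=name in collect_predictions_for)

    names = list(configurations)
    rmse_matrix = np.stack([reports[n].metric("rmse") for n in names])  # (cfg, folds)
    fold_sets = [tuple(f.test_patients) for f in reports[names[0]].folds]
    for n in names[1:]:
        assert [tuple(f.test_patients) for f in reports[n].folds] == fold_sets, \
            "fold assignments must be identical across configurations"

    rows = []
    clin_rmse = reports["clinical_only"].summary.loc["rmse", "mean"] \
        if "clinical_only" in reports else float("nan")
    for n in names:
        summ = reports[n].summary
        rmse_mean = summ.loc["rmse", "mean"]
        rows.append({
            "configuration": n,
            "modalities": "+".join(ABLATION_CONFIGS[n]),
            "rmse_mean": rmse_mean,
            "rmse_sd": summ.loc["rmse", "sd"],
            "r2_mean": summ.loc["r2", "mean"],
            "r2_sd": summ.loc["r2", "sd"],
            "pct_change_vs_clinical": 100.0 * (rmse_mean - clin_rmse) / clin_rmse
            if np.isfinite(clin_rmse) else float("nan"),
        })
    table = pd.DataFrame(rows)

    # fold-wise ranks of configurations (1 = best RMSE), folds act as raters
    ranks = np.apply_along_axis(sps.rankdata, 0, rmse_matrix).T  # (folds, cfg)
    table.attrs["kendalls_w"] = kendalls_w(ranks) if len(names) >= 2 else float("nan")
    table.attrs["rank_matrix"] = ranks
    return table, reports


# ---------------------------------------------------------------------------
# classical baselines


class SimpleLSTMRegressor:
    """Single-layer LSTM + linear head; the 'simple recurrent net' comparator."""

    def __init__(self, hidden: int = 32, epochs: int = 40, lr: float = 3e-3,
                 batch_size: int = 64, seed: int = 0):
        self.hidden = hidden
        self.epochs = epochs
        self.lr = lr
        self.batch_size = batch_size
        self.seed = seed
        self.params: dict[str, nn.Tensor] | None = None

    def _forward(self, X):
        p = self.params
        h = nn.lstm(nn.Tensor(X), p["Wx"], p["Wh"], p["b"])
        out = nn.add(nn.matmul(h[:, -1, :], p["Wo"]), p["bo"])
        return nn.reshape(out, (-1,))

    def fit(self, X: np.ndarray, y: np.ndarray):
        rng = np.random.default_rng(self.seed)
        D = X.shape[2]
        H = self.hidden
        self.params = {
            "Wx": nn.Tensor(nn.glorot(rng, D, 4 * H), requires_grad=True),
            "Wh": nn.Tensor(nn.glorot(rng, H, 4 * H), requires_grad=True),
            "b": nn.Tensor(np.zeros(4 * H), requires_grad=True),
            "Wo": nn.Tensor(nn.glorot(rng, H, 1), requires_grad=True),
            "bo": nn.Tensor(np.zeros(1), requires_grad=True),
        }
        self._mu, self._sd = float(y.mean()), float(y.std() or 1.0)
        yz = (y - self._mu) / self._sd
        opt = nn.AdamW(self.params, lr=self.lr, weight_decay=0.0)
        n = len(y)
        for _ in range(self.epochs):
            order = rng.permutation(n)
            for lo in range(0, n, self.batch_size):
                idx = order[lo : lo + self.batch_size]
                for p in self.params.values():
                    p.grad = None
                pred = self._forward(X[idx])
                diff = nn.add(pred, -yz[idx])
                loss = nn.mean_(nn.mul(diff, diff))
                loss.backward()
                grads = {k: p.grad for k, p in self.params.items() if p.grad is not None}
                grads, _ = nn.clip_global_norm(grads, 1.0)
                opt.step(grads)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self._forward(X).data * self._sd + self._mu


def _flatten_final(samples, include_text: bool) -> np.ndarray:
    feats = [np.concatenate([s.X_v[-1], s.X_c[-1], s.X_m[-1]]) for s in samples]
    if include_text:
        feats = [np.concatenate([f, s.X_t[-1]]) for f, s in zip(feats, samples)]
    return np.stack(feats)


def _stack_sequences(samples) -> np.ndarray:
    return np.stack(
        [np.concatenate([s.X_v, s.X_c, s.X_m], axis=1) for s in samples])


def baseline_harness(
    cohort: list[PatientSeries],
    spec: CVSpec,
    feature_config: FeatureConfig | None = None,
    include_text: bool = False,
    models: tuple[str, ...] = ("ridge", "gbrt", "random_forest", "simple_lstm"),
    windows: dict[str, list] | None = None,
    rf_estimators: int = 100,
    lstm_epochs: int = 40,
) -> pd.DataFrame:
    """Fit classical comparators under the same patient-level folds.

    Features are the scaled final-timestep voice+clinical+meta columns
    (text embeddings optional); the recurrent baseline consumes the full
    scaled window. Per-baseline failures are recorded, not fatal.
    """
    from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
    from sklearn.linear_model import Ridge

    feature_config = feature_config or FeatureConfig()
    if windows is None:
        windows = prepare_windows(cohort, feature_config, spec)
    assignments = repeated_patient_kfold(
        list(windows), k=spec.k, repeats=spec.repeats, seed=spec.seed)
    all_ids = set(windows)

    rows = []
    for (rep, fold), grp in assignments.groupby(["repetition", "fold"], sort=True):
        test_ids = sorted(grp["subject_id"])
        train_ids = sorted(all_ids - set(test_ids))
        train_pool = [s for sid in train_ids for s in windows[sid]]
        test_pool = [s for sid in test_ids for s in windows[sid]]
        scalers = fit_scalers(train_pool)
        tr = apply_scalers(train_pool, scalers)
        te = apply_scalers(test_pool, scalers)
        Xtr = _flatten_final(tr, include_text)
        Xte = _flatten_final(te, include_text)
        ytr = np.array([s.y for s in tr])
        yte = np.array([s.y for s in te])

        fits = {}
        if "ridge" in models:
            fits["ridge"] = Ridge(alpha=1.0)
        if "gbrt" in models:
            fits["gbrt"] = GradientBoostingRegressor(random_state=spec.seed)
        if "random_forest" in models:
            fits["random_forest"] = RandomForestRegressor(
                n_estimators=rf_estimators, random_state=spec.seed, n_jobs=1)
        for name, est in fits.items():
            try:
                est.fit(Xtr, ytr)
                y_hat = est.predict(Xte)
            except Exception as exc:  # noqa: BLE001 - isolate baseline failures
                rows.append({"model": name, "repetition": rep, "fold": fold,
                             "error": str(exc)})
                continue
            mae, mse, rmse, r2 = regression_metrics(yte, y_hat)
            rows.append({"model": name, "repetition": rep, "fold": fold,
                         "mae": mae, "rmse": rmse, "r2": r2})
        if "simple_lstm" in models:
            try:
                reg = SimpleLSTMRegressor(epochs=lstm_epochs, seed=spec.seed)
                reg.fit(_stack_sequences(tr), ytr)
                y_hat = reg.predict(_stack_sequences(te))
                mae, mse, rmse, r2 = regression_metrics(yte, y_hat)
                rows.append({"model": "simple_lstm", "repetition": rep, "fold": fold,
                             "mae": mae, "rmse": rmse, "r2": r2})
            except Exception as exc:  # noqa: BLE001
                rows.append({"model": "simple_lstm", "repetition": rep,
                             "fold": fold, "error": str(exc)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# plots (optional artifacts)


def bland_altman_plot(y, y_hat, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    bias, lo, hi = bland_altman(y, y_hat)
    means = (np.asarray(y) + np.asarray(y_hat)) / 2.0
    diffs = np.asarray(y_hat) - np.asarray(y)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(means, diffs, s=8, alpha=0.5)
    for val, style in ((bias, "-"), (lo, "--"), (hi, "--")):
        ax.axhline(val, linestyle=style, color="tab:red", linewidth=1)
    ax.set_xlabel("mean of prediction and observation (UPDRS)")
    ax.set_ylabel("prediction - observation (UPDRS)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def residual_plot(y, y_hat, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    y = np.asarray(y)
    resid = np.asarray(y_hat) - y
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(y, resid, s=8, alpha=0.5)
    ax.axhline(0.0, color="tab:red", linewidth=1)
    ax.set_xlabel("observed motor UPDRS")
    ax.set_ylabel("residual (points)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
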