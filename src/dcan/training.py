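"""Loss, schedules, scaling, and the fit loop.

Training follows the published protocol: mean Huber loss (delta = 2.0 UPDRS
points) plus an L2 kernel penalty, AdamW with decoupled weight decay 0.005,
global gradient-norm clipping at 1.0, batch size 16, a piecewise learning
rate schedule starting at 3e-4, plateau-based learning-rate reduction,
early stopping with best-weight restoration, and a patient-level 15%
validation holdout. Voice/meta/clinical numeric columns are robust-scaled
(median / IQR) with post-scaling clipping to [-5, 5]; text embeddings are
mean-centered.

For optimizer conditioning the target is standardized internally with the
Huber elbow transformed to delta/sigma - exactly equivalent to minimizing
the raw-scale Huber objective - and predictions are mapped back to UPDRS
points on the way out.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import nn
from .errors import ConfigError, DomainError, StateError
from .features import SequenceSample
from .model import EnhancedDCAN, batch_from_samples, slice_batch

#: clinical columns that are categorical codes (passed through unscaled)
CLINICAL_CATEGORICAL = (7, 8)  # stage_code, progression_rate_code


@dataclass
class TrainConfig:
    """Optimization hyperparameters."""

    huber_delta: float = 2.0
    base_lr: float = 3e-4
    weight_decay: float = 0.005
    grad_clip_norm: float = 1.0
    batch_size: int = 16
    max_epochs: int = 150
    early_stop_patience: int = 25
    val_fraction: float = 0.15
    plateau_factor: float = 0.5
    plateau_patience: int = 10
    min_lr: float = 1e-6
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.huber_delta <= 0:
            raise ConfigError("huber_delta must be > 0")
        if not (0.0 < self.val_fraction < 1.0):
            raise ConfigError("val_fraction must lie in (0, 1)")
        if self.early_stop_patience < 1 or self.plateau_patience < 1:
            raise ConfigError("patience values must be >= 1")

    def ablation_preset(self) -> "TrainConfig":
        """Reduced schedule used by the ablation experiments."""
        return replace(self, max_epochs=50, early_stop_patience=10)


def huber_loss(y, y_hat, delta: float = 2.0) -> float:
    """Mean Huber loss: 0.5 r^2 for |r| <= delta, else delta(|r| - delta/2)."""
    if delta <= 0:
        raise ConfigError("delta must be > 0")
    r = np.asarray(y, dtype=float) - np.asarray(y_hat, dtype=float)
    a = np.abs(r)
    return float(np.mean(np.where(a <= delta, 0.5 * r**2, delta * (a - 0.5 * delta))))


def lr_at_epoch(epoch: int, config: TrainConfig) -> float:
    """Piecewise multiplicative schedule.

    Constant for the first 10 epochs; 5% decays at epochs 10, 20 and 30;
    a 10% decay at epoch 60 (10% per 30 epochs over the 30-60 span); 15%
    decays every 30 epochs thereafter (90, 120, ...).
    """
    lr = config.base_lr
    for milestone in (10, 20, 30):
        if epoch >= milestone:
            lr *= 0.95
    if epoch >= 60:
        lr *= 0.90
    m = 90
    while epoch >= m:
        lr *= 0.85
        m += 30
    return lr


@dataclass
class ScalerState:
    """Per-block robust scaling statistics, fitted on training data only."""

    centers: dict[str, np.ndarray] = field(default_factory=dict)
    scales: dict[str, np.ndarray] = field(default_factory=dict)
    clip: float = 5.0
    fitted: bool = False

    def transform_block(self, name: str, X: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise StateError("scaler used before fitting")
        Z = (X - self.centers[name]) / self.scales[name]
        if name == "text":
            return Z  # centering only
        Z = np.clip(Z, -self.clip, self.clip)
        if name == "clinical":
            Z[..., list(CLINICAL_CATEGORICAL)] = X[..., list(CLINICAL_CATEGORICAL)]
        return Z


def fit_scalers(train_samples: list[SequenceSample], clip: float = 5.0) -> ScalerState:
    """Fit median/IQR scalers per column on *training* windows only.

    Voice, meta and numeric clinical columns: center = median, scale = IQR
    (columns with IQR < 1e-9 get scale 1), then post-scaling clipping to
    [-clip, clip]. Text embeddings are mean-centered with no scaling.
    Categorical clinical codes pass through untouched. Statistics are
    computed over real (unmasked) timesteps.
    """
    if not train_samples:
        raise DomainError("cannot fit scalers on an empty training set")
    state = ScalerState(clip=clip)
    stacks = {
        "voice": np.concatenate([s.X_v[s.mask] for s in train_samples]),
        "clinical": np.concatenate([s.X_c[s.mask] for s in train_samples]),
        "meta": np.concatenate([s.X_m[s.mask] for s in train_samples]),
        "text": np.concatenate([s.X_t[s.mask] for s in train_samples]),
    }
    for name, X in stacks.items():
        if name == "text":
            state.centers[name] = X.mean(axis=0)
            state.scales[name] = np.ones(X.shape[1])
            continue
        center = np.median(X, axis=0)
        q75, q25 = np.percentile(X, [75, 25], axis=0)
        iqr = q75 - q25
        iqr[iqr < 1e-9] = 1.0
        state.centers[name] = center
        state.scales[name] = iqr
    state.fitted = True
    return state


def apply_scalers(samples: list[SequenceSample], state: ScalerState) -> list[SequenceSample]:
    """Return scaled copies of the samples (padded steps stay zero)."""
    out = []
    for s in samples:
        m = s.mask[:, None].astype(float)
        out.append(
            SequenceSample(
                subject_id=s.subject_id,
                target_visit_index=s.target_visit_index,
                X_v=state.transform_block("voice", s.X_v) * m,
                X_c=state.transform_block("clinical", s.X_c) * m,
                X_m=state.transform_block("meta", s.X_m) * m,
                X_t=state.transform_block("text", s.X_t) * m,
                y=s.y,
                mask=s.mask.copy(),
            )
        )
    return out


def split_patients_for_validation(
    samples: list[SequenceSample], val_fraction: float, rng: np.random.Generator
) -> tuple[list[SequenceSample], list[SequenceSample]]:
    """Hold out whole patients (never windows) as the validation set."""
    patients = sorted({s.subject_id for s in samples})
    if len(patients) < 2:
        return samples, samples  # degenerate single-patient cohort
    n_val = max(1, int(round(val_fraction * len(patients))))
    if n_val >= len(patients):
        n_val = len(patients) - 1
    order = list(rng.permutation(patients))
    val_ids = set(order[:n_val])
    train = [s for s in samples if s.subject_id not in val_ids]
    val = [s for s in samples if s.subject_id in val_ids]
    return train, val


@dataclass
class TrainHistory:
    """Per-epoch training trace."""

    records: list[dict] = field(default_factory=list)
    grad_norms: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stopped_epoch: int = -1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)


def _eval_loss(model, data, y_scale, y_center, delta, batch_size=512):
    n = len(data["y"])
    preds_z = []
    for lo in range(0, n, batch_size):
        batch = slice_batch(data, slice(lo, lo + batch_size))
        preds_z.append(model.forward(batch, training=False).data)
    pz = np.concatenate(preds_z)
    y = data["y"]
    yz = (y - y_center) / y_scale
    loss = huber_loss(yz, pz, delta / y_scale)
    pred_raw = pz * y_scale + y_center
    return loss, float(np.mean(np.abs(pred_raw - y))), float(np.mean((pred_raw - y) ** 2))


def train_model(
    model: EnhancedDCAN,
    samples: list[SequenceSample],
    config: TrainConfig,
    val_samples: list[SequenceSample] | None = None,
) -> tuple[EnhancedDCAN, TrainHistory]:
    """Fit the model with the full callback stack.

    If ``val_samples`` is None, a patient-level 15% split is carved out of
    ``samples``. Callbacks: epoch learning-rate schedule, plateau reduction
    of the learning rate on validation loss, early stopping with patience
    and best-checkpoint restoration. The history records per-epoch train
    and validation Huber loss, MAE and MSE (raw UPDRS units) plus every
    post-clip gradient norm.
    """
    if not samples:
        raise DomainError("empty training set")
    rng = np.random.default_rng(config.rng_seed)
    if val_samples is None:
        train_samples, val_samples = split_patients_for_validation(
            samples, config.val_fraction, rng)
    else:
        train_samples = samples
    if not train_samples or not val_samples:
        raise DomainError("train/validation split produced an empty side")

    train_data = batch_from_samples(train_samples)
    val_data = batch_from_samples(val_samples)
    y_train = train_data["y"]
    y_center = float(np.mean(y_train))
    y_scale = float(np.std(y_train))
    if y_scale < 1e-8:
        y_scale = 1.0
    delta_z = config.huber_delta / y_scale
    yz_train = (y_train - y_center) / y_scale

    opt = nn.AdamW(model.params, lr=config.base_lr, weight_decay=config.weight_decay)
    history = TrainHistory()
    best_val = np.inf
    best_state = model.state_dict()
    epochs_since_best = 0
    plateau_wait = 0
    plateau_factor = 1.0

    n = len(train_samples)
    for epoch in range(config.max_epochs):
        lr = max(lr_at_epoch(epoch, config) * plateau_factor, config.min_lr)
        opt.lr = lr
        order = rng.permutation(n)
        epoch_losses = []
        for lo in range(0, n, config.batch_size):
            idx = order[lo : lo + config.batch_size]
            batch = slice_batch(train_data, idx)
            yz = yz_train[idx]
            model.zero_grad()
            pred = model.forward(batch, training=True, rng=rng)
            loss = nn.huber_loss_t(pred, yz, delta_z)
            if not np.isfinite(loss.data):
                raise DomainError(
                    f"non-finite training loss at epoch {epoch}; aborting")
            loss.backward()
            grads = model.gradients()
            for k, g in model.l2_gradients().items():
                grads[k] = grads.get(k, 0.0) + g
            grads, norm = nn.clip_global_norm(grads, config.grad_clip_norm)
            history.grad_norms.append(norm)
            opt.step(grads)
            epoch_losses.append(float(loss.data))

        val_loss, val_mae, val_mse = _eval_loss(
            model, val_data, y_scale, y_center, config.huber_delta)
        history.records.append({
            "epoch": epoch,
            "lr": lr,
            "train_loss": float(np.mean(epoch_losses)),
            "val_loss": val_loss,
            "val_mae": val_mae,
            "val_mse": val_mse,
        })

        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_state = model.state_dict()
            history.best_epoch = epoch
            epochs_since_best = 0
            plateau_wait = 0
        else:
            epochs_since_best += 1
            plateau_wait += 1
            if plateau_wait >= config.plateau_patience:
                plateau_factor *= config.plateau_factor
                plateau_wait = 0
            if epochs_since_best >= config.early_stop_patience:
                history.stopped_epoch = epoch
                break

    model.load_state_dict(best_state)
    model._y_center = y_center
    model._y_scale = y_scale
    return model, history


def predict_updrs(model: EnhancedDCAN, samples: list[SequenceSample]) -> np.ndarray:
    """Predictions in raw UPDRS points (undoes target standardization)."""
    center = getattr(model, "_y_center", 0.0)
    scale = getattr(model, "_y_scale", 1.0)
    return model.predict(samples) * scale + center
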