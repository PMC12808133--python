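"""Per-visit feature blocks and leakage-safe supervised windows.

Four blocks are built per patient, aligned to the visit axis:

* voice: each of the 16 acoustic measures expanded into raw, denoised,
  velocity, acceleration, rolling mean/sd (3-visit), within-patient
  z-score, and rolling skewness/kurtosis (5-visit), plus two composite
  indices - 146 columns in the default manifest;
* clinical: 9 progression features computed from *lagged* motor-UPDRS only,
  so no cell can see the prediction target;
* meta: age, sex code, test_time;
* text: a 768-dim narrative embedding tiled across timesteps (filled in by
  :mod:`dcan.narrative`).

Supervised windows take the trailing ``T`` visits up to each target visit
(left-padded with zeros and a validity mask for short histories); the
target is the motor-UPDRS score at the final window position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .errors import ConfigError, DomainError
from .telemon import VOICE_FEATURES, PatientSeries, classify_disease_stage

#: transform families applied to every base acoustic measure, in manifest order
VOICE_TRANSFORMS = (
    "raw",
    "denoised",
    "velocity",
    "acceleration",
    "roll_mean",
    "roll_sd",
    "zscore",
    "roll_skew",
    "roll_kurt",
)

CLINICAL_COLUMNS = (
    "days_since_first_visit",
    "visit_number",
    "inter_visit_interval",
    "motor_updrs_lag1",
    "motor_updrs_lag2",
    "motor_updrs_delta",
    "motor_updrs_trend_3visit",
    "stage_code",
    "progression_rate_code",
)

META_COLUMNS = ("age", "sex", "test_time")

STAGE_CODES = {"Early": 0.0, "Moderate": 1.0, "Advanced": 2.0}


@dataclass
class FeatureConfig:
    """Knobs of the feature pipeline (defaults follow the published recipe)."""

    savgol_window: int = 5
    savgol_polyorder: int = 2
    roll_window_stats: int = 3  # rolling mean / sd
    roll_window_moments: int = 5  # rolling skewness / kurtosis
    zscore_eps: float = 0.01
    zscore_clip: float = 5.0
    delta_threshold: float = 0.5  # points; improving/stable/worsening split
    sequence_length: int = 10  # T, visits per supervised window
    causal_denoise: bool = False  # one-sided smoother variant
    rolling_on_denoised: bool = False

    def __post_init__(self) -> None:
        if self.savgol_window % 2 == 0 or self.savgol_window < 3:
            raise ConfigError("savgol_window must be odd and >= 3")
        if self.savgol_polyorder >= self.savgol_window:
            raise ConfigError("savgol_polyorder must be < savgol_window")
        if self.zscore_eps <= 0:
            raise ConfigError("zscore_eps must be > 0")
        if self.sequence_length < 3:
            raise ConfigError("sequence_length must be >= 3")

    @property
    def voice_manifest(self) -> list[str]:
        cols = [f"{feat}:{tr}" for feat in VOICE_FEATURES for tr in VOICE_TRANSFORMS]
        return cols + ["voice_instability_index", "voice_quality_ratio"]


@dataclass
class SequenceSample:
    """One supervised window: four T-step feature blocks plus the target."""

    subject_id: str
    target_visit_index: int
    X_v: np.ndarray  # (T, D_v)
    X_c: np.ndarray  # (T, 9)
    X_m: np.ndarray  # (T, 3)
    X_t: np.ndarray  # (T, 768)
    y: float  # motor-UPDRS points at the target visit
    mask: np.ndarray = field(default=None)  # (T,) bool; True = real visit

    def __post_init__(self) -> None:
        if self.mask is None:
            self.mask = np.ones(self.X_v.shape[0], dtype=bool)


def savgol_denoise(series, window: int, polyorder: int) -> np.ndarray:
    """Savitzky-Golay smoothing with polynomial boundary extrapolation.

    Interior points are the centres of local least-squares polynomial fits;
    the edges are filled by evaluating the boundary fits (scipy's ``interp``
    mode). Series shorter than the window are returned unchanged: there is
    no full window to fit.
    """
    if window % 2 == 0:
        raise ConfigError("savgol window must be odd")
    x = np.asarray(series, dtype=float)
    if x.size < window:
        return x.copy()
    return savgol_filter(x, window_length=window, polyorder=polyorder, mode="interp")


def causal_savgol_denoise(series, window: int, polyorder: int) -> np.ndarray:
    """One-sided variant: fit on the trailing window only, take the last point."""
    if window % 2 == 0:
        raise ConfigError("savgol window must be odd")
    x = np.asarray(series, dtype=float)
    out = x.copy()
    for i in range(x.size):
        lo = max(0, i - window + 1)
        seg = x[lo : i + 1]
        if seg.size <= polyorder:
            continue
        coef = np.polyfit(np.arange(seg.size), seg, polyorder)
        out[i] = np.polyval(coef, seg.size - 1)
    return out


def temporal_derivatives(series, times) -> tuple[np.ndarray, np.ndarray]:
    """Finite-difference velocity and acceleration on an irregular grid.

    Velocity is the backward difference divided by the actual day gap (first
    element 0); acceleration is the same operator applied to velocity.
    """
    x = np.asarray(series, dtype=float)
    t = np.asarray(times, dtype=float)
    if x.size != t.size:
        raise DomainError("series and times must have equal length")
    if x.size <= 1:
        return np.zeros_like(x), np.zeros_like(x)
    gaps = np.diff(t)
    if np.any(gaps <= 0):
        raise DomainError("times must be strictly increasing")
    vel = np.zeros_like(x)
    vel[1:] = np.diff(x) / gaps
    acc = np.zeros_like(x)
    acc[1:] = np.diff(vel) / gaps
    return vel, acc


def rolling_statistics(series, window: int, which: str) -> np.ndarray:
    """Trailing-window rolling statistic with ``min_periods=1``.

    ``which`` is one of mean / sd / skewness / kurtosis; sd is the sample
    (n-1) standard deviation, skewness the adjusted Fisher-Pearson estimate
    and kurtosis the bias-corrected excess kurtosis. Where the statistic is
    undefined (too few points) the value is 0.
    """
    s = pd.Series(np.asarray(series, dtype=float))
    roll = s.rolling(window=window, min_periods=1)
    if which == "mean":
        out = roll.mean()
    elif which == "sd":
        out = roll.std(ddof=1)
    elif which == "skewness":
        out = roll.skew()
    elif which == "kurtosis":
        out = roll.kurt()
    else:
        raise DomainError(f"unknown rolling statistic {which!r}")
    return out.fillna(0.0).to_numpy()


def within_patient_zscore(series, eps: float = 0.01, clip: float = 5.0) -> np.ndarray:
    """(x - mean) / (sd + eps), clipped to +-clip; eps guards zero spread."""
    x = np.asarray(series, dtype=float)
    sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    z = (x - float(np.mean(x))) / (sd + eps)
    return np.clip(z, -clip, clip)


def composite_indices(jitter_pct, shimmer, hnr, nhr) -> tuple[np.ndarray, np.ndarray]:
    """Voice instability index and voice quality ratio.

    Instability is the mean of min-max-normalized jitter and shimmer
    (normalized within the patient's series; a constant trace maps to 0);
    quality is HNR / (NHR + 1e-6).
    """
    def _minmax(v):
        v = np.asarray(v, dtype=float)
        span = v.max() - v.min()
        if span <= 0:
            return np.zeros_like(v)
        return (v - v.min()) / span

    instability = 0.5 * (_minmax(jitter_pct) + _minmax(shimmer))
    quality = np.asarray(hnr, dtype=float) / (np.asarray(nhr, dtype=float) + 1e-6)
    return instability, quality


def build_voice_features(
    series: PatientSeries, config: FeatureConfig
) -> tuple[np.ndarray, list[str]]:
    """Full-length voice block (n_visits x 146) plus its column manifest."""
    t = series.times
    columns: dict[str, np.ndarray] = {}
    denoiser = causal_savgol_denoise if config.causal_denoise else savgol_denoise
    for feat in VOICE_FEATURES:
        raw = series.voice_trace(feat)
        den = denoiser(raw, config.savgol_window, config.savgol_polyorder)
        base = den if config.rolling_on_denoised else raw
        vel, acc = temporal_derivatives(base, t)
        columns[f"{feat}:raw"] = raw
        columns[f"{feat}:denoised"] = den
        columns[f"{feat}:velocity"] = vel
        columns[f"{feat}:acceleration"] = acc
        columns[f"{feat}:roll_mean"] = rolling_statistics(base, config.roll_window_stats, "mean")
        columns[f"{feat}:roll_sd"] = rolling_statistics(base, config.roll_window_stats, "sd")
        columns[f"{feat}:zscore"] = within_patient_zscore(base, config.zscore_eps, config.zscore_clip)
        columns[f"{feat}:roll_skew"] = rolling_statistics(base, config.roll_window_moments, "skewness")
        columns[f"{feat}:roll_kurt"] = rolling_statistics(base, config.roll_window_moments, "kurtosis")
    inst, qual = composite_indices(
        series.voice_trace("Jitter(%)"),
        series.voice_trace("Shimmer"),
        series.voice_trace("HNR"),
        series.voice_trace("NHR"),
    )
    columns["voice_instability_index"] = inst
    columns["voice_quality_ratio"] = qual
    manifest = config.voice_manifest
    block = np.column_stack([columns[name] for name in manifest])
    if not np.all(np.isfinite(block)):
        raise DomainError("voice feature block contains non-finite values")
    return block, manifest


def build_clinical_features(series: PatientSeries, config: FeatureConfig) -> np.ndarray:
    """9-column clinical-progression block computed from lagged UPDRS only.

    Lags missing at the head of the series are imputed with the patient's
    first observed score; the supervised-window mask carries the validity
    information.
    """
    t = series.times
    y = series.motor_updrs
    n = len(y)
    first = y[0]
    lag1 = np.concatenate([[first], y[:-1]])
    lag2 = np.concatenate([[first, first], y[:-2]]) if n >= 2 else np.array([first])
    delta = lag1 - lag2
    trend = rolling_statistics(delta, 3, "mean")
    stage = np.array([STAGE_CODES[classify_disease_stage(max(v, 0.0))] for v in lag1])
    thr = config.delta_threshold
    prog = np.where(delta > thr, 1.0, np.where(delta < -thr, -1.0, 0.0))
    interval = np.zeros(n)
    if n > 1:
        interval[1:] = np.diff(t)
    block = np.column_stack([
        t - t[0],
        np.arange(1, n + 1, dtype=float),
        interval,
        lag1,
        lag2,
        delta,
        trend,
        stage,
        prog,
    ])
    return block


def build_meta_features(series: PatientSeries) -> np.ndarray:
    """(age, sex code, test_time) per visit; age/sex constant per patient."""
    return np.column_stack([
        np.full(len(series), float(series.visits[0].age)),
        np.full(len(series), float(series.visits[0].sex)),
        series.times,
    ])


@dataclass
class PatientBlocks:
    """Full-length, visit-aligned feature blocks for one patient."""

    subject_id: str
    voice: np.ndarray  # (n_visits, D_v)
    clinical: np.ndarray  # (n_visits, 9)
    meta: np.ndarray  # (n_visits, 3)
    text: np.ndarray  # (n_visits, 768) or (768,) tiled at window time
    targets: np.ndarray  # (n_visits,) motor-UPDRS
    manifest: list[str]


def build_patient_blocks(
    series: PatientSeries,
    config: FeatureConfig,
    text_embedding: np.ndarray | None = None,
) -> PatientBlocks:
    voice, manifest = build_voice_features(series, config)
    clinical = build_clinical_features(series, config)
    meta = build_meta_features(series)
    n = len(series)
    if text_embedding is None:
        text = np.zeros((n, 768))
    else:
        e = np.asarray(text_embedding, dtype=float)
        text = np.tile(e.reshape(1, -1), (n, 1)) if e.ndim == 1 else e
    return PatientBlocks(
        subject_id=series.subject_id,
        voice=voice,
        clinical=clinical,
        meta=meta,
        text=text,
        targets=series.motor_updrs,
        manifest=manifest,
    )


def make_supervised_windows(
    blocks: PatientBlocks,
    config: FeatureConfig,
    stride: int = 1,
) -> list[SequenceSample]:
    """Cut trailing-T windows, one per target visit index >= 2.

    The window covers visits ``max(0, i-T+1) .. i`` and is left-padded with
    zeros where history is short; the mask marks real visits. The target is
    the motor-UPDRS at visit ``i``. Exogenous measurements at the target
    visit (voice, meta) are included; the clinical block at any row uses
    only lagged UPDRS, so no feature cell depends on the target-or-later
    scores. ``stride`` subsamples target indices (i = 2, 2+stride, ...).
    """
    T = config.sequence_length
    n = blocks.voice.shape[0]
    samples: list[SequenceSample] = []
    for i in range(2, n, stride):
        lo = max(0, i - T + 1)
        span = i - lo + 1
        pad = T - span

        def windowed(arr):
            out = np.zeros((T, arr.shape[1]))
            out[pad:] = arr[lo : i + 1]
            return out

        mask = np.zeros(T, dtype=bool)
        mask[pad:] = True
        samples.append(
            SequenceSample(
                subject_id=blocks.subject_id,
                target_visit_index=i,
                X_v=windowed(blocks.voice),
                X_c=windowed(blocks.clinical),
                X_m=windowed(blocks.meta),
                X_t=windowed(blocks.text),
                y=float(blocks.targets[i]),
                mask=mask,
            )
        )
    return samples
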