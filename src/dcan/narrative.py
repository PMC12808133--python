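"""Patient narrative summaries and their dense embeddings.

Each patient's longitudinal record is condensed into a structured clinical
narrative - a fixed template filled with per-patient statistics (mean and
spread of motor-UPDRS, its per-visit trend, key acoustic means and trends,
monitoring cadence) - which is then encoded into a 768-dimensional vector
and tiled across the timesteps of every supervised window.

Two encoder backends satisfy the text -> 768-dim contract:

* :class:`HashingTextEncoder` (default): a seeded feature-hashing
  projector. It is fully offline and deterministic; identical texts map to
  identical vectors and unrelated texts are nearly orthogonal.
* :class:`PretrainedSentenceEncoder`: the ``all-mpnet-base-v2`` sentence
  encoder, available when the optional ``sentence-transformers``
  dependency is installed.

Two statistic modes exist: ``full_history`` computes statistics over the
patient's complete record (so a window's text block can reflect visits
after its target - acceptable under patient-level cross-validation, but a
documented caveat), while ``causal`` restricts them to visits up to the
window's target.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass

import numpy as np

from .errors import ContractError, DomainError
from .telemon import SEX_CODES, PatientSeries

EMBED_DIM = 768

SEVERITY_LABELS = ("mild", "moderate", "severe")
PATTERN_LABELS = ("progressive", "stable", "improving")
VARIABILITY_LABELS = ("high", "moderate")
TREND_LABELS = ("increasing", "stable")
IMPAIRMENT_LABELS = ("significant", "moderate", "mild")

#: slope dead-band for the progression-pattern label, points per visit
PATTERN_DEADBAND = 0.05
#: voice-trend dead-band, as a fraction of the feature's patient mean
VOICE_TREND_FRACTION = 0.05
#: variability split on the UPDRS standard deviation, points
VARIABILITY_SD_THRESHOLD = 5.0
#: vocal-impairment thresholds on mean jitter / shimmer (common clinical
#: voice-norm ranges; configurable choices, not published constants)
IMPAIRMENT_SIGNIFICANT = {"jitter": 0.01, "shimmer": 0.06}
IMPAIRMENT_MILD = {"jitter": 0.004, "shimmer": 0.02}

SUMMARY_TEMPLATE = (
    "Clinical presentation: {age}-year-old {sex} patient with Parkinson’s "
    "disease under longitudinal telemonitoring. Disease severity: {severity} "
    "(mean UPDRS: {updrs_mean:.1f}, SD: {updrs_sd:.1f}). Progression pattern: "
    "{pattern} trajectory over {duration_days} days with {n_assessments} "
    "assessments, showing {direction} trend of {updrs_slope:.2f} points per "
    "visit. Voice biomarkers indicate {impairment} vocal impairment: jitter "
    "{jitter_mean:.4f} ({jitter_trend_label}), shimmer {shimmer_mean:.4f}, "
    "harmonics-to-noise ratio {hnr_mean:.1f} dB. Clinical monitoring shows "
    "{variability} symptom variability, suggesting {expression} disease "
    "expression. Assessment frequency: {mean_interval_days:.1f} days per "
    "visit interval."
)


@dataclass
class NarrativeStats:
    """Per-patient longitudinal statistics feeding the summary template."""

    age: int
    sex_label: str
    updrs_mean: float
    updrs_sd: float
    updrs_slope: float  # points per visit, OLS on visit index
    severity: str
    pattern: str
    variability: str
    jitter_mean: float
    shimmer_mean: float
    hnr_mean: float
    jitter_slope: float
    shimmer_slope: float
    jitter_trend_label: str
    shimmer_trend_label: str
    impairment: str
    duration_days: float
    n_assessments: int
    mean_interval_days: float

    def __post_init__(self) -> None:
        assert self.severity in SEVERITY_LABELS
        assert self.pattern in PATTERN_LABELS
        assert self.variability in VARIABILITY_LABELS
        assert self.jitter_trend_label in TREND_LABELS
        assert self.impairment in IMPAIRMENT_LABELS
        assert self.n_assessments >= 1


def _ols_slope(values: np.ndarray) -> float:
    if values.size < 2:
        return 0.0
    idx = np.arange(values.size, dtype=float)
    return float(np.polyfit(idx, values, 1)[0])


def _severity_label(mean_updrs: float) -> str:
    if mean_updrs <= 20:
        return "mild"
    if mean_updrs <= 40:
        return "moderate"
    return "severe"


def _impairment_label(jitter_mean: float, shimmer_mean: float) -> str:
    if jitter_mean >= IMPAIRMENT_SIGNIFICANT["jitter"] or shimmer_mean >= IMPAIRMENT_SIGNIFICANT["shimmer"]:
        return "significant"
    if jitter_mean < IMPAIRMENT_MILD["jitter"] and shimmer_mean < IMPAIRMENT_MILD["shimmer"]:
        return "mild"
    return "moderate"


def _trend_label(slope: float, mean: float, n: int) -> str:
    # increasing iff the fitted change over the record exceeds 5% of the mean
    thr = VOICE_TREND_FRACTION * abs(mean) / max(n - 1, 1)
    return "increasing" if slope > thr else "stable"


def compute_narrative_stats(
    series: PatientSeries, mode: str = "full_history", upto: int | None = None
) -> NarrativeStats:
    """Longitudinal statistics for one patient.

    ``mode="full_history"`` uses every visit; ``mode="causal"`` uses visits
    up to index ``upto`` (inclusive), keeping the statistics free of
    information later than the prediction target.
    """
    if mode not in ("full_history", "causal"):
        raise DomainError(f"unknown narrative mode {mode!r}")
    visits = series.visits
    if mode == "causal":
        if upto is None:
            raise DomainError("causal mode requires an 'upto' visit index")
        visits = visits[: upto + 1]
    if not visits:
        raise DomainError("no visits in scope")

    y = np.array([v.motor_updrs for v in visits])
    t = np.array([v.test_time for v in visits])
    jit = np.array([v.voice["Jitter(%)"] for v in visits])
    shi = np.array([v.voice["Shimmer"] for v in visits])
    hnr = np.array([v.voice["HNR"] for v in visits])

    n = len(visits)
    updrs_mean = float(np.mean(y))
    updrs_sd = float(np.std(y, ddof=1)) if n > 1 else 0.0
    slope = _ols_slope(y)
    if slope > PATTERN_DEADBAND:
        pattern = "progressive"
    elif slope < -PATTERN_DEADBAND:
        pattern = "improving"
    else:
        pattern = "stable"
    duration = float(t[-1] - t[0])
    jitter_slope = _ols_slope(jit)
    shimmer_slope = _ols_slope(shi)
    return NarrativeStats(
        age=visits[0].age,
        sex_label=SEX_CODES[visits[0].sex],
        updrs_mean=updrs_mean,
        updrs_sd=updrs_sd,
        updrs_slope=slope,
        severity=_severity_label(updrs_mean),
        pattern=pattern,
        variability="high" if updrs_sd > VARIABILITY_SD_THRESHOLD else "moderate",
        jitter_mean=float(np.mean(jit)),
        shimmer_mean=float(np.mean(shi)),
        hnr_mean=float(np.mean(hnr)),
        jitter_slope=jitter_slope,
        shimmer_slope=shimmer_slope,
        jitter_trend_label=_trend_label(jitter_slope, float(np.mean(jit)), n),
        shimmer_trend_label=_trend_label(shimmer_slope, float(np.mean(shi)), n),
        impairment=_impairment_label(float(np.mean(jit)), float(np.mean(shi))),
        duration_days=duration,
        n_assessments=n,
        mean_interval_days=duration / n if n else 0.0,
    )


def render_summary(stats: NarrativeStats) -> str:
    """Instantiate the clinical-summary template (deterministic formatting)."""
    return SUMMARY_TEMPLATE.format(
        age=stats.age,
        sex=stats.sex_label,
        severity=stats.severity,
        updrs_mean=stats.updrs_mean,
        updrs_sd=stats.updrs_sd,
        pattern=stats.pattern,
        duration_days=int(round(stats.duration_days)),
        n_assessments=stats.n_assessments,
        direction="upward" if stats.updrs_slope >= 0 else "downward",
        updrs_slope=abs(stats.updrs_slope),
        impairment=stats.impairment,
        jitter_mean=stats.jitter_mean,
        jitter_trend_label=stats.jitter_trend_label,
        shimmer_mean=stats.shimmer_mean,
        hnr_mean=stats.hnr_mean,
        variability=stats.variability,
        expression="variable" if stats.variability == "high" else "consistent",
        mean_interval_days=stats.mean_interval_days,
    )


_SLOT_PATTERN = re.compile(
    r"mean UPDRS: ([\d.]+), SD: ([\d.]+)\).*?over (\d+) days with (\d+) "
    r"assessments.*?trend of ([\d.]+) points per visit.*?jitter ([\d.]+) "
    r"\((\w+)\), shimmer ([\d.]+), harmonics-to-noise ratio ([\d.]+) dB"
)


def parse_summary_numbers(text: str) -> dict[str, float]:
    """Regex-extract the numeric slots back out of a rendered summary."""
    m = _SLOT_PATTERN.search(text)
    if m is None:
        raise DomainError("text does not match the summary template")
    keys = ("updrs_mean", "updrs_sd", "duration_days", "n_assessments",
            "updrs_slope", "jitter_mean", "jitter_trend", "shimmer_mean", "hnr_mean")
    out = {}
    for k, v in zip(keys, m.groups()):
        out[k] = v if k == "jitter_trend" else float(v)
    return out


@dataclass
class NarrativeEmbedding:
    """A 768-dim embedding together with its source text."""

    vector: np.ndarray
    source_text: str

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=float)
        if self.vector.shape != (EMBED_DIM,):
            raise ContractError(
                f"embedding must have dimension {EMBED_DIM}, got {self.vector.shape}"
            )
        if not np.all(np.isfinite(self.vector)):
            raise ContractError("embedding contains non-finite entries")


class HashingTextEncoder:
    """Deterministic feature-hashing sentence projector (offline backend).

    Tokenizes on word boundaries (including numbers, so the template's
    numeric slots shift the vector), hashes each token and its bigrams into
    one of 768 signed buckets, and L2-normalizes. Identical texts map to
    identical vectors; texts with disjoint vocabulary are nearly orthogonal.
    """

    dim = EMBED_DIM

    def __init__(self, seed: int = 0):
        self.seed = int(seed)

    def _bucket(self, token: str) -> tuple[int, float]:
        digest = hashlib.blake2b(
            token.encode("utf-8"), digest_size=8, salt=str(self.seed).encode()[:16]
        ).digest()
        val = int.from_bytes(digest, "little")
        return val % EMBED_DIM, 1.0 if (val >> 63) & 1 else -1.0

    def encode(self, text: str) -> np.ndarray:
        tokens = re.findall(r"[A-Za-z]+|\d+(?:\.\d+)?", text.lower())
        vec = np.zeros(EMBED_DIM)
        for tok in tokens:
            i, s = self._bucket(tok)
            vec[i] += s
        for a, b in zip(tokens, tokens[1:]):
            i, s = self._bucket(a + "_" + b)
            vec[i] += 0.5 * s
        norm = np.linalg.norm(vec)
        return vec / norm if norm > 0 else vec


class PretrainedSentenceEncoder:
    """Sentence-transformer backend (``all-mpnet-base-v2``); optional."""

    dim = EMBED_DIM

    def __init__(self, model_name: str = "sentence-transformers/all-mpnet-base-v2"):
        try:
            from sentence_transformers import SentenceTransformer
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ImportError(
                "the pretrained encoder backend requires the optional "
                "'sentence-transformers' dependency (pip install dcan[pretrained])"
            ) from exc
        self._model = SentenceTransformer(model_name)

    def encode(self, text: str) -> np.ndarray:  # pragma: no cover - optional
        return np.asarray(self._model.encode([text])[0], dtype=float)


def embed_summary(text: str, encoder) -> NarrativeEmbedding:
    """Encode a summary through any backend satisfying the 768-dim contract."""
    if not text:
        raise DomainError("cannot embed an empty summary")
    vec = np.asarray(encoder.encode(text), dtype=float)
    if vec.shape != (EMBED_DIM,):
        raise ContractError(
            f"encoder returned shape {vec.shape}, expected ({EMBED_DIM},)"
        )
    return NarrativeEmbedding(vector=vec, source_text=text)


def tile_embedding(e: NarrativeEmbedding, T: int) -> np.ndarray:
    """Repeat the patient embedding across ``T`` timesteps -> (T, 768)."""
    if T < 1:
        raise DomainError("T must be >= 1")
    return np.tile(e.vector.reshape(1, -1), (T, 1))


def patient_embedding(
    series: PatientSeries,
    encoder,
    mode: str = "full_history",
    upto: int | None = None,
) -> NarrativeEmbedding:
    """Stats -> summary -> embedding for one patient in one call."""
    stats = compute_narrative_stats(series, mode=mode, upto=upto)
    return embed_summary(render_summary(stats), encoder)
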