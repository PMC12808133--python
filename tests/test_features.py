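"""Feature engineering: smoothing, derivatives, rolling moments, windows."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import kurtosis as sp_kurtosis
from scipy.stats import skew as sp_skew

from dcan.errors import ConfigError, DomainError
from dcan.features import (
    FeatureConfig,
    build_clinical_features,
    build_meta_features,
    build_patient_blocks,
    build_voice_features,
    composite_indices,
    make_supervised_windows,
    rolling_statistics,
    savgol_denoise,
    temporal_derivatives,
    within_patient_zscore,
)
from dcan.telemon import PatientSeries, VisitRecord


# ---------------------------------------------------------------------------
# Savitzky-Golay


def test_savgol_preserves_quadratics(rng):
    t = np.arange(20, dtype=float)
    x = 0.3 * t**2 - 2.0 * t + 5.0
    np.testing.assert_allclose(savgol_denoise(x, 5, 2), x, atol=1e-9)


def test_savgol_constant_unchanged():
    x = np.full(11, 3.7)
    np.testing.assert_allclose(savgol_denoise(x, 5, 2), x, atol=1e-12)


def test_savgol_matches_local_least_squares_oracle(rng):
    """Interior points equal the centre of a window-local quadratic fit."""
    x = rng.normal(size=20)
    out = savgol_denoise(x, 5, 2)
    for i in range(2, 18):
        seg = x[i - 2 : i + 3]
        coef = np.polyfit(np.arange(-2, 3), seg, 2)
        assert out[i] == pytest.approx(np.polyval(coef, 0), abs=1e-9)


def test_savgol_short_series_unchanged(rng):
    x = rng.normal(size=3)
    np.testing.assert_array_equal(savgol_denoise(x, 5, 2), x)


def test_savgol_even_window_rejected():
    with pytest.raises(ConfigError):
        savgol_denoise(np.zeros(10), 4, 2)


# ---------------------------------------------------------------------------
# derivatives


def test_derivatives_linear_series():
    t = np.array([0.0, 2.0, 3.5, 7.0])
    x = 2.5 * t + 1.0
    vel, acc = temporal_derivatives(x, t)
    np.testing.assert_allclose(vel[1:], 2.5, atol=1e-12)
    assert vel[0] == 0.0
    np.testing.assert_allclose(acc[2:], 0.0, atol=1e-12)


def test_derivatives_constant_series():
    t = np.array([0.0, 1.0, 4.0])
    vel, acc = temporal_derivatives(np.full(3, 2.0), t)
    np.testing.assert_array_equal(vel, 0.0)
    np.testing.assert_array_equal(acc, 0.0)


def test_derivatives_match_finite_difference_oracle(rng):
    t = np.cumsum(rng.uniform(0.5, 3.0, size=15))
    x = rng.normal(size=15)
    vel, acc = temporal_derivatives(x, t)
    for i in range(1, 15):
        assert vel[i] == pytest.approx((x[i] - x[i - 1]) / (t[i] - t[i - 1]), abs=1e-12)
        assert acc[i] == pytest.approx((vel[i] - vel[i - 1]) / (t[i] - t[i - 1]), abs=1e-12)


def test_derivatives_reject_non_increasing_times():
    with pytest.raises(DomainError):
        temporal_derivatives(np.zeros(3), np.array([0.0, 1.0, 1.0]))


# ---------------------------------------------------------------------------
# rolling statistics


def test_rolling_constant_series():
    x = np.full(8, 4.0)
    np.testing.assert_allclose(rolling_statistics(x, 3, "mean"), 4.0)
    np.testing.assert_allclose(rolling_statistics(x, 3, "sd"), 0.0)


def test_rolling_mean_simple():
    out = rolling_statistics([1.0, 2.0, 3.0], 3, "mean")
    assert out[2] == pytest.approx(2.0)
    assert out[0] == pytest.approx(1.0)  # min_periods = 1
    assert out[1] == pytest.approx(1.5)


@pytest.mark.parametrize("which,window", [("mean", 3), ("sd", 3),
                                          ("skewness", 5), ("kurtosis", 5)])
def test_rolling_matches_per_window_oracle(rng, which, window):
    x = rng.normal(size=25)
    out = rolling_statistics(x, window, which)
    for i in range(25):
        seg = x[max(0, i - window + 1) : i + 1]
        if which == "mean":
            expect = seg.mean()
        elif which == "sd":
            expect = seg.std(ddof=1) if seg.size > 1 else 0.0
        elif which == "skewness":
            expect = sp_skew(seg, bias=False) if seg.size > 2 else 0.0
        else:
            expect = sp_kurtosis(seg, bias=False) if seg.size > 3 else 0.0
        assert out[i] == pytest.approx(expect, abs=1e-9), (which, i)


def test_rolling_unknown_statistic():
    with pytest.raises(DomainError):
        rolling_statistics(np.zeros(4), 3, "median")


# ---------------------------------------------------------------------------
# z-scores and composites


def test_zscore_constant_series_is_zero():
    np.testing.assert_array_equal(within_patient_zscore(np.full(6, 9.0)), 0.0)


def test_zscore_clips_extreme_outlier():
    x = np.concatenate([np.zeros(50), [1000.0]])
    z = within_patient_zscore(x, eps=0.01, clip=5.0)
    assert z[-1] == 5.0


def test_zscore_matches_formula_oracle(rng):
    x = rng.normal(size=30)
    z = within_patient_zscore(x, eps=0.01, clip=5.0)
    expect = np.clip((x - x.mean()) / (x.std(ddof=1) + 0.01), -5, 5)
    np.testing.assert_allclose(z, expect, atol=1e-12)


def test_composite_quality_ratio():
    _, q = composite_indices(np.array([0.01]), np.array([0.03]),
                             np.array([20.0]), np.array([0.5]))
    assert q[0] == pytest.approx(40.0, rel=1e-4)


def test_composite_constant_traces_give_zero_instability():
    inst, _ = composite_indices(np.full(5, 0.01), np.full(5, 0.03),
                                np.full(5, 20.0), np.full(5, 0.5))
    np.testing.assert_array_equal(inst, 0.0)


def test_composite_matches_formula_oracle(rng):
    j = rng.uniform(0.001, 0.02, size=12)
    s = rng.uniform(0.01, 0.08, size=12)
    h = rng.uniform(10, 30, size=12)
    n = rng.uniform(0.001, 0.2, size=12)
    inst, q = composite_indices(j, s, h, n)
    jn = (j - j.min()) / (j.max() - j.min())
    sn = (s - s.min()) / (s.max() - s.min())
    np.testing.assert_allclose(inst, 0.5 * (jn + sn), atol=1e-12)
    np.testing.assert_allclose(q, h / (n + 1e-6), atol=1e-12)


# ---------------------------------------------------------------------------
# blocks


def test_voice_block_has_146_columns(small_cohort, feature_config):
    block, manifest = build_voice_features(small_cohort[0], feature_config)
    assert block.shape == (len(small_cohort[0]), 146)
    assert manifest == feature_config.voice_manifest
    assert len(manifest) == 146
    assert np.all(np.isfinite(block))


def test_voice_block_composes_from_sub_operations(small_cohort, feature_config):
    series = small_cohort[0]
    block, manifest = build_voice_features(series, feature_config)
    cols = {name: block[:, i] for i, name in enumerate(manifest)}
    raw = series.voice_trace("HNR")
    np.testing.assert_array_equal(cols["HNR:raw"], raw)
    np.testing.assert_allclose(
        cols["HNR:denoised"], savgol_denoise(raw, 5, 2), atol=1e-12)
    vel, acc = temporal_derivatives(raw, series.times)
    np.testing.assert_allclose(cols["HNR:velocity"], vel, atol=1e-12)
    np.testing.assert_allclose(cols["HNR:acceleration"], acc, atol=1e-12)
    np.testing.assert_allclose(
        cols["HNR:roll_mean"], rolling_statistics(raw, 3, "mean"), atol=1e-12)
    np.testing.assert_allclose(
        cols["HNR:zscore"], within_patient_zscore(raw), atol=1e-12)


def _single_visit_series(small_cohort):
    v = small_cohort[0].visits[0]
    return PatientSeries(subject_id=v.subject_id, visits=(v,))


def test_single_visit_patient_has_finite_blocks(small_cohort, feature_config):
    series = _single_visit_series(small_cohort)
    block, _ = build_voice_features(series, feature_config)
    assert block.shape[0] == 1
    assert np.all(np.isfinite(block))
    clin = build_clinical_features(series, feature_config)
    assert np.all(np.isfinite(clin))


def test_clinical_block_lags_and_shape(small_cohort, feature_config):
    series = small_cohort[0]
    clin = build_clinical_features(series, feature_config)
    assert clin.shape == (len(series), 9)
    y = series.motor_updrs
    np.testing.assert_array_equal(clin[1:, 3], y[:-1])  # lag1
    np.testing.assert_array_equal(clin[2:, 4], y[:-2])  # lag2
    np.testing.assert_allclose(clin[:, 5], clin[:, 3] - clin[:, 4], atol=1e-12)


def test_clinical_block_ignores_same_row_updrs(small_cohort, feature_config):
    """Perturbing the score at visit t leaves row t's features unchanged."""
    series = small_cohort[0]
    base = build_clinical_features(series, feature_config)
    t_idx = 10
    visits = list(series.visits)
    v = visits[t_idx]
    visits[t_idx] = VisitRecord(subject_id=v.subject_id, age=v.age, sex=v.sex,
                                test_time=v.test_time, motor_updrs=v.motor_updrs + 50,
                                total_updrs=v.total_updrs, voice=v.voice)
    perturbed = build_clinical_features(
        PatientSeries(series.subject_id, tuple(visits)), feature_config)
    np.testing.assert_array_equal(base[: t_idx + 1], perturbed[: t_idx + 1])


def test_meta_block(small_cohort):
    series = small_cohort[0]
    meta = build_meta_features(series)
    assert meta.shape == (len(series), 3)
    assert np.ptp(meta[:, 0]) == 0 and np.ptp(meta[:, 1]) == 0
    np.testing.assert_array_equal(meta[:, 2], series.times)


def test_blocks_are_deterministic(small_cohort, feature_config):
    a = build_patient_blocks(small_cohort[0], feature_config)
    b = build_patient_blocks(small_cohort[0], feature_config)
    np.testing.assert_array_equal(a.voice, b.voice)
    np.testing.assert_array_equal(a.clinical, b.clinical)


# ---------------------------------------------------------------------------
# supervised windows


def _windows(series, feature_config, T=None):
    cfg = feature_config if T is None else FeatureConfig(sequence_length=T)
    blocks = build_patient_blocks(series, cfg)
    return make_supervised_windows(blocks, cfg)


def test_window_count_five_visits(small_cohort):
    series = PatientSeries(small_cohort[0].subject_id, small_cohort[0].visits[:5])
    samples = _windows(series, None, T=3)
    assert len(samples) == 3  # targets at (0-based) visits 2, 3, 4
    assert [s.target_visit_index for s in samples] == [2, 3, 4]
    np.testing.assert_allclose(
        [s.y for s in samples], series.motor_updrs[2:], atol=1e-12)


def test_window_padding_mask(small_cohort, feature_config):
    samples = _windows(small_cohort[0], feature_config)
    T = feature_config.sequence_length
    for s in samples:
        available = min(s.target_visit_index + 1, T)
        assert s.mask.sum() == available
        assert not s.mask[: T - available].any()
        np.testing.assert_array_equal(s.X_v[~s.mask], 0.0)


def test_leakage_guard_target_perturbation(small_cohort, feature_config):
    """Future (target-or-later) UPDRS never reaches any feature cell."""
    series = small_cohort[0]
    base = _windows(series, feature_config)
    target = 12
    visits = list(series.visits)
    for j in range(target, len(visits)):
        v = visits[j]
        visits[j] = VisitRecord(subject_id=v.subject_id, age=v.age, sex=v.sex,
                                test_time=v.test_time, motor_updrs=v.motor_updrs + 17.0,
                                total_updrs=v.total_updrs, voice=v.voice)
    perturbed = make_supervised_windows(
        build_patient_blocks(PatientSeries(series.subject_id, tuple(visits)),
                             feature_config),
        feature_config)
    b = next(s for s in base if s.target_visit_index == target)
    p = next(s for s in perturbed if s.target_visit_index == target)
    np.testing.assert_array_equal(b.X_v, p.X_v)
    np.testing.assert_array_equal(b.X_c, p.X_c)
    np.testing.assert_array_equal(b.X_m, p.X_m)
    assert p.y == pytest.approx(b.y + 17.0)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(n=st.integers(min_value=1, max_value=6), seed=st.integers(0, 10_000))
def test_engineered_values_finite_for_short_series(n, seed, small_cohort):
    """Any series length down to 1 visit yields finite blocks, no NaN."""
    gen = np.random.default_rng(seed)
    template = small_cohort[0].visits[0]
    visits = []
    t = 0.0
    for i in range(n):
        t += float(gen.uniform(0.5, 5.0))
        voice = {k: float(v * gen.uniform(0.5, 1.5)) for k, v in template.voice.items()}
        visits.append(VisitRecord(subject_id="z", age=60, sex=0, test_time=t,
                                  motor_updrs=float(gen.uniform(5, 40)),
                                  total_updrs=float(gen.uniform(40, 50)), voice=voice))
    series = PatientSeries("z", tuple(visits))
    cfg = FeatureConfig()
    blocks = build_patient_blocks(series, cfg)
    for arr in (blocks.voice, blocks.clinical, blocks.meta):
        assert np.all(np.isfinite(arr))


def test_sequence_length_must_be_at_least_three():
    with pytest.raises(ConfigError):
        FeatureConfig(sequence_length=2)
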