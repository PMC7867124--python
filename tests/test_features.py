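"""Feature definitions vs independent brute-force oracles and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from awear.features import (
    BandSpec,
    FeatureConfig,
    FeatureError,
    SpectralEstimate,
    approximate_entropy,
    band_power,
    build_feature_table,
    correlation_dimension,
    extract_feature_vector,
    linear_time_features,
    spectral_features,
    welch_psd,
)
from awear.preprocess import preprocess_recording
from awear.synth import generate_cohort

from conftest import small_cohort_spec


# ------------------------------------------------------------ oracles


def apen_oracle(x, m, r):
    """Direct O(n^2) Pincus template counting (self-matches included)."""
    x = np.asarray(x, dtype=float)

    def phi(mm):
        templates = [x[i : i + mm] for i in range(len(x) - mm + 1)]
        total = 0.0
        for a in templates:
            count = sum(
                1 for b in templates if np.max(np.abs(a - b)) <= r
            )
            total += np.log(count / len(templates))
        return total / len(templates)

    return phi(m) - phi(m + 1)


def correlation_sum_oracle(points, r):
    """Fraction of distinct pairs within Euclidean distance r, by loop."""
    n = len(points)
    count = 0
    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(points[i] - points[j]) <= r:
                count += 1
    return count / (n * (n - 1) / 2)


# ----------------------------------------------------- linear features


def test_linear_features_constant():
    out = linear_time_features([1.0, 1.0, 1.0, 1.0], allow_constant=True)
    assert out["mean"] == 1.0 and out["sd"] == 0.0
    assert out["rms"] == 1.0 and out["peak_value"] == 1.0
    assert "kurtosis" not in out and "skewness" not in out
    with pytest.raises(FeatureError):
        linear_time_features([1.0, 1.0, 1.0, 1.0])


def test_linear_features_alternating():
    out = linear_time_features([-2.0, 2.0, -2.0, 2.0], allow_constant=True)
    assert out["mean"] == 0.0
    assert out["rms"] == 2.0
    assert out["peak_value"] == 2.0


def test_linear_features_gaussian_moments():
    rng = np.random.default_rng(12)
    x = rng.standard_normal(100_000)
    out = linear_time_features(x)
    assert out["kurtosis"] == pytest.approx(3.0, abs=0.1)
    assert out["skewness"] == pytest.approx(0.0, abs=0.05)


@settings(max_examples=50, deadline=None)
@given(st.lists(st.floats(-1e3, 1e3), min_size=4, max_size=200), st.data())
def test_rms_identity(xs, data):
    """RMS^2 = mean^2 + (n-1)/n * SD^2."""
    x = np.asarray(xs)
    out = linear_time_features(x, allow_constant=True)
    n = len(x)
    lhs = out["rms"] ** 2
    rhs = out["mean"] ** 2 + (n - 1) / n * out["sd"] ** 2
    assert lhs == pytest.approx(rhs, rel=1e-9, abs=1e-12)


# --------------------------------------------------------------- ApEn


def test_apen_periodic_square_wave_is_regular():
    x = np.tile([0.0, 1.0], 100)
    val = approximate_entropy(x, m=2, r=0.2 * np.std(x, ddof=1))
    assert 0 <= val < 0.01


def test_apen_noise_exceeds_sine():
    rng = np.random.default_rng(5)
    n = 300
    sine = np.sin(2 * np.pi * 5 * np.arange(n) / 100.0)
    noise = rng.standard_normal(n)
    noise *= np.std(sine, ddof=1) / np.std(noise, ddof=1)
    r = 0.2 * np.std(sine, ddof=1)
    assert approximate_entropy(noise, 2, r) > approximate_entropy(sine, 2, r)


def test_apen_matches_bruteforce_oracle():
    rng = np.random.default_rng(42)
    x = rng.standard_normal(100)
    got = approximate_entropy(x, m=2, r=0.25)
    assert got == pytest.approx(apen_oracle(x, 2, 0.25), abs=1e-10)


def test_apen_input_validation():
    with pytest.raises(ValueError):
        approximate_entropy(np.zeros(10), m=2, r=0.2)
    with pytest.raises(ValueError):
        approximate_entropy(np.random.default_rng(0).normal(size=100), m=0, r=0.2)
    with pytest.raises(ValueError):
        approximate_entropy(np.random.default_rng(0).normal(size=100), m=2, r=-1.0)


# -------------------------------------------------- correlation dimension


def test_corr_dim_limit_cycle_is_one_dimensional():
    t = np.arange(3000) / 100.0
    x = np.sin(2 * np.pi * 2.0 * t)
    d = correlation_dimension(x, emb_dim=5)
    assert 0.9 <= d <= 1.2


def test_corr_dim_noise_fills_plane():
    rng = np.random.default_rng(9)
    x = rng.uniform(-1, 1, size=2000)
    d = correlation_dimension(x, emb_dim=2, delay=1)
    assert 1.7 <= d <= 2.1


def test_corr_dim_scale_invariance():
    rng = np.random.default_rng(3)
    x = np.sin(2 * np.pi * 3.0 * np.arange(2000) / 100.0) + 0.05 * rng.normal(size=2000)
    d1 = correlation_dimension(x, emb_dim=5, delay=5)
    d2 = correlation_dimension(7.3 * x, emb_dim=5, delay=5)
    assert d1 == pytest.approx(d2, rel=1e-9)


def test_correlation_sums_match_bruteforce_oracle():
    """The correlation-sum values behind the slope match a pairwise loop."""
    from awear.features import _embed

    rng = np.random.default_rng(21)
    x = rng.normal(size=260)
    points = _embed(x, 3, 2)
    from scipy.spatial.distance import pdist

    dists = pdist(points)
    for r in np.quantile(dists, [0.2, 0.4]):
        got = np.count_nonzero(dists <= r) / (len(points) * (len(points) - 1) / 2)
        assert got == pytest.approx(correlation_sum_oracle(points, r), abs=1e-12)


def test_corr_dim_errors():
    with pytest.raises((FeatureError, ValueError)):
        correlation_dimension(np.ones(500))
    with pytest.raises(ValueError):
        correlation_dimension(np.random.default_rng(0).normal(size=150), emb_dim=10)


# --------------------------------------------------------------- Welch


def test_welch_zero_signal():
    est = welch_psd(np.zeros(1024), 100.0)
    assert np.all(est.psd == 0.0)
    assert est.frequencies[0] == 0.0 and est.frequencies[-1] == 50.0


def test_welch_peak_at_tone():
    t = np.arange(6000) / 100.0
    est = welch_psd(np.sin(2 * np.pi * 5.0 * t), 100.0)
    assert est.frequencies[np.argmax(est.psd)] == pytest.approx(5.0, abs=0.4)


def test_welch_parseval():
    rng = np.random.default_rng(8)
    x = rng.standard_normal(6000)
    est = welch_psd(x, 100.0)
    integral = np.trapezoid(est.psd, est.frequencies)
    assert integral == pytest.approx(np.var(x), rel=0.10)


def test_welch_nonnegative_and_errors():
    rng = np.random.default_rng(1)
    est = welch_psd(rng.normal(size=1000), 100.0)
    assert np.all(est.psd >= 0)
    with pytest.raises(ValueError):
        welch_psd(np.zeros(100), 100.0, segment_length=256)
    with pytest.raises(ValueError):
        welch_psd(np.zeros(1000), 100.0, overlap_fraction=1.0)


# ---------------------------------------------------- spectral features


def _flat_estimate(c=2.0, f_max=50.0, n=501):
    f = np.linspace(0, f_max, n)
    return SpectralEstimate(f, np.full(n, c), 256, 0.5)


def test_band_power_flat_psd():
    est = _flat_estimate(c=2.0)
    assert band_power(est, 4.0, 6.0) == pytest.approx(4.0)  # 2c over 2 Hz


def test_spectral_peak_localization():
    f = np.linspace(0, 50, 501)
    psd = np.zeros_like(f)
    psd[np.argmin(np.abs(f - 5.0))] = 10.0
    est = SpectralEstimate(f, psd, 256, 0.5)
    out = spectral_features(est, [BandSpec("band_power_4_6", 4, 6)], (2.0, 20.0))
    assert out["peak_frequency"] == pytest.approx(5.0, abs=0.1)
    assert out["peak_amplitude"] == pytest.approx(10.0)


def test_spectral_two_tones():
    f = np.linspace(0, 50, 501)
    psd = np.zeros_like(f)
    psd[np.argmin(np.abs(f - 5.0))] = 10.0
    psd[np.argmin(np.abs(f - 9.0))] = 4.0
    est = SpectralEstimate(f, psd, 256, 0.5)
    out = spectral_features(
        est, [BandSpec("band_power_8_12", 8, 12)], (2.0, 20.0)
    )
    assert out["peak_frequency"] == pytest.approx(5.0, abs=0.1)
    assert out["band_power_8_12"] > 0


def test_spectral_features_empty_band_rejected():
    with pytest.raises(ValueError):
        band_power(_flat_estimate(), 6.0, 6.0)


# ------------------------------------------------------ vector assembly


def test_feature_vector_layout_and_determinism(small_feature_table):
    feature_cols = [
        c for c in small_feature_table.columns if c not in ("subject_id", "class_label")
    ]
    assert len(feature_cols) == 66
    for ch in ("ax", "gy"):
        for feat in ("mean", "sd", "rms", "kurtosis", "skewness", "peak_value",
                     "apen", "corr_dim", "peak_amplitude", "peak_frequency",
                     "band_power_4_6"):
            assert f"{ch}_{feat}" in feature_cols
    assert small_feature_table[feature_cols].notna().all().all()


def test_identical_recordings_identical_rows():
    spec = small_cohort_spec(seed=2, n_healthy=1, n_tremor=1, n_bradykinesia=1)
    recs, labels = generate_cohort(spec)
    filt = [preprocess_recording(r) for r in recs]
    t1 = build_feature_table(filt, labels)
    t2 = build_feature_table(filt, labels)
    assert t1.equals(t2)


def test_magnitude_mode_two_channels():
    spec = small_cohort_spec(seed=2, n_healthy=1, n_tremor=1, n_bradykinesia=1)
    recs, labels = generate_cohort(spec)
    filt = [preprocess_recording(r) for r in recs]
    tab = build_feature_table(filt, labels, FeatureConfig(magnitude_mode=True))
    feats = [c for c in tab.columns if c not in ("subject_id", "class_label")]
    assert len(feats) == 22
    assert all(c.startswith(("amag_", "gmag_")) for c in feats)


def test_label_mismatch_rejected(small_cohort):
    recs, labels = small_cohort
    bad = list(labels)
    bad[0] = "tremor" if bad[0] != "tremor" else "healthy"
    with pytest.raises(ValueError):
        build_feature_table(recs[:3], bad[:3])
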