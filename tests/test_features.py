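"""The 20-feature extractor: loop oracles, spectral concentration, Parseval."""

import math

import numpy as np
import pytest
import pywt

from cchp.annotation import LabeledTrialSet, segment_trials
from cchp.errors import DegenerateSignalError, ValidationError
from cchp.features import (
    BANDS,
    FEATURE_COLUMNS,
    extract_features,
    feature_vector,
    katz_fd,
    kurtosis,
    line_length,
    peak_to_peak,
    relative_band_powers,
    skewness,
    spectral_entropy,
    wavelet_energies,
)

FS = 128.0


def test_line_length_and_ptp_oracles():
    assert line_length([0.0, 1.0, 0.0, 1.0]) == 3.0
    assert line_length(np.full(10, 2.0)) == 0.0
    assert peak_to_peak([0.0, 1.0, 0.0, 1.0]) == 1.0
    assert peak_to_peak(np.full(4, 7.0)) == 0.0
    rng = np.random.default_rng(0)
    x = rng.normal(size=200)
    ll = sum(abs(x[i] - x[i - 1]) for i in range(1, len(x)))
    assert line_length(x) == pytest.approx(ll, rel=1e-10)
    assert line_length(3.0 * x) == pytest.approx(3.0 * line_length(x), rel=1e-10)
    assert peak_to_peak(x + 5.0) == pytest.approx(peak_to_peak(x), rel=1e-10)


def test_moments_population_convention():
    x = np.array([-1.0, 1.0, -1.0, 1.0])
    assert skewness(x) == pytest.approx(0.0, abs=1e-12)
    assert kurtosis(x) == pytest.approx(1.0, rel=1e-12)  # all |z| = 1
    rng = np.random.default_rng(1)
    g = rng.standard_normal(100_000)
    assert kurtosis(g) == pytest.approx(3.0, rel=0.05)
    # loop oracle with 1/T normalization
    x = rng.normal(size=64)
    mu = sum(x) / len(x)
    sd = math.sqrt(sum((v - mu) ** 2 for v in x) / len(x))
    k4 = sum(((v - mu) / sd) ** 4 for v in x) / len(x)
    assert kurtosis(x) == pytest.approx(k4, rel=1e-10)
    with pytest.raises(DegenerateSignalError):
        kurtosis(np.ones(8))


def test_relative_power_tone_concentration():
    t = np.arange(480) / FS
    rp10 = relative_band_powers(np.sin(2 * np.pi * 10 * t), FS)
    names = list(BANDS)
    assert rp10[names.index("low_alpha")] >= 95
    assert rp10.sum() - rp10[names.index("low_alpha")] <= 5
    rp6 = relative_band_powers(np.sin(2 * np.pi * 6 * t), FS)
    assert rp6[names.index("theta")] >= 95
    # bounds: each in [0, 100], 5-band sum <= 100 (bands cover 4-30 of 4-45)
    assert np.all(rp10 >= 0) and np.all(rp10 <= 100 + 1e-9)
    assert rp10.sum() <= 100 + 1e-9


def test_relative_power_white_noise_flat_spectrum():
    rng = np.random.default_rng(2)
    rp = np.mean(
        [relative_band_powers(rng.standard_normal(8192), FS) for _ in range(5)], axis=0
    )
    expected = np.array([(hi - lo) / 41 * 100 for lo, hi in BANDS.values()])
    np.testing.assert_allclose(rp, expected, atol=3.0)


def test_wavelet_energies_parseval_and_localization():
    assert np.all(wavelet_energies(np.zeros(480)) == 0)
    rng = np.random.default_rng(3)
    x = rng.normal(size=480)
    energies = wavelet_energies(x)
    coeffs = pywt.wavedec(x, "db4", mode="symmetric", level=6)
    a6_energy = float(np.sum(coeffs[0] ** 2))
    # db4 is orthogonal but symmetric extension adds boundary coefficients;
    # compare against the decomposition's own total, not the raw signal energy
    assert energies.sum() + a6_energy == pytest.approx(
        sum(float(np.sum(c**2)) for c in coeffs), rel=1e-12
    )
    # periodized extension preserves Parseval exactly against signal energy
    # (length divisible by 2**level so no padding occurs)
    y = rng.normal(size=512)
    coeffs_pp = pywt.wavedec(y, "db4", mode="periodization", level=6)
    total_pp = sum(float(np.sum(c**2)) for c in coeffs_pp)
    assert total_pp == pytest.approx(float(np.sum(y**2)), rel=1e-8)
    # the d2_d6_a6 set swaps D1 for the approximation energy
    e_alt = wavelet_energies(x, coeff_set="d2_d6_a6")
    np.testing.assert_allclose(e_alt[:5], energies[1:], rtol=1e-12)
    assert e_alt[5] == pytest.approx(a6_energy, rel=1e-12)
    # alternating signal -> energy concentrated in D1
    alt = np.tile([1.0, -1.0], 240)
    e = wavelet_energies(alt)
    assert e[0] / e.sum() > 0.95


def test_spectral_entropy_concentration_ordering():
    t = np.arange(480) / FS
    tone = np.sin(2 * np.pi * 10 * t)
    rng = np.random.default_rng(4)
    noise = rng.standard_normal(480)
    n_bins = 42  # 1 Hz Welch bins from 4 to 45 Hz
    h_tone = spectral_entropy(tone, FS)
    h_noise = spectral_entropy(noise, FS)
    assert h_tone < 0.25 * math.log(n_bins)
    assert h_noise > 0.9 * math.log(n_bins)
    assert h_noise > h_tone
    assert spectral_entropy(10.0 * tone, FS) == pytest.approx(h_tone, rel=1e-9)


def test_katz_fd_limits_and_scale_invariance():
    ramp = np.linspace(0.0, 1.0, 200)
    assert katz_fd(ramp) == pytest.approx(1.0, abs=1e-9)
    rng = np.random.default_rng(5)
    noise = rng.standard_normal(480)
    assert katz_fd(noise) > 1.0
    assert katz_fd(4.2 * noise) == pytest.approx(katz_fd(noise), rel=1e-10)
    # loop oracle
    x = rng.normal(size=100)
    L = sum(abs(x[i] - x[i - 1]) for i in range(1, 100))
    d = max(abs(v - x[0]) for v in x)
    n = 99
    expected = math.log10(n) / (math.log10(d / L) + math.log10(n))
    assert katz_fd(x) == pytest.approx(expected, rel=1e-10)


def test_feature_vector_hjorth_columns_delegate():
    from cchp.hjorth import activity, complexity, mobility

    rng = np.random.default_rng(6)
    x = rng.standard_normal(480)
    vec = feature_vector(x, FS)
    assert vec.size == len(FEATURE_COLUMNS) == 20
    i = FEATURE_COLUMNS.index("hjorth_activity")
    np.testing.assert_allclose(
        vec[i : i + 3], [activity(x), mobility(x), complexity(x)], rtol=1e-12
    )
    assert np.all(np.isfinite(vec))


def _segments(n_trials=4, n_parts=4, n_ch=2):
    rng = np.random.default_rng(7)
    trials = [rng.standard_normal((n_ch, n_parts * 480)) for _ in range(n_trials)]
    labels = ["stress", "calm"] * (n_trials // 2)
    ts = LabeledTrialSet("s01", trials, labels, FS, [f"c{i}" for i in range(n_ch)])
    return segment_trials(ts, n_parts)


def test_extract_features_shape_and_restriction():
    seg = _segments()
    df = extract_features(seg)
    assert len(df) == 4 * 4 * 2  # trials x parts x channels
    assert list(df.columns[-20:]) == FEATURE_COLUMNS
    assert df[FEATURE_COLUMNS].notna().all().all()
    one = extract_features(seg, channels=["c1"])
    assert len(one) == 16
    assert set(one["channel"]) == {"c1"}
    with pytest.raises(ValidationError):
        extract_features(seg, channels=["nope"])
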