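"""The 20-feature multi-domain vector extracted per channel per segment.

Time domain: line length, peak-to-peak amplitude, kurtosis, skewness (both
as population standardized moments, no excess correction) and the three
Hjorth descriptors (delegated to cchp.hjorth so there is a single source of
truth for those).

Frequency domain: relative Welch band powers (percent of total 4-45 Hz
power) of theta (4-8), low alpha (8-12), high alpha (12-15), low beta
(15-20) and high beta (20-30 Hz).

Time-frequency domain: squared-coefficient energies of the 6 detail levels
of a db4 discrete wavelet decomposition, the Shannon spectral entropy of the
4-45 Hz Welch spectrum (natural log), and Katz's fractal dimension.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pywt
from scipy import signal as sps

from .annotation import SegmentSet
from .errors import DegenerateSignalError, ValidationError
from .hjorth import activity as _hj_activity
from .hjorth import complexity as _hj_complexity
from .hjorth import mobility as _hj_mobility

__all__ = [
    "BANDS",
    "TOTAL_BAND",
    "FEATURE_COLUMNS",
    "line_length",
    "peak_to_peak",
    "kurtosis",
    "skewness",
    "relative_band_powers",
    "wavelet_energies",
    "spectral_entropy",
    "katz_fd",
    "feature_vector",
    "extract_features",
]

BANDS = {
    "theta": (4.0, 8.0),
    "low_alpha": (8.0, 12.0),
    "high_alpha": (12.0, 15.0),
    "low_beta": (15.0, 20.0),
    "high_beta": (20.0, 30.0),
}
TOTAL_BAND = (4.0, 45.0)

FEATURE_COLUMNS = [
    "line_length",
    "ptp",
    "kurtosis",
    "skewness",
    "hjorth_activity",
    "hjorth_mobility",
    "hjorth_complexity",
    "relpow_theta",
    "relpow_low_alpha",
    "relpow_high_alpha",
    "relpow_low_beta",
    "relpow_high_beta",
    "wavelet_e1",
    "wavelet_e2",
    "wavelet_e3",
    "wavelet_e4",
    "wavelet_e5",
    "wavelet_e6",
    "spectral_entropy",
    "katz_fd",
]


def line_length(x) -> float:
    """Total vertical excursion: sum of absolute successive differences."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValidationError("line length needs >= 2 samples")
    return float(np.abs(np.diff(x)).sum())


def peak_to_peak(x) -> float:
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValidationError("empty signal")
    return float(np.max(x) - np.min(x))


def _standardized_moment(x, order: int) -> float:
    x = np.asarray(x, dtype=float)
    mu = x.mean()
    sd = x.std()  # population (1/T) convention for these moments
    if sd <= 0:
        raise DegenerateSignalError("zero-sd signal: standardized moment undefined")
    return float(np.mean(((x - mu) / sd) ** order))


def kurtosis(x) -> float:
    """4th standardized moment (Gaussian -> 3; no -3 excess term)."""
    return _standardized_moment(x, 4)


def skewness(x) -> float:
    """3rd standardized moment."""
    return _standardized_moment(x, 3)


def _welch_psd(x, fs: float, nperseg: int = 128):
    x = np.asarray(x, dtype=float)
    if fs <= 2 * TOTAL_BAND[1]:
        raise ValidationError(f"fs={fs} too low for the {TOTAL_BAND[1]} Hz band edge")
    if x.size < nperseg:
        raise ValidationError(f"segment of {x.size} samples shorter than one Welch window")
    return sps.welch(x, fs=fs, window="hamming", nperseg=nperseg, noverlap=nperseg // 2)


def _band_power(freqs, psd, lo: float, hi: float) -> float:
    mask = (freqs >= lo) & (freqs <= hi)
    if mask.sum() < 2:
        return 0.0
    return float(np.trapezoid(psd[mask], freqs[mask]))


def relative_band_powers(x, fs: float, nperseg: int = 128) -> np.ndarray:
    """Band powers as percentages of total 4-45 Hz Welch power (5 values)."""
    freqs, psd = _welch_psd(x, fs, nperseg)
    total = _band_power(freqs, psd, *TOTAL_BAND)
    if total <= 0:
        raise DegenerateSignalError("zero total band power")
    return np.array(
        [100.0 * _band_power(freqs, psd, lo, hi) / total for lo, hi in BANDS.values()]
    )


def wavelet_energies(
    x,
    wavelet: str = "db4",
    level: int = 6,
    mode: str = "symmetric",
    coeff_set: str = "d1_d6",
) -> np.ndarray:
    """Squared-coefficient energies of six wavelet coefficient sets.

    ``coeff_set="d1_d6"`` (default) returns detail levels D1..D6 in that
    order, excluding the approximation: at 128 Hz the approximation band sits
    below 1 Hz, a range already removed by the 4-45 Hz band-pass of the input
    data. ``coeff_set="d2_d6_a6"`` swaps D1 for the approximation instead.

    Symmetric boundary extension is the default (reproducible bit-for-bit);
    ``mode="periodization"`` gives exact energy conservation (Parseval) for
    orthogonal wavelets when the length is divisible by 2**level.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2**level:
        raise ValidationError(f"{x.size} samples too short for a {level}-level decomposition")
    coeffs = pywt.wavedec(x, wavelet, mode=mode, level=level)
    approx, details = coeffs[0], coeffs[1:]  # details are [D6, ..., D1]
    energies = [float(np.sum(d**2)) for d in details[::-1]]  # D1 -> D6
    if coeff_set == "d1_d6":
        return np.array(energies)
    if coeff_set == "d2_d6_a6":
        return np.array(energies[1:] + [float(np.sum(approx**2))])
    raise ValidationError(f"unknown coeff_set {coeff_set!r}")


def spectral_entropy(x, fs: float, nperseg: int = 128, base: str = "e") -> float:
    """Shannon entropy of the normalized 4-45 Hz Welch spectrum."""
    freqs, psd = _welch_psd(x, fs, nperseg)
    mask = (freqs >= TOTAL_BAND[0]) & (freqs <= TOTAL_BAND[1])
    p = psd[mask]
    total = p.sum()
    if total <= 0:
        raise DegenerateSignalError("all-zero spectrum: entropy undefined")
    p = p / total
    p = p[p > 0]
    log = np.log2 if base == "2" else np.log
    return float(-(p * log(p)).sum())


def katz_fd(x) -> float:
    """Katz fractal dimension: log10(n) / (log10(d/L) + log10(n)).

    L is the curve length, d the maximal distance from the first sample, and
    n = N - 1 the number of steps (curve length over the mean step).
    """
    x = np.asarray(x, dtype=float)
    L = line_length(x)
    if L <= 0:
        raise DegenerateSignalError("zero-length curve")
    d = float(np.max(np.abs(x - x[0])))
    n = x.size - 1
    return float(np.log10(n) / (np.log10(d / L) + np.log10(n)))


def feature_vector(x, fs: float, nperseg: int = 128) -> np.ndarray:
    """All 20 features of one channel's segment, in FEATURE_COLUMNS order."""
    x = np.asarray(x, dtype=float)
    rel = relative_band_powers(x, fs, nperseg)
    wav = wavelet_energies(x)
    vec = np.concatenate(
        [
            [
                line_length(x),
                peak_to_peak(x),
                kurtosis(x),
                skewness(x),
                _hj_activity(x),
                _hj_mobility(x),
                _hj_complexity(x),
            ],
            rel,
            wav,
            [spectral_entropy(x, fs, nperseg), katz_fd(x)],
        ]
    )
    assert vec.size == len(FEATURE_COLUMNS)
    return vec


def extract_features(
    segments: SegmentSet,
    channels: list[str] | None = None,
    nperseg: int = 128,
) -> pd.DataFrame:
    """One feature row per (segment, channel), restricted to ``channels``.

    Returns a DataFrame with identifier columns (subject, trial, segment,
    channel, label) followed by the 20 feature columns.
    """
    if channels is None:
        channels = list(segments.channel_names)
    unknown = [c for c in channels if c not in segments.channel_names]
    if unknown:
        raise ValidationError(f"unknown channels: {unknown}")
    idx = [segments.channel_names.index(c) for c in channels]
    rows = []
    meta = []
    for seg, lab, ti, si in zip(
        segments.segments, segments.labels, segments.trial_index, segments.segment_index
    ):
        for c, ci in zip(channels, idx):
            rows.append(feature_vector(seg[ci], segments.fs, nperseg))
            meta.append((segments.subject_id, ti, si, c, lab))
    meta_df = pd.DataFrame(
        meta, columns=["subject", "trial", "segment", "channel", "label"]
    )
    feat_df = pd.DataFrame(np.asarray(rows), columns=FEATURE_COLUMNS)
    return pd.concat([meta_df, feat_df], axis=1)
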