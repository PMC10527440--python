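"""Synthetic EEG-like data with a planted channel-class structure.

The generator emulates the shape of a preprocessed affect-rating study:
per-subject sets of fixed-length trials (default 40 trials of 60 s at
128 Hz across 32 named channels), two latent classes (stress / calm), and a
small planted subset of channels whose Hjorth signature differs between the
classes while every other channel is class-independent.

Backgrounds are synthesized in the frequency domain: a random-phase spectrum
with a 1/f amplitude envelope restricted to the 4-45 Hz band, inverse
transformed. This gives exact band control (nothing outside 4-45 Hz) at the
cost of physiological realism -- there are no blinks, drifts or evoked
responses, and inter-channel correlation is zero unless ``mixing`` > 0.

Effect kinds applied to stress trials of the planted channels:

* ``bandpower_shift`` -- adds a 15-30 Hz narrowband component with RMS equal
  to ``effect`` times the channel's background RMS, raising activity (and
  mobility) for the stress class;
* ``mobility_shift`` -- tilts the spectral envelope from 1/f toward flat by
  a factor f^(0.15 * effect), moving the spectral centroid (and hence the
  discrete mobility) upward;
* ``mixed`` -- both.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import CALM, STRESS, LabeledTrialSet
from .errors import ValidationError

__all__ = ["DEAP_CHANNELS", "SimSpec", "GroundTruth", "simulate_subject", "simulate_dataset", "simulate_ratings", "to_recording"]

# 10-20 montage labels in the 32-channel layout common to affect datasets
DEAP_CHANNELS = [
    "Fp1", "AF3", "F3", "F7", "FC5", "FC1", "C3", "T7",
    "CP5", "CP1", "P3", "P7", "PO3", "O1", "Oz", "Pz",
    "Fp2", "AF4", "Fz", "F4", "F8", "FC6", "FC2", "Cz",
    "C4", "T8", "CP6", "CP2", "P4", "P8", "PO4", "O2",
]

BAND = (4.0, 45.0)
BETA_BAND = (15.0, 30.0)


@dataclass
class SimSpec:
    """Conditions of a simulated study; defaults mirror the 32-channel,
    40-trial, 60-s, 128 Hz shape of the reference dataset."""

    n_subjects: int = 10
    n_channels: int = 32
    channel_names: tuple = ()
    fs: float = 128.0
    trial_s: float = 60.0
    n_trials: int = 40
    stress_fraction: float = 0.5
    planted_channels: tuple = ("Fp1", "AF3", "F7")
    effect: float = 2.0
    effect_kind: str = "bandpower_shift"
    mixing: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.channel_names:
            if self.n_channels > len(DEAP_CHANNELS):
                raise ValidationError(
                    f"at most {len(DEAP_CHANNELS)} default channel names"
                )
            self.channel_names = tuple(DEAP_CHANNELS[: self.n_channels])
        if len(self.channel_names) != self.n_channels:
            raise ValidationError("channel_names length != n_channels")
        unknown = set(self.planted_channels) - set(self.channel_names)
        if unknown:
            raise ValidationError(f"planted channels not in montage: {sorted(unknown)}")
        if not 0 < self.stress_fraction < 1:
            raise ValidationError("stress_fraction must be in (0, 1)")
        if self.fs <= 2 * BAND[1]:
            raise ValidationError(f"fs must exceed {2 * BAND[1]} Hz")
        if self.effect_kind not in ("bandpower_shift", "mobility_shift", "mixed"):
            raise ValidationError(f"unknown effect_kind {self.effect_kind!r}")
        if self.effect < 0:
            raise ValidationError("effect must be >= 0")

    @property
    def trial_samples(self) -> int:
        return int(round(self.fs * self.trial_s))


@dataclass
class GroundTruth:
    subject_id: str
    labels: list[str] = field(default_factory=list)
    planted_channels: tuple = ()
    effect: float = 0.0
    effect_kind: str = "bandpower_shift"


def _band_noise(rng, n_samples: int, fs: float, lo: float, hi: float, tilt: float = 0.0):
    """Gaussian noise with a 1/f^(1-tilt) spectral envelope inside [lo, hi] Hz.

    Spectral coefficients are complex Gaussian (Rayleigh amplitudes, uniform
    phases), so per-trial power fluctuates naturally instead of being fixed
    by the envelope.
    """
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    mask = (freqs >= lo) & (freqs <= hi)
    amp = np.zeros_like(freqs)
    amp[mask] = freqs[mask] ** (tilt - 1.0)
    coef = rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)
    x = np.fft.irfft(amp * coef, n=n_samples)
    return x


def _envelope_rms(n_samples: int, fs: float, tilt: float = 0.0) -> float:
    """Expected RMS of ``_band_noise`` output for a given envelope."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    mask = (freqs >= BAND[0]) & (freqs <= BAND[1])
    amp2 = (freqs[mask] ** (tilt - 1.0)) ** 2
    return float(2.0 * np.sqrt(amp2.sum()) / n_samples)


def _trial_signal(rng, spec: SimSpec, is_stress: bool) -> np.ndarray:
    n = spec.trial_samples
    tilt_p = 0.15 * spec.effect if spec.effect_kind in ("mobility_shift", "mixed") else 0.0
    rows = []
    shared = _band_noise(rng, n, spec.fs, *BAND) if spec.mixing > 0 else None
    for name in spec.channel_names:
        planted = name in spec.planted_channels
        tilt = tilt_p if (planted and is_stress) else 0.0
        x = _band_noise(rng, n, spec.fs, *BAND, tilt=tilt)
        x = x / _envelope_rms(n, spec.fs, tilt)  # unit expected RMS
        if shared is not None:
            x = np.sqrt(1 - spec.mixing**2) * x + spec.mixing * shared / shared.std()
        if (
            planted
            and is_stress
            and spec.effect > 0
            and spec.effect_kind in ("bandpower_shift", "mixed")
        ):
            beta = _band_noise(rng, n, spec.fs, *BETA_BAND)
            x = x + spec.effect * beta / beta.std()
        rows.append(x)
    return np.asarray(rows)


def simulate_subject(spec: SimSpec, subject_seed: int) -> tuple[LabeledTrialSet, GroundTruth]:
    """One subject's labeled trials, reproducible from (spec.seed, subject_seed)."""
    rng = np.random.default_rng([spec.seed, int(subject_seed)])
    n_stress = int(round(spec.stress_fraction * spec.n_trials))
    n_stress = min(max(n_stress, 1), spec.n_trials - 1)
    labels = [STRESS] * n_stress + [CALM] * (spec.n_trials - n_stress)
    labels = [labels[i] for i in rng.permutation(spec.n_trials)]
    trials = [_trial_signal(rng, spec, lab == STRESS) for lab in labels]
    sid = f"sim{subject_seed:02d}"
    trial_set = LabeledTrialSet(
        subject_id=sid,
        trials=trials,
        labels=labels,
        fs=spec.fs,
        channel_names=list(spec.channel_names),
    )
    truth = GroundTruth(
        subject_id=sid,
        labels=list(labels),
        planted_channels=tuple(spec.planted_channels),
        effect=spec.effect,
        effect_kind=spec.effect_kind,
    )
    return trial_set, truth


def simulate_dataset(spec: SimSpec) -> list[tuple[LabeledTrialSet, GroundTruth]]:
    """Independent subjects sharing one planted channel set (the cross-subject
    commonality the selection stage is designed to recover)."""
    return [simulate_subject(spec, i) for i in range(spec.n_subjects)]


def simulate_ratings(truths, seed: int = 0) -> pd.DataFrame:
    """Valence/arousal ratings that round-trip to the ground-truth labels.

    Stress trials draw valence in [1, 3) and arousal in (5, 9]; calm trials
    valence in (4, 6) and arousal in [1, 4). Strict interior margins keep
    the labels stable under the strict labelling boundaries.
    """
    if isinstance(truths, GroundTruth):
        truths = [truths]
    rng = np.random.default_rng(seed)
    rows = []
    for gt in truths:
        for t, lab in enumerate(gt.labels):
            if lab == STRESS:
                v = rng.uniform(1.0, 2.999)
                a = rng.uniform(5.001, 9.0)
            else:
                v = rng.uniform(4.001, 5.999)
                a = rng.uniform(1.0, 3.999)
            rows.append((gt.subject_id, t, round(v, 3), round(a, 3)))
    return pd.DataFrame(rows, columns=["subject", "trial", "valence", "arousal"])


def to_recording(trial_set: LabeledTrialSet):
    """Concatenate a subject's trials back into one continuous Recording."""
    from .io import Recording

    return Recording(
        subject_id=trial_set.subject_id,
        signal=np.concatenate(trial_set.trials, axis=1),
        fs=trial_set.fs,
        channel_names=list(trial_set.channel_names),
    )
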