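"""Labelling, subject exclusion, pretrial trimming and segmentation.

Valence/arousal self-reports (each on a 1-9 scale) are mapped to a binary
stress/calm label with a deliberate gap between the two regions:

* stress  : valence < 3 and arousal > 5
* calm    : 4 < valence < 6 and arousal < 4
* anything else is left unlabeled and dropped.

Boundaries are strict, so a trial at valence exactly 3 (or arousal exactly
5) is unlabeled. Subjects whose labeled trials do not contain both classes
cannot support a within-subject contrast and are excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import Recording

__all__ = [
    "STRESS",
    "CALM",
    "UNLABELED",
    "LabeledTrialSet",
    "SegmentSet",
    "label_trial",
    "label_ratings",
    "make_labeled_trials",
    "filter_subjects",
    "trim_pretrial",
    "segment_trial",
    "segment_trials",
]

logger = logging.getLogger(__name__)

STRESS = "stress"
CALM = "calm"
UNLABELED = "unlabeled"


@dataclass
class LabeledTrialSet:
    """One subject's labeled trials, all with identical shape."""

    subject_id: str
    trials: list[np.ndarray]  # each (n_channels, n_samples)
    labels: list[str]  # parallel to trials, values in {stress, calm}
    fs: float
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.trials) != len(self.labels):
            raise ValidationError("trials and labels differ in length")
        shapes = {t.shape for t in self.trials}
        if len(shapes) > 1:
            raise ValidationError(f"trials have inconsistent shapes: {shapes}")
        bad = set(self.labels) - {STRESS, CALM}
        if bad:
            raise ValidationError(f"unexpected labels: {bad}")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def has_both_classes(self) -> bool:
        return STRESS in self.labels and CALM in self.labels


@dataclass
class SegmentSet:
    """Fixed-length, contiguous, non-overlapping windows cut from trials."""

    subject_id: str
    segments: list[np.ndarray]  # each (n_channels, segment_samples)
    labels: list[str]
    trial_index: list[int]
    segment_index: list[int]
    fs: float
    channel_names: list[str] = field(default_factory=list)

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def segment_samples(self) -> int:
        return self.segments[0].shape[1] if self.segments else 0


def label_trial(valence: float, arousal: float) -> str:
    """Map one (valence, arousal) rating to stress / calm / unlabeled."""
    if not (1 <= valence <= 9) or not (1 <= arousal <= 9):
        raise ValidationError(
            f"ratings must be in [1, 9]: valence={valence}, arousal={arousal}"
        )
    if valence < 3 and arousal > 5:
        return STRESS
    if 4 < valence < 6 and arousal < 4:
        return CALM
    return UNLABELED


def label_ratings(ratings: pd.DataFrame) -> pd.DataFrame:
    """Append a ``label`` column to a rating table (see cchp.io.read_ratings)."""
    out = ratings.copy()
    out["label"] = [
        label_trial(v, a) for v, a in zip(out["valence"], out["arousal"])
    ]
    return out


def trim_pretrial(trial: np.ndarray, fs: float, pretrial_s: float) -> np.ndarray:
    """Drop the first ``round(pretrial_s * fs)`` samples of every channel."""
    trial = np.asarray(trial)
    n_drop = int(round(pretrial_s * fs))
    if n_drop >= trial.shape[-1]:
        raise ValidationError(
            f"pretrial of {n_drop} samples >= trial length {trial.shape[-1]}"
        )
    return trial[..., n_drop:]


def make_labeled_trials(
    rec: Recording,
    ratings: pd.DataFrame,
    n_trials: int,
    pretrial_s: float = 0.0,
) -> LabeledTrialSet:
    """Split a concatenated-trials recording, trim pretrials and attach labels.

    The recording's sample axis is assumed to hold ``n_trials`` equal-length
    trials back to back, in the order of the rating table's 0-based trial
    indices. Unlabeled trials are dropped.
    """
    if rec.n_samples % n_trials != 0:
        raise ValidationError(
            f"{rec.n_samples} samples do not divide into {n_trials} trials"
        )
    trial_len = rec.n_samples // n_trials
    sub = ratings[ratings["subject"] == rec.subject_id]
    if sub.empty:
        raise ValidationError(f"no ratings for subject {rec.subject_id!r}")
    labels_by_trial = {
        int(t): label_trial(v, a)
        for t, v, a in zip(sub["trial"], sub["valence"], sub["arousal"])
    }
    trials, labels = [], []
    for i in range(n_trials):
        lab = labels_by_trial.get(i, UNLABELED)
        if lab == UNLABELED:
            continue
        chunk = rec.signal[:, i * trial_len : (i + 1) * trial_len]
        trials.append(trim_pretrial(chunk, rec.fs, pretrial_s))
        labels.append(lab)
    return LabeledTrialSet(
        subject_id=rec.subject_id,
        trials=trials,
        labels=labels,
        fs=rec.fs,
        channel_names=list(rec.channel_names),
    )


def filter_subjects(
    datasets: list[LabeledTrialSet],
) -> tuple[list[LabeledTrialSet], list[str]]:
    """Retain subjects with at least one trial of each class.

    Returns (retained, excluded_ids); a subject lacking either class carries
    no within-subject contrast and is dropped, mirroring the exclusion of
    participants whose self-reports never hit one of the two regions.
    """
    retained, excluded = [], []
    for ds in datasets:
        if ds.has_both_classes():
            retained.append(ds)
        else:
            excluded.append(ds.subject_id)
    return retained, excluded


def segment_trial(trial: np.ndarray, n_parts: int, strict: bool = True) -> list[np.ndarray]:
    """Split a trial into ``n_parts`` contiguous equal windows.

    In strict mode the sample count must divide evenly; in tolerant mode the
    trailing remainder is dropped (and logged).
    """
    trial = np.asarray(trial)
    if n_parts < 1:
        raise ValidationError(f"n_parts must be >= 1, got {n_parts}")
    n = trial.shape[-1]
    if n % n_parts != 0:
        if strict:
            raise ValidationError(f"{n} samples not divisible into {n_parts} parts")
        logger.warning("dropping %d trailing samples", n % n_parts)
    width = n // n_parts
    if width == 0:
        raise ValidationError(f"trial too short to cut into {n_parts} parts")
    return [trial[..., i * width : (i + 1) * width] for i in range(n_parts)]


def segments_as_trials(segments: SegmentSet) -> LabeledTrialSet:
    """Reinterpret segments as pseudo-trials (e.g. to run channel selection
    at segment rather than trial granularity)."""
    return LabeledTrialSet(
        subject_id=segments.subject_id,
        trials=list(segments.segments),
        labels=list(segments.labels),
        fs=segments.fs,
        channel_names=list(segments.channel_names),
    )


def segment_trials(trials: LabeledTrialSet, n_parts: int, strict: bool = True) -> SegmentSet:
    """Segment every trial of a subject; labels propagate to each window."""
    segments, labels, t_idx, s_idx = [], [], [], []
    for ti, (trial, lab) in enumerate(zip(trials.trials, trials.labels)):
        for si, win in enumerate(segment_trial(trial, n_parts, strict=strict)):
            segments.append(win)
            labels.append(lab)
            t_idx.append(ti)
            s_idx.append(si)
    return SegmentSet(
        subject_id=trials.subject_id,
        segments=segments,
        labels=labels,
        trial_index=t_idx,
        segment_index=s_idx,
        fs=trials.fs,
        channel_names=list(trials.channel_names),
    )
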