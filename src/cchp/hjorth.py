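"""Time-domain Hjorth parameters and the per-subject parameter table.

The three Hjorth descriptors summarise a signal ``x`` through variances of
its successive differences:

* activity    = var(x)                       -- signal power
* mobility    = sqrt(var(dx) / var(x))       -- mean-frequency proxy
* complexity  = mobility(dx) / mobility(x)   -- bandwidth proxy; 1 for a
  pure sinusoid, > 1 for broader-band signals

The derivative is the first-order forward difference without sampling-rate
scaling: mobility and complexity are ratios in which the fs factor cancels,
and activity never involves it, so results are comparable across sampling
rates. Variances use the unbiased N-1 convention throughout this module.

``hjorth_table`` evaluates the three descriptors per (trial, channel) and
``zscore`` standardizes each (channel, parameter) column across a subject's
trials, which removes per-channel scale before any correlation is taken.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .annotation import LabeledTrialSet
from .errors import DegenerateSignalError, ValidationError

__all__ = [
    "PARAMETERS",
    "HjorthTable",
    "activity",
    "mobility",
    "complexity",
    "hjorth_table",
    "zscore",
]

PARAMETERS = ("activity", "mobility", "complexity")


def _as_signal(x, min_len: int) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValidationError(f"expected 1-D signal, got shape {x.shape}")
    if x.size < min_len:
        raise ValidationError(f"signal length {x.size} < required {min_len}")
    return x


def activity(x) -> float:
    """Variance of the signal (unbiased, N-1 denominator)."""
    x = _as_signal(x, 2)
    return float(np.var(x, ddof=1))


def mobility(x) -> float:
    """sqrt of the variance ratio between the first difference and the signal."""
    x = _as_signal(x, 3)
    v = np.var(x, ddof=1)
    if v <= 0:
        raise DegenerateSignalError("zero-variance signal has undefined mobility")
    return float(np.sqrt(np.var(np.diff(x), ddof=1) / v))


def complexity(x) -> float:
    """Mobility of the first difference relative to the signal's own mobility."""
    x = _as_signal(x, 4)
    m = mobility(x)
    if m <= 0:
        raise DegenerateSignalError("zero mobility: complexity undefined")
    return float(mobility(np.diff(x)) / m)


@dataclass
class HjorthTable:
    """Hjorth descriptors for one subject, indexed (trial, channel, parameter).

    ``values[t, c, :]`` holds (activity, mobility, complexity) of channel ``c``
    in trial ``t``. ``normalized`` records whether ``zscore`` has been applied.
    """

    subject_id: str
    values: np.ndarray  # (n_trials, n_channels, 3)
    labels: list[str]
    channel_names: list[str] = field(default_factory=list)
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[2] != len(PARAMETERS):
            raise ValidationError(
                f"values must be (trials, channels, 3), got {self.values.shape}"
            )
        if self.values.shape[0] != len(self.labels):
            raise ValidationError("labels do not match trial dimension")
        if self.values.shape[1] != len(self.channel_names):
            raise ValidationError("channel names do not match channel dimension")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    def class_mask(self, label: str) -> np.ndarray:
        return np.asarray([l == label for l in self.labels], dtype=bool)


def hjorth_table(trials: LabeledTrialSet) -> HjorthTable:
    """Evaluate the three Hjorth descriptors per (trial, channel).

    Raises a degenerate-signal error naming the first (trial, channel) whose
    variance vanishes, rather than silently emitting zeros.
    """
    if trials.n_trials == 0:
        raise ValidationError("empty trial set")
    vals = np.empty((trials.n_trials, len(trials.channel_names), 3))
    for t, trial in enumerate(trials.trials):
        sig = np.asarray(trial, dtype=float)
        v0 = np.var(sig, axis=1, ddof=1)
        d1 = np.diff(sig, axis=1)
        v1 = np.var(d1, axis=1, ddof=1)
        d2 = np.diff(d1, axis=1)
        v2 = np.var(d2, axis=1, ddof=1)
        bad = (v0 <= 0) | (v1 <= 0)
        if bad.any():
            c = int(np.argmax(bad))
            raise DegenerateSignalError(
                f"degenerate signal at trial {t}, channel "
                f"{trials.channel_names[c]!r}"
            )
        mob = np.sqrt(v1 / v0)
        comp = np.sqrt(v2 / v1) / mob
        vals[t, :, 0] = v0
        vals[t, :, 1] = mob
        vals[t, :, 2] = comp
    return HjorthTable(
        subject_id=trials.subject_id,
        values=vals,
        labels=list(trials.labels),
        channel_names=list(trials.channel_names),
    )


def zscore(table: HjorthTable, per_class: bool = False) -> HjorthTable:
    """Standardize each (channel, parameter) column across trials.

    By default both classes are pooled: selection is per-subject and the
    class contrast must survive normalization. ``per_class=True`` normalizes
    within each class separately (a sensitivity-analysis variant that
    removes the between-class mean shift). Uses the N-1 standard deviation;
    a constant column is an error because the corresponding correlation is
    undefined.
    """
    if table.n_trials < 2:
        raise ValidationError("z-scoring requires at least 2 trials")
    values = table.values.copy()
    groups = (
        [table.class_mask(lab) for lab in sorted(set(table.labels))]
        if per_class
        else [np.ones(table.n_trials, dtype=bool)]
    )
    for mask in groups:
        if mask.sum() < 2:
            raise ValidationError("z-scoring requires >= 2 trials per group")
        sub = values[mask]
        mean = sub.mean(axis=0, keepdims=True)
        sd = sub.std(axis=0, ddof=1, keepdims=True)
        if (sd <= 0).any():
            c, p = np.argwhere(sd[0] <= 0)[0]
            raise DegenerateSignalError(
                f"constant {PARAMETERS[int(p)]} across trials for channel "
                f"{table.channel_names[int(c)]!r}"
            )
        values[mask] = (sub - mean) / sd
    return replace(table, values=values, normalized=True)
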