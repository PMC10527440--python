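"""Channel selection by correlation of Hjorth parameters (the CCHP core).

Given a subject's z-scored Hjorth table the method scores

* redundancy: a channel-channel correlation per class, aggregating the three
  Hjorth descriptors -- for channels S, K the entry is

      (cov(A_S,A_K) + cov(M_S,M_K) + cov(C_S,C_K))
      / (sd(A_S)sd(A_K) + sd(M_S)sd(M_K) + sd(C_S)sd(C_K))

  computed across the class's trials, then pooled over the two classes by
  an elementwise mean;

* relevance: a channel-class correlation. The default ("pointbiserial")
  computes, per descriptor, the Pearson correlation between the descriptor
  across all labeled trials and the binary class indicator, and averages the
  absolute values over the three descriptors. A "paired" mode implements the
  alternative reading in which stress and calm trials are rank-paired and a
  stress/calm cross-correlation is taken per descriptor.

A subset of k channels is scored by the merit function (mode "literal")

    E = k * r_cf / (k + k(k+1) * k * r_ff)

with r_cf the mean relevance and r_ff the mean absolute pooled pair
correlation inside the subset (0 when k = 1, which makes E = r_cf). The
classical correlation-feature-selection merit k*r_cf / sqrt(k + k(k-1)*r_ff)
is available as mode "cfs". Per-subject subsets come from a greedy best-first
forward search over this merit (or plain top-k relevance); the cross-subject
"general optimal" set is the occurrence-ranked union of per-subject subsets
above a frequency threshold.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateSignalError, ValidationError
from .hjorth import HjorthTable, zscore

__all__ = [
    "SubjectSelection",
    "SelectionResult",
    "pair_channel_corr",
    "pooled_pair_corr",
    "channel_class_corr",
    "merit",
    "select_subject_channels",
    "aggregate_occurrences",
    "rank_and_threshold",
    "select_channels",
]


@dataclass
class SubjectSelection:
    """One subject's significant channels with the subset merit score."""

    subject_id: str
    channels: list[str]  # insertion order of the greedy search
    merit: float
    channel_scores: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "channels": list(self.channels),
            "merit": self.merit,
            "channel_scores": dict(self.channel_scores),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SubjectSelection":
        return cls(
            subject_id=d["subject_id"],
            channels=list(d["channels"]),
            merit=float(d["merit"]),
            channel_scores={k: float(v) for k, v in d["channel_scores"].items()},
        )


@dataclass
class SelectionResult:
    """Per-subject selections plus the cross-subject occurrence ranking."""

    selections: list[SubjectSelection]
    occurrences: dict[str, int]
    ranked: list[str]  # all selected channels, occurrence-ranked
    general_optimal: list[str]  # ranked channels passing the threshold
    params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "selections": [s.to_dict() for s in self.selections],
            "occurrences": dict(self.occurrences),
            "ranked": list(self.ranked),
            "general_optimal": list(self.general_optimal),
            "params": dict(self.params),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SelectionResult":
        return cls(
            selections=[SubjectSelection.from_dict(s) for s in d["selections"]],
            occurrences={k: int(v) for k, v in d["occurrences"].items()},
            ranked=list(d["ranked"]),
            general_optimal=list(d["general_optimal"]),
            params=dict(d["params"]),
        )


def _class_values(table: HjorthTable, class_label: str) -> np.ndarray:
    mask = table.class_mask(class_label)
    if mask.sum() < 2:
        raise ValidationError(
            f"need >= 2 trials of class {class_label!r}, got {int(mask.sum())}"
        )
    return table.values[mask]  # (n_class_trials, n_channels, 3)


def pair_channel_corr(table: HjorthTable, class_label: str) -> np.ndarray:
    """Within-class channel-channel correlation matrix over the 3 descriptors.

    Entry (S, K) sums the three descriptor covariances across the class's
    trials and divides by the sum of the descriptor sd products. Symmetric
    with unit diagonal; a zero denominator (all three descriptors constant)
    raises naming the offending pair.
    """
    vals = _class_values(table, class_label)
    n_ch = vals.shape[1]
    num = np.zeros((n_ch, n_ch))
    den = np.zeros((n_ch, n_ch))
    for p in range(vals.shape[2]):
        x = vals[:, :, p]  # (trials, channels)
        c = np.cov(x, rowvar=False, ddof=1)
        c = np.atleast_2d(c)
        sd = np.sqrt(np.diag(c))
        num += c
        den += np.outer(sd, sd)
    if (den <= 0).any():
        s, k = np.argwhere(den <= 0)[0]
        raise DegenerateSignalError(
            f"zero correlation denominator for channel pair "
            f"({table.channel_names[int(s)]!r}, {table.channel_names[int(k)]!r})"
        )
    mat = num / den
    return (mat + mat.T) / 2.0


def pooled_pair_corr(p_stress: np.ndarray, p_calm: np.ndarray) -> np.ndarray:
    """Elementwise mean of the two class matrices."""
    p_stress = np.asarray(p_stress, dtype=float)
    p_calm = np.asarray(p_calm, dtype=float)
    if p_stress.shape != p_calm.shape:
        raise ValidationError(
            f"shape mismatch: {p_stress.shape} vs {p_calm.shape}"
        )
    return (p_stress + p_calm) / 2.0


def channel_class_corr(table: HjorthTable, mode: str = "pointbiserial") -> np.ndarray:
    """Per-channel class-relevance scores averaged over the 3 descriptors.

    pointbiserial (default): Pearson correlation of each descriptor with the
    binary stress indicator across all labeled trials; the score is the mean
    absolute correlation over the three descriptors, so anti-correlated
    channels count as relevant.

    paired: rank-pair stress and calm trials (truncated to the smaller class)
    and take cov(T_s, T_c) / (sd_s * sd_c) per descriptor; an interpretation
    mode kept for reproduction experiments.
    """
    from .annotation import CALM, STRESS

    stress = _class_values(table, STRESS)
    calm = _class_values(table, CALM)
    if mode == "pointbiserial":
        y = table.class_mask(STRESS).astype(float)
        scores = np.empty(table.n_channels)
        for c in range(table.n_channels):
            rs = []
            for p in range(3):
                x = table.values[:, c, p]
                sx = x.std(ddof=1)
                sy = y.std(ddof=1)
                if sx <= 0 or sy <= 0:
                    raise DegenerateSignalError(
                        f"zero variance for channel {table.channel_names[c]!r}"
                    )
                cov = np.cov(x, y, ddof=1)[0, 1]
                rs.append(abs(cov / (sx * sy)))
            scores[c] = np.mean(rs)
        return scores
    if mode == "paired":
        m = min(stress.shape[0], calm.shape[0])
        scores = np.empty(table.n_channels)
        for c in range(table.n_channels):
            rs = []
            for p in range(3):
                xs = np.sort(stress[:, c, p])[:m]
                xc = np.sort(calm[:, c, p])[:m]
                ss, sc = xs.std(ddof=1), xc.std(ddof=1)
                if ss <= 0 or sc <= 0:
                    raise DegenerateSignalError(
                        f"zero variance for channel {table.channel_names[c]!r}"
                    )
                rs.append(abs(np.cov(xs, xc, ddof=1)[0, 1] / (ss * sc)))
            scores[c] = np.mean(rs)
        return scores
    raise ValidationError(f"unknown channel-class mode {mode!r}")


def merit(
    subset_class_corr_mean: float,
    subset_pair_corr_mean: float,
    k: int,
    mode: str = "literal",
) -> float:
    """Subset score rewarding class relevance, penalizing inter-channel redundancy.

    literal: k*r_cf / (k + k(k+1)*k*r_ff); with k = 1 there are no pairs,
    r_ff is 0 by convention and the merit reduces to r_cf.
    cfs: the classical k*r_cf / sqrt(k + k(k-1)*r_ff).
    """
    r_cf = float(subset_class_corr_mean)
    r_ff = float(subset_pair_corr_mean)
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    if not (np.isfinite(r_cf) and np.isfinite(r_ff)):
        raise ValidationError("non-finite correlation inputs")
    if mode == "literal":
        den = k + k * (k + 1) * k * r_ff
    elif mode == "cfs":
        den = np.sqrt(k + k * (k - 1) * r_ff)
    else:
        raise ValidationError(f"unknown merit mode {mode!r}")
    if den <= 0:
        raise DegenerateSignalError(f"nonpositive merit denominator ({den})")
    return k * r_cf / den


def _subset_merit(
    idx: list[int],
    class_scores: np.ndarray,
    pooled: np.ndarray,
    merit_mode: str,
) -> float:
    k = len(idx)
    r_cf = float(class_scores[idx].mean())
    if k == 1:
        r_ff = 0.0
    else:
        pairs = [abs(pooled[a, b]) for a, b in itertools.combinations(idx, 2)]
        r_ff = float(np.mean(pairs))
    return merit(r_cf, r_ff, k, mode=merit_mode)


def select_subject_channels(
    table: HjorthTable,
    strategy: str = "bestfirst",
    k: int | None = None,
    mode: str = "pointbiserial",
    merit_mode: str = "cfs",
) -> SubjectSelection:
    """Pick one subject's significant channels.

    bestfirst (default): greedy forward search on the subset merit -- start
    empty, repeatedly add the channel that maximizes the merit of the
    augmented subset, stop as soon as no addition improves it. topk: the k
    channels with the highest relevance scores. Ties break toward the higher
    relevance score, then the lexicographically smaller channel name, so the
    result is deterministic for a given table.
    """
    from .annotation import CALM, STRESS

    if not table.normalized:
        table = zscore(table)
    names = table.channel_names
    class_scores = channel_class_corr(table, mode=mode)
    pooled = pooled_pair_corr(
        pair_channel_corr(table, STRESS), pair_channel_corr(table, CALM)
    )

    def tie_key(c: int):
        return (-class_scores[c], names[c])

    if strategy == "topk":
        if k is None:
            raise ValidationError("strategy 'topk' requires k")
        if not 1 <= k <= len(names):
            raise ValidationError(f"k={k} outside [1, {len(names)}]")
        order = sorted(range(len(names)), key=tie_key)
        chosen = order[:k]
        m = _subset_merit(chosen, class_scores, pooled, merit_mode)
    elif strategy == "bestfirst":
        chosen: list[int] = []
        remaining = list(range(len(names)))
        m = -np.inf
        while remaining:
            cand = [
                (_subset_merit(chosen + [c], class_scores, pooled, merit_mode), c)
                for c in remaining
            ]
            top_m = max(mc[0] for mc in cand)  # merit ties → relevance, then name
            tied = [c for mm, c in cand if mm == top_m]
            best_c = min(tied, key=tie_key)
            if top_m <= m:
                break
            chosen.append(best_c)
            remaining.remove(best_c)
            m = top_m
        if not chosen:
            raise DegenerateSignalError("greedy search selected no channel")
    else:
        raise ValidationError(f"unknown strategy {strategy!r}")

    return SubjectSelection(
        subject_id=table.subject_id,
        channels=[names[c] for c in chosen],
        merit=float(m),
        channel_scores={names[c]: float(class_scores[c]) for c in range(len(names))},
    )


def aggregate_occurrences(selections: list[SubjectSelection]) -> dict[str, int]:
    """Count, per channel, in how many subjects' significant sets it appears."""
    if not selections:
        raise ValidationError("no subject selections to aggregate")
    counts: dict[str, int] = {}
    for sel in selections:
        for ch in set(sel.channels):
            counts[ch] = counts.get(ch, 0) + 1
    return counts


def rank_and_threshold(
    occurrences: dict[str, int],
    f_thr: int,
    n_max: int | None = None,
    tie_break_scores: dict[str, float] | None = None,
) -> list[str]:
    """Occurrence-ranked channels passing the frequency threshold.

    Channels selected by at least ``f_thr`` subjects, sorted by descending
    count, ties broken by descending mean relevance then name; truncated to
    ``n_max`` when given. An empty result is returned (not raised) when no
    channel clears the threshold.
    """
    if f_thr < 1:
        raise ValidationError(f"f_thr must be >= 1, got {f_thr}")
    scores = tie_break_scores or {}
    ranked = sorted(
        (ch for ch, n in occurrences.items() if n >= f_thr),
        key=lambda ch: (-occurrences[ch], -scores.get(ch, 0.0), ch),
    )
    if n_max is not None:
        ranked = ranked[:n_max]
    return ranked


def select_channels(
    tables: list[HjorthTable],
    strategy: str = "bestfirst",
    k: int | None = None,
    mode: str = "pointbiserial",
    merit_mode: str = "cfs",
    f_thr: int | None = None,
    n_max: int | None = 8,
) -> SelectionResult:
    """End-to-end selection: per-subject search, occurrence count, ranking.

    ``f_thr`` defaults to ceil(n_subjects / 2): a channel must be significant
    for at least half the subjects to enter the general optimal set.
    """
    if not tables:
        raise ValidationError("no subjects")
    selections = [
        select_subject_channels(t, strategy=strategy, k=k, mode=mode, merit_mode=merit_mode)
        for t in tables
    ]
    occurrences = aggregate_occurrences(selections)
    if f_thr is None:
        f_thr = int(np.ceil(len(tables) / 2))
    mean_scores: dict[str, float] = {}
    for ch in occurrences:
        vals = [s.channel_scores[ch] for s in selections if ch in s.channel_scores]
        mean_scores[ch] = float(np.mean(vals)) if vals else 0.0
    ranked = rank_and_threshold(occurrences, f_thr=1, tie_break_scores=mean_scores)
    general = rank_and_threshold(
        occurrences, f_thr=f_thr, n_max=n_max, tie_break_scores=mean_scores
    )
    return SelectionResult(
        selections=selections,
        occurrences=occurrences,
        ranked=ranked,
        general_optimal=general,
        params={
            "strategy": strategy,
            "k": k,
            "mode": mode,
            "merit_mode": merit_mode,
            "f_thr": int(f_thr),
            "n_max": n_max,
        },
    )
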