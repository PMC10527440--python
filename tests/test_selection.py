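"""Correlation machinery and the channel-subset search."""

import itertools

import numpy as np
import pytest

from cchp.errors import DegenerateSignalError, ValidationError
from cchp.hjorth import HjorthTable, hjorth_table, zscore
from cchp.selection import (
    aggregate_occurrences,
    channel_class_corr,
    merit,
    pair_channel_corr,
    pooled_pair_corr,
    rank_and_threshold,
    select_channels,
    select_subject_channels,
    SubjectSelection,
)
from conftest import planted_table


def _random_table(seed, n_trials=10, n_ch=4):
    rng = np.random.default_rng(seed)
    labels = ["stress", "calm"] * (n_trials // 2)
    names = [f"c{i}" for i in range(n_ch)]
    return HjorthTable("s", rng.normal(size=(n_trials, n_ch, 3)), labels, names)


def _pair_corr_loop(table, label):
    """Brute-force covariance/sd implementation with explicit loops."""
    vals = table.values[table.class_mask(label)]
    n_ch = vals.shape[1]
    out = np.zeros((n_ch, n_ch))
    for s in range(n_ch):
        for k in range(n_ch):
            num = 0.0
            den = 0.0
            for p in range(3):
                a, b = vals[:, s, p], vals[:, k, p]
                num += float(np.cov(a, b, ddof=1)[0, 1])
                den += float(a.std(ddof=1) * b.std(ddof=1))
            out[s, k] = num / den
    return out


def test_pair_corr_matches_brute_force_and_invariants():
    for seed in range(10):
        table = _random_table(seed)
        for label in ("stress", "calm"):
            mat = pair_channel_corr(table, label)
            np.testing.assert_allclose(mat, _pair_corr_loop(table, label), rtol=1e-12)
            np.testing.assert_allclose(mat, mat.T, atol=1e-14)
            np.testing.assert_allclose(np.diag(mat), 1.0, atol=1e-12)
            assert np.all(np.abs(mat) <= 1 + 1e-9)


def test_pair_corr_self_and_anti_correlation():
    rng = np.random.default_rng(0)
    base = rng.normal(size=(8, 1, 3))
    vals = np.concatenate([base, base, -base], axis=1)
    table = HjorthTable("s", vals, ["stress", "calm"] * 4, ["a", "copy", "neg"])
    mat = pair_channel_corr(table, "stress")
    assert mat[0, 1] == pytest.approx(1.0, abs=1e-12)
    assert mat[0, 2] == pytest.approx(-1.0, abs=1e-12)


def test_pooled_pair_corr_is_elementwise_mean():
    a = np.array([[1.0, 0.4], [0.4, 1.0]])
    b = np.array([[1.0, 0.8], [0.8, 1.0]])
    np.testing.assert_allclose(pooled_pair_corr(a, b)[0, 1], 0.6)
    np.testing.assert_allclose(pooled_pair_corr(a, a), a)
    with pytest.raises(ValidationError):
        pooled_pair_corr(a, np.eye(3))


def test_channel_class_corr_planted_limit_and_null_bound():
    # strong planted effect -> score near 1
    strong = planted_table(0, n_planted=1, n_null=1, n_per_class=50, delta=20.0)
    scores = channel_class_corr(zscore(strong))
    assert scores[0] > 0.98
    # null channels stay below the 3/sqrt(n) noise bound
    n = 100
    null_scores = []
    for seed in range(50):
        table = planted_table(seed, n_planted=1, n_null=1, n_per_class=n // 2, delta=0.0)
        null_scores.append(channel_class_corr(zscore(table))[1])
    assert np.mean(null_scores) < 3 / np.sqrt(n)


def test_channel_class_corr_duplicating_trials_preserves_score():
    table = planted_table(1, n_planted=1, n_null=2, n_per_class=10)
    doubled = HjorthTable(
        "s",
        np.concatenate([table.values, table.values], axis=0),
        table.labels * 2,
        table.channel_names,
    )
    np.testing.assert_allclose(
        channel_class_corr(table), channel_class_corr(doubled), rtol=1e-9
    )


def test_merit_printed_formula_and_monotonicity():
    assert merit(0.0, 0.5, 3, mode="literal") == 0.0
    assert merit(0.5, 0.0, 1, mode="literal") == pytest.approx(0.5)
    # k=2 literal: 2*r / (2 + 2*3*2*rff)
    assert merit(0.5, 0.25, 2, mode="literal") == pytest.approx(1.0 / 5.0)
    assert merit(0.5, 0.25, 2, mode="cfs") == pytest.approx(
        2 * 0.5 / np.sqrt(2 + 2 * 0.25)
    )
    for mode in ("literal", "cfs"):
        lo = merit(0.3, 0.2, 3, mode=mode)
        hi = merit(0.6, 0.2, 3, mode=mode)
        assert hi > lo
    with pytest.raises(DegenerateSignalError):
        merit(0.5, -0.5, 2, mode="literal")


def test_select_recovers_planted_pair():
    hits = 0
    for seed in range(100):
        sel = select_subject_channels(planted_table(seed))
        if set(sel.channels) == {"P0", "P1"}:
            hits += 1
    assert hits >= 95


def test_select_on_identical_copies_returns_single_channel():
    rng = np.random.default_rng(5)
    col = rng.normal(size=(20, 1, 3))
    sign = np.array([1.0] * 10 + [-1.0] * 10)
    col[:, 0, :] += sign[:, None]
    vals = np.concatenate([col] * 4, axis=1)
    table = HjorthTable("s", vals, ["stress"] * 10 + ["calm"] * 10, list("abcd"))
    sel = select_subject_channels(table)
    assert len(sel.channels) == 1
    # brute force: no multi-channel subset of copies beats the singleton
    z = zscore(table)
    scores = channel_class_corr(z)
    pooled = pooled_pair_corr(
        pair_channel_corr(z, "stress"), pair_channel_corr(z, "calm")
    )
    best_single = scores.max()
    for k in (2, 3, 4):
        for idx in itertools.combinations(range(4), k):
            r_cf = scores[list(idx)].mean()
            r_ff = np.mean([abs(pooled[a, b]) for a, b in itertools.combinations(idx, 2)])
            assert merit(r_cf, r_ff, k, mode="cfs") <= best_single + 1e-9


def test_select_single_channel_input():
    table = planted_table(0, n_planted=1, n_null=0, n_per_class=10)
    sel = select_subject_channels(table)
    assert sel.channels == ["P0"]
    assert sel.merit == pytest.approx(sel.channel_scores["P0"])


def test_selection_invariant_under_channel_permutation():
    table = planted_table(7)
    sel = select_subject_channels(table)
    perm = [3, 0, 5, 1, 7, 2, 6, 4]
    permuted = HjorthTable(
        "s",
        table.values[:, perm, :],
        table.labels,
        [table.channel_names[i] for i in perm],
    )
    sel_p = select_subject_channels(permuted)
    assert set(sel_p.channels) == set(sel.channels)
    assert sel_p.merit == pytest.approx(sel.merit, rel=1e-9)


def test_selection_invariant_under_positive_rescaling_of_raw_signal():
    from cchp.annotation import LabeledTrialSet

    rng = np.random.default_rng(2)
    trials = [rng.normal(size=(3, 256)) for _ in range(12)]
    for t, trial in enumerate(trials[:6]):
        trial[0] *= 3.0  # planted activity contrast on channel 0
    labels = ["stress"] * 6 + ["calm"] * 6
    ts = LabeledTrialSet("s", trials, labels, 128.0, ["a", "b", "c"])
    sel = select_subject_channels(zscore(hjorth_table(ts)))
    scaled = LabeledTrialSet(
        "s", [np.diag([5.0, 0.2, 1.0]) @ t for t in ts.trials], labels, 128.0, ["a", "b", "c"]
    )
    sel_s = select_subject_channels(zscore(hjorth_table(scaled)))
    assert set(sel.channels) == set(sel_s.channels)


def test_aggregate_occurrences_counts():
    sels = [
        SubjectSelection("s1", ["A", "B"], 0.5),
        SubjectSelection("s2", ["A", "C"], 0.5),
        SubjectSelection("s3", ["A", "B"], 0.5),
    ]
    assert aggregate_occurrences(sels) == {"A": 3, "B": 2, "C": 1}
    assert aggregate_occurrences([SubjectSelection("s", ["X"], 0.1)]) == {"X": 1}


def test_rank_and_threshold_rules():
    counts = {"A": 3, "B": 2, "C": 1}
    assert rank_and_threshold(counts, f_thr=2) == ["A", "B"]
    assert rank_and_threshold(counts, f_thr=1) == ["A", "B", "C"]
    assert rank_and_threshold(counts, f_thr=4) == []
    # ties broken by mean merit, then name
    tied = {"X": 2, "Y": 2}
    assert rank_and_threshold(tied, 1, tie_break_scores={"X": 0.4, "Y": 0.9}) == ["Y", "X"]
    assert rank_and_threshold(tied, 1) == ["X", "Y"]
    assert rank_and_threshold(counts, f_thr=1, n_max=2) == ["A", "B"]


def test_select_channels_end_to_end_defaults():
    tables = [planted_table(seed) for seed in range(5)]
    result = select_channels(tables, n_max=4)
    assert result.general_optimal[:2] == sorted(
        result.general_optimal[:2]
    ) or set(result.general_optimal[:2]) == {"P0", "P1"}
    assert set(result.general_optimal[:2]) == {"P0", "P1"}
    assert result.params["f_thr"] == 3  # ceil(5/2)
    assert all(result.occurrences[c] <= 5 for c in result.occurrences)
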