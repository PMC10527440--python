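"""Hjorth descriptor correctness against brute-force loop oracles and
closed-form sine limits."""

import math

import numpy as np
import pytest

from cchp.annotation import LabeledTrialSet
from cchp.errors import DegenerateSignalError, ValidationError
from cchp.hjorth import HjorthTable, activity, complexity, hjorth_table, mobility, zscore


# --- independent loop oracles (kept deliberately naive) ---------------------

def _var_loop(x):
    m = sum(x) / len(x)
    return sum((v - m) ** 2 for v in x) / (len(x) - 1)


def _diff_loop(x):
    return [x[i + 1] - x[i] for i in range(len(x) - 1)]


def _mobility_loop(x):
    return math.sqrt(_var_loop(_diff_loop(x)) / _var_loop(x))


def _complexity_loop(x):
    return _mobility_loop(_diff_loop(x)) / _mobility_loop(x)


def test_scalar_ops_match_loop_oracles_on_seeded_signals():
    rng = np.random.default_rng(42)
    for _ in range(100):
        x = rng.normal(size=rng.integers(16, 64))
        xs = list(x)
        assert activity(x) == pytest.approx(_var_loop(xs), rel=1e-12)
        assert mobility(x) == pytest.approx(_mobility_loop(xs), rel=1e-12)
        assert complexity(x) == pytest.approx(_complexity_loop(xs), rel=1e-12)


def test_hand_computed_values():
    x = [1.0, -1.0, 1.0, -1.0]
    assert activity(x) == pytest.approx(4.0 / 3.0, rel=1e-12)
    assert mobility(x) == pytest.approx(_mobility_loop(x), rel=1e-12)
    assert activity([5.0, 5.0, 5.0]) == 0.0


def test_sine_closed_forms():
    fs, f, a = 128.0, 1.0, 3.0
    t = np.arange(int(100 * fs)) / fs
    x = a * np.sin(2 * np.pi * f * t)
    assert activity(x) == pytest.approx(a**2 / 2, rel=0.01)
    assert mobility(x) == pytest.approx(2 * np.pi * f / fs, rel=0.02)
    assert complexity(x) == pytest.approx(1.0, rel=0.02)


def test_scale_and_offset_invariance():
    rng = np.random.default_rng(3)
    x = rng.normal(size=256)
    for c, b in [(2.5, 0.0), (0.1, 7.0), (-4.0, -1.0)]:
        y = c * x + b
        assert activity(y) == pytest.approx(c**2 * activity(x), rel=1e-10)
        assert mobility(y) == pytest.approx(mobility(x), rel=1e-10)
        assert complexity(y) == pytest.approx(complexity(x), rel=1e-10)


def test_degenerate_signals_raise():
    with pytest.raises(DegenerateSignalError):
        mobility(np.ones(16))
    with pytest.raises(ValidationError):
        activity([1.0])


def _trialset(values_rng, n_trials=4, n_ch=2):
    trials = [values_rng.normal(size=(n_ch, 64)) for _ in range(n_trials)]
    labels = ["stress", "calm"] * (n_trials // 2)
    return LabeledTrialSet("s01", trials, labels, 128.0, [f"c{i}" for i in range(n_ch)])


def test_hjorth_table_matches_scalar_ops_and_keeps_labels():
    ts = _trialset(np.random.default_rng(0))
    table = hjorth_table(ts)
    assert table.values.shape == (4, 2, 3)
    assert table.labels == ts.labels
    for t in range(4):
        for c in range(2):
            x = ts.trials[t][c]
            np.testing.assert_allclose(
                table.values[t, c],
                [activity(x), mobility(x), complexity(x)],
                rtol=1e-12,
            )


def test_hjorth_table_names_degenerate_channel():
    trials = [np.vstack([np.random.default_rng(0).normal(size=32), np.zeros(32)])]
    ts = LabeledTrialSet("s01", trials, ["stress"], 128.0, ["good", "flat"])
    with pytest.raises(DegenerateSignalError, match="flat"):
        hjorth_table(ts)


def test_zscore_two_point_oracle_and_column_stats():
    vals = np.zeros((2, 1, 3))
    vals[:, 0, 0] = [1.0, 3.0]
    vals[:, 0, 1] = [0.0, 2.0]
    vals[:, 0, 2] = [5.0, 9.0]
    table = HjorthTable("s", vals, ["stress", "calm"], ["c0"])
    z = zscore(table)
    np.testing.assert_allclose(z.values[:, 0, 0], [-1 / np.sqrt(2), 1 / np.sqrt(2)])
    assert z.normalized

    rng = np.random.default_rng(1)
    big = HjorthTable(
        "s", rng.normal(size=(30, 4, 3)), ["stress", "calm"] * 15, list("abcd")
    )
    zz = zscore(big)
    assert np.abs(zz.values.mean(axis=0)).max() < 1e-9
    assert np.abs(zz.values.std(axis=0, ddof=1) - 1).max() < 1e-9
    # idempotent within tolerance
    np.testing.assert_allclose(zscore(zz).values, zz.values, atol=1e-9)


def test_zscore_rejects_constant_column():
    vals = np.random.default_rng(0).normal(size=(4, 1, 3))
    vals[:, 0, 1] = 2.0
    table = HjorthTable("s", vals, ["stress", "calm"] * 2, ["c0"])
    with pytest.raises(DegenerateSignalError, match="mobility"):
        zscore(table)


def test_zscore_per_class_normalizes_within_each_class():
    rng = np.random.default_rng(9)
    vals = rng.normal(size=(20, 2, 3))
    labels = ["stress"] * 10 + ["calm"] * 10
    vals[:10] += 5.0  # strong class shift
    table = HjorthTable("s", vals, labels, ["a", "b"])
    z = zscore(table, per_class=True)
    for mask in (np.arange(20) < 10, np.arange(20) >= 10):
        assert np.abs(z.values[mask].mean(axis=0)).max() < 1e-9
        assert np.abs(z.values[mask].std(axis=0, ddof=1) - 1).max() < 1e-9
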