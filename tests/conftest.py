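import numpy as np
import pytest

from cchp.hjorth import HjorthTable
from cchp.synthetic import SimSpec, simulate_dataset


def planted_table(
    seed: int,
    n_planted: int = 2,
    n_null: int = 6,
    n_per_class: int = 20,
    delta: float = 1.0,
) -> HjorthTable:
    """Hjorth table with a class shift of 2*delta (in noise-sd units) planted
    on the first ``n_planted`` channels; remaining channels are pure noise."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    labels = ["stress"] * n_per_class + ["calm"] * n_per_class
    names = [f"P{i}" for i in range(n_planted)] + [f"N{i}" for i in range(n_null)]
    vals = rng.normal(size=(n, n_planted + n_null, 3))
    sign = np.array([1.0] * n_per_class + [-1.0] * n_per_class)
    vals[:, :n_planted, :] += delta * sign[:, None, None]
    return HjorthTable("s", vals, labels, names)


@pytest.fixture(scope="session")
def small_dataset():
    """Three simulated subjects, 8 channels, 2 planted, short trials."""
    spec = SimSpec(
        n_subjects=3,
        n_channels=8,
        n_trials=16,
        trial_s=15.0,
        planted_channels=("Fp1", "AF3"),
        effect=2.0,
        seed=11,
    )
    return spec, simulate_dataset(spec)
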