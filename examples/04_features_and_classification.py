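"""Multi-domain features on selected channels, then cross-validated accuracy.

Extracts the 20-feature vector per 480-sample segment per channel and
evaluates the three classifiers with subject-wise stratified 10-fold CV.
"""

import pandas as pd

from cchp.annotation import segment_trials
from cchp.classify import channel_sweep, crossvalidate
from cchp.features import extract_features
from cchp.synthetic import SimSpec, simulate_dataset

spec = SimSpec(
    n_subjects=3,
    n_channels=8,
    n_trials=24,
    trial_s=15.0,
    planted_channels=("Fp1", "AF3"),
    effect=0.4,
    seed=3,
)
frames = []
for trial_set, _ in simulate_dataset(spec):
    segments = segment_trials(trial_set, n_parts=4)
    frames.append(extract_features(segments))
features = pd.concat(frames, ignore_index=True)
print(f"feature table: {len(features)} rows (segment x channel), 20 feature columns")

report = crossvalidate(features, ["svm", "knn", "rlda"], channels=["Fp1", "AF3"], seed=0)
print(report.to_frame().groupby("classifier")[["precision", "recall", "accuracy"]].mean())

sweep = channel_sweep(features, ["Fp1", "AF3", "F3", "F7"], [1, 2, 4], classifier="svm", seed=0)
print()
print(sweep.to_string(index=False))
# Accuracy saturates once the informative (planted) channels are included;
# adding uninformative channels beyond them buys nothing.
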