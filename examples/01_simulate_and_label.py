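"""Simulate a small stress/calm EEG study and label trials from ratings.

Generates two synthetic subjects, derives valence/arousal self-reports from
the ground-truth labels, and runs the labelling rule back over them.
"""

from cchp.annotation import label_trial
from cchp.synthetic import SimSpec, simulate_dataset, simulate_ratings

spec = SimSpec(n_subjects=2, n_channels=8, n_trials=10, trial_s=8.0, seed=0)
dataset = simulate_dataset(spec)
ratings = simulate_ratings([gt for _, gt in dataset], seed=0)

print(ratings.head(5).to_string(index=False))
print()
for _, gt in dataset:
    sub = ratings[ratings["subject"] == gt.subject_id]
    relabelled = [label_trial(v, a) for v, a in zip(sub["valence"], sub["arousal"])]
    n_stress = relabelled.count("stress")
    print(
        f"{gt.subject_id}: {n_stress} stress / {len(relabelled) - n_stress} calm "
        f"trials; labels round-trip: {relabelled == gt.labels}"
    )

# The rule maps low valence + high arousal to stress, mid valence + low
# arousal to calm; everything else would be dropped as unlabeled.
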