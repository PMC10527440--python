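"""The whole pipeline from one config: simulate -> annotate -> select ->
extract -> classify, with every artifact written under a working directory."""

import json

from cchp.pipeline import RunConfig, run_pipeline

config = RunConfig(
    workdir="scratch/example_run",
    simulate={
        "n_subjects": 3,
        "n_channels": 8,
        "n_trials": 16,
        "trial_s": 15.0,
        "planted_channels": ["Fp1", "AF3"],
        "effect": 2.0,
    },
    n_parts=4,
    n_folds=4,
    classifiers=["svm"],
    n_max=4,
    seed=1,
)
summary = run_pipeline(config)
print("general optimal channels:", summary["general_optimal_channels"])
print("mean accuracy:", json.dumps(summary["mean_accuracy"]))
print("artifacts in", config.workdir, "(ratings, labels, selection report, features, CV report)")
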