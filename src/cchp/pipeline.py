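"""End-to-end run: simulate/load -> annotate -> select -> extract -> classify.

The pipeline is deterministic given the resolved configuration: every
report embeds the configuration and the package version, no timestamps are
written, and all randomness flows from the configured seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .annotation import filter_subjects, make_labeled_trials, segment_trials
from .classify import channel_sweep, crossvalidate
from .errors import ValidationError
from .features import extract_features
from .hjorth import hjorth_table, zscore
from .io import (
    read_ratings,
    read_recording,
    write_matrix_recording,
    write_ratings,
    write_selection_report,
)
from .selection import select_channels
from .synthetic import SimSpec, simulate_dataset, simulate_ratings, to_recording

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Resolved parameters of one pipeline run (serialized into reports)."""

    workdir: str = "cchp_run"
    # input: either simulate, or point at existing matrix recordings + ratings
    simulate: dict | None = None  # kwargs for SimSpec
    recordings: list[str] = field(default_factory=list)  # matrix CSV paths
    ratings: str | None = None
    n_trials: int = 40
    pretrial_s: float = 0.0
    # segmentation
    n_parts: int = 16
    # selection
    mode: str = "pointbiserial"
    merit_mode: str = "cfs"
    strategy: str = "bestfirst"
    selection_unit: str = "trial"  # or "segment": select on 480-sample windows
    per_class_zscore: bool = False
    f_thr: int | None = None
    n_max: int | None = 8
    # classification
    classifiers: list[str] = field(default_factory=lambda: ["svm", "knn", "rlda"])
    n_folds: int = 10
    sweep_sizes: list[int] | None = None
    scale: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the summary dict (also written to disk)."""
    workdir = Path(config.workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    cfg = config.to_dict()

    # --- stage: input -------------------------------------------------------
    if config.simulate is not None:
        logger.info("stage simulate: generating synthetic dataset")
        spec = SimSpec(seed=config.seed, **config.simulate)
        dataset = simulate_dataset(spec)
        ratings = simulate_ratings([gt for _, gt in dataset], seed=config.seed)
        rat_path = workdir / "ratings.csv"
        write_ratings(ratings, rat_path)
        rec_paths = []
        for ts, _ in dataset:
            p = workdir / f"{ts.subject_id}.csv"
            write_matrix_recording(to_recording(ts), p)
            rec_paths.append(str(p))
        (workdir / "ground_truth.json").write_text(
            json.dumps(
                {
                    "planted_channels": list(spec.planted_channels),
                    "effect": spec.effect,
                    "effect_kind": spec.effect_kind,
                    "labels": {gt.subject_id: gt.labels for _, gt in dataset},
                },
                indent=2,
            )
        )
        n_trials = spec.n_trials
        pretrial_s = 0.0
    else:
        if not config.recordings or config.ratings is None:
            raise ValidationError("config must provide either 'simulate' or recordings + ratings")
        rat_path = Path(config.ratings)
        rec_paths = list(config.recordings)
        n_trials = config.n_trials
        pretrial_s = config.pretrial_s

    # --- stage: annotate ----------------------------------------------------
    logger.info("stage annotate: labelling trials")
    ratings = read_ratings(rat_path)
    trial_sets = []
    for p in rec_paths:
        rec = read_recording(p, format="matrix")
        trial_sets.append(
            make_labeled_trials(rec, ratings, n_trials=n_trials, pretrial_s=pretrial_s)
        )
    retained, excluded = filter_subjects(trial_sets)
    if not retained:
        raise ValidationError("no subject retained after labelling")
    labels_rows = [
        {"subject": ts.subject_id, "trial": i, "label": lab}
        for ts in retained
        for i, lab in enumerate(ts.labels)
    ]
    import pandas as pd

    pd.DataFrame(labels_rows).to_csv(workdir / "labels.csv", index=False)

    # --- stage: select ------------------------------------------------------
    logger.info("stage select: CCHP channel selection on %d subjects", len(retained))
    if config.selection_unit == "trial":
        units = retained
    elif config.selection_unit == "segment":
        from .annotation import segments_as_trials

        units = [segments_as_trials(segment_trials(ts, config.n_parts)) for ts in retained]
    else:
        raise ValidationError(f"unknown selection_unit {config.selection_unit!r}")
    tables = [
        zscore(hjorth_table(ts), per_class=config.per_class_zscore) for ts in units
    ]
    result = select_channels(
        tables,
        strategy=config.strategy,
        mode=config.mode,
        merit_mode=config.merit_mode,
        f_thr=config.f_thr,
        n_max=config.n_max,
    )
    result.params.update({"config": cfg, "version": __version__, "excluded_subjects": excluded})
    write_selection_report(result, workdir / "selection_report.json")

    # --- stage: extract -----------------------------------------------------
    logger.info("stage extract: features on %d channels", len(result.general_optimal))
    frames = []
    for ts in retained:
        seg = segment_trials(ts, n_parts=config.n_parts)
        frames.append(extract_features(seg, channels=result.general_optimal))
    features = pd.concat(frames, ignore_index=True)
    features.to_csv(workdir / "features.csv", index=False)

    # --- stage: classify ----------------------------------------------------
    logger.info("stage classify: %s", config.classifiers)
    report = crossvalidate(
        features,
        classifiers=config.classifiers,
        n_folds=config.n_folds,
        seed=config.seed,
        scale=config.scale,
    )
    report.to_frame().to_csv(workdir / "cv_report.csv", index=False)
    sweep = None
    if config.sweep_sizes:
        sweep = channel_sweep(
            features,
            result.general_optimal,
            set_sizes=[s for s in config.sweep_sizes if s <= len(result.general_optimal)],
            classifier=config.classifiers[0],
            n_folds=config.n_folds,
            seed=config.seed,
            scale=config.scale,
        )
        sweep.to_csv(workdir / "sweep.csv", index=False)

    summary = {
        "version": __version__,
        "config": cfg,
        "excluded_subjects": excluded,
        "general_optimal_channels": result.general_optimal,
        "mean_accuracy": {
            name: float(
                report.to_frame().query("classifier == @name")["accuracy"].mean()
            )
            for name in config.classifiers
        },
        "sweep": sweep.to_dict(orient="records") if sweep is not None else None,
    }
    (workdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
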