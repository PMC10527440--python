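"""Convert preprocessed DEAP ``.dat`` pickles to the package's matrix format.

DEAP's preprocessed archive is EULA-gated, so this converter ships as an
optional, untested utility: it is not exercised by the test suite and
requires a local copy of ``data_preprocessed_python/``.

Each ``sXX.dat`` pickle holds ``data`` with shape (40 trials, 40 channels,
8064 samples at 128 Hz incl. the 3-s pretrial) and ``labels`` with columns
(valence, arousal, dominance, liking). Only the first 32 (EEG) channels are
kept. Trials are concatenated along the sample axis into one channels x
samples CSV per subject (pretrial retained; pass ``--pretrial-s 3`` to the
pipeline to trim it), plus a shared ratings.csv.

Usage:
    python scripts/convert_deap.py data_preprocessed_python/ out_dir/
"""

from __future__ import annotations

import argparse
import pickle
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from cchp.io import Recording, write_matrix_recording
from cchp.synthetic import DEAP_CHANNELS


def convert(src: Path, dst: Path) -> None:
    dst.mkdir(parents=True, exist_ok=True)
    rating_rows = []
    for dat in sorted(src.glob("s*.dat")):
        sid = dat.stem
        with open(dat, "rb") as fh:
            payload = pickle.load(fh, encoding="latin1")
        data = np.asarray(payload["data"])[:, :32, :]  # EEG channels only
        labels = np.asarray(payload["labels"])
        signal = np.concatenate(list(data), axis=1)
        rec = Recording(sid, signal, 128.0, DEAP_CHANNELS)
        write_matrix_recording(rec, dst / f"{sid}.csv")
        for trial, (valence, arousal, *_rest) in enumerate(labels):
            rating_rows.append((sid, trial, float(valence), float(arousal)))
        print(f"converted {sid}: {data.shape[0]} trials")
    pd.DataFrame(
        rating_rows, columns=["subject", "trial", "valence", "arousal"]
    ).to_csv(dst / "ratings.csv", index=False)


if __name__ == "__main__":
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("src", type=Path, help="data_preprocessed_python directory")
    parser.add_argument("dst", type=Path, help="output directory")
    args = parser.parse_args()
    if not args.src.is_dir():
        sys.exit(f"not a directory: {args.src}")
    convert(args.src, args.dst)
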