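"""Reading and writing recordings, rating tables, and selection reports.

Two signal formats are supported: European Data Format (EDF), read through
mne, and a plain-text matrix format (CSV with channels as rows, samples as
columns) accompanied by a YAML sidecar holding the sampling rate and channel
names.  Reports are JSON.

A minimal 16-bit EDF writer is included so recordings can be exported and
round-tripped; it writes one EDF+ -compatible continuous file with a single
physical dimension (microvolts).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError

__all__ = [
    "Recording",
    "read_recording",
    "write_matrix_recording",
    "write_edf",
    "read_ratings",
    "write_ratings",
    "write_selection_report",
    "read_selection_report",
]


@dataclass
class Recording:
    """One subject's multichannel signal.

    Attributes
    ----------
    subject_id : str
        Identifier matching the rating table's ``subject`` column.
    signal : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz (> 0).
    channel_names : list of str
        Ordered, unique channel labels (10-20 montage names in practice).
    """

    subject_id: str
    signal: np.ndarray
    fs: float
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValidationError(
                f"signal must be 2-D (channels x samples), got ndim={self.signal.ndim}"
            )
        if self.fs <= 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        if len(self.channel_names) != self.signal.shape[0]:
            raise ValidationError(
                f"{len(self.channel_names)} channel names for "
                f"{self.signal.shape[0]} signal rows"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValidationError("duplicate channel names")
        bad = ~np.isfinite(self.signal)
        if bad.any():
            ch = self.channel_names[int(np.argwhere(bad.any(axis=1))[0, 0])]
            raise ValidationError(f"non-finite samples in channel {ch!r}")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]


def _read_matrix(path: Path, sidecar: Path | None, subject_id: str | None) -> Recording:
    if sidecar is None:
        sidecar = path.with_suffix(".yaml")
    if not Path(sidecar).exists():
        raise FileNotFoundError(f"sidecar not found: {sidecar}")
    meta = yaml.safe_load(Path(sidecar).read_text())
    if not isinstance(meta, dict) or "fs" not in meta or "channel_names" not in meta:
        raise ValidationError(f"sidecar {sidecar} must define 'fs' and 'channel_names'")
    signal = np.loadtxt(path, delimiter=",", ndmin=2)
    return Recording(
        subject_id=subject_id or meta.get("subject_id", Path(path).stem),
        signal=signal,
        fs=float(meta["fs"]),
        channel_names=[str(c) for c in meta["channel_names"]],
    )


def _read_edf(path: Path, subject_id: str | None) -> Recording:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    try:
        data = raw.get_data(units="uV")
    except (ValueError, TypeError):  # channels without a unit (e.g. 'misc')
        data = raw.get_data() * 1e6
    return Recording(
        subject_id=subject_id or Path(path).stem,
        signal=np.asarray(data, dtype=float),
        fs=float(raw.info["sfreq"]),
        channel_names=list(raw.ch_names),
    )


def read_recording(
    path: str | Path,
    format: str | None = None,
    sidecar: str | Path | None = None,
    subject_id: str | None = None,
) -> Recording:
    """Read a recording from EDF or matrix format.

    ``format`` is inferred from the extension when omitted (``.edf`` vs
    anything else). Channel order is preserved exactly as stored.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"recording not found: {path}")
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "matrix"
    if format == "edf":
        return _read_edf(path, subject_id)
    if format == "matrix":
        return _read_matrix(path, Path(sidecar) if sidecar else None, subject_id)
    raise ValidationError(f"unknown recording format {format!r}")


def write_matrix_recording(rec: Recording, path: str | Path, sidecar: str | Path | None = None) -> None:
    """Write a recording as channels-x-samples CSV plus a YAML sidecar."""
    path = Path(path)
    if sidecar is None:
        sidecar = path.with_suffix(".yaml")
    np.savetxt(path, rec.signal, delimiter=",", fmt="%.10g")
    meta = {
        "subject_id": rec.subject_id,
        "fs": float(rec.fs),
        "channel_names": list(rec.channel_names),
    }
    Path(sidecar).write_text(yaml.safe_dump(meta, sort_keys=False))


def _ascii(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValidationError(f"EDF header field {s!r} exceeds {width} bytes")
    return s.ljust(width).encode("ascii")


def write_edf(rec: Recording, path: str | Path) -> None:
    """Write a recording to a minimal 16-bit EDF file.

    Samples are quantized onto the per-channel physical range, so a
    write-then-read round trip agrees only to within one quantization step
    (range / 2^16). Record length is one second when the sample count is a
    whole number of seconds, otherwise a single record holds everything.
    """
    path = Path(path)
    ns = rec.n_channels
    n_samples = rec.n_samples
    fs = rec.fs
    if abs(fs - round(fs)) < 1e-9 and n_samples % int(round(fs)) == 0:
        spr = int(round(fs))
        n_records = n_samples // spr
        duration = 1.0
    else:
        spr = n_samples
        n_records = 1
        duration = n_samples / fs

    pmins, pmaxs, digital = [], [], []
    for row in rec.signal:
        lo, hi = float(np.min(row)), float(np.max(row))
        if hi <= lo:
            hi = lo + 1.0
        # widen so that 8-char decimal headers still bracket the data
        span = hi - lo
        lo -= 0.001 * span
        hi += 0.001 * span
        pmin, pmax = float(f"{lo:.6g}"), float(f"{hi:.6g}")
        if pmin > lo:
            pmin = lo - abs(lo) * 1e-4 - 1e-12
            pmin = float(f"{pmin:.6g}")
        if pmax < hi:
            pmax = hi + abs(hi) * 1e-4 + 1e-12
            pmax = float(f"{pmax:.6g}")
        pmins.append(pmin)
        pmaxs.append(pmax)
        scale = (pmax - pmin) / (32767 - (-32768))
        dig = np.round((row - pmin) / scale) + (-32768)
        digital.append(np.clip(dig, -32768, 32767).astype("<i2"))

    header = b""
    header += _ascii("0", 8)
    header += _ascii(rec.subject_id, 80)
    header += _ascii("recording", 80)
    header += _ascii("01.01.00", 8)
    header += _ascii("00.00.00", 8)
    header += _ascii(256 * (ns + 1), 8)
    header += _ascii("", 44)
    header += _ascii(n_records, 8)
    header += _ascii(f"{duration:g}", 8)
    header += _ascii(ns, 4)
    for name in rec.channel_names:
        header += _ascii(name, 16)
    header += b"".join(_ascii("", 80) for _ in range(ns))
    header += b"".join(_ascii("uV", 8) for _ in range(ns))
    header += b"".join(_ascii(f"{v:.6g}", 8) for v in pmins)
    header += b"".join(_ascii(f"{v:.6g}", 8) for v in pmaxs)
    header += b"".join(_ascii(-32768, 8) for _ in range(ns))
    header += b"".join(_ascii(32767, 8) for _ in range(ns))
    header += b"".join(_ascii("", 80) for _ in range(ns))
    header += b"".join(_ascii(spr, 8) for _ in range(ns))
    header += b"".join(_ascii("", 32) for _ in range(ns))
    assert len(header) == 256 * (ns + 1)

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            for d in digital:
                fh.write(d[r * spr : (r + 1) * spr].tobytes())


def read_ratings(path: str | Path) -> pd.DataFrame:
    """Read a valence/arousal rating table.

    The file is a delimited table with header columns ``subject``, ``trial``,
    ``valence``, ``arousal``. Ratings must lie in [1, 9]; trial indices are
    0-based and unique per subject.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"ratings file not found: {path}")
    df = pd.read_csv(path)
    required = ["subject", "trial", "valence", "arousal"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"ratings file missing columns: {missing}")
    df = df[required].copy()
    df["subject"] = df["subject"].astype(str)
    for col in ("valence", "arousal"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals < 1) | (vals > 9)
        if bad.any():
            row = int(np.argmax(bad.to_numpy())) + 2  # 1-based incl. header
            raise ValidationError(f"invalid {col} at file row {row}")
        df[col] = vals.astype(float)
    trials = pd.to_numeric(df["trial"], errors="coerce")
    if trials.isna().any() or (trials < 0).any() or (trials != trials.round()).any():
        row = int(np.argmax((trials.isna() | (trials < 0)).to_numpy())) + 2
        raise ValidationError(f"invalid trial index at file row {row}")
    df["trial"] = trials.astype(int)
    if df.duplicated(["subject", "trial"]).any():
        raise ValidationError("duplicate (subject, trial) rating rows")
    return df.reset_index(drop=True)


def write_ratings(ratings: pd.DataFrame, path: str | Path) -> None:
    ratings.to_csv(path, index=False)


def write_selection_report(result, path: str | Path) -> None:
    """Serialize a SelectionResult (see cchp.selection) to JSON.

    The report always embeds the run parameters so that a reload plus the
    recorded configuration reproduces the selection exactly. Trial-free
    quantities are written verbatim; merit scores keep full float precision.
    """
    payload = result.to_dict()
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_selection_report(path: str | Path):
    from .selection import SelectionResult

    payload = json.loads(Path(path).read_text())
    return SelectionResult.from_dict(payload)
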