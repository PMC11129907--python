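"""Reading/writing recordings and score logs; cutting the 30 s pre-score windows.

On-disk dialects:

* recording CSV: header ``time,acc_x,acc_y,acc_z,gyr_x,gyr_y,gyr_z`` (SI units);
* recording HDF5: one group per limb with datasets ``t``, ``acc``, ``gyr`` and
  attrs ``fs``, ``subject_id``;
* score log CSV: ``time,limb,label`` with label in {0, 1, 2, NA};
* window store HDF5: datasets ``windows`` (n x samples x 6), ``labels`` (n) and
  per-window metadata (subject, limb, window end time).

Each labelled sample is the 30 seconds of sensor data leading up to one
clinician score entry; windows keep the sensor stream and the label from
the same limb.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .synth import NO_DATA, ImuRecording, ScoreEvent

logger = logging.getLogger(__name__)

RECORDING_COLUMNS = ["time", "acc_x", "acc_y", "acc_z", "gyr_x", "gyr_y", "gyr_z"]

#: Length of the pre-score analysis window, seconds.
WINDOW_S: float = 30.0


class FormatError(ValueError):
    """A file does not conform to the expected recording/score dialect."""


@dataclass
class LabelledWindow:
    """A 30 s x 6-channel segment preceding one score entry, with its label."""

    subject_id: str
    limb: str
    label: int
    data: np.ndarray  # (round(30*fs), 6): acc_x..z then gyr_x..z
    window_end_s: float
    fs: float

    def __post_init__(self) -> None:
        if self.label not in (0, 1, 2):
            raise ValueError("LabelledWindow label must be 0, 1 or 2")
        expected = int(round(WINDOW_S * self.fs))
        if self.data.shape != (expected, 6):
            raise ValueError(
                f"window must be ({expected}, 6) at fs={self.fs}, got {self.data.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("window contains non-finite values")


# ---------------------------------------------------------------------------
# recordings


def write_recording(rec: ImuRecording, path: str | Path) -> None:
    """Write a recording as CSV (``.csv``) or HDF5 (``.h5``/``.hdf5``)."""
    path = Path(path)
    if path.suffix == ".csv":
        df = pd.DataFrame(
            np.column_stack([rec.t, rec.acc, rec.gyr]), columns=RECORDING_COLUMNS
        )
        df.to_csv(path, index=False)  # default float repr round-trips exactly
    elif path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "a") as f:
            if rec.limb in f:
                del f[rec.limb]
            g = f.create_group(rec.limb)
            g.create_dataset("t", data=rec.t)
            g.create_dataset("acc", data=rec.acc)
            g.create_dataset("gyr", data=rec.gyr)
            g.attrs["fs"] = rec.fs
            g.attrs["subject_id"] = rec.subject_id
    else:
        raise FormatError(f"unsupported recording extension: {path.suffix}")


def _validate_time(t: np.ndarray, fs: float, origin: str) -> None:
    if len(t) > 1:
        dt = np.diff(t)
        bad = np.flatnonzero(dt <= 0)
        if bad.size:
            raise FormatError(f"{origin}: non-monotone time at row {bad[0] + 1}")
        gaps = np.flatnonzero(dt > 2.0 / fs)
        if gaps.size:
            raise FormatError(
                f"{origin}: timestamp gap of {dt[gaps[0]]:.6g} s at row {gaps[0] + 1} "
                f"(t={t[gaps[0]]:.6g} s)"
            )
        if np.max(np.abs(dt - 1.0 / fs)) > 1e-6:
            raise FormatError(f"{origin}: non-uniform sampling (expected 1/fs = {1/fs:.6g} s)")


def load_recording(
    path: str | Path,
    subject_id: str = "unknown",
    limb: str = "right_wrist",
    fs: float | None = None,
) -> ImuRecording:
    """Load and validate a recording from CSV or HDF5.

    For CSV the sampling rate is inferred from the timestamps unless given.
    For HDF5 the ``limb`` argument selects the group. Malformed headers,
    non-monotone time, gaps larger than 2/fs and wrong channel counts raise
    :class:`FormatError` naming the offending row or field.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".csv":
        df = pd.read_csv(path, float_precision="round_trip")
        if list(df.columns) != RECORDING_COLUMNS:
            raise FormatError(
                f"{path.name}: expected header {RECORDING_COLUMNS}, got {list(df.columns)}"
            )
        if df.isna().any().any():
            row = int(np.flatnonzero(df.isna().any(axis=1))[0])
            raise FormatError(f"{path.name}: missing value at row {row + 1}")
        t = df["time"].to_numpy(dtype=float)
        if fs is None:
            if len(t) < 2:
                raise FormatError(f"{path.name}: cannot infer fs from fewer than 2 rows")
            fs = 1.0 / float(np.median(np.diff(t)))
        _validate_time(t, fs, path.name)
        acc = df[["acc_x", "acc_y", "acc_z"]].to_numpy(dtype=float)
        gyr = df[["gyr_x", "gyr_y", "gyr_z"]].to_numpy(dtype=float)
        return ImuRecording(subject_id=subject_id, limb=limb, t=t, acc=acc, gyr=gyr, fs=fs)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            if limb not in f:
                raise FormatError(f"{path.name}: no group for limb '{limb}'")
            g = f[limb]
            for name in ("t", "acc", "gyr"):
                if name not in g:
                    raise FormatError(f"{path.name}/{limb}: missing dataset '{name}'")
            t = g["t"][...]
            acc = g["acc"][...]
            gyr = g["gyr"][...]
            fs_file = float(g.attrs["fs"])
            subject = str(g.attrs.get("subject_id", subject_id))
        if acc.ndim != 2 or acc.shape[1] != 3 or gyr.ndim != 2 or gyr.shape[1] != 3:
            raise FormatError(f"{path.name}/{limb}: acc and gyr must each have 3 channels")
        _validate_time(t, fs_file, f"{path.name}/{limb}")
        return ImuRecording(subject_id=subject, limb=limb, t=t, acc=acc, gyr=gyr, fs=fs_file)
    raise FormatError(f"unsupported recording extension: {path.suffix}")


# ---------------------------------------------------------------------------
# score logs


def write_scores(events: list[ScoreEvent], path: str | Path) -> None:
    """Write a score log CSV ``time,limb,label`` with NO_DATA written as NA."""
    rows = [
        {
            "time": ev.time_s,
            "limb": ev.limb,
            "label": "NA" if ev.label == NO_DATA else ev.label,
        }
        for ev in events
    ]
    pd.DataFrame(rows, columns=["time", "limb", "label"]).to_csv(Path(path), index=False)


def load_scores(path: str | Path) -> list[ScoreEvent]:
    """Load a score log CSV; 'NA' labels map to NO_DATA."""
    df = pd.read_csv(path, keep_default_na=False)
    if list(df.columns) != ["time", "limb", "label"]:
        raise FormatError(f"{Path(path).name}: expected header time,limb,label")
    events = []
    for i, row in df.iterrows():
        raw = str(row["label"]).strip()
        if raw in ("NA", ""):
            label = NO_DATA
        else:
            try:
                label = int(raw)
            except ValueError as exc:
                raise FormatError(f"{Path(path).name}: bad label {raw!r} at row {i + 1}") from exc
        events.append(ScoreEvent(time_s=float(row["time"]), label=label, limb=str(row["limb"])))
    return events


# ---------------------------------------------------------------------------
# window extraction


def extract_windows(
    rec: ImuRecording, events: list[ScoreEvent]
) -> list[LabelledWindow]:
    """Cut one 30 s pre-score window per usable score event.

    The window is the half-open interval (end - 30 s, end] anchored at the
    score timestamp. NO_DATA events, events from other limbs and events
    with less than 30 s of preceding data are skipped (counts are logged);
    skipping is part of the contract, not an error.
    """
    n_samples = int(round(WINDOW_S * rec.fs))
    out: list[LabelledWindow] = []
    skipped_nodata = skipped_short = skipped_limb = 0
    for ev in events:
        if ev.limb != rec.limb:
            skipped_limb += 1
            continue
        if ev.label == NO_DATA:
            skipped_nodata += 1
            continue
        end = int(round(ev.time_s * rec.fs))
        start = end - n_samples
        if start < 0 or end > len(rec.t):
            skipped_short += 1
            continue
        data = np.column_stack([rec.acc[start:end], rec.gyr[start:end]])
        out.append(
            LabelledWindow(
                subject_id=rec.subject_id,
                limb=rec.limb,
                label=int(ev.label),
                data=data,
                window_end_s=ev.time_s,
                fs=rec.fs,
            )
        )
    logger.info(
        "extract_windows: %d kept, %d NO_DATA, %d insufficient history, %d other-limb",
        len(out), skipped_nodata, skipped_short, skipped_limb,
    )
    return out


# ---------------------------------------------------------------------------
# window store


def save_windows(windows: list[LabelledWindow], path: str | Path) -> None:
    """Persist windows to one HDF5 file (datasets windows/labels/meta)."""
    if not windows:
        raise ValueError("no windows to save")
    with h5py.File(Path(path), "w") as f:
        f.create_dataset("windows", data=np.stack([w.data for w in windows]))
        f.create_dataset("labels", data=np.array([w.label for w in windows]))
        f.create_dataset(
            "subject", data=np.array([w.subject_id for w in windows], dtype="S32")
        )
        f.create_dataset("limb", data=np.array([w.limb for w in windows], dtype="S32"))
        f.create_dataset("window_end_s", data=np.array([w.window_end_s for w in windows]))
        f.attrs["fs"] = windows[0].fs


def load_windows(path: str | Path) -> list[LabelledWindow]:
    with h5py.File(Path(path), "r") as f:
        fs = float(f.attrs["fs"])
        return [
            LabelledWindow(
                subject_id=s.decode(),
                limb=l.decode(),
                label=int(lab),
                data=np.asarray(d),
                window_end_s=float(te),
                fs=fs,
            )
            for d, lab, s, l, te in zip(
                f["windows"], f["labels"], f["subject"], f["limb"], f["window_end_s"]
            )
        ]


def windows_to_frame(windows: list[LabelledWindow]) -> pd.DataFrame:
    """Long-format CSV-exportable view: one row per sample per window."""
    frames = []
    for i, w in enumerate(windows):
        df = pd.DataFrame(w.data, columns=RECORDING_COLUMNS[1:])
        df.insert(0, "window", i)
        df.insert(1, "label", w.label)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
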