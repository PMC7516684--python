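"""Data model and file I/O for bilateral smart-insole recordings.

One insole carries 8 plantar-pressure channels (N/cm^2, channel order
heel -> toe: p1-p2 heel, p3-p5 midfoot/metatarsal, p6-p8 forefoot/toe),
a 3-axis accelerometer (m/s^2, foot frame with x = gravity-compensated
forward axis) and a 3-axis gyroscope (deg/s), all sampled on a uniform
100 Hz grid.  A trial is one bilateral pair of recordings plus a JSON
metadata sidecar; a cohort is a manifest CSV of subjects with group
labels, affected side and clinical scores.

On-disk dialect
---------------
* insole CSV header: ``t,p1,...,p8,ax,ay,az,gx,gy,gz`` (t in s, comma
  separated, ``.`` decimal, UTF-8, LF);
* trial sidecar JSON: ``{subject_id, group, affected_side, fs,
  track_length_m, left_file, right_file}``;
* cohort manifest CSV: one row per subject,
  ``subject_id,group,affected_side,mmse,mbi,fma_uex,fma_lex,trial_dir``.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass
from typing import TYPE_CHECKING, Optional

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    DataValidationError,
    EmptyInputError,
    FormatError,
    MetadataError,
)

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .gait_parameters import GaitParameterSet

PRESSURE_COLUMNS = tuple(f"p{i}" for i in range(1, 9))
ACCEL_COLUMNS = ("ax", "ay", "az")
GYRO_COLUMNS = ("gx", "gy", "gz")
CSV_COLUMNS = ("t",) + PRESSURE_COLUMNS + ACCEL_COLUMNS + GYRO_COLUMNS

SIDES = ("left", "right")
GROUPS = ("patient", "control")
AFFECTED_SIDES = ("left", "right", "none")

#: max tolerated deviation of an explicit time column from the uniform grid (s)
TIME_GRID_TOL = 1e-6


@dataclass
class InsoleRecording:
    """One foot's synchronized pressure + IMU time series at a fixed rate.

    All matrices share ``n_samples`` rows; the time base is the implicit
    uniform grid ``t_i = i / fs``.
    """

    side: str
    fs: float
    pressure: np.ndarray  # (n, 8) N/cm^2
    accel: np.ndarray  # (n, 3) m/s^2
    gyro: np.ndarray  # (n, 3) deg/s

    def __post_init__(self) -> None:
        if self.side not in SIDES:
            raise DataValidationError(f"side must be one of {SIDES}, got {self.side!r}")
        if not (self.fs > 0):
            raise DataValidationError(f"fs must be positive, got {self.fs}")
        self.pressure = np.asarray(self.pressure, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        n = self.pressure.shape[0]
        if self.pressure.ndim != 2 or self.pressure.shape[1] != 8:
            raise DataValidationError("pressure must have shape (n_samples, 8)")
        if self.accel.shape != (n, 3):
            raise DataValidationError("accel must have shape (n_samples, 3)")
        if self.gyro.shape != (n, 3):
            raise DataValidationError("gyro must have shape (n_samples, 3)")
        if n and np.nanmin(self.pressure) < 0:
            row = int(np.argwhere(self.pressure < 0)[0, 0])
            raise DataValidationError(f"negative pressure at row {row}")

    @property
    def n_samples(self) -> int:
        return self.pressure.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def t(self) -> np.ndarray:
        """Implicit uniform time base (s)."""
        return np.arange(self.n_samples) / self.fs


@dataclass
class TrialMeta:
    subject_id: str
    group: str
    affected_side: str
    track_length_m: float = 3.0
    notes: str = ""

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise MetadataError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.affected_side not in AFFECTED_SIDES:
            raise MetadataError(
                f"affected_side must be one of {AFFECTED_SIDES}, got {self.affected_side!r}"
            )
        if self.group == "control" and self.affected_side != "none":
            raise MetadataError("controls must have affected_side == 'none'")
        if self.group == "patient" and self.affected_side == "none":
            raise MetadataError("patients must declare an affected_side (left/right)")
        if not (self.track_length_m > 0):
            raise MetadataError("track_length_m must be positive")


@dataclass
class TrialRecording:
    """An aligned bilateral TUG trial (shared session clock)."""

    left: InsoleRecording
    right: InsoleRecording
    meta: TrialMeta

    def __post_init__(self) -> None:
        if self.left.fs != self.right.fs:
            raise AlignmentError(
                f"sampling rates differ: left {self.left.fs} Hz vs right {self.right.fs} Hz"
            )
        if self.left.side != "left" or self.right.side != "right":
            raise DataValidationError("left/right recordings have wrong side labels")

    @property
    def fs(self) -> float:
        return self.left.fs

    @property
    def n_samples(self) -> int:
        return min(self.left.n_samples, self.right.n_samples)

    def aligned(self) -> "TrialRecording":
        """Truncate both feet to the common sample count (idempotent)."""
        n = self.n_samples
        if self.left.n_samples == n and self.right.n_samples == n:
            return self

        def cut(rec: InsoleRecording) -> InsoleRecording:
            return InsoleRecording(
                side=rec.side,
                fs=rec.fs,
                pressure=rec.pressure[:n],
                accel=rec.accel[:n],
                gyro=rec.gyro[:n],
            )

        return TrialRecording(left=cut(self.left), right=cut(self.right), meta=self.meta)


@dataclass
class ClinicalScores:
    """Stroke severity scale results (missing values as NaN/None)."""

    mmse: Optional[float] = None  # 0-30
    mbi: Optional[float] = None  # 0-100
    fma_uex: Optional[float] = None  # >= 0
    fma_lex: Optional[float] = None  # >= 0

    _RANGES = {
        "mmse": (0.0, 30.0),
        "mbi": (0.0, 100.0),
        "fma_uex": (0.0, math.inf),
        "fma_lex": (0.0, math.inf),
    }

    def __post_init__(self) -> None:
        for name, (lo, hi) in self._RANGES.items():
            v = getattr(self, name)
            if v is None or (isinstance(v, float) and math.isnan(v)):
                setattr(self, name, None)
                continue
            v = float(v)
            if not (lo <= v <= hi):
                raise DataValidationError(f"{name}={v} outside instrument range [{lo}, {hi}]")
            setattr(self, name, v)

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self._RANGES}


@dataclass
class SubjectRecord:
    """One subject-trial row: gait parameters joined with group/scores."""

    subject_id: str
    group: str
    affected_side: str
    scores: Optional[ClinicalScores] = None
    params: Optional["GaitParameterSet"] = None


# ---------------------------------------------------------------------------
# CSV / JSON I/O
# ---------------------------------------------------------------------------


def read_insole_csv(path: str | os.PathLike, side: str = "left",
                    fs: Optional[float] = None) -> InsoleRecording:
    """Read one insole CSV into a validated :class:`InsoleRecording`.

    ``fs`` normally comes from the trial sidecar; when omitted it is
    inferred from the first step of the explicit time column.  The time
    column must lie on the uniform grid ``t_0 + i/fs`` to within 1e-6 s.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path}: file is empty") from None
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
    if len(df) == 0:
        raise EmptyInputError(f"{path}: no data rows")
    t = df["t"].to_numpy(dtype=float)
    if fs is None:
        if len(t) >= 2:
            fs = 1.0 / (t[1] - t[0])
        else:
            fs = 100.0
    grid = t[0] + np.arange(len(t)) / fs
    dev = np.abs(t - grid)
    if np.any(dev > TIME_GRID_TOL):
        i = int(np.argmax(dev > TIME_GRID_TOL))
        raise DataValidationError(
            f"{path}: time column off the uniform 1/fs grid at row {i} "
            f"(deviation {dev[i]:.3g} s)"
        )
    pressure = df[list(PRESSURE_COLUMNS)].to_numpy(dtype=float)
    if np.any(pressure < 0):
        row = int(np.argwhere(pressure < 0)[0, 0])
        raise DataValidationError(f"{path}: negative pressure at row {row}")
    return InsoleRecording(
        side=side,
        fs=float(fs),
        pressure=pressure,
        accel=df[list(ACCEL_COLUMNS)].to_numpy(dtype=float),
        gyro=df[list(GYRO_COLUMNS)].to_numpy(dtype=float),
    )


def write_insole_csv(rec: InsoleRecording, path: str | os.PathLike) -> str:
    """Write a recording in the declared dialect, lossless to >= 9 sig. digits."""
    data = np.column_stack(
        [rec.t, rec.pressure, rec.accel, rec.gyro]
    ) if rec.n_samples else np.empty((0, len(CSV_COLUMNS)))
    df = pd.DataFrame(data, columns=list(CSV_COLUMNS))
    df.to_csv(path, index=False, float_format="%.12g", lineterminator="\n")
    return str(path)


def write_trial(trial: TrialRecording, out_dir: str | os.PathLike) -> str:
    """Write a trial as left.csv + right.csv + trial.json under ``out_dir``."""
    os.makedirs(out_dir, exist_ok=True)
    out_dir = str(out_dir)
    write_insole_csv(trial.left, os.path.join(out_dir, "left.csv"))
    write_insole_csv(trial.right, os.path.join(out_dir, "right.csv"))
    sidecar = {
        "subject_id": trial.meta.subject_id,
        "group": trial.meta.group,
        "affected_side": trial.meta.affected_side,
        "fs": trial.fs,
        "track_length_m": trial.meta.track_length_m,
        "left_file": "left.csv",
        "right_file": "right.csv",
    }
    with open(os.path.join(out_dir, "trial.json"), "w", encoding="utf-8") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out_dir


def load_trial(left_path: str | os.PathLike, right_path: str | os.PathLike,
               meta_path: str | os.PathLike) -> TrialRecording:
    """Load and align one bilateral trial from its three files.

    Both feet share the session clock; the longer recording is truncated
    to the common sample count.  Loading an already-aligned pair is a
    no-op (idempotent).
    """
    with open(meta_path, encoding="utf-8") as fh:
        sidecar = json.load(fh)
    for key in ("subject_id", "group", "affected_side", "fs"):
        if key not in sidecar:
            raise MetadataError(f"{meta_path}: sidecar missing key {key!r}")
    fs = float(sidecar["fs"])
    left = read_insole_csv(left_path, side="left", fs=fs)
    right = read_insole_csv(right_path, side="right", fs=fs)
    if left.fs != right.fs:
        raise AlignmentError(f"sampling rates differ: {left.fs} vs {right.fs}")
    meta = TrialMeta(
        subject_id=str(sidecar["subject_id"]),
        group=sidecar["group"],
        affected_side=sidecar["affected_side"],
        track_length_m=float(sidecar.get("track_length_m", 3.0)),
        notes=str(sidecar.get("notes", "")),
    )
    return TrialRecording(left=left, right=right, meta=meta).aligned()


def load_trial_dir(trial_dir: str | os.PathLike) -> TrialRecording:
    """Load a trial from a directory laid out by :func:`write_trial`."""
    trial_dir = str(trial_dir)
    meta_path = os.path.join(trial_dir, "trial.json")
    with open(meta_path, encoding="utf-8") as fh:
        sidecar = json.load(fh)
    return load_trial(
        os.path.join(trial_dir, sidecar.get("left_file", "left.csv")),
        os.path.join(trial_dir, sidecar.get("right_file", "right.csv")),
        meta_path,
    )


MANIFEST_COLUMNS = (
    "subject_id", "group", "affected_side",
    "mmse", "mbi", "fma_uex", "fma_lex", "trial_dir",
)


def read_manifest(path: str | os.PathLike) -> pd.DataFrame:
    """Read a cohort manifest CSV, validating the column set."""
    df = pd.read_csv(path, comment="#")
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: manifest missing column(s) {', '.join(missing)}")
    for g in df["group"]:
        if g not in GROUPS:
            raise MetadataError(f"{path}: unknown group {g!r}")
    return df


def write_manifest(rows: list[dict], path: str | os.PathLike) -> str:
    df = pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS))
    df.to_csv(path, index=False, float_format="%.12g", lineterminator="\n")
    return str(path)
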