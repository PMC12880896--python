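"""Trial containers and the on-disk dataset layout.

A dataset is a directory with one manifest CSV plus two CSV files per trial
(EMG block and IMU block — the two streams run at different native rates, so
a single wide file would force resampling at I/O time).

Trial CSV schema: header ``time_s,<channel>...`` with time in seconds from
acquisition start.  Manifest schema:
``trial_id,subject_id,task,gaze,repetition,emg_path,imu_path,emg_rate_hz,imu_rate_hz``
with paths relative to the manifest's directory.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DatasetIntegrityError, MalformedFileError, MetadataError

TASKS = ("DL", "SB", "SF", "AS")
GAZES = ("down", "ahead")

#: Surface-EMG channels, dominant lower limb (order fixed across the package).
EMG_CHANNELS = (
    "rectus_femoris",
    "vastus_medialis",
    "biceps_femoris",
    "tibialis_anterior",
    "peroneus_longus",
    "gastrocnemius_medialis",
)

#: Lower-back inertial channels: specific force in g, angular velocity in deg/s.
IMU_CHANNELS = (
    "acc_ml",
    "acc_ap",
    "acc_v",
    "gyro_sagittal",
    "gyro_frontal",
    "gyro_transverse",
)
ACC_CHANNELS = IMU_CHANNELS[:3]
GYRO_CHANNELS = IMU_CHANNELS[3:]

MANIFEST_COLUMNS = (
    "trial_id",
    "subject_id",
    "task",
    "gaze",
    "repetition",
    "emg_path",
    "imu_path",
    "emg_rate_hz",
    "imu_rate_hz",
)

_FLOAT_FMT = "%.12g"  # >= 9 significant digits so write->read round-trips
_JITTER_TOL_S = 1e-6


@dataclass(frozen=True)
class TrialMeta:
    """Identity and acquisition metadata of one landing attempt."""

    subject_id: str
    task: str
    gaze: str
    repetition: int
    emg_rate_hz: float
    imu_rate_hz: float = 370.4

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise MetadataError(f"unknown task token {self.task!r}; expected one of {TASKS}")
        if self.gaze not in GAZES:
            raise MetadataError(f"unknown gaze token {self.gaze!r}; expected one of {GAZES}")
        if self.repetition < 1:
            raise MetadataError("repetition must be a positive count")
        if self.emg_rate_hz <= 0 or self.imu_rate_hz <= 0:
            raise MetadataError("sampling rates must be strictly positive")

    @property
    def trial_id(self) -> str:
        return f"{self.subject_id}_{self.task}_{self.gaze}_r{self.repetition}"


@dataclass
class RawTrial:
    """One landing attempt: synchronised EMG and IMU blocks on a common time origin."""

    meta: TrialMeta
    emg: pd.DataFrame  # columns: time_s + EMG_CHANNELS, mV
    imu: pd.DataFrame  # columns: time_s + IMU_CHANNELS, g / deg/s


def _check_block(df: pd.DataFrame, channels: tuple[str, ...], path: str) -> None:
    expected = ["time_s", *channels]
    if list(df.columns) != expected:
        missing = [c for c in expected if c not in df.columns]
        raise MalformedFileError(
            f"{path}: bad header; missing columns {missing}" if missing
            else f"{path}: columns {list(df.columns)} != expected {expected}"
        )
    values = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise MalformedFileError(f"{path}: non-finite values present")
    t = values[:, 0]
    if len(t) >= 2:
        dt = np.diff(t)
        if np.max(np.abs(dt - np.median(dt))) > _JITTER_TOL_S:
            raise MalformedFileError(f"{path}: non-uniform time base (jitter > {_JITTER_TOL_S} s)")


def read_trial(emg_path: str, imu_path: str, meta: TrialMeta) -> RawTrial:
    """Read one trial (EMG + IMU CSV blocks) and validate its schema."""
    for path in (emg_path, imu_path):
        if not os.path.exists(path):
            raise DatasetIntegrityError(f"trial file not found: {path}")
    emg = pd.read_csv(emg_path)
    imu = pd.read_csv(imu_path)
    _check_block(emg, EMG_CHANNELS, emg_path)
    _check_block(imu, IMU_CHANNELS, imu_path)
    return RawTrial(meta=meta, emg=emg, imu=imu)


def write_trial(trial: RawTrial, emg_path: str, imu_path: str) -> None:
    _check_block(trial.emg, EMG_CHANNELS, emg_path)
    _check_block(trial.imu, IMU_CHANNELS, imu_path)
    trial.emg.to_csv(emg_path, index=False, float_format=_FLOAT_FMT)
    trial.imu.to_csv(imu_path, index=False, float_format=_FLOAT_FMT)


@dataclass(frozen=True)
class DatasetEntry:
    meta: TrialMeta
    emg_path: str
    imu_path: str

    @property
    def trial_id(self) -> str:
        return self.meta.trial_id


def discover_dataset(manifest_path: str, check_files: bool = True) -> list[DatasetEntry]:
    """Read a manifest and return trial entries in stable order.

    Ordering is (subject, task, gaze, repetition) with task/gaze in their
    canonical enum order, independent of manifest row order.  Duplicate
    (subject, task, gaze, repetition) keys are rejected.
    """
    if not os.path.exists(manifest_path):
        raise DatasetIntegrityError(f"manifest not found: {manifest_path}")
    df = pd.read_csv(manifest_path, dtype={"subject_id": str, "trial_id": str})
    if list(df.columns) != list(MANIFEST_COLUMNS):
        raise MalformedFileError(
            f"{manifest_path}: manifest columns {list(df.columns)} != {list(MANIFEST_COLUMNS)}"
        )
    key_cols = ["subject_id", "task", "gaze", "repetition"]
    dup = df.duplicated(subset=key_cols, keep=False)
    if dup.any():
        rows = df.loc[dup, key_cols].to_dict("records")
        raise DatasetIntegrityError(f"duplicate trial keys in manifest: {rows}")

    base = os.path.dirname(os.path.abspath(manifest_path))
    entries: list[DatasetEntry] = []
    for row in df.itertuples(index=False):
        meta = TrialMeta(
            subject_id=str(row.subject_id),
            task=str(row.task),
            gaze=str(row.gaze),
            repetition=int(row.repetition),
            emg_rate_hz=float(row.emg_rate_hz),
            imu_rate_hz=float(row.imu_rate_hz),
        )
        emg_path = os.path.join(base, str(row.emg_path))
        imu_path = os.path.join(base, str(row.imu_path))
        if check_files:
            for path in (emg_path, imu_path):
                if not os.path.exists(path):
                    raise DatasetIntegrityError(
                        f"manifest row {meta.trial_id} points to absent file: {path}"
                    )
        entries.append(DatasetEntry(meta=meta, emg_path=emg_path, imu_path=imu_path))

    entries.sort(
        key=lambda e: (
            e.meta.subject_id,
            TASKS.index(e.meta.task),
            GAZES.index(e.meta.gaze),
            e.meta.repetition,
        )
    )
    return entries


def write_manifest(entries: pd.DataFrame, manifest_path: str) -> None:
    if list(entries.columns) != list(MANIFEST_COLUMNS):
        raise MalformedFileError(f"manifest columns must be {list(MANIFEST_COLUMNS)}")
    entries.to_csv(manifest_path, index=False, float_format=_FLOAT_FMT)
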