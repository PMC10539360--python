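"""Reading, cleaning, aligning and splitting actigraphy recordings and metadata.

A raw recording is a per-patient minute-epoch series of (activity counts,
light lux). Preprocessing discards everything before the second midnight
(the first partial day plus the first full day), keeps exactly the next
10,080 epochs (one week), log-pseudocount transforms both channels, and
annotates sleep with the Oakley scorer. Splits are always by patient so no
measurement from one patient leaks across train/val/test.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .circadian import MINUTES_PER_DAY, oakley_sleep_wake

logger = logging.getLogger(__name__)

WEEK_EPOCHS = 7 * MINUTES_PER_DAY  # 10,080 one-minute epochs


@dataclass
class ActigraphyRecording:
    """Raw minute-epoch two-channel series for one patient."""

    patient_id: str
    start_time: pd.Timestamp
    activity: np.ndarray
    light: Optional[np.ndarray]
    epoch_minutes: int = 1
    has_gap: bool = False

    def __post_init__(self):
        self.activity = np.asarray(self.activity)
        if self.light is not None:
            self.light = np.asarray(self.light)
            if self.light.shape != self.activity.shape:
                raise ValueError("activity and light must have the same length")
        if self.epoch_minutes != 1:
            raise ValueError("only 1-minute epochs are supported")

    @property
    def length(self) -> int:
        return int(self.activity.size)


@dataclass
class MeasurementSample:
    """Cleaned, midnight-aligned one-week sample.

    `signal` is the 2 x 10,080 log-pseudocount matrix (activity, light);
    `activity_counts` keeps the raw count channel for circadian metrics.
    """

    sample_id: str
    patient_id: str
    ga_weeks: float
    signal: np.ndarray
    sleep_mask: np.ndarray
    start_weekday: int
    activity_counts: Optional[np.ndarray] = None

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=np.float32)
        if self.signal.ndim != 2 or self.signal.shape[0] != 2:
            raise ValueError("signal must be a 2 x L matrix")


@dataclass
class MetadataTable:
    """Per-sample clinical metadata with declared variable kinds.

    `kinds` maps column -> {continuous, categorical, ordinal}; `categories`
    maps column -> {sleep, activity, stress, comorbidity, social, outcome}.
    """

    data: pd.DataFrame
    kinds: dict
    categories: dict = field(default_factory=dict)

    def __post_init__(self):
        unknown = set(self.kinds) - set(self.data.columns)
        if unknown:
            raise ValueError(f"kinds declared for unknown columns: {sorted(unknown)}")

    @property
    def variables(self) -> list:
        return [c for c in self.data.columns if c in self.kinds]

    def to_csv(self, path, sidecar_path=None) -> None:
        self.data.to_csv(path, index=False)
        sidecar = Path(sidecar_path) if sidecar_path else Path(path).with_suffix(".vars.json")
        sidecar.write_text(
            json.dumps({"kinds": self.kinds, "categories": self.categories}, indent=1)
        )

    @classmethod
    def from_csv(cls, path, sidecar_path=None) -> "MetadataTable":
        sidecar = Path(sidecar_path) if sidecar_path else Path(path).with_suffix(".vars.json")
        meta = json.loads(sidecar.read_text())
        return cls(pd.read_csv(path), meta["kinds"], meta.get("categories", {}))


@dataclass
class CohortDataset:
    """Processed samples plus a per-patient split assignment."""

    samples: list
    splits: dict  # patient_id -> {train, val, test}
    metadata: Optional[MetadataTable] = None

    def subset(self, split: str) -> list:
        return [s for s in self.samples if self.splits.get(s.patient_id) == split]

    def patients(self) -> list:
        return sorted({s.patient_id for s in self.samples})


def read_recordings(path) -> list:
    """Read a long-format CSV (patient_id, timestamp, activity, light).

    Emits one recording per patient; a broken 1-min grid is flagged
    (`has_gap`) and later dropped by `quality_filter`. Rows with negative
    counts are rejected with a logged warning; a patient block with
    non-monotone timestamps is rejected entirely.
    """
    df = pd.read_csv(path)
    if df.empty:
        return []
    required = {"patient_id", "timestamp", "activity"}
    if not required.issubset(df.columns):
        raise ValueError(f"CSV must contain columns {sorted(required)}")
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    has_light = "light" in df.columns and df["light"].notna().all()

    negative = (df["activity"] < 0) | (has_light & (df.get("light", 0) < 0))
    if negative.any():
        logger.warning("dropping %d rows with negative counts", int(negative.sum()))
        df = df[~negative]

    recordings = []
    for pid, block in df.groupby("patient_id", sort=True):
        block = block.reset_index(drop=True)
        deltas = block["timestamp"].diff().dropna()
        if (deltas <= pd.Timedelta(0)).any():
            logger.warning("rejecting patient %s: non-monotone timestamps", pid)
            continue
        gap = bool((deltas != pd.Timedelta(minutes=1)).any())
        recordings.append(
            ActigraphyRecording(
                patient_id=str(pid),
                start_time=block["timestamp"].iloc[0],
                activity=block["activity"].to_numpy(),
                light=block["light"].to_numpy() if has_light else None,
                has_gap=gap,
            )
        )
    return recordings


def _epochs_after_second_midnight(rec: ActigraphyRecording) -> int:
    """Epochs remaining once everything before the second midnight is discarded."""
    start = rec.start_time
    if start == start.normalize():
        first_midnight_offset = 0
    else:
        first_midnight_offset = int(
            (start.normalize() + pd.Timedelta(days=1) - start).total_seconds() // 60
        )
    drop = first_midnight_offset + MINUTES_PER_DAY
    return rec.length - drop, drop


def quality_filter(recording: ActigraphyRecording, has_light: bool = True):
    """Keep/drop decision with a reason code in {no_light, gap, too_short}."""
    if not has_light or recording.light is None:
        return False, "no_light"
    if recording.has_gap:
        return False, "gap"
    if recording.length < MINUTES_PER_DAY:
        return False, "too_short"
    remaining, _ = _epochs_after_second_midnight(recording)
    if remaining < WEEK_EPOCHS:
        return False, "too_short"
    return True, None


def align_and_truncate(recording: ActigraphyRecording) -> tuple:
    """Discard everything before the second midnight; emit the next 10,080 epochs.

    The first (possibly partial) day up to the first midnight and the first
    full day after it are both dropped; samples that would need trailing
    padding are excluded. Returns (raw 2 x 10,080 matrix, start_weekday).
    """
    remaining, drop = _epochs_after_second_midnight(recording)
    if remaining < WEEK_EPOCHS:
        raise ValueError("too_short: fewer than 10,080 epochs after first-day drop")
    sl = slice(drop, drop + WEEK_EPOCHS)
    activity = recording.activity[sl]
    light = recording.light[sl] if recording.light is not None else np.zeros(WEEK_EPOCHS)
    first_kept = recording.start_time + pd.Timedelta(minutes=drop)
    return np.stack([activity, light]).astype(float), int(first_kept.weekday())


def log_transform(x):
    """Log-pseudocount transform: log10(x + 1), elementwise."""
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise ValueError("log_transform requires nonnegative counts")
    return np.log10(arr + 1.0)


def make_sample(
    recording: ActigraphyRecording,
    sample_id: str,
    ga_weeks: float,
    oakley_threshold: float = 80.0,
) -> MeasurementSample:
    """Full preprocessing of one kept recording into a MeasurementSample."""
    raw, start_weekday = align_and_truncate(recording)
    mask = oakley_sleep_wake(raw[0], threshold=oakley_threshold)
    return MeasurementSample(
        sample_id=sample_id,
        patient_id=recording.patient_id,
        ga_weeks=float(ga_weeks),
        signal=log_transform(raw),
        sleep_mask=mask,
        start_weekday=start_weekday,
        activity_counts=raw[0].copy(),
    )


def preprocess_metadata(
    table: MetadataTable,
    train_index: Optional[Sequence[bool]] = None,
) -> MetadataTable:
    """Impute: continuous NA -> train-split column mean; categorical NA -> "missing".

    `train_index` is a boolean mask of rows used to compute imputation means
    (all rows when omitted). An all-missing continuous column is an error.
    """
    df = table.data.copy()
    mask = np.asarray(train_index, dtype=bool) if train_index is not None else np.ones(len(df), bool)
    for col, kind in table.kinds.items():
        if kind == "continuous":
            ref = df.loc[mask, col]
            if ref.isna().all():
                raise ValueError(f"continuous column {col!r} is entirely missing")
            df[col] = df[col].fillna(float(ref.mean()))
        else:
            if df[col].isna().any():
                df[col] = df[col].astype(object).where(df[col].notna(), "missing")
    return MetadataTable(df, dict(table.kinds), dict(table.categories))


def split_by_patient(
    samples: Sequence[MeasurementSample],
    fractions=(0.6, 0.1, 0.3),
    seed: int = 0,
    metadata: Optional[MetadataTable] = None,
) -> CohortDataset:
    """Partition patients (not samples) into train/val/test at given fractions."""
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError("fractions must sum to 1")
    patients = sorted({s.patient_id for s in samples})
    if len(patients) < 3:
        raise ValueError("need at least 3 patients to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(patients))
    n = len(patients)
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    splits = {}
    for rank, idx in enumerate(order):
        if rank < n_train:
            part = "train"
        elif rank < n_train + n_val:
            part = "val"
        else:
            part = "test"
        splits[patients[idx]] = part
    return CohortDataset(samples=list(samples), splits=splits, metadata=metadata)


def downsample_signal(signal: np.ndarray, factor: int) -> np.ndarray:
    """Reduce a 2 x L signal to 2 x (L // factor) by non-overlapping bin means.

    Used for desk-scale model configurations (e.g. factor 7 turns the weekly
    10,080-epoch grid into 1,440 seven-minute bins).
    """
    x = np.asarray(signal)
    L = x.shape[-1] - x.shape[-1] % factor
    return x[..., :L].reshape(*x.shape[:-1], L // factor, factor).mean(axis=-1)


def write_samples(samples: Iterable[MeasurementSample], directory, splits=None) -> Path:
    """Persist samples as one CSV matrix per sample plus a manifest CSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in samples:
        f = directory / f"{s.sample_id}.csv"
        frame = pd.DataFrame(
            {
                "activity": s.signal[0],
                "light": s.signal[1],
                "sleep": s.sleep_mask,
                "activity_counts": s.activity_counts
                if s.activity_counts is not None
                else np.zeros(s.signal.shape[1]),
            }
        )
        frame.to_csv(f, index=False)
        rows.append(
            {
                "sample_id": s.sample_id,
                "patient_id": s.patient_id,
                "ga_weeks": s.ga_weeks,
                "start_weekday": s.start_weekday,
                "split": (splits or {}).get(s.patient_id, ""),
            }
        )
    manifest = directory / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_samples(manifest_path) -> list:
    """Inverse of `write_samples`; round-trips signals bit-identically."""
    manifest_path = Path(manifest_path)
    directory = manifest_path.parent
    manifest = pd.read_csv(manifest_path, keep_default_na=False)
    samples = []
    for _, row in manifest.iterrows():
        frame = pd.read_csv(directory / f"{row.sample_id}.csv")
        samples.append(
            MeasurementSample(
                sample_id=str(row.sample_id),
                patient_id=str(row.patient_id),
                ga_weeks=float(row.ga_weeks),
                signal=np.stack([frame["activity"], frame["light"]]),
                sleep_mask=frame["sleep"].to_numpy(),
                start_weekday=int(row.start_weekday),
                activity_counts=frame["activity_counts"].to_numpy(),
            )
        )
    return samples
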