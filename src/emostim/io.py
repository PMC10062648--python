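"""Readers and writers for rating tables, EEG recordings and configuration.

Rating tables are long-format delimited text: one row per
(participant, stimulus) with both rating scales. EEG is read either from
EDF (via MNE) or from delimited text with samples in rows and labelled
channels in columns; trial windows live in a sidecar table.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .catalog import AGE_BANDS, GENDERS, GroupKey, parse_stimulus_filename
from .eeg import CANONICAL_CHANNELS, EEGRecording, Trial

PathLike = Union[str, Path]

RATING_COLUMNS = (
    "participant_id", "gender", "age_band", "stimulus_id",
    "ee_positive", "ee_neutral", "ee_negative",
    "sam_valence", "sam_arousal",
    "sam_dominance", "sam_liking", "sam_familiarity",
)
#: rating columns that may be empty (not collected in every experiment)
OPTIONAL_RATING_COLUMNS = ("sam_dominance", "sam_liking", "sam_familiarity")


class RatingValidationError(ValueError):
    """A rating table violated the documented schema."""


@dataclass(frozen=True)
class RatingRecord:
    """One participant's ratings for one stimulus on both scales."""

    participant_id: str
    group: GroupKey
    stimulus_id: str
    emo_eval: tuple[int, int, int]  # positive, neutral, negative intensity
    sam: dict

    @classmethod
    def from_row(cls, row: pd.Series) -> "RatingRecord":
        sam = {
            k.removeprefix("sam_"): (None if pd.isna(row[k]) else int(row[k]))
            for k in RATING_COLUMNS
            if k.startswith("sam_")
        }
        return cls(
            participant_id=str(row["participant_id"]),
            group=GroupKey(row["gender"], row["age_band"]),
            stimulus_id=str(row["stimulus_id"]),
            emo_eval=(int(row["ee_positive"]), int(row["ee_neutral"]), int(row["ee_negative"])),
            sam=sam,
        )


def _check_rating_range(df: pd.DataFrame, col: str, optional: bool) -> None:
    vals = df[col]
    mask = vals.notna()
    if not optional and not mask.all():
        rows = list(df.index[~mask][:5])
        raise RatingValidationError(f"column {col!r}: missing values at rows {rows}")
    present = vals[mask]
    numeric = pd.to_numeric(present, errors="coerce")
    bad = mask & (numeric.reindex(vals.index).isna() | (numeric.reindex(vals.index) % 1 != 0))
    ok = numeric.reindex(vals.index).between(1, 9)
    bad |= mask & ~ok
    if bad.any():
        row = int(df.index[bad][0])
        raise RatingValidationError(
            f"column {col!r}, row {row}: rating {vals.loc[row]!r} is not an integer in [1, 9]"
        )


def validate_ratings(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a rating table against the documented schema.

    Checks columns, 1-9 integer ranges, group vocabulary and uniqueness of
    (participant_id, stimulus_id). Returns the table with rating columns
    coerced to nullable integers. Row numbers in error messages are
    0-based data rows.
    """
    missing = [c for c in RATING_COLUMNS if c not in df.columns]
    if missing:
        raise RatingValidationError(f"missing columns: {missing}")
    df = df.reset_index(drop=True)
    for col in RATING_COLUMNS[4:]:
        _check_rating_range(df, col, optional=col in OPTIONAL_RATING_COLUMNS)
    bad_gender = ~df["gender"].isin(GENDERS)
    if bad_gender.any():
        row = int(df.index[bad_gender][0])
        raise RatingValidationError(f"row {row}: unknown gender {df.loc[row, 'gender']!r}")
    bad_age = ~df["age_band"].isin(AGE_BANDS)
    if bad_age.any():
        row = int(df.index[bad_age][0])
        raise RatingValidationError(f"row {row}: unknown age band {df.loc[row, 'age_band']!r}")
    dup = df.duplicated(subset=["participant_id", "stimulus_id"], keep=False)
    if dup.any():
        pair = tuple(df.loc[df.index[dup][0], ["participant_id", "stimulus_id"]])
        raise RatingValidationError(f"duplicate (participant, stimulus) pair {pair}")
    out = df.copy()
    for col in RATING_COLUMNS[4:]:
        out[col] = pd.to_numeric(out[col]).astype("Int64")
    return out


def read_ratings(path: PathLike) -> pd.DataFrame:
    """Read and validate a long-format rating CSV."""
    df = pd.read_csv(path)
    return validate_ratings(df)


def write_ratings(df: pd.DataFrame, path: PathLike) -> None:
    """Validate and write a rating table; round-trips bit-exactly."""
    validate_ratings(df)[list(RATING_COLUMNS)].to_csv(path, index=False)


def ratings_to_records(df: pd.DataFrame) -> list[RatingRecord]:
    """Typed view of a validated rating table."""
    return [RatingRecord.from_row(row) for _, row in df.iterrows()]


# ---------------------------------------------------------------------------
# EEG


def _normalize_channel_order(
    data: np.ndarray, labels: list[str]
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Reorder channels to the canonical montage when all its labels are present."""
    if set(labels) == set(CANONICAL_CHANNELS):
        perm = [labels.index(ch) for ch in CANONICAL_CHANNELS]
        return data[perm], CANONICAL_CHANNELS
    return data, tuple(labels)


def read_eeg(path: PathLike, fs: Optional[float] = None) -> EEGRecording:
    """Read an EEG recording from EDF or delimited text.

    EDF files carry their own sampling rate and labels. Delimited text has
    a one-line header of channel labels and samples in rows; ``fs`` must
    then be supplied (defaults to 256 Hz). Channels are reordered to the
    canonical 14-label montage whenever exactly those labels are present.
    """
    path = Path(path)
    if path.suffix.lower() == ".edf":
        import mne

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        data = raw.get_data() * 1e6  # MNE loads volts; the package works in uV
        labels = list(raw.ch_names)
        data, labels = _normalize_channel_order(data, labels)
        return EEGRecording(data=data, fs=float(raw.info["sfreq"]), channel_labels=labels)
    df = pd.read_csv(path)
    labels = [str(c) for c in df.columns]
    data = df.to_numpy(dtype=float).T
    if data.shape[0] != len(labels):
        raise ValueError(f"{data.shape[0]} channels for {len(labels)} labels")
    data, labels = _normalize_channel_order(data, labels)
    return EEGRecording(data=data, fs=float(fs or 256.0), channel_labels=labels)


def write_eeg_csv(rec: EEGRecording, path: PathLike) -> None:
    """Write a recording as delimited text (samples in rows)."""
    pd.DataFrame(rec.data.T, columns=list(rec.channel_labels)).to_csv(path, index=False)


def read_trials(path: PathLike, fs: float) -> list[Trial]:
    """Read a trial sidecar table: ``trial_id, stimulus_id, t_start_s, t_end_s``.

    The condition label is derived from the stimulus name's valence.
    """
    df = pd.read_csv(path)
    required = {"stimulus_id", "t_start_s", "t_end_s"}
    if not required <= set(df.columns):
        raise ValueError(f"trial table must have columns {sorted(required)}")
    trials = []
    for _, row in df.iterrows():
        desc = parse_stimulus_filename(str(row["stimulus_id"]) + ".MP4")
        trials.append(
            Trial(
                stimulus_id=str(row["stimulus_id"]),
                condition=desc.valence,
                start_sample=int(round(row["t_start_s"] * fs)),
                end_sample=int(round(row["t_end_s"] * fs)),
            )
        )
    return trials


def write_trials(trials: list[Trial], fs: float, path: PathLike) -> None:
    rows = [
        {
            "trial_id": i,
            "stimulus_id": t.stimulus_id,
            "t_start_s": t.start_sample / fs,
            "t_end_s": t.end_sample / fs,
        }
        for i, t in enumerate(trials)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Configuration

DEFAULT_CONFIG: dict = {
    "bands": {
        "delta": [1.0, 4.0], "theta": [4.0, 8.0], "alpha": [8.0, 12.0],
        "beta": [13.0, 30.0], "gamma": [31.0, 45.0],
    },
    "bandpass": {"low": 0.1, "high": 50.0, "order": 8},
    "notch": {"f0": 50.0, "quality": 30.0},
    "artifact": {"amplitude_threshold_uv": 100.0, "robust_z_threshold": 5.0, "cap": 0.10},
    "split": {"ratio": 0.8},
    "seed": 0,
}


def load_config(path: Optional[PathLike] = None) -> dict:
    """Load a YAML config, merged shallowly over the defaults."""
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for key, value in user.items():
            if isinstance(value, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(value)
            else:
                cfg[key] = value
    return cfg
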