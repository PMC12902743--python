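"""On-disk formats for recordings, events, attendance logs and score tables.

Sampled signals are stored as plain comma-delimited text with one row per
time sample (``<stem>.csv``) plus a JSON sidecar ``<stem>.meta.json``
carrying the sampling rate, channel labels and per-channel units.
Stimulation events, when present, live in ``<stem>.events.csv`` with
columns ``sample_index,label,intensity``.  Event sample indices are
0-based and epoch windows downstream are half-open in samples; both
conventions are recorded in the sidecar.  All amplitudes are stored in μV
so that the 50 μV response thresholds used downstream are unambiguous.

Attendance logs and score tables are ordinary CSVs validated into pandas
DataFrames.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """A file does not match the expected on-disk layout."""


class ValidationError(ValueError):
    """Parsed data violates a domain invariant."""


#: The six assessment timepoints of the study schedule.
TIMEPOINTS = ("base", "FES", "TESCS_6", "TESCS_10", "TESCS_16", "post_12")

#: Outcome-measure groups assessed on separate visits.
OUTCOME_GROUPS = ("neurophys_ax1", "neurophys_ax2", "functional_clinical")

EVENT_COLUMNS = ["sample_index", "label", "intensity"]
ATTENDANCE_COLUMNS = [
    "participant", "phase", "outcome_group", "scheduled", "attended", "delay_weeks",
]
SCORE_COLUMNS = ["participant", "timepoint", "limb", "measure", "value"]


@dataclass
class Recording:
    """A multichannel sampled signal (time x channel) with optional events.

    Parameters
    ----------
    sample_rate
        Sampling rate in Hz; must be positive.
    channels
        Ordered, unique channel labels.
    samples
        Array of shape ``(n_samples, n_channels)``; a 1-D array is treated
        as a single channel.  EMG amplitudes are in μV.
    units
        Per-channel unit strings; defaults to ``"uV"`` for every channel.
    events
        Optional event table with columns ``sample_index,label,intensity``.
    """

    sample_rate: float
    channels: list[str]
    samples: np.ndarray
    units: list[str] | None = None
    events: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim == 1:
            self.samples = self.samples[:, None]
        if self.samples.ndim != 2:
            raise ValidationError("samples must be a (time x channel) matrix")
        self.channels = list(self.channels)
        if self.sample_rate <= 0:
            raise ValidationError("sample_rate must be positive")
        if len(set(self.channels)) != len(self.channels):
            raise ValidationError("channel labels must be unique")
        if len(self.channels) != self.samples.shape[1]:
            raise ValidationError(
                f"{len(self.channels)} labels for {self.samples.shape[1]} columns"
            )
        if self.units is None:
            self.units = ["uV"] * len(self.channels)
        self.units = list(self.units)
        if len(self.units) != len(self.channels):
            raise ValidationError("one unit string per channel required")
        if self.events is not None:
            self.events = validate_events(self.events, self.n_samples)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate

    def channel(self, label: str) -> np.ndarray:
        """Return the 1-D signal of the named channel."""
        try:
            idx = self.channels.index(label)
        except ValueError:
            raise KeyError(f"no channel {label!r}") from None
        return self.samples[:, idx]


def validate_events(events: pd.DataFrame, n_samples: int | None = None) -> pd.DataFrame:
    events = pd.DataFrame(events).reset_index(drop=True)
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise FormatError(f"event table missing columns {missing}")
    events = events[EVENT_COLUMNS].copy()
    events["sample_index"] = events["sample_index"].astype(int)
    if (events["sample_index"] < 0).any():
        raise ValidationError("event sample_index must be non-negative")
    if n_samples is not None and (events["sample_index"] >= n_samples).any():
        raise ValidationError("event sample_index beyond recording length")
    for label, grp in events.groupby("label"):
        idx = grp["sample_index"].to_numpy()
        if np.any(np.diff(idx) <= 0):
            raise ValidationError(
                f"event sample_index not strictly increasing for label {label!r}"
            )
    return events


def _stem(path: str | Path) -> Path:
    path = Path(path)
    if path.suffix == ".csv":
        return path.with_suffix("")
    return path


def read_recording(path: str | Path) -> Recording:
    """Read a delimited-text recording and its JSON sidecar.

    ``path`` may be the ``.csv`` sample file or its stem.  Raises
    :class:`FormatError` for a missing sidecar, ragged rows, or a
    label/column-count mismatch.
    """
    stem = _stem(path)
    csv_path = stem.with_suffix(".csv")
    meta_path = stem.parent / (stem.name + ".meta.json")
    if not meta_path.exists():
        raise FormatError(f"missing sidecar {meta_path}")
    if not csv_path.exists():
        raise FormatError(f"missing sample file {csv_path}")
    meta = json.loads(meta_path.read_text())
    try:
        samples = pd.read_csv(csv_path, header=None, dtype=float)
    except (pd.errors.ParserError, ValueError) as exc:
        raise FormatError(f"cannot parse {csv_path}: {exc}") from exc
    channels = meta["channels"]
    if samples.shape[1] != len(channels):
        raise FormatError(
            f"{samples.shape[1]} columns in {csv_path} but {len(channels)} labels"
        )
    events = None
    events_path = stem.parent / (stem.name + ".events.csv")
    if events_path.exists():
        events = pd.read_csv(events_path)
    return Recording(
        sample_rate=float(meta["sample_rate_hz"]),
        channels=channels,
        samples=samples.to_numpy(),
        units=meta.get("units"),
        events=events,
    )


def write_recording(rec: Recording, path: str | Path) -> None:
    """Write ``rec`` as ``<stem>.csv`` + ``<stem>.meta.json`` (+ events).

    Values are written with 17 significant digits, so a round trip is
    lossless for float64 (and bit-exact for integer-valued input).  The
    events file is only emitted when events are present.
    """
    stem = _stem(path)
    stem.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(stem.with_suffix(".csv"), rec.samples, fmt="%.17g", delimiter=",")
    meta = {
        "sample_rate_hz": rec.sample_rate,
        "channels": rec.channels,
        "units": rec.units,
        "conventions": {"event_indexing": "0-based", "windows": "half-open"},
    }
    (stem.parent / (stem.name + ".meta.json")).write_text(json.dumps(meta, indent=1))
    if rec.events is not None and len(rec.events):
        rec.events.to_csv(stem.parent / (stem.name + ".events.csv"), index=False)


def validate_attendance(log: pd.DataFrame) -> pd.DataFrame:
    """Validate an attendance log.

    Rows with ``scheduled == 0`` are the baseline / follow-up sentinel
    phases (no therapy block, only an assessment delay); they must have
    ``attended == 0``.  For therapy phases ``0 <= attended <= scheduled``.
    """
    log = pd.DataFrame(log).reset_index(drop=True)
    missing = [c for c in ATTENDANCE_COLUMNS if c not in log.columns]
    if missing:
        raise FormatError(f"attendance log missing columns {missing}")
    log = log[ATTENDANCE_COLUMNS].copy()
    log["scheduled"] = log["scheduled"].astype(int)
    log["attended"] = log["attended"].astype(int)
    log["delay_weeks"] = log["delay_weeks"].astype(float)
    if (log["scheduled"] < 0).any():
        raise ValidationError("scheduled must be non-negative")
    if (log["attended"] < 0).any():
        raise ValidationError("attended must be non-negative")
    if (log["attended"] > log["scheduled"]).any():
        raise ValidationError("attended exceeds scheduled")
    if (log["delay_weeks"] < 0).any():
        raise ValidationError("delay_weeks must be non-negative")
    bad_groups = set(log["outcome_group"]) - set(OUTCOME_GROUPS)
    if bad_groups:
        raise ValidationError(f"unknown outcome groups {sorted(bad_groups)}")
    return log


def read_attendance(path: str | Path) -> pd.DataFrame:
    """Read and validate an attendance CSV; row count is preserved."""
    log = pd.read_csv(path)
    return validate_attendance(log)


def write_attendance(log: pd.DataFrame, path: str | Path) -> None:
    validate_attendance(log).to_csv(path, index=False)


def validate_scores(scores: pd.DataFrame) -> pd.DataFrame:
    scores = pd.DataFrame(scores).reset_index(drop=True)
    missing = [c for c in SCORE_COLUMNS if c not in scores.columns]
    if missing:
        raise FormatError(f"score table missing columns {missing}")
    scores = scores[SCORE_COLUMNS].copy()
    bad_tp = set(scores["timepoint"]) - set(TIMEPOINTS)
    if bad_tp:
        raise ValidationError(f"unknown timepoints {sorted(bad_tp)}")
    key = ["participant", "timepoint", "limb", "measure"]
    if scores.duplicated(key).any():
        raise ValidationError("duplicate (participant, timepoint, limb, measure) rows")
    return scores


def read_scores(path: str | Path) -> pd.DataFrame:
    return validate_scores(pd.read_csv(path))


def write_scores(scores: pd.DataFrame, path: str | Path) -> None:
    validate_scores(scores).to_csv(path, index=False)
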