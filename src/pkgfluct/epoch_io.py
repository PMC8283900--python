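"""Reading, validating and writing epoch-level wrist-sensor data.

The on-disk interchange format is plain CSV:

* epoch files — header ``subject_id,timestamp,bks,dks,worn,tremor,walking``,
  one row per 2-minute epoch, ISO-8601 local timestamps.  ``bks`` is the
  per-epoch bradykinesia score, ``dks`` the dyskinesia score (>= 0);
  ``worn``/``tremor``/``walking`` are booleans accepted as 0/1/true/false
  (case-insensitive).
* dose files — header ``subject_id,reminder_time,acknowledged``, one row per
  medication reminder.

Missing epochs are represented by absence: gaps in the 2-minute grid are
never interpolated, and every downstream denominator counts only present
("available") epochs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import ParseError, ValidationError

EPOCH_COLUMNS = ["subject_id", "timestamp", "bks", "dks", "worn", "tremor", "walking"]
DOSE_COLUMNS = ["subject_id", "reminder_time", "acknowledged"]

_TRUE = {"1", "true", "t", "yes"}
_FALSE = {"0", "false", "f", "no", ""}


@dataclass(frozen=True)
class EpochRecord:
    """One scored 2-minute epoch."""

    timestamp: datetime
    bks: float
    dks: float
    worn: bool = True
    tremor: bool = False
    walking: bool = False


@dataclass(frozen=True)
class DoseEvent:
    """A programmed medication reminder with its acknowledgement flag."""

    reminder_time: datetime
    acknowledged: bool = True


@dataclass
class SubjectRecording:
    """A multi-day recording for one subject.

    ``epochs`` is a DataFrame with columns timestamp/bks/dks/worn/tremor/
    walking, sorted by timestamp, one row per *present* epoch.  ``ledd`` is
    the levodopa-equivalent daily dose (mg/day) when known; ``clinical``
    maps clinical-scale names (e.g. ``UPDRS_III``) to scores.
    """

    subject_id: str
    epochs: pd.DataFrame
    doses: list[DoseEvent] = field(default_factory=list)
    ledd: float | None = None
    clinical: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ep = self.epochs
        missing = [c for c in EPOCH_COLUMNS[1:] if c not in ep.columns]
        if missing:
            raise ValidationError(f"epochs frame missing columns {missing}")
        if len(ep) == 0:
            raise ValidationError(f"subject {self.subject_id}: no epochs")
        ts = pd.to_datetime(ep["timestamp"])
        if ts.duplicated().any():
            dup = ts[ts.duplicated()].iloc[0]
            raise ValidationError(f"subject {self.subject_id}: duplicate timestamp {dup}")
        if not ts.is_monotonic_increasing:
            ep = ep.sort_values("timestamp", kind="mergesort").reset_index(drop=True)
            self.epochs = ep
            ts = pd.to_datetime(ep["timestamp"])
        span_days = (ts.iloc[-1] - ts.iloc[0]).total_seconds() / 86400.0
        if span_days > 10:
            raise ValidationError(
                f"subject {self.subject_id}: recording spans {span_days:.1f} days (> 10)"
            )
        if (ep["dks"] < 0).any():
            raise ValidationError(f"subject {self.subject_id}: negative dks")

    @property
    def n_days(self) -> int:
        """Number of distinct calendar dates with at least one epoch."""
        return pd.to_datetime(self.epochs["timestamp"]).dt.normalize().nunique()

    def records(self) -> list[EpochRecord]:
        return [
            EpochRecord(
                timestamp=row.timestamp.to_pydatetime() if hasattr(row.timestamp, "to_pydatetime") else row.timestamp,
                bks=float(row.bks),
                dks=float(row.dks),
                worn=bool(row.worn),
                tremor=bool(row.tremor),
                walking=bool(row.walking),
            )
            for row in self.epochs.itertuples(index=False)
        ]


def records_to_frame(records: Iterable[EpochRecord]) -> pd.DataFrame:
    """Assemble EpochRecords into the canonical epochs DataFrame (sorted)."""
    rows = [
        (r.timestamp, r.bks, r.dks, r.worn, r.tremor, r.walking) for r in records
    ]
    df = pd.DataFrame(rows, columns=EPOCH_COLUMNS[1:])
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df.sort_values("timestamp", kind="mergesort").reset_index(drop=True)


def _parse_bool(value, line_no: int, column: str) -> bool:
    s = str(value).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise ParseError(f"line {line_no}: cannot parse boolean {column}={value!r}")


def _parse_timestamp(value, line_no: int, column: str = "timestamp") -> pd.Timestamp:
    try:
        ts = pd.Timestamp(str(value))
    except (ValueError, TypeError) as exc:
        raise ParseError(f"line {line_no}: malformed {column} {value!r}") from exc
    if pd.isna(ts):
        raise ParseError(f"line {line_no}: malformed {column} {value!r}")
    return ts


def read_epochs(path: str | Path) -> pd.DataFrame:
    """Read an epoch CSV into a validated, timestamp-sorted DataFrame.

    Rows out of order are sorted; duplicate timestamps (within a subject) and
    negative dyskinesia scores raise :class:`ValidationError` naming the row.
    Gaps in the 2-minute grid are preserved as absent rows, never filled.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in EPOCH_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path.name}: missing columns {missing}")
    if len(df) == 0:
        return pd.DataFrame(columns=EPOCH_COLUMNS)

    out = pd.DataFrame()
    out["subject_id"] = df["subject_id"].astype(str)
    # header is line 1, first data row is line 2
    lines = df.index + 2
    out["timestamp"] = [
        _parse_timestamp(v, ln) for v, ln in zip(df["timestamp"], lines)
    ]
    for col in ("bks", "dks"):
        try:
            out[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError):
            bad = pd.to_numeric(df[col], errors="coerce").isna()
            ln = int(lines[bad.to_numpy().nonzero()[0][0]])
            raise ParseError(f"line {ln}: cannot parse {col}={df[col][bad].iloc[0]!r}") from None
    for col in ("worn", "tremor", "walking"):
        out[col] = [_parse_bool(v, ln, col) for v, ln in zip(df[col], lines)]

    neg = out["dks"] < 0
    if neg.any():
        ln = int(lines[neg.to_numpy().nonzero()[0][0]])
        raise ValidationError(f"line {ln}: negative dks {out['dks'][neg].iloc[0]}")
    for sid, grp in out.groupby("subject_id", sort=False):
        dup = grp["timestamp"].duplicated()
        if dup.any():
            raise ValidationError(
                f"subject {sid}: duplicate timestamp {grp['timestamp'][dup].iloc[0]}"
            )
    return out.sort_values(["subject_id", "timestamp"], kind="mergesort").reset_index(drop=True)


def read_doses(path: str | Path) -> pd.DataFrame:
    """Read a dose-reminder CSV. An empty file yields an empty frame (the
    subject's levodopa response is then not estimable downstream)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in DOSE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path.name}: missing columns {missing}")
    if len(df) == 0:
        return pd.DataFrame(columns=DOSE_COLUMNS)
    lines = df.index + 2
    out = pd.DataFrame()
    out["subject_id"] = df["subject_id"].astype(str)
    out["reminder_time"] = [
        _parse_timestamp(v, ln, "reminder_time") for v, ln in zip(df["reminder_time"], lines)
    ]
    out["acknowledged"] = [
        _parse_bool(v, ln, "acknowledged") for v, ln in zip(df["acknowledged"], lines)
    ]
    return out.sort_values(["subject_id", "reminder_time"], kind="mergesort").reset_index(drop=True)


def load_recordings(
    epochs_path: str | Path,
    doses_path: str | Path | None = None,
    ledd: Mapping[str, float] | None = None,
    clinical: Mapping[str, Mapping[str, float]] | None = None,
) -> list[SubjectRecording]:
    """Assemble per-subject recordings from epoch and dose CSVs."""
    epochs = read_epochs(epochs_path)
    doses = read_doses(doses_path) if doses_path is not None else pd.DataFrame(columns=DOSE_COLUMNS)
    recordings = []
    for sid, grp in epochs.groupby("subject_id", sort=True):
        sub_doses = doses[doses["subject_id"] == sid]
        events = [
            DoseEvent(reminder_time=row.reminder_time, acknowledged=bool(row.acknowledged))
            for row in sub_doses.itertuples(index=False)
        ]
        recordings.append(
            SubjectRecording(
                subject_id=str(sid),
                epochs=grp.drop(columns="subject_id").reset_index(drop=True),
                doses=events,
                ledd=None if ledd is None else ledd.get(str(sid)),
                clinical=dict(clinical.get(str(sid), {})) if clinical else {},
            )
        )
    return recordings


def write_doses(doses: Mapping[str, Sequence[DoseEvent]], path: str | Path) -> None:
    rows = [
        (sid, ev.reminder_time.isoformat(), int(ev.acknowledged))
        for sid, events in doses.items()
        for ev in events
    ]
    pd.DataFrame(rows, columns=DOSE_COLUMNS).to_csv(path, index=False)


def write_epochs(recordings: Sequence[SubjectRecording], path: str | Path) -> None:
    frames = []
    for rec in recordings:
        df = rec.epochs.copy()
        df.insert(0, "subject_id", rec.subject_id)
        df["timestamp"] = pd.to_datetime(df["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
        for col in ("worn", "tremor", "walking"):
            df[col] = df[col].astype(int)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


# --- summary output ------------------------------------------------------

def write_summary(summary: pd.DataFrame, path: str | Path) -> None:
    """Write the per-subject summary table (one row per subject).

    CSV by default; a ``.json`` suffix writes a list of row objects. Floats
    are written at full (repr) precision so the file round-trips exactly.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        records = summary.to_dict(orient="records")
        cleaned = [
            {k: (None if isinstance(v, float) and math.isnan(v) else v) for k, v in row.items()}
            for row in records
        ]
        path.write_text(json.dumps(cleaned, indent=2, default=str))
    else:
        summary.to_csv(path, index=False, float_format=None)


def read_summary(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() == ".json":
        return pd.DataFrame(json.loads(path.read_text()))
    return pd.read_csv(path)
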