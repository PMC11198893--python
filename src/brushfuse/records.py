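"""Core record schemas and CSV input/output.

All downstream stages operate on :class:`pandas.DataFrame` objects with the
column conventions defined here.  Timestamps live on disk as ISO 8601 strings
with millisecond precision; in memory every time is a float number of seconds
measured from the *stream epoch* — midnight (00:00:00) of the day on which the
stream's first record falls.  Working in seconds keeps the bout logic (1 s and
10 s thresholds) and the signed attribution intervals free of datetime
arithmetic.

On-disk schemas
---------------
``events.csv``
    ``event_id,start,duration_s,direction`` — one row per brush rotation
    event (the brush arm changing direction), ``direction`` in ``{cw, ccw}``.
``detections.csv``
    ``timestamp,animal_id,source`` — one row per identity read,
    ``source`` in ``{rfid, vision}``.
``annotations.csv``
    ``unit_kind,unit_id,true_users`` — ground-truth user sets per event or
    bout; ``true_users`` is a ``;``-separated animal-id list (empty string
    means no user).
``daily_use.csv``
    ``cow_id,day,seconds`` — per-animal per-day brush-use totals.

Malformed rows are dropped and reported, never fatal: a pipeline run over
days of barn sensor logs must survive isolated corruption.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Default calendar anchor used when serialising simulated streams.
DEFAULT_EPOCH = pd.Timestamp("2024-01-01 00:00:00")

#: Gap value assigned to the first event of a stream (one day, in seconds).
SENTINEL_FIRST = 86400.0

SECONDS_PER_DAY = 86400.0

EVENT_COLUMNS = ["event_id", "start", "duration_s", "direction"]
DETECTION_COLUMNS = ["timestamp", "animal_id", "source"]
ANNOTATION_COLUMNS = ["unit_kind", "unit_id", "true_users"]
DAILY_COLUMNS = ["cow_id", "day", "seconds"]

VALID_DIRECTIONS = frozenset({"cw", "ccw"})
VALID_SOURCES = frozenset({"rfid", "vision"})
VALID_UNIT_KINDS = frozenset({"event", "bout"})


class SchemaError(ValueError):
    """Raised when a CSV file does not carry the expected header."""


@dataclass
class ValidationReport:
    """Row-level accounting for one file read.

    ``warnings`` holds ``(row_index, reason)`` pairs for every row that was
    dropped or looked suspicious; ``row_index`` is the 0-based position in
    the input file (excluding the header).
    """

    n_rows: int = 0
    n_dropped: int = 0
    warnings: list[tuple[int, str]] = field(default_factory=list)

    def add(self, row: int, reason: str, dropped: bool = True) -> None:
        self.warnings.append((row, reason))
        if dropped:
            self.n_dropped += 1


def _check_header(df: pd.DataFrame, expected: list[str], path: str) -> None:
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing column(s) {missing}; expected header {expected}"
        )


def _seconds_since_epoch(ts: pd.Series) -> tuple[np.ndarray, pd.Timestamp]:
    """Convert parsed timestamps to float seconds from first-day midnight."""
    epoch = ts.iloc[0].normalize()
    sec = (ts - epoch) / pd.Timedelta(seconds=1)
    return sec.to_numpy(dtype=float), epoch


def _format_timestamps(seconds: np.ndarray, epoch: pd.Timestamp) -> pd.Series:
    # Round to the millisecond grid so that a write/read cycle is exact.
    ms = np.round(np.asarray(seconds, dtype=float) * 1000.0).astype(np.int64)
    ts = epoch + pd.to_timedelta(ms, unit="ms")
    return pd.Series(ts).dt.strftime("%Y-%m-%dT%H:%M:%S.%f").str[:-3]


def read_events(path) -> tuple[pd.DataFrame, ValidationReport]:
    """Read a rotation-event CSV.

    Returns a frame with columns ``event_id`` (int), ``start_s`` (float
    seconds from stream epoch), ``duration_s`` (float) and ``direction``,
    sorted by ``start_s``, plus a :class:`ValidationReport`.  Overlapping,
    non-positive-duration, bad-direction and unparseable rows are dropped and
    reported.  ``gap_s`` is *not* populated here (see
    :func:`brushfuse.bouts.compute_gaps`).  The stream epoch is stored in
    ``frame.attrs["epoch"]``.
    """
    raw = pd.read_csv(path, dtype=str)
    _check_header(raw, EVENT_COLUMNS, str(path))
    report = ValidationReport(n_rows=len(raw))
    if raw.empty:
        out = pd.DataFrame(
            {"event_id": pd.Series(dtype=int), "start_s": pd.Series(dtype=float),
             "duration_s": pd.Series(dtype=float), "direction": pd.Series(dtype=str)}
        )
        out.attrs["epoch"] = DEFAULT_EPOCH
        return out, report

    ts = pd.to_datetime(raw["start"], errors="coerce", format="ISO8601")
    dur = pd.to_numeric(raw["duration_s"], errors="coerce")
    keep = np.ones(len(raw), dtype=bool)
    for i in np.flatnonzero(ts.isna().to_numpy()):
        report.add(int(i), "unparseable timestamp")
        keep[i] = False
    for i in np.flatnonzero((dur.isna() | (dur <= 0)).to_numpy() & keep):
        report.add(int(i), "nonpositive duration")
        keep[i] = False
    bad_dir = ~raw["direction"].isin(VALID_DIRECTIONS).to_numpy()
    for i in np.flatnonzero(bad_dir & keep):
        report.add(int(i), f"invalid direction {raw['direction'].iloc[i]!r}")
        keep[i] = False

    df = pd.DataFrame(
        {
            "event_id": pd.to_numeric(raw["event_id"], errors="coerce"),
            "_ts": ts,
            "duration_s": dur,
            "direction": raw["direction"],
        }
    )[keep]
    if df.empty:
        out = pd.DataFrame(
            {"event_id": pd.Series(dtype=int), "start_s": pd.Series(dtype=float),
             "duration_s": pd.Series(dtype=float), "direction": pd.Series(dtype=str)}
        )
        out.attrs["epoch"] = DEFAULT_EPOCH
        return out, report

    if not df["_ts"].is_monotonic_increasing:
        report.add(-1, "input not sorted", dropped=False)
        df = df.sort_values("_ts", kind="stable")
    df = df.reset_index(drop=True)

    start_s, epoch = _seconds_since_epoch(df["_ts"])
    duration = df["duration_s"].to_numpy(dtype=float)
    # drop rows that overlap their predecessor (keep the earlier one)
    keep2 = np.ones(len(df), dtype=bool)
    last_end = -np.inf
    for i in range(len(df)):
        if start_s[i] < last_end - 1e-9:
            report.add(i, "overlaps previous event")
            keep2[i] = False
        else:
            last_end = start_s[i] + duration[i]

    out = pd.DataFrame(
        {
            "event_id": df["event_id"].to_numpy()[keep2].astype(int),
            "start_s": start_s[keep2],
            "duration_s": duration[keep2],
            "direction": df["direction"].to_numpy()[keep2],
        }
    ).reset_index(drop=True)
    out.attrs["epoch"] = epoch
    return out, report


def write_events(events: pd.DataFrame, path, epoch: pd.Timestamp | None = None) -> None:
    """Write an in-memory event frame back to the on-disk schema."""
    if epoch is None:
        epoch = events.attrs.get("epoch", DEFAULT_EPOCH)
    out = pd.DataFrame(
        {
            "event_id": events["event_id"].astype(int)
            if len(events)
            else pd.Series(dtype=int),
            "start": _format_timestamps(events["start_s"].to_numpy(), epoch)
            if len(events)
            else pd.Series(dtype=str),
            "duration_s": events["duration_s"],
            "direction": events["direction"],
        }
    )
    out.to_csv(path, index=False)


def read_detections(path) -> tuple[pd.DataFrame, ValidationReport]:
    """Read an identity-detection CSV.

    Returns a frame ``time_s`` (float seconds from stream epoch),
    ``animal_id`` (str), ``source``, sorted by ``time_s``.  Rows with an
    unknown source or an empty animal id are dropped; exact duplicate rows
    are *kept* (hardware repeats carry timing information) but flagged.
    """
    raw = pd.read_csv(path, dtype=str)
    _check_header(raw, DETECTION_COLUMNS, str(path))
    report = ValidationReport(n_rows=len(raw))
    if raw.empty:
        out = pd.DataFrame(
            {"time_s": pd.Series(dtype=float), "animal_id": pd.Series(dtype=str),
             "source": pd.Series(dtype=str)}
        )
        out.attrs["epoch"] = DEFAULT_EPOCH
        return out, report

    ts = pd.to_datetime(raw["timestamp"], errors="coerce", format="ISO8601")
    keep = np.ones(len(raw), dtype=bool)
    for i in np.flatnonzero(ts.isna().to_numpy()):
        report.add(int(i), "unparseable timestamp")
        keep[i] = False
    empty_id = raw["animal_id"].isna().to_numpy() | (
        raw["animal_id"].fillna("").str.len() == 0
    ).to_numpy()
    for i in np.flatnonzero(empty_id & keep):
        report.add(int(i), "empty animal_id")
        keep[i] = False
    bad_src = ~raw["source"].isin(VALID_SOURCES).to_numpy()
    for i in np.flatnonzero(bad_src & keep):
        report.add(int(i), f"invalid source {raw['source'].iloc[i]!r}")
        keep[i] = False

    dupes = raw.duplicated(keep="first").to_numpy()
    for i in np.flatnonzero(dupes & keep):
        report.add(int(i), "duplicate detection row", dropped=False)

    df = pd.DataFrame(
        {"_ts": ts, "animal_id": raw["animal_id"], "source": raw["source"]}
    )[keep]
    if df.empty:
        out = pd.DataFrame(
            {"time_s": pd.Series(dtype=float), "animal_id": pd.Series(dtype=str),
             "source": pd.Series(dtype=str)}
        )
        out.attrs["epoch"] = DEFAULT_EPOCH
        return out, report
    if not df["_ts"].is_monotonic_increasing:
        report.add(-1, "input not sorted", dropped=False)
        df = df.sort_values("_ts", kind="stable")
    df = df.reset_index(drop=True)
    time_s, epoch = _seconds_since_epoch(df["_ts"])
    out = pd.DataFrame(
        {"time_s": time_s, "animal_id": df["animal_id"], "source": df["source"]}
    )
    out.attrs["epoch"] = epoch
    return out, report


def write_detections(
    detections: pd.DataFrame, path, epoch: pd.Timestamp | None = None
) -> None:
    if epoch is None:
        epoch = detections.attrs.get("epoch", DEFAULT_EPOCH)
    out = pd.DataFrame(
        {
            "timestamp": _format_timestamps(detections["time_s"].to_numpy(), epoch)
            if len(detections)
            else pd.Series(dtype=str),
            "animal_id": detections["animal_id"],
            "source": detections["source"],
        }
    )
    out.to_csv(path, index=False)


def parse_user_set(token) -> frozenset:
    """Parse a ``;``-separated animal-id list; '' or NaN → empty set."""
    if token is None or (isinstance(token, float) and np.isnan(token)):
        return frozenset()
    token = str(token).strip()
    if not token:
        return frozenset()
    return frozenset(t for t in token.split(";") if t)


def format_user_set(users) -> str:
    return ";".join(sorted(users))


def read_annotations(path) -> tuple[pd.DataFrame, ValidationReport]:
    """Read ground-truth user-set annotations.

    Returns a frame ``unit_kind``, ``unit_id`` (int), ``true_users``
    (frozenset of animal ids).
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    _check_header(raw, ANNOTATION_COLUMNS, str(path))
    report = ValidationReport(n_rows=len(raw))
    keep = np.ones(len(raw), dtype=bool)
    bad_kind = ~raw["unit_kind"].isin(VALID_UNIT_KINDS).to_numpy()
    for i in np.flatnonzero(bad_kind):
        report.add(int(i), f"invalid unit_kind {raw['unit_kind'].iloc[i]!r}")
        keep[i] = False
    df = raw[keep].reset_index(drop=True)
    out = pd.DataFrame(
        {
            "unit_kind": df["unit_kind"],
            "unit_id": pd.to_numeric(df["unit_id"]).astype(int)
            if len(df)
            else pd.Series(dtype=int),
            "true_users": [parse_user_set(t) for t in df["true_users"]],
        }
    )
    return out, report


def write_annotations(annotations: pd.DataFrame, path) -> None:
    out = pd.DataFrame(
        {
            "unit_kind": annotations["unit_kind"],
            "unit_id": annotations["unit_id"],
            "true_users": [format_user_set(u) for u in annotations["true_users"]],
        }
    )
    out.to_csv(path, index=False)


def read_daily_use(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_header(df, DAILY_COLUMNS, str(path))
    return pd.DataFrame(
        {
            "cow_id": df["cow_id"].astype(str),
            "day": df["day"].astype(int),
            "seconds": df["seconds"].astype(float),
        }
    )


def write_daily_use(daily: pd.DataFrame, path) -> None:
    daily.loc[:, DAILY_COLUMNS].to_csv(path, index=False)
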