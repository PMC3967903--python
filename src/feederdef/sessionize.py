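"""Turn per-second RFID detections into feeder visits.

A detector reports, once per second, the PIT tag perched in its antenna.
Birds make small back-and-forth movements while feeding and detectors
occasionally skip readings, so a visit appears as a run of readings with
short internal gaps.  Two consecutive readings by the same individual at
the same feeder strictly less than ``gap_threshold`` seconds apart
(default 21 s) belong to the same visit; a gap of 21 s or more starts a
new one.  A visit is summarized by its start time and an inclusive
duration (a single reading is a 1-s visit).
"""

from __future__ import annotations

import logging

import pandas as pd

log = logging.getLogger(__name__)

DETECTION_COLUMNS = ("timestamp", "tag_id", "feeder_id")
VISIT_COLUMNS = ("tag_id", "feeder_id", "start", "duration_s",
                 "n_readings", "date")


class FormatError(ValueError):
    """Input table does not match the documented delimited format."""


def read_detections(path) -> pd.DataFrame:
    """Read a detection table (CSV: timestamp, tag_id, feeder_id).

    Raises :class:`FormatError` naming any missing column, or listing the
    1-based data line numbers of unparseable timestamps.
    """
    df = pd.read_csv(path, dtype={"tag_id": str, "feeder_id": str})
    missing = [c for c in DETECTION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"detection file {path} is missing column(s): "
                          f"{', '.join(missing)}")
    ts = pd.to_datetime(df["timestamp"], errors="coerce",
                        format="ISO8601")
    bad = ts.isna() & df["timestamp"].notna()
    if bad.any():
        lines = [str(i + 2) for i in df.index[bad][:10]]  # +2: header + 1-based
        raise FormatError(
            f"unparseable timestamp(s) in {path} at line(s) "
            f"{', '.join(lines)}")
    df["timestamp"] = ts
    return df[list(DETECTION_COLUMNS)]


def detections_to_visits(records: pd.DataFrame,
                         gap_threshold: int = 21) -> pd.DataFrame:
    """Merge per-second detections into visits.

    Within each (tag, feeder), time-sorted readings are chained into one
    visit while every inter-reading gap is strictly less than
    ``gap_threshold`` seconds.  Duplicate (timestamp, tag, feeder) rows
    are dropped with a warning — reader chatter must not inflate the
    reading count.  Readings from different tags or feeders never merge.

    Returns a visit table sorted by (tag, feeder, start) with columns
    ``tag_id, feeder_id, start, duration_s, n_readings, date`` where
    ``duration_s = last reading − first reading + 1`` and ``date`` is the
    calendar day of the visit's start.
    """
    if gap_threshold < 1:
        raise ValueError("gap_threshold must be >= 1 second")
    if records.empty:
        return pd.DataFrame(columns=VISIT_COLUMNS)

    df = records[list(DETECTION_COLUMNS)].copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    n0 = len(df)
    df = df.drop_duplicates(subset=list(DETECTION_COLUMNS))
    if len(df) < n0:
        log.warning("dropped %d duplicate detection record(s)", n0 - len(df))

    df = df.sort_values(["tag_id", "feeder_id", "timestamp"],
                        kind="mergesort").reset_index(drop=True)
    gap = df["timestamp"].diff().dt.total_seconds()
    new_group = (df["tag_id"] != df["tag_id"].shift()) \
        | (df["feeder_id"] != df["feeder_id"].shift())
    new_visit = new_group | (gap >= gap_threshold)
    visit_id = new_visit.cumsum()

    g = df.groupby(visit_id)
    visits = pd.DataFrame({
        "tag_id": g["tag_id"].first(),
        "feeder_id": g["feeder_id"].first(),
        "start": g["timestamp"].min(),
        "duration_s": (
            (g["timestamp"].max() - g["timestamp"].min())
            .dt.total_seconds().astype(int) + 1),
        "n_readings": g.size(),
    })
    visits["date"] = visits["start"].dt.date
    visits = visits.sort_values(["tag_id", "feeder_id", "start"],
                                kind="mergesort").reset_index(drop=True)
    return visits


def write_visits(visits: pd.DataFrame, path) -> None:
    """Write a visit table as CSV with ISO-8601 start times."""
    out = visits.copy()
    out["start"] = pd.to_datetime(out["start"]).dt.strftime(
        "%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


def read_visits(path) -> pd.DataFrame:
    """Read a visit table written by :func:`write_visits`."""
    df = pd.read_csv(path, dtype={"tag_id": str, "feeder_id": str})
    missing = [c for c in VISIT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"visit file {path} is missing column(s): "
                          f"{', '.join(missing)}")
    df["start"] = pd.to_datetime(df["start"])
    df["date"] = pd.to_datetime(df["date"]).dt.date
    return df[list(VISIT_COLUMNS)]
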