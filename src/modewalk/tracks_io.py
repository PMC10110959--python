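"""Reading and writing of 2D cell-track tables.

On-disk contract: delimited text with one row per (track, time) sample.
The default dialect expects columns ``track_id,time_min,x_um,y_um`` with an
optional ``condition`` column; alternate column names and unit factors can
be declared through a dialect mapping.  Coordinates are Cartesian
micrometers with y increasing upward, times are minutes stored as reals
(nominal 1-min sampling, arbitrary spacing tolerated at I/O).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

from .errors import ConsistencyError, FormatError, ValidationError

#: Canonical column names and unit factors.  ``time_factor`` converts the
#: file's time unit to minutes, ``length_factor`` its length unit to um.
DEFAULT_DIALECT: dict = {
    "track_id": "track_id",
    "time_min": "time_min",
    "x_um": "x_um",
    "y_um": "y_um",
    "condition": "condition",
    "time_factor": 1.0,
    "length_factor": 1.0,
    "delimiter": ",",
}

_REQUIRED = ("track_id", "time_min", "x_um", "y_um")


@dataclass
class Trajectory:
    """One cell's timestamped 2D positions.

    times are strictly increasing minutes; positions is an (N, 2) float
    array in micrometers.  N >= 2 and no missing coordinates: raw gaps are
    represented by absent rows, never placeholder values.
    """

    track_id: str
    times: np.ndarray
    positions: np.ndarray
    condition: str | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.times.ndim != 1 or self.positions.shape != (self.times.size, 2):
            raise ValidationError(
                f"track {self.track_id!r}: positions must be (N, 2) matching times"
            )
        if self.times.size < 2:
            raise ValidationError(f"track {self.track_id!r}: needs >= 2 points")
        if not np.all(np.diff(self.times) > 0):
            raise ValidationError(f"track {self.track_id!r}: times not strictly increasing")
        if not (np.isfinite(self.times).all() and np.isfinite(self.positions).all()):
            raise ValidationError(f"track {self.track_id!r}: non-finite coordinates")

    @property
    def n_points(self) -> int:
        return int(self.times.size)

    @property
    def duration(self) -> float:
        """Observation span T_obs in minutes."""
        return float(self.times[-1] - self.times[0])


@dataclass
class TrackTable:
    """Collection of tracks backed by a tidy DataFrame.

    Rows are (track_id, time_min, x_um, y_um[, condition]), one row per
    (track_id, time_min) pair, groupable into valid trajectories.
    """

    frame: pd.DataFrame = field(repr=False)

    @classmethod
    def from_trajectories(cls, trajs: Iterable[Trajectory]) -> "TrackTable":
        parts = []
        for tr in trajs:
            part = pd.DataFrame(
                {
                    "track_id": tr.track_id,
                    "time_min": tr.times,
                    "x_um": tr.positions[:, 0],
                    "y_um": tr.positions[:, 1],
                }
            )
            if tr.condition is not None:
                part["condition"] = tr.condition
            parts.append(part)
        if not parts:
            frame = pd.DataFrame(columns=["track_id", "time_min", "x_um", "y_um"])
        else:
            frame = pd.concat(parts, ignore_index=True)
        return cls(frame)

    def trajectories(self) -> Iterator[Trajectory]:
        """Yield per-track trajectories in order of first appearance."""
        has_cond = "condition" in self.frame.columns
        for tid, grp in self.frame.groupby("track_id", sort=False):
            grp = grp.sort_values("time_min")
            cond = None
            if has_cond and grp["condition"].notna().any():
                cond = str(grp["condition"].iloc[0])
            yield Trajectory(
                track_id=str(tid),
                times=grp["time_min"].to_numpy(float),
                positions=grp[["x_um", "y_um"]].to_numpy(float),
                condition=cond,
            )

    def track_ids(self) -> list[str]:
        return [str(t) for t in self.frame["track_id"].drop_duplicates()]

    def __len__(self) -> int:
        return len(self.frame)


def _resolve_dialect(dialect: Mapping | None) -> dict:
    d = dict(DEFAULT_DIALECT)
    if dialect:
        unknown = set(dialect) - set(DEFAULT_DIALECT)
        if unknown:
            raise FormatError(f"unknown dialect keys: {sorted(unknown)}")
        d.update(dialect)
    return d


def read_tracks(source, dialect: Mapping | None = None) -> TrackTable:
    """Read a delimited track table into a :class:`TrackTable`.

    ``source`` is a path or open text stream with a header row.  The
    dialect maps canonical names to the file's column names and declares
    linear unit factors; times are coerced to minutes, positions to um.

    Raises :class:`FormatError` if a required column is missing and
    :class:`ValidationError` on duplicate (track_id, time) rows.
    """
    d = _resolve_dialect(dialect)
    raw = pd.read_csv(source, sep=d["delimiter"])
    rename = {}
    for canon in (*_REQUIRED, "condition"):
        col = d[canon]
        if col in raw.columns:
            rename[col] = canon
        elif canon != "condition":
            raise FormatError(f"missing required column {col!r} (for {canon})")
    frame = raw.rename(columns=rename)
    keep = [c for c in ("track_id", "time_min", "x_um", "y_um", "condition") if c in frame.columns]
    frame = frame[keep].copy()
    frame["track_id"] = frame["track_id"].astype(str)
    frame["time_min"] = frame["time_min"].astype(float) * float(d["time_factor"])
    for c in ("x_um", "y_um"):
        frame[c] = frame[c].astype(float) * float(d["length_factor"])

    dup = frame.duplicated(subset=["track_id", "time_min"], keep=False)
    if dup.any():
        bad = sorted(frame.loc[dup, "track_id"].unique())
        raise ValidationError(f"duplicate (track_id, time) rows in tracks: {bad}")
    return TrackTable(frame)


def _as_label_frame(modes) -> pd.DataFrame:
    """Normalize per-window labels to (track_id, window_start_min, window_end_min, mode)."""
    cols = ["track_id", "window_start_min", "window_end_min", "mode"]
    if isinstance(modes, pd.DataFrame):
        missing = [c for c in cols if c not in modes.columns]
        if missing:
            raise FormatError(f"label frame missing columns {missing}")
        return modes[cols].copy()
    records = []
    for item in modes:
        if hasattr(item, "windows"):  # ModeSequence-like
            for start, end, mode in item.windows:
                records.append((item.track_id, float(start), float(end), str(mode)))
        else:
            tid, start, end, mode = item
            records.append((str(tid), float(start), float(end), str(mode)))
    return pd.DataFrame(records, columns=cols)


def write_annotated(tracks: TrackTable, modes, sink) -> None:
    """Write the track table with per-window mode annotations.

    Each output row carries the original columns plus
    ``window_start_min``, ``window_end_min`` and ``mode`` for the window
    containing its timestamp (empty where no window applies).  Positions
    round-trip bit-exactly through decimal text (shortest-repr floats).
    """
    labels = _as_label_frame(modes)
    known = set(tracks.track_ids())
    unknown = sorted(set(labels["track_id"].astype(str)) - known)
    if unknown:
        raise ConsistencyError(f"labels reference unknown track ids: {unknown}")

    out = tracks.frame.copy()
    out["window_start_min"] = np.nan
    out["window_end_min"] = np.nan
    out["mode"] = ""
    for _, row in labels.iterrows():
        sel = (
            (out["track_id"] == row["track_id"])
            & (out["time_min"] >= row["window_start_min"])
            & (out["time_min"] < row["window_end_min"])
        )
        out.loc[sel, ["window_start_min", "window_end_min", "mode"]] = (
            row["window_start_min"],
            row["window_end_min"],
            row["mode"],
        )
    out.to_csv(sink, index=False)


def write_tracks(tracks: TrackTable, sink) -> None:
    """Write a plain track table (canonical dialect)."""
    tracks.frame.to_csv(sink, index=False)
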