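"""Track polishing: gap handling, quality filtering and windowing.

The cleaning rules mirror the study design for long-term confined-cell
tracks sampled nominally every minute:

1. tracks are split wherever an untracked period of >= 10 min occurs;
2. shorter gaps (< 10 min) are filled on the 1-min grid by per-coordinate
   cubic-spline interpolation through the observed samples;
3. tracks failing any of three quality criteria are removed — mean track
   speed >= 1.5 um/min, duration >= 60 min, maximal displacement from the
   starting position >= 20 um;
4. surviving tracks are cut into consecutive non-overlapping one-hour
   windows; windows with fewer than 50 points are dropped, so admissible
   segments hold 50-60 points.

Splitting is applied before interpolation when both gap classes occur in
one track, so interpolation never bridges a split boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.interpolate import CubicSpline

from .errors import TooShortError
from .tracks_io import Trajectory


@dataclass(frozen=True)
class FilterCriteria:
    """The three track-quality thresholds (all must be met to keep a track)."""

    min_mean_speed: float = 1.5   # um/min
    min_duration: float = 60.0    # min
    min_max_displacement: float = 20.0  # um

    def __post_init__(self) -> None:
        if min(self.min_mean_speed, self.min_duration, self.min_max_displacement) <= 0:
            raise ValueError("all filter thresholds must be > 0")


@dataclass
class Segment:
    """A one-hour window cut from a trajectory; the unit of classification."""

    parent_id: str
    start_min: float
    end_min: float
    times: np.ndarray
    positions: np.ndarray

    @property
    def n_points(self) -> int:
        return int(self.times.size)


def split_on_long_gaps(raw: Trajectory, threshold: float = 10.0) -> list[Trajectory]:
    """Split a trajectory at every inter-sample gap >= ``threshold`` minutes.

    Child ids are suffixed ``#1``, ``#2``, ... in time order; an unsplit
    track keeps its id.  Pieces left with fewer than 2 points are
    discarded (they carry no displacement information and would fail the
    duration filter regardless).
    """
    gaps = np.diff(raw.times)
    cut_after = np.nonzero(gaps >= threshold)[0]
    if cut_after.size == 0:
        return [raw]
    bounds = [0, *(cut_after + 1), raw.n_points]
    pieces = []
    part = 1
    for lo, hi in zip(bounds, bounds[1:]):
        if hi - lo < 2:
            continue
        pieces.append(Trajectory(
            track_id=f"{raw.track_id}#{part}",
            times=raw.times[lo:hi],
            positions=raw.positions[lo:hi],
            condition=raw.condition,
        ))
        part += 1
    return pieces


def interpolate_gaps(raw: Trajectory, max_gap: float = 10.0) -> Trajectory:
    """Fill short tracking gaps on the 1-min grid by cubic-spline interpolation.

    Every inter-sample gap strictly shorter than ``max_gap`` minutes is
    filled at the missing 1-min grid points (relative to the preceding
    sample) by a per-coordinate cubic spline (not-a-knot boundary, so the
    interpolant reproduces cubic motion exactly) through all observed
    points.  Observed samples are never altered; gaps >= ``max_gap`` are
    left untouched for :func:`split_on_long_gaps` to handle.
    """
    if raw.n_points < 4:
        raise TooShortError(
            f"track {raw.track_id!r}: cubic interpolation needs >= 4 points")
    gaps = np.diff(raw.times)
    fill: list[float] = []
    for i, g in enumerate(gaps):
        if 1.0 < g < max_gap:
            t0 = raw.times[i]
            new = t0 + np.arange(1.0, np.ceil(g - 1e-9))
            fill.extend(t for t in new if t < raw.times[i + 1] - 1e-9)
    if not fill:
        return raw
    spline_x = CubicSpline(raw.times, raw.positions[:, 0])
    spline_y = CubicSpline(raw.times, raw.positions[:, 1])
    t_new = np.asarray(fill)
    filled = np.stack((spline_x(t_new), spline_y(t_new)), axis=1)
    times = np.concatenate((raw.times, t_new))
    positions = np.vstack((raw.positions, filled))
    order = np.argsort(times)
    return Trajectory(track_id=raw.track_id, times=times[order],
                      positions=positions[order], condition=raw.condition)


def mean_track_speed(traj: Trajectory) -> float:
    """Mean of per-step displacement / time-step over the whole track (um/min)."""
    d = np.linalg.norm(np.diff(traj.positions, axis=0), axis=1)
    return float(np.mean(d / np.diff(traj.times)))


def max_displacement(traj: Trajectory) -> float:
    """max_t |r(t) - r(t0)| in um."""
    return float(np.max(np.linalg.norm(traj.positions - traj.positions[0], axis=1)))


def filter_tracks(
    trajs: Iterable[Trajectory],
    criteria: FilterCriteria = FilterCriteria(),
) -> tuple[list[Trajectory], list[tuple[Trajectory, tuple[str, ...]]]]:
    """Partition tracks into (kept, removed-with-reasons) by the three criteria.

    A track is kept iff its mean step speed, duration and maximal
    displacement from the start all meet their thresholds; removed entries
    carry every violated criterion name ("speed", "duration",
    "displacement").
    """
    kept: list[Trajectory] = []
    removed: list[tuple[Trajectory, tuple[str, ...]]] = []
    for tr in trajs:
        reasons = []
        if mean_track_speed(tr) < criteria.min_mean_speed:
            reasons.append("speed")
        if tr.duration < criteria.min_duration:
            reasons.append("duration")
        if max_displacement(tr) < criteria.min_max_displacement:
            reasons.append("displacement")
        if reasons:
            removed.append((tr, tuple(reasons)))
        else:
            kept.append(tr)
    return kept, removed


def segment_trajectory(
    traj: Trajectory,
    window: float = 60.0,
    min_points: int = 50,
) -> list[Segment]:
    """Cut a gap-free trajectory into consecutive non-overlapping windows.

    Windows are anchored at the track's first timestamp: [t0, t0+window),
    [t0+window, t0+2*window), ...  Windows holding fewer than
    ``min_points`` samples (or more than ``window`` — possible only for
    oversampled input) are dropped.
    """
    max_points = int(round(window))
    t0 = traj.times[0]
    n_windows = int(np.floor((traj.times[-1] - t0) / window)) + 1
    out: list[Segment] = []
    for w in range(n_windows):
        lo = t0 + w * window
        hi = lo + window
        mask = (traj.times >= lo) & (traj.times < hi)
        n = int(mask.sum())
        if n < min_points or n > max_points:
            continue
        out.append(Segment(parent_id=traj.track_id, start_min=float(lo),
                           end_min=float(hi), times=traj.times[mask],
                           positions=traj.positions[mask]))
    return out


def preprocess_trajectory(
    raw: Trajectory,
    max_gap: float = 10.0,
    split_threshold: float = 10.0,
) -> list[Trajectory]:
    """Split on long gaps, then interpolate short gaps within each piece.

    Pieces too short for spline interpolation (< 4 points) are passed
    through unfilled if gapless, otherwise dropped.
    """
    out = []
    for piece in split_on_long_gaps(raw, split_threshold):
        if piece.n_points >= 4:
            out.append(interpolate_gaps(piece, max_gap))
        elif np.all(np.diff(piece.times) <= 1.0 + 1e-9):
            out.append(piece)
    return out
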