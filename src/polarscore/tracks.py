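"""Migration-track statistics for time-lapse cell tracks.

A :class:`Track` is an ordered sequence of (frame, x, y) positions for one
cell, with a physical frame interval ``dt`` (seconds) and ``pixel_size``
(length per pixel).  :func:`track_metrics` reduces a track to the per-cell
numbers commonly drawn on migration plots: total path length, net
displacement, mean speed (path length over elapsed time), the directionality
ratio (net / path, 1 for straight runs, 0 for closed loops), signed turning
angles, and the endpoint rebased to the origin for rose plots.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Track", "TrackMetrics", "track_metrics", "summarize_condition"]


@dataclass
class Track:
    """One cell's positions over time, in pixel coordinates (x=col, y=row)."""

    track_id: str
    frames: np.ndarray
    x: np.ndarray
    y: np.ndarray
    dt: float = 1.0
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.frames) == len(self.x) == len(self.y)):
            raise ValueError("frames, x, y must have equal length")
        if len(self.frames) >= 2 and not np.all(np.diff(self.frames) > 0):
            raise ValueError(f"track {self.track_id!r}: frames must be strictly increasing")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValueError(f"track {self.track_id!r}: non-finite coordinates")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def has_gaps(self) -> bool:
        """True when frames skip (missed detections); elapsed time stays real."""
        return len(self.frames) >= 2 and bool(np.any(np.diff(self.frames) != 1))

    def positions(self) -> np.ndarray:
        """(N, 2) physical positions (x, y) in length units."""
        return np.column_stack([self.x, self.y]) * self.pixel_size


@dataclass
class TrackMetrics:
    track_id: str
    n_positions: int
    path_length: float
    net_displacement: float
    elapsed_time: float
    mean_speed: float
    directionality: float
    turning_angles: np.ndarray = field(repr=False)
    rebased_endpoint: tuple[float, float] = (0.0, 0.0)
    instantaneous_speeds: np.ndarray = field(default=None, repr=False)


def track_metrics(track: Track) -> TrackMetrics:
    """Per-cell migration statistics; lengths in physical units, speed per second.

    Raises ``ValueError`` for tracks with fewer than 2 positions, ``dt <= 0``,
    or zero total path length (a stationary track has no defined direction).
    """
    if len(track) < 2:
        raise ValueError(f"track {track.track_id!r}: need >= 2 positions")
    if track.dt <= 0:
        raise ValueError("dt must be positive")
    pos = track.positions()
    steps = np.diff(pos, axis=0)
    step_lengths = np.hypot(steps[:, 0], steps[:, 1])
    path_length = float(step_lengths.sum())
    if path_length == 0.0:
        raise ValueError(f"track {track.track_id!r}: zero path length")
    net_vec = pos[-1] - pos[0]
    net = float(np.hypot(*net_vec))
    # gap-aware: elapsed time uses actual frame span, not number of rows
    elapsed = float(track.frames[-1] - track.frames[0]) * track.dt
    step_times = np.diff(track.frames) * track.dt
    with np.errstate(divide="ignore", invalid="ignore"):
        inst = step_lengths / step_times

    headings = np.arctan2(steps[:, 1], steps[:, 0])
    nz = step_lengths > 0
    hz = headings[nz]
    turns = np.arctan2(np.sin(np.diff(hz)), np.cos(np.diff(hz)))  # wrap to (-pi, pi]

    return TrackMetrics(
        track_id=track.track_id,
        n_positions=len(track),
        path_length=path_length,
        net_displacement=net,
        elapsed_time=elapsed,
        mean_speed=path_length / elapsed,
        directionality=net / path_length,
        turning_angles=turns,
        rebased_endpoint=(float(net_vec[0]), float(net_vec[1])),
        instantaneous_speeds=inst,
    )


def metrics_table(metrics: list[TrackMetrics]) -> pd.DataFrame:
    """One row per track with the scalar metrics (CSV-writable)."""
    return pd.DataFrame(
        {
            "track_id": [m.track_id for m in metrics],
            "n_positions": [m.n_positions for m in metrics],
            "path_length": [m.path_length for m in metrics],
            "net_displacement": [m.net_displacement for m in metrics],
            "elapsed_time": [m.elapsed_time for m in metrics],
            "mean_speed": [m.mean_speed for m in metrics],
            "directionality": [m.directionality for m in metrics],
            "endpoint_x": [m.rebased_endpoint[0] for m in metrics],
            "endpoint_y": [m.rebased_endpoint[1] for m in metrics],
        }
    )


def summarize_condition(metrics: list[TrackMetrics]) -> pd.DataFrame:
    """Mean +/- SEM of path length, speed and directionality for one condition.

    SEM is reported as NaN for a single track (sample SEM undefined at n=1).
    """
    if not metrics:
        raise ValueError("no tracks to summarize")
    tab = metrics_table(metrics)
    rows = []
    for col in ("path_length", "mean_speed", "directionality"):
        vals = tab[col].to_numpy()
        sem = float(np.std(vals, ddof=1) / math.sqrt(len(vals))) if len(vals) > 1 else float("nan")
        rows.append({"metric": col, "n": len(vals), "mean": float(vals.mean()), "sem": sem})
    return pd.DataFrame(rows)
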