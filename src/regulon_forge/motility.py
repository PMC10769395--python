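"""Cell-movement quantification from nucleus-detection tables.

Detections (frame, x, y, quality) are optionally linked into trajectories
by greedy nearest-neighbour matching, filtered on mean quality (strict
``> min``), duration (inclusive ``>= min`` occurrences), and an ROI
rectangle, and summarized per track as total distance traveled (sum of
step lengths) and movement range (maximum pairwise displacement, i.e.
trajectory diameter). Units follow the input coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Trajectory",
    "TrackMetrics",
    "link_detections",
    "trajectories_from_table",
    "filter_tracks",
    "track_metrics",
    "transwell_normalize",
    "confluency_normalize",
]


@dataclass(frozen=True)
class Trajectory:
    """Time-ordered positions of one tracked nucleus."""

    track_id: str
    frames: tuple[int, ...]
    x: tuple[float, ...]
    y: tuple[float, ...]
    quality: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.frames) == 0:
            raise ValueError(f"track {self.track_id!r} has no points")
        if not all(b > a for a, b in zip(self.frames, self.frames[1:])):
            raise ValueError(f"track {self.track_id!r}: frames not strictly increasing")
        n = len(self.frames)
        if not (len(self.x) == len(self.y) == len(self.quality) == n):
            raise ValueError(f"track {self.track_id!r}: ragged point arrays")

    @property
    def n_points(self) -> int:
        return len(self.frames)

    @property
    def mean_quality(self) -> float:
        return float(np.mean(self.quality))


@dataclass(frozen=True)
class TrackMetrics:
    track_id: str
    n_points: int
    mean_quality: float
    total_distance: float
    movement_range: float
    passed_filters: bool = True


def trajectories_from_table(detections: pd.DataFrame) -> list[Trajectory]:
    """Group a detections table by its ``track_id`` column (linking bypass)."""
    if "track_id" not in detections.columns:
        raise ValueError("detections table has no track_id column; use link_detections")
    tracks: list[Trajectory] = []
    for tid, grp in detections.groupby("track_id", sort=True):
        grp = grp.sort_values("frame")
        tracks.append(
            Trajectory(
                track_id=str(tid),
                frames=tuple(int(f) for f in grp["frame"]),
                x=tuple(float(v) for v in grp["x"]),
                y=tuple(float(v) for v in grp["y"]),
                quality=tuple(float(v) for v in grp["quality"]),
            )
        )
    return tracks


def link_detections(detections: pd.DataFrame, max_displacement: float) -> list[Trajectory]:
    """Greedy nearest-neighbour frame-to-frame linking.

    For each consecutive frame pair, candidate (track end, detection)
    matches within ``max_displacement`` are taken in ascending distance
    order; unmatched detections seed new tracks and tracks missing a
    frame terminate. This is deliberately simple plumbing for
    collision-free data, not a full tracking algorithm.
    """
    if detections.empty:
        raise ValueError("empty detections table")
    if max_displacement <= 0:
        raise ValueError("max_displacement must be > 0")
    frames = sorted(int(f) for f in detections["frame"].unique())
    lo, hi = frames[0], frames[-1]
    if frames != list(range(lo, hi + 1)):
        raise ValueError("frames must form a contiguous integer range")

    by_frame = {int(f): grp for f, grp in detections.groupby("frame")}
    next_id = 0
    # an open track: dict with accumulated point lists and last position
    open_tracks: list[dict] = []
    done: list[dict] = []

    def new_track(row) -> dict:
        nonlocal next_id
        t = {
            "id": f"track_{next_id:05d}",
            "frames": [int(row.frame)],
            "x": [float(row.x)],
            "y": [float(row.y)],
            "q": [float(row.quality)],
        }
        next_id += 1
        return t

    for row in by_frame[lo].itertuples(index=False):
        open_tracks.append(new_track(row))

    for f in range(lo + 1, hi + 1):
        dets = list(by_frame[f].itertuples(index=False))
        pairs = []
        for ti, track in enumerate(open_tracks):
            tx, ty = track["x"][-1], track["y"][-1]
            for di, det in enumerate(dets):
                d = math.hypot(float(det.x) - tx, float(det.y) - ty)
                if d <= max_displacement:
                    pairs.append((d, ti, di))
        pairs.sort(key=lambda t: (t[0], t[1], t[2]))
        used_tracks: set[int] = set()
        used_dets: set[int] = set()
        for d, ti, di in pairs:
            if ti in used_tracks or di in used_dets:
                continue
            used_tracks.add(ti)
            used_dets.add(di)
            det = dets[di]
            track = open_tracks[ti]
            track["frames"].append(f)
            track["x"].append(float(det.x))
            track["y"].append(float(det.y))
            track["q"].append(float(det.quality))
        # unmatched open tracks terminate; unmatched detections start tracks
        still_open = []
        for ti, track in enumerate(open_tracks):
            (still_open if ti in used_tracks else done).append(track)
        for di, det in enumerate(dets):
            if di not in used_dets:
                still_open.append(new_track(det))
        open_tracks = still_open
    done.extend(open_tracks)
    done.sort(key=lambda t: t["id"])
    return [
        Trajectory(
            track_id=t["id"],
            frames=tuple(t["frames"]),
            x=tuple(t["x"]),
            y=tuple(t["y"]),
            quality=tuple(t["q"]),
        )
        for t in done
    ]


def filter_tracks(
    tracks: Sequence[Trajectory],
    min_mean_quality: float = 100.0,
    min_occurrences: int = 10,
    roi: tuple[float, float, float, float] | None = None,
) -> list[Trajectory]:
    """Keep tracks with mean quality strictly above ``min_mean_quality``,
    at least ``min_occurrences`` points, and (if an ROI ``(x0, y0, width,
    height)`` is given) every point inside the half-open ROI rectangle."""
    kept: list[Trajectory] = []
    for track in tracks:
        if track.mean_quality <= min_mean_quality:
            continue
        if track.n_points < min_occurrences:
            continue
        if roi is not None:
            x0, y0, w, h = roi
            inside = all(
                x0 <= x < x0 + w and y0 <= y < y0 + h
                for x, y in zip(track.x, track.y)
            )
            if not inside:
                continue
        kept.append(track)
    return kept


def track_metrics(track: Trajectory) -> TrackMetrics:
    """Total distance (sum of step lengths) and movement range (diameter)."""
    xs = np.asarray(track.x, dtype=float)
    ys = np.asarray(track.y, dtype=float)
    if len(xs) == 1:
        total = diameter = 0.0
    else:
        steps = np.hypot(np.diff(xs), np.diff(ys))
        total = float(steps.sum())
        dx = xs[:, None] - xs[None, :]
        dy = ys[:, None] - ys[None, :]
        # diameter <= path length mathematically; clamp away float rounding
        # on perfectly straight tracks so the invariant holds exactly
        diameter = min(float(np.sqrt(dx * dx + dy * dy).max()), total)
    return TrackMetrics(
        track_id=track.track_id,
        n_points=track.n_points,
        mean_quality=track.mean_quality,
        total_distance=total,
        movement_range=diameter,
    )


def net_displacement(track: Trajectory) -> float:
    """First-to-last displacement (alternative range definition)."""
    return math.hypot(track.x[-1] - track.x[0], track.y[-1] - track.y[0])


def metrics_table(tracks: Sequence[Trajectory]) -> pd.DataFrame:
    rows = [track_metrics(t).__dict__ for t in tracks]
    return pd.DataFrame(
        rows,
        columns=[
            "track_id",
            "n_points",
            "mean_quality",
            "total_distance",
            "movement_range",
            "passed_filters",
        ],
    )


def transwell_normalize(
    bottom_area: Sequence[float], top_area_initial: float
) -> np.ndarray:
    """Bottom-chamber cell area normalized to the initial top-chamber area."""
    if top_area_initial <= 0:
        raise ValueError("top_area_initial must be > 0")
    return np.asarray(bottom_area, dtype=float) / float(top_area_initial)


def confluency_normalize(series: Sequence[float]) -> np.ndarray:
    """Confluency series normalized to its first time point."""
    arr = np.asarray(series, dtype=float)
    if arr.size == 0 or arr[0] <= 0:
        raise ValueError("first confluency value must be > 0")
    return arr / arr[0]
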