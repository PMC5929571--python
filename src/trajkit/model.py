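"""Lineage-forest data model for 3D+t cell-tracking data.

A tracking result is represented as a *lineage forest*: a set of tracks
(time-ordered cell observations at consecutive frames) connected by
parent -> daughter links created by cell divisions.  Merges are not
representable; the structure is a forest by construction.

Positions are stored in physical micrometres (voxel sizes are applied once
at import time).  Frames are 0-based integers; an optional calibration
(``time_origin`` in hours post fertilisation plus ``frame_interval`` in
seconds) maps frames to developmental time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "Detection",
    "Track",
    "LineageForest",
    "Box",
    "PolygonRegion",
    "crop_time",
    "crop_space",
    "filter_by_span",
    "merge_tracks",
    "split_track",
]


@dataclass(frozen=True)
class Detection:
    """A single cell observation.

    Attributes
    ----------
    detection_id : int
        Globally unique identifier.
    track_id : int
        Track the observation belongs to.
    frame : int
        0-based time index.
    position : np.ndarray
        ``(x, y, z)`` in micrometres.
    intensity : float or None
        Mean fluorescence intensity (arbitrary units); ``None`` when the
        source data carries no intensity.
    synthetic : bool
        True for detections created by gap interpolation rather than
        observed in the images.
    """

    detection_id: int
    track_id: int
    frame: int
    position: np.ndarray
    intensity: float | None = None
    synthetic: bool = False


class Track:
    """A time-ordered run of detections at consecutive frames.

    Internally stored as dense per-track arrays (positions ``(n, 3)``,
    optional intensities ``(n,)``) for speed; :meth:`detections` exposes
    the per-observation view.
    """

    __slots__ = (
        "track_id",
        "start_frame",
        "positions",
        "intensities",
        "detection_ids",
        "synthetic",
        "parent_id",
        "child_ids",
    )

    def __init__(
        self,
        track_id: int,
        start_frame: int,
        positions: np.ndarray,
        detection_ids: np.ndarray,
        intensities: np.ndarray | None = None,
        synthetic: np.ndarray | None = None,
        parent_id: int | None = None,
        child_ids: set[int] | None = None,
    ):
        positions = np.asarray(positions, dtype=float)
        if positions.ndim != 2 or positions.shape[1] != 3:
            raise ValueError("positions must have shape (n, 3)")
        if not np.all(np.isfinite(positions)):
            raise ValueError(f"track {track_id}: non-finite position")
        n = len(positions)
        self.track_id = int(track_id)
        self.start_frame = int(start_frame)
        self.positions = positions
        self.detection_ids = np.asarray(detection_ids, dtype=np.int64)
        if len(self.detection_ids) != n:
            raise ValueError("detection_ids length mismatch")
        if intensities is not None:
            intensities = np.asarray(intensities, dtype=float)
            if len(intensities) != n:
                raise ValueError("intensities length mismatch")
        self.intensities = intensities
        if synthetic is None:
            synthetic = np.zeros(n, dtype=bool)
        self.synthetic = np.asarray(synthetic, dtype=bool)
        self.parent_id = parent_id
        self.child_ids = set(child_ids) if child_ids else set()

    # -- basic queries -------------------------------------------------
    @property
    def n_frames(self) -> int:
        return len(self.positions)

    @property
    def last_frame(self) -> int:
        return self.start_frame + self.n_frames - 1

    @property
    def frames(self) -> np.ndarray:
        return np.arange(self.start_frame, self.start_frame + self.n_frames)

    @property
    def start_position(self) -> np.ndarray:
        return self.positions[0]

    @property
    def end_position(self) -> np.ndarray:
        return self.positions[-1]

    def position_at(self, frame: int) -> np.ndarray:
        i = frame - self.start_frame
        if not 0 <= i < self.n_frames:
            raise KeyError(f"track {self.track_id} has no frame {frame}")
        return self.positions[i]

    def has_frame(self, frame: int) -> bool:
        return self.start_frame <= frame <= self.last_frame

    def detections(self) -> Iterator[Detection]:
        for i in range(self.n_frames):
            yield Detection(
                detection_id=int(self.detection_ids[i]),
                track_id=self.track_id,
                frame=self.start_frame + i,
                position=self.positions[i],
                intensity=None if self.intensities is None else float(self.intensities[i]),
                synthetic=bool(self.synthetic[i]),
            )

    def copy(self) -> "Track":
        return Track(
            self.track_id,
            self.start_frame,
            self.positions.copy(),
            self.detection_ids.copy(),
            None if self.intensities is None else self.intensities.copy(),
            self.synthetic.copy(),
            self.parent_id,
            set(self.child_ids),
        )

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return (
            f"Track({self.track_id}, frames {self.start_frame}..{self.last_frame}, "
            f"parent={self.parent_id}, children={sorted(self.child_ids)})"
        )


class LineageForest:
    """All tracks of a data set plus time/space calibration.

    Parameters
    ----------
    tracks : iterable of Track
    frame_interval : float, optional
        Seconds per frame.
    time_origin : float, optional
        Developmental time (hours post fertilisation) of frame 0.
    voxel_size : sequence of 3 floats
        Micrometres per voxel used at import (kept for provenance).
    """

    def __init__(
        self,
        tracks: Iterable[Track] = (),
        frame_interval: float | None = None,
        time_origin: float | None = None,
        voxel_size: Sequence[float] = (1.0, 1.0, 1.0),
    ):
        self.tracks: dict[int, Track] = {}
        for tr in tracks:
            if tr.track_id in self.tracks:
                raise ValueError(f"duplicate track id {tr.track_id}")
            self.tracks[tr.track_id] = tr
        self.frame_interval = frame_interval
        self.time_origin = time_origin
        self.voxel_size = tuple(float(v) for v in voxel_size)
        self.log: list[str] = []
        self.severed_links: list[tuple[int, int]] = []

    # -- counts and extents --------------------------------------------
    @property
    def n_tracks(self) -> int:
        return len(self.tracks)

    @property
    def n_detections(self) -> int:
        return sum(tr.n_frames for tr in self.tracks.values())

    @property
    def n_divisions(self) -> int:
        return sum(1 for tr in self.tracks.values() if len(tr.child_ids) >= 2)

    def frame_range(self) -> tuple[int, int]:
        """(first, last) frame over all tracks; raises on an empty forest."""
        if not self.tracks:
            raise ValueError("empty forest has no frame range")
        first = min(tr.start_frame for tr in self.tracks.values())
        last = max(tr.last_frame for tr in self.tracks.values())
        return first, last

    def n_interval_frames(self) -> int:
        first, last = self.frame_range()
        return last - first + 1

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Axis-aligned spatial bounding box (lo, hi) in micrometres."""
        if not self.tracks:
            raise ValueError("empty forest has no bounds")
        los = np.min([tr.positions.min(axis=0) for tr in self.tracks.values()], axis=0)
        his = np.max([tr.positions.max(axis=0) for tr in self.tracks.values()], axis=0)
        return los, his

    # -- time calibration ----------------------------------------------
    def has_time_mapping(self) -> bool:
        return self.frame_interval is not None and self.time_origin is not None

    def frame_to_hpf(self, frame: float) -> float:
        if not self.has_time_mapping():
            raise ValueError(
                "no time calibration: set frame_interval (s) and time_origin (hpf)"
            )
        return self.time_origin + frame * self.frame_interval / 3600.0

    def hpf_to_frame(self, hpf: float) -> float:
        if not self.has_time_mapping():
            raise ValueError(
                "no time calibration: set frame_interval (s) and time_origin (hpf)"
            )
        return (hpf - self.time_origin) * 3600.0 / self.frame_interval

    # -- bookkeeping ---------------------------------------------------
    def next_track_id(self) -> int:
        return max(self.tracks, default=0) + 1

    def next_detection_id(self) -> int:
        m = 0
        for tr in self.tracks.values():
            if tr.n_frames:
                m = max(m, int(tr.detection_ids.max()))
        return m + 1

    def copy(self) -> "LineageForest":
        out = LineageForest(
            (tr.copy() for tr in self.tracks.values()),
            self.frame_interval,
            self.time_origin,
            self.voxel_size,
        )
        out.log = list(self.log)
        out.severed_links = list(self.severed_links)
        return out

    def to_dataframe(self):
        """Long-format view: one row per detection (native CSV schema)."""
        import pandas as pd

        rows = []
        for tid in sorted(self.tracks):
            tr = self.tracks[tid]
            n = tr.n_frames
            rows.append(
                pd.DataFrame(
                    {
                        "detection_id": tr.detection_ids,
                        "track_id": tid,
                        "frame": tr.frames,
                        "x": tr.positions[:, 0],
                        "y": tr.positions[:, 1],
                        "z": tr.positions[:, 2],
                        "intensity": (
                            np.full(n, np.nan) if tr.intensities is None else tr.intensities
                        ),
                        "parent_track_id": (
                            -1 if tr.parent_id is None else tr.parent_id
                        ),
                        "synthetic": tr.synthetic.astype(int),
                    }
                )
            )
        if not rows:
            return pd.DataFrame(
                columns=[
                    "detection_id",
                    "track_id",
                    "frame",
                    "x",
                    "y",
                    "z",
                    "intensity",
                    "parent_track_id",
                    "synthetic",
                ]
            )
        return pd.concat(rows, ignore_index=True)

    def validate(self) -> None:
        """Assert structural invariants; raise ValueError on violation."""
        seen_det: set[int] = set()
        for tid, tr in self.tracks.items():
            if tr.track_id != tid:
                raise ValueError(f"track key {tid} != track_id {tr.track_id}")
            if tr.n_frames == 0:
                raise ValueError(f"track {tid} is empty")
            ids = set(int(i) for i in tr.detection_ids)
            if len(ids) != tr.n_frames:
                raise ValueError(f"track {tid}: duplicate detection ids")
            if ids & seen_det:
                raise ValueError(f"track {tid}: detection ids reused across tracks")
            seen_det |= ids
            if tr.parent_id is not None:
                parent = self.tracks.get(tr.parent_id)
                if parent is None:
                    raise ValueError(f"track {tid}: dangling parent {tr.parent_id}")
                if tid not in parent.child_ids:
                    raise ValueError(f"track {tid}: parent {tr.parent_id} does not list it")
                if tr.start_frame != parent.last_frame + 1:
                    raise ValueError(
                        f"track {tid}: starts at {tr.start_frame}, parent "
                        f"{tr.parent_id} ends at {parent.last_frame}"
                    )
            for cid in tr.child_ids:
                child = self.tracks.get(cid)
                if child is None:
                    raise ValueError(f"track {tid}: dangling child {cid}")
                if child.parent_id != tid:
                    raise ValueError(f"track {tid}: child {cid} disagrees on parent")

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return (
            f"LineageForest({self.n_tracks} tracks, {self.n_detections} detections, "
            f"{self.n_divisions} divisions)"
        )


# ---------------------------------------------------------------------------
# Spatial regions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Box:
    """Axis-aligned box in micrometres; either corner may be +-inf."""

    lo: tuple[float, float, float]
    hi: tuple[float, float, float]

    def __post_init__(self):
        lo = np.asarray(self.lo, float)
        hi = np.asarray(self.hi, float)
        if np.any(hi <= lo):
            raise ValueError("degenerate box: hi must exceed lo on every axis")

    def contains(self, positions: np.ndarray) -> np.ndarray:
        lo = np.asarray(self.lo, float)
        hi = np.asarray(self.hi, float)
        p = np.atleast_2d(positions)
        return np.all((p >= lo) & (p <= hi), axis=1)

    def to_dict(self) -> dict:
        return {"kind": "box", "lo": list(self.lo), "hi": list(self.hi)}


@dataclass(frozen=True)
class PolygonRegion:
    """2D polygon applied to positions projected along one axis.

    ``axis`` names the projection axis (``"x"``, ``"y"`` or ``"z"``); the
    polygon lives in the plane of the two remaining axes, in their natural
    order (project along z -> polygon over (x, y)).
    """

    vertices: tuple[tuple[float, float], ...]
    axis: str = "z"

    def __post_init__(self):
        if len(self.vertices) < 3:
            raise ValueError("polygon needs at least 3 vertices")
        if self.axis not in ("x", "y", "z"):
            raise ValueError("axis must be one of x, y, z")

    def _plane_axes(self) -> tuple[int, int]:
        keep = [i for i, a in enumerate("xyz") if a != self.axis]
        return keep[0], keep[1]

    def contains(self, positions: np.ndarray) -> np.ndarray:
        from shapely import Point, Polygon

        poly = Polygon(self.vertices)
        i, j = self._plane_axes()
        p = np.atleast_2d(positions)
        # covers() includes the boundary, matching the closed-interval
        # convention used by feature intervals
        return np.array([poly.covers(Point(q[i], q[j])) for q in p], dtype=bool)

    def to_dict(self) -> dict:
        return {
            "kind": "polygon",
            "vertices": [list(v) for v in self.vertices],
            "axis": self.axis,
        }


def region_from_dict(d: dict) -> Box | PolygonRegion:
    if d["kind"] == "box":
        return Box(tuple(d["lo"]), tuple(d["hi"]))
    if d["kind"] == "polygon":
        return PolygonRegion(tuple(tuple(v) for v in d["vertices"]), d["axis"])
    raise ValueError(f"unknown region kind {d['kind']!r}")


# ---------------------------------------------------------------------------
# Structural operations (all pure: the input forest is never modified)
# ---------------------------------------------------------------------------


def crop_time(
    forest: LineageForest,
    t_start: float,
    t_end: float,
    unit: str = "frame",
) -> LineageForest:
    """Restrict the forest to a time window.

    ``unit="frame"`` interprets the bounds as 0-based frame indices,
    ``unit="hpf"`` as hours post fertilisation (requires the forest's time
    calibration).  Detections outside the window are removed, tracks
    emptied by the crop are deleted, and division links crossing the cut
    are severed and recorded in ``result.severed_links``.
    """
    if t_start > t_end:
        raise ValueError(f"t_start {t_start} > t_end {t_end}")
    if unit == "hpf":
        f_start = int(np.ceil(forest.hpf_to_frame(t_start) - 1e-9))
        f_end = int(np.floor(forest.hpf_to_frame(t_end) + 1e-9))
    elif unit == "frame":
        f_start, f_end = int(t_start), int(t_end)
    else:
        raise ValueError(f"unknown unit {unit!r}")

    out = LineageForest((), forest.frame_interval, forest.time_origin, forest.voxel_size)
    for tid in sorted(forest.tracks):
        tr = forest.tracks[tid]
        lo = max(tr.start_frame, f_start)
        hi = min(tr.last_frame, f_end)
        if lo > hi:
            continue
        i0 = lo - tr.start_frame
        i1 = hi - tr.start_frame + 1
        out.tracks[tid] = Track(
            tid,
            lo,
            tr.positions[i0:i1].copy(),
            tr.detection_ids[i0:i1].copy(),
            None if tr.intensities is None else tr.intensities[i0:i1].copy(),
            tr.synthetic[i0:i1].copy(),
            tr.parent_id,
            set(tr.child_ids),
        )
    _prune_links(out, forest, reason=f"time crop [{t_start}, {t_end}] ({unit})")
    return out


def _prune_links(out: LineageForest, source: LineageForest, reason: str) -> None:
    """Drop parent/child references that are no longer valid after a crop."""
    # pass 1: sever from the child side (parent gone, or frames no longer abut)
    for tid, tr in out.tracks.items():
        if tr.parent_id is None:
            continue
        parent = out.tracks.get(tr.parent_id)
        if parent is None or tr.start_frame != parent.last_frame + 1:
            out.severed_links.append((tr.parent_id, tid))
            out.log.append(f"severed parent link {tr.parent_id} -> {tid} ({reason})")
            tr.parent_id = None
    # pass 2: mirror on the parent side (incl. children deleted outright)
    for tid, tr in out.tracks.items():
        stale = {
            c
            for c in tr.child_ids
            if c not in out.tracks or out.tracks[c].parent_id != tid
        }
        for c in sorted(stale):
            if c not in out.tracks:
                out.severed_links.append((tid, c))
                out.log.append(f"severed child link {tid} -> {c} ({reason})")
        tr.child_ids -= stale


def crop_space(
    forest: LineageForest,
    region: Box | PolygonRegion,
    mode: str = "any-frame-inside",
) -> LineageForest:
    """Keep tracks intersecting (or contained in) a spatial region.

    ``"any-frame-inside"`` keeps a track whole if at least one detection
    falls in the region (the convention used when carving out an
    anatomical region such as the blastoderm margin, where complete tracks
    of the region's cells are wanted).  ``"all-frames-inside"`` keeps only
    tracks entirely inside.
    """
    if mode not in ("any-frame-inside", "all-frames-inside"):
        raise ValueError(f"unknown mode {mode!r}")
    out = LineageForest((), forest.frame_interval, forest.time_origin, forest.voxel_size)
    for tid in sorted(forest.tracks):
        tr = forest.tracks[tid]
        inside = region.contains(tr.positions)
        keep = inside.any() if mode == "any-frame-inside" else inside.all()
        if keep:
            out.tracks[tid] = tr.copy()
    _prune_links(out, forest, reason=f"spatial crop ({mode})")
    if not out.tracks:
        out.log.append("spatial crop produced an empty forest")
    return out


def filter_by_span(
    forest: LineageForest, min_fraction: float
) -> tuple[LineageForest, LineageForest]:
    """Split tracks into (kept, short) by temporal coverage.

    A track is kept iff its frame count is at least
    ``ceil(min_fraction * L)`` where ``L`` is the forest's current
    interval length in frames.  The complement is returned as a second
    forest so that short tracks can later be assigned by label
    propagation.
    """
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    total = forest.n_interval_frames()
    need = int(np.ceil(min_fraction * total - 1e-9))
    kept_ids = {tid for tid, tr in forest.tracks.items() if tr.n_frames >= need}
    kept = LineageForest((), forest.frame_interval, forest.time_origin, forest.voxel_size)
    short = LineageForest((), forest.frame_interval, forest.time_origin, forest.voxel_size)
    for tid in sorted(forest.tracks):
        (kept if tid in kept_ids else short).tracks[tid] = forest.tracks[tid].copy()
    _prune_links(kept, forest, reason=f"span filter >= {min_fraction}")
    _prune_links(short, forest, reason=f"span filter < {min_fraction}")
    return kept, short


def merge_tracks(
    forest: LineageForest, upstream_id: int, downstream_id: int
) -> LineageForest:
    """Join two track fragments into one track (gap closing).

    The downstream fragment must start after the upstream fragment ends
    and must not already have a parent.  Any gap frames are bridged by
    linear interpolation of position (and intensity, when both ends carry
    one); bridged detections are flagged synthetic.  The merged track
    keeps the upstream id; the downstream's children are re-parented.
    """
    if upstream_id not in forest.tracks:
        raise KeyError(f"unknown track {upstream_id}")
    if downstream_id not in forest.tracks:
        raise KeyError(f"unknown track {downstream_id}")
    up = forest.tracks[upstream_id]
    down = forest.tracks[downstream_id]
    if down.parent_id is not None:
        raise ValueError(
            f"track {downstream_id} already has parent {down.parent_id}"
        )
    if down.start_frame <= up.last_frame:
        overlap = range(down.start_frame, min(up.last_frame, down.last_frame) + 1)
        raise ValueError(
            f"temporal overlap merging {upstream_id} -> {downstream_id}: "
            f"frames {overlap.start}..{overlap.stop - 1} present in both"
        )
    if up.child_ids:
        raise ValueError(
            f"track {upstream_id} ends in a division (children {sorted(up.child_ids)})"
        )

    out = forest.copy()
    up = out.tracks[upstream_id]
    down = out.tracks.pop(downstream_id)

    n_gap = down.start_frame - up.last_frame - 1
    if n_gap > 0:
        w = np.arange(1, n_gap + 1, dtype=float) / (n_gap + 1)
        gap_pos = up.end_position + np.outer(w, down.start_position - up.end_position)
        gap_syn = np.ones(n_gap, dtype=bool)
        det0 = out.next_detection_id()
        gap_ids = np.arange(det0, det0 + n_gap, dtype=np.int64)
        if up.intensities is not None and down.intensities is not None:
            gap_int = up.intensities[-1] + w * (down.intensities[0] - up.intensities[-1])
        else:
            gap_int = None
    else:
        gap_pos = np.empty((0, 3))
        gap_syn = np.empty(0, dtype=bool)
        gap_ids = np.empty(0, dtype=np.int64)
        gap_int = np.empty(0) if (up.intensities is not None and down.intensities is not None) else None

    positions = np.vstack([up.positions, gap_pos, down.positions])
    det_ids = np.concatenate([up.detection_ids, gap_ids, down.detection_ids])
    synthetic = np.concatenate([up.synthetic, gap_syn, down.synthetic])
    if up.intensities is not None and down.intensities is not None:
        intens = np.concatenate(
            [up.intensities, np.empty(0) if gap_int is None else gap_int, down.intensities]
        )
    else:
        intens = None
        if (up.intensities is None) != (down.intensities is None):
            out.log.append(
                f"merge {upstream_id}+{downstream_id}: intensity present on only "
                "one fragment, dropped"
            )

    merged = Track(
        upstream_id,
        up.start_frame,
        positions,
        det_ids,
        intens,
        synthetic,
        up.parent_id,
        set(down.child_ids),
    )
    out.tracks[upstream_id] = merged
    for cid in merged.child_ids:
        out.tracks[cid].parent_id = upstream_id
    out.log.append(
        f"merged {downstream_id} into {upstream_id} ({n_gap} gap frames interpolated)"
    )
    return out


def split_track(
    forest: LineageForest, track_id: int, first_frame_of_right: int
) -> tuple[LineageForest, int]:
    """Cut one track into two fragments at a frame boundary.

    The left fragment keeps the original id, parent link and frames
    ``< first_frame_of_right``; the right fragment receives a fresh id,
    no parent, and inherits the original's children.  Returns the new
    forest and the right fragment's id.
    """
    tr = forest.tracks.get(track_id)
    if tr is None:
        raise KeyError(f"unknown track {track_id}")
    if not tr.start_frame < first_frame_of_right <= tr.last_frame:
        raise ValueError(
            f"split frame {first_frame_of_right} outside ({tr.start_frame}, "
            f"{tr.last_frame}] of track {track_id}"
        )
    out = forest.copy()
    tr = out.tracks[track_id]
    i = first_frame_of_right - tr.start_frame
    new_id = out.next_track_id()
    right = Track(
        new_id,
        first_frame_of_right,
        tr.positions[i:].copy(),
        tr.detection_ids[i:].copy(),
        None if tr.intensities is None else tr.intensities[i:].copy(),
        tr.synthetic[i:].copy(),
        None,
        set(tr.child_ids),
    )
    left = Track(
        track_id,
        tr.start_frame,
        tr.positions[:i].copy(),
        tr.detection_ids[:i].copy(),
        None if tr.intensities is None else tr.intensities[:i].copy(),
        tr.synthetic[:i].copy(),
        tr.parent_id,
        set(),
    )
    out.tracks[track_id] = left
    out.tracks[new_id] = right
    for cid in right.child_ids:
        out.tracks[cid].parent_id = new_id
    return out, new_id
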