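"""Per-track features, per-frame time series, smoothing and group aggregation.

Two kinds of quantities are computed from a lineage forest:

* *single features* — one scalar (or small vector) per track, e.g. path
  length, start-to-end displacement, or their ratio (near 1 for straight
  tracks, near 0 for U-shaped tracks that return to their origin);
* *time-series features* — one value per track per frame, e.g. speed,
  local cell density, or distance to a reference point.

Smoothing is explicit: callers that want features on denoised tracks pass
a forest returned by :func:`smooth_tracks`.  Nothing smooths implicitly.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .model import LineageForest, Track

__all__ = [
    "SINGLE_FEATURES",
    "TIMESERIES_FEATURES",
    "smooth_tracks",
    "single_features",
    "timeseries_features",
    "aggregate_group",
]


# ---------------------------------------------------------------------------
# Smoothing
# ---------------------------------------------------------------------------


def smooth_tracks(
    forest: LineageForest, order: int = 2, cutoff: float = 0.01
) -> LineageForest:
    """Zero-phase Butterworth low-pass filter on every coordinate series.

    ``cutoff`` is a normalized frequency (fraction of Nyquist).  The filter
    is applied forward and backward (``filtfilt``), so it is zero-phase and
    has unit DC gain: constant tracks pass unchanged.  Tracks shorter than
    the minimum stable filter length fall back to a centred moving average
    of window 3 with a notice in ``forest.log``.
    """
    from scipy import signal

    if order < 1:
        raise ValueError("order must be >= 1")
    if not 0 < cutoff < 1:
        raise ValueError("cutoff must be a normalized frequency in (0, 1)")
    b, a = signal.butter(order, cutoff)
    min_len = 3 * max(len(a), len(b))  # filtfilt's hard lower length bound
    out = forest.copy()
    for tid in sorted(out.tracks):
        tr = out.tracks[tid]
        if tr.n_frames > min_len + 1:
            # pad with the filter's settling length (~3 / cutoff samples)
            # where the track allows, to keep edge transients off the data
            padlen = min(tr.n_frames - 1, int(np.ceil(3.0 / cutoff)))
            tr.positions = signal.filtfilt(b, a, tr.positions, axis=0, padlen=padlen)
        else:
            tr.positions = _moving_average3(tr.positions)
            out.log.append(
                f"track {tid}: {tr.n_frames} frames too short for the Butterworth "
                "filter; centred moving average (window 3) applied instead"
            )
    return out


def _moving_average3(x: np.ndarray) -> np.ndarray:
    """Centred moving average, window 3; endpoints average the 2 available."""
    n = len(x)
    if n < 3:
        return x.copy()
    out = x.copy()
    out[1:-1] = (x[:-2] + x[1:-1] + x[2:]) / 3.0
    out[0] = (x[0] + x[1]) / 2.0
    out[-1] = (x[-2] + x[-1]) / 2.0
    return out


# ---------------------------------------------------------------------------
# Single features
# ---------------------------------------------------------------------------


def _steps(tr: Track) -> np.ndarray:
    return np.diff(tr.positions, axis=0)


def _path_length(tr: Track) -> float:
    if tr.n_frames < 2:
        return 0.0
    return float(np.linalg.norm(_steps(tr), axis=1).sum())


def _displacement(tr: Track) -> float:
    return float(np.linalg.norm(tr.end_position - tr.start_position))


def _displacement_ratio(tr: Track) -> float:
    # a stationary cell never deviates from the straight line between its
    # endpoints, so the degenerate zero-length path gets ratio 1
    L = _path_length(tr)
    if L == 0.0:
        return 1.0
    return _displacement(tr) / L


def _mean_speed(tr: Track) -> float:
    if tr.n_frames < 2:
        return 0.0
    return _path_length(tr) / (tr.n_frames - 1)


def _angle_changes(tr: Track) -> np.ndarray:
    """Angle between successive displacement vectors; zero-length steps -> 0."""
    steps = _steps(tr)
    if len(steps) < 2:
        return np.empty(0)
    a, b = steps[:-1], steps[1:]
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    ok = (na > 0) & (nb > 0)
    cosang = np.zeros(len(a))
    cosang[ok] = np.einsum("ij,ij->i", a[ok], b[ok]) / (na[ok] * nb[ok])
    ang = np.arccos(np.clip(cosang, -1.0, 1.0))
    ang[~ok] = 0.0
    return ang


def _mean_angle_change(tr: Track) -> float:
    ang = _angle_changes(tr)
    return float(ang.mean()) if len(ang) else 0.0


SINGLE_FEATURES: dict[str, Callable[[Track], float | np.ndarray]] = {
    "time_span": lambda tr: float(tr.n_frames),
    "path_length": _path_length,
    "displacement": _displacement,
    "displacement_ratio": _displacement_ratio,
    "centroid": lambda tr: tr.positions.mean(axis=0),
    "mean_speed": _mean_speed,
    "mean_angle_change": _mean_angle_change,
    "start_position": lambda tr: tr.start_position,
    "end_position": lambda tr: tr.end_position,
}

_VECTOR_FEATURES = {"centroid", "start_position", "end_position"}


def single_features(
    forest: LineageForest, features: Sequence[str] | None = None
) -> pd.DataFrame:
    """One row per track; vector features expand to ``name_x/_y/_z`` columns.

    Units: ``time_span`` frames, ``path_length``/``displacement`` um,
    ``displacement_ratio`` dimensionless in [0, 1], ``mean_speed``
    um/frame, ``mean_angle_change`` radians, positions um.
    """
    if features is None:
        features = list(SINGLE_FEATURES)
    unknown = [f for f in features if f not in SINGLE_FEATURES]
    if unknown:
        raise KeyError(
            f"unknown feature(s) {unknown}; available: {sorted(SINGLE_FEATURES)}"
        )
    rows = {}
    for tid in sorted(forest.tracks):
        tr = forest.tracks[tid]
        row = {}
        for name in features:
            val = SINGLE_FEATURES[name](tr)
            if name in _VECTOR_FEATURES:
                for ax, v in zip("xyz", val):
                    row[f"{name}_{ax}"] = float(v)
            else:
                row[name] = float(val)
        rows[tid] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "track_id"
    return df


# ---------------------------------------------------------------------------
# Time-series features
# ---------------------------------------------------------------------------


def _series_speed(forest: LineageForest, params: dict) -> pd.Series:
    from .deformation import estimate_velocity

    vel = estimate_velocity(forest)
    idx, vals = [], []
    for tid in sorted(forest.tracks):
        v = vel.get(tid)
        if v is None:
            continue
        for frame, speed in zip(forest.tracks[tid].frames, np.linalg.norm(v, axis=1)):
            idx.append((tid, int(frame)))
            vals.append(speed)
    return pd.Series(
        vals, index=pd.MultiIndex.from_tuples(idx, names=["track_id", "frame"])
    )


def _series_density(forest: LineageForest, params: dict) -> pd.Series:
    """Neighbour count within a fixed sphere (default 40 um), self excluded."""
    from scipy.spatial import cKDTree

    radius = float(params.get("radius", 40.0))
    by_frame: dict[int, list[tuple[int, np.ndarray]]] = {}
    for tid in sorted(forest.tracks):
        tr = forest.tracks[tid]
        for frame, p in zip(tr.frames, tr.positions):
            by_frame.setdefault(int(frame), []).append((tid, p))
    idx, vals = [], []
    for frame in sorted(by_frame):
        entries = by_frame[frame]
        pts = np.array([p for _, p in entries])
        tree = cKDTree(pts)
        counts = tree.query_ball_point(pts, r=radius, return_length=True) - 1
        for (tid, _), c in zip(entries, counts):
            idx.append((tid, frame))
            vals.append(float(c))
    s = pd.Series(
        vals, index=pd.MultiIndex.from_tuples(idx, names=["track_id", "frame"])
    )
    return s.sort_index()


def _series_angle_change(forest: LineageForest, params: dict) -> pd.Series:
    idx, vals = [], []
    for tid in sorted(forest.tracks):
        tr = forest.tracks[tid]
        ang = _angle_changes(tr)
        # angle at interior frames only (needs a step on both sides)
        for frame, a in zip(tr.frames[1:-1], ang):
            idx.append((tid, int(frame)))
            vals.append(float(a))
    return pd.Series(
        vals,
        index=pd.MultiIndex.from_tuples(idx, names=["track_id", "frame"]),
        dtype=float,
    )


def _series_distance_to_reference(forest: LineageForest, params: dict) -> pd.Series:
    ref = params.get("reference")
    if ref is None:
        raise ValueError("distance_to_reference requires params['reference'] = (x, y, z)")
    ref = np.asarray(ref, float)
    idx, vals = [], []
    for tid in sorted(forest.tracks):
        tr = forest.tracks[tid]
        d = np.linalg.norm(tr.positions - ref, axis=1)
        for frame, v in zip(tr.frames, d):
            idx.append((tid, int(frame)))
            vals.append(float(v))
    return pd.Series(
        vals, index=pd.MultiIndex.from_tuples(idx, names=["track_id", "frame"])
    )


TIMESERIES_FEATURES: dict[str, Callable[[LineageForest, dict], pd.Series]] = {
    "speed": _series_speed,
    "density": _series_density,
    "angle_change": _series_angle_change,
    "distance_to_reference": _series_distance_to_reference,
}


def timeseries_features(
    forest: LineageForest,
    features: Sequence[str],
    params: dict | None = None,
) -> pd.DataFrame:
    """Per-(track, frame) table, one column per requested series.

    Units: ``speed`` um/frame, ``density`` neighbour count, ``angle_change``
    radians, ``distance_to_reference`` um.  ``params`` may set ``radius``
    (density sphere, default 40 um) and ``reference`` (a point in um).
    """
    params = dict(params or {})
    unknown = [f for f in features if f not in TIMESERIES_FEATURES]
    if unknown:
        raise KeyError(
            f"unknown feature(s) {unknown}; available: {sorted(TIMESERIES_FEATURES)}"
        )
    cols = {name: TIMESERIES_FEATURES[name](forest, params) for name in features}
    df = pd.DataFrame(cols)
    df.index.names = ["track_id", "frame"]
    return df.sort_index()


# ---------------------------------------------------------------------------
# Group aggregation
# ---------------------------------------------------------------------------


def aggregate_group(
    series: pd.Series | pd.DataFrame,
    member_ids: set[int] | Sequence[int],
    statistic: str | float = "median",
) -> pd.DataFrame:
    """Per-frame group statistic of a time-series feature.

    ``statistic`` is ``"median"``, ``"mean"`` or a quantile in (0, 1)
    (linear interpolation between order statistics).  Returns a frame-
    indexed table with one ``value`` column per input series plus ``n``,
    the member count contributing at that frame; frames where no member
    exists are absent.
    """
    if isinstance(series, pd.Series):
        series = series.to_frame("value")
    members = set(int(m) for m in member_ids)
    unknown = members - set(series.index.get_level_values("track_id"))
    if unknown:
        raise KeyError(f"member ids not in series: {sorted(unknown)[:5]}")
    sub = series[series.index.get_level_values("track_id").isin(members)]
    g = sub.groupby(level="frame")
    if statistic == "median":
        agg = g.median()
    elif statistic == "mean":
        agg = g.mean()
    elif isinstance(statistic, float) and 0 < statistic < 1:
        agg = g.quantile(statistic)  # pandas 'linear' interpolation
    else:
        raise ValueError(
            f"statistic must be 'median', 'mean' or a quantile in (0,1); got {statistic!r}"
        )
    agg["n"] = g.size()
    return agg
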