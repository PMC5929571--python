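"""Local tissue-deformation analysis from cell velocities.

For every detection, the velocities of the cells inside a fixed-radius
neighbourhood are fitted by an affine field ``v = A (x - x_ref) + b``.
Three rotation/translation-invariant quantities of the velocity-gradient
tensor ``A`` summarise the local deformation:

* ``P = tr(A)`` — volume change rate (1/frame): positive where the tissue
  expands, negative where it compresses;
* ``D`` — the discriminant of the characteristic polynomial of the
  deviatoric tensor ``A' = A - (P/3) I``: positive exactly when ``A'``
  has a complex-conjugate eigenpair, i.e. the neighbourhood spirals
  around the reference cell (units 1/frame^6);
* ``Q_d`` — the Frobenius norm of the deviatoric symmetric part of ``A``
  (1/frame): the rate at which cells rearrange relative to each other
  while the enclosed volume stays constant (shear / intercalation).

These are the standard invariants of critical-point analysis of velocity
gradient fields, reconstructed here from their qualitative semantics
(``P`` sign = expansion/compression, ``D > 0`` = rotation, ``Q_d`` =
volume-preserving distortion); see docs/methods.md for the derivation
and its caveats.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .model import LineageForest

__all__ = [
    "VelocityField",
    "estimate_velocity",
    "fit_velocity_gradient",
    "deformation_invariants",
    "deformation_table",
]

CONDITION_LIMIT = 1e8  # scatter-matrix condition number above which a fit is invalid
MIN_NEIGHBORS = 4  # an affine field in 3D has 12 dof; 4 points is the floor


class VelocityField(dict):
    """track_id -> (n_frames, 3) velocity array in um/frame.

    Tracks too short for differencing (a single frame) are absent and
    listed in ``skipped``.
    """

    def __init__(self, *args, **kwargs):
        super().__init__(*args, **kwargs)
        self.skipped: list[int] = []


def estimate_velocity(forest: LineageForest) -> VelocityField:
    """Finite-difference velocities per track (um/frame).

    Central differences at interior frames, forward/backward differences
    at the track ends.  Single-frame tracks carry no velocity and are
    flagged in ``result.skipped``.
    """
    field = VelocityField()
    for tid in sorted(forest.tracks):
        tr = forest.tracks[tid]
        if tr.n_frames < 2:
            field.skipped.append(tid)
            continue
        field[tid] = np.gradient(tr.positions, axis=0)
    return field


def fit_velocity_gradient(
    positions: np.ndarray,
    velocities: np.ndarray,
    reference: Sequence[float],
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Least-squares affine fit ``v ~ A (x - x_ref) + b`` over a neighbourhood.

    Returns ``(A, b, valid)``.  The fit is invalid (and ``A``, ``b`` are
    NaN) when fewer than 4 points are given or the centred position
    scatter matrix is rank-deficient (condition number above 1e8), e.g.
    for coplanar neighbourhoods.
    """
    X = np.asarray(positions, float) - np.asarray(reference, float)
    V = np.asarray(velocities, float)
    n = len(X)
    if n < MIN_NEIGHBORS:
        return np.full((3, 3), np.nan), np.full(3, np.nan), False
    Xc = X - X.mean(axis=0)
    scatter = Xc.T @ Xc
    if np.linalg.cond(scatter) > CONDITION_LIMIT:
        return np.full((3, 3), np.nan), np.full(3, np.nan), False
    design = np.column_stack([X, np.ones(n)])
    beta, *_ = np.linalg.lstsq(design, V, rcond=None)
    A = beta[:3].T
    b = beta[3]
    return A, b, True


def deformation_invariants(A: np.ndarray) -> tuple[float, float, float]:
    """(P, D, Q_d) of a 3x3 velocity-gradient tensor.

    ``P = tr A``; on the deviatoric part ``A' = A - (P/3) I`` the
    characteristic polynomial is ``lambda^3 + Q lambda + R`` with
    ``Q = -tr(A'^2)/2`` and ``R = -det A'``, whose discriminant
    ``D = (27/4) R^2 + Q^3`` is positive iff ``A'`` has a complex
    eigenpair (local rotation).  ``Q_d = || sym(A) - (P/3) I ||_F``.
    """
    A = np.asarray(A, float)
    if A.shape != (3, 3) or not np.all(np.isfinite(A)):
        raise ValueError("A must be a finite 3x3 tensor")
    P = float(np.trace(A))
    dev = A - (P / 3.0) * np.eye(3)
    Q = -0.5 * float(np.trace(dev @ dev))
    R = -float(np.linalg.det(dev))
    D = (27.0 / 4.0) * R * R + Q * Q * Q
    sym_dev = 0.5 * (A + A.T) - (P / 3.0) * np.eye(3)
    Q_d = float(np.linalg.norm(sym_dev, "fro"))
    return P, D, Q_d


def deformation_table(
    forest: LineageForest,
    radius: float = 40.0,
    velocity: VelocityField | None = None,
) -> pd.DataFrame:
    """Per-detection speed and deformation invariants.

    For each detection, the neighbourhood is every same-frame detection
    within ``radius`` micrometres (including the reference cell).  Rows
    where the local fit is under-determined carry ``valid = False`` and
    NaN invariants — they are flagged rather than zero-filled so that
    group medians are not biased.  Callers wanting the denoised variant
    smooth the forest first (smoothing is never implicit).

    Columns: ``speed`` (um/frame), ``P`` (1/frame), ``D`` (1/frame^6),
    ``Q_d`` (1/frame), ``n_neighbors``, ``valid``; index (track_id, frame).
    """
    from scipy.spatial import cKDTree

    if velocity is None:
        velocity = estimate_velocity(forest)

    by_frame: dict[int, list[tuple[int, np.ndarray, np.ndarray]]] = {}
    for tid in sorted(forest.tracks):
        v = velocity.get(tid)
        if v is None:
            continue
        tr = forest.tracks[tid]
        for i, frame in enumerate(tr.frames):
            by_frame.setdefault(int(frame), []).append((tid, tr.positions[i], v[i]))

    idx, rows = [], []
    for frame in sorted(by_frame):
        entries = by_frame[frame]
        pts = np.array([p for _, p, _ in entries])
        vels = np.array([v for _, _, v in entries])
        tree = cKDTree(pts)
        neighbor_lists = tree.query_ball_point(pts, r=radius)
        for (tid, p, v), nbrs in zip(entries, neighbor_lists):
            A, b, valid = fit_velocity_gradient(pts[nbrs], vels[nbrs], p)
            if valid:
                P, D, Q_d = deformation_invariants(A)
            else:
                P = D = Q_d = np.nan
            idx.append((tid, frame))
            rows.append(
                (float(np.linalg.norm(v)), P, D, Q_d, len(nbrs), valid)
            )
    df = pd.DataFrame(
        rows,
        index=pd.MultiIndex.from_tuples(idx, names=["track_id", "frame"]),
        columns=["speed", "P", "D", "Q_d", "n_neighbors", "valid"],
    )
    return df.sort_index()
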