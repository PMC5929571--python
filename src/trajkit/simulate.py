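"""Synthetic tracking data with known ground truth.

Three generators provide the test substrate for the whole toolkit:

* :func:`simulate_embryo` — a kinematic two-population gastrula: cells on
  a spherical shell, one population ("epiblast") spreading monotonically
  toward the vegetal pole, the other ("hypoblast") drifting to a margin
  latitude, stepping inward, and reversing toward the animal pole.  The
  reversal makes hypoblast tracks U-shaped: their start-to-end
  displacement is far below their integrated path length, which is the
  signature feature-based dissection exploits.  Divisions, positional
  noise and per-track intensities are included; everything is
  deterministic under the seed.
* :func:`sample_field` — a point cloud advected by a prescribed affine
  velocity field (expansion/rotation/shear/translation), the analytic
  oracle substrate for the deformation invariants.
* :func:`fragment_tracks` — a corruptor that splits tracks at random
  interior frames, recording the true fragment pairs for evaluating gap
  closing.

The motion model is kinematic, not mechanistic: it reproduces the
geometric signatures the analysis pipelines rely on, nothing more.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model import LineageForest, Track, split_track

__all__ = [
    "EmbryoSimConfig",
    "GroundTruth",
    "simulate_embryo",
    "sample_field",
    "fragment_tracks",
    "expansion",
    "rotation",
    "shear",
    "translation",
]


@dataclass
class EmbryoSimConfig:
    """Study conditions for the synthetic gastrula.

    Defaults describe a desk-scale embryo: 2 x 300 cells followed for 90
    frames at 90 s/frame starting at 5 hpf (so the movie spans the
    5-7.25 hpf gastrulation window), on a 150 um shell, moving at
    1.5 um/frame (= 1 um/min).  Hypoblast cells reach the margin latitude
    at an individual turn time drawn from the middle of the movie, step
    20 um inward over 15 frames, then reverse.  See docs/methods.md for
    the reasoning behind each value.
    """

    n_cells: int = 300  # per population
    n_frames: int = 90
    radius: float = 150.0  # shell radius, um
    margin_latitude: float = 1.2  # polar angle of the germ-ring margin, rad
    epiboly_speed: float = 1.5  # tangential speed, um/frame
    involution_offset: float = 20.0  # inward radial step of the hypoblast, um
    involution_frames: int = 15  # frames over which the inward step happens
    turn_window: tuple[float, float] = (0.35, 0.58)  # turn time, fraction of movie
    epiblast_band: tuple[float, float] = (0.20, 0.65)  # start latitudes, rad
    noise_sigma: float = 1.0  # isotropic positional noise, um
    division_rate: float = 5e-4  # per cell per frame
    daughter_offset: float = 8.0  # tangential separation of daughters, um
    intensity_mean: float = 500.0  # a.u.
    intensity_track_sigma: float = 50.0  # per-track offset, a.u.
    intensity_frame_sigma: float = 10.0  # per-frame jitter, a.u.
    frame_interval: float = 90.0  # seconds per frame
    time_origin: float = 5.0  # hpf of frame 0
    seed: int = 0

    def __post_init__(self):
        if self.n_frames < 3:
            raise ValueError("n_frames must be >= 3")
        for name in ("epiboly_speed", "involution_offset", "noise_sigma", "division_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class GroundTruth:
    """What the generator knows: per-track population labels, the true
    lineage links, and (after corruption) the true fragment-join pairs."""

    labels: dict[int, str] = field(default_factory=dict)
    lineage_links: list[tuple[int, int]] = field(default_factory=list)
    joins: list[tuple[int, int]] = field(default_factory=list)


class _Agent:
    __slots__ = ("population", "theta", "phi", "r", "turn_frame", "phase", "intensity_mean")

    def __init__(self, population, theta, phi, r, turn_frame, intensity_mean):
        self.population = population
        self.theta = theta
        self.phi = phi
        self.r = r
        self.turn_frame = turn_frame
        self.phase = "down"
        self.intensity_mean = intensity_mean


def _shell_position(r: float, theta: float, phi: float) -> np.ndarray:
    return r * np.array(
        [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)]
    )


def simulate_embryo(config: EmbryoSimConfig) -> tuple[LineageForest, GroundTruth]:
    """Generate the two-population gastrula with known labels."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    omega = cfg.epiboly_speed / cfg.radius  # angular speed on the outer shell
    radial_step = (
        cfg.involution_offset / cfg.involution_frames if cfg.involution_frames else 0.0
    )

    agents: dict[int, _Agent] = {}
    next_tid = 1
    truth = GroundTruth()
    # per live track: accumulating buffers
    buffers: dict[int, dict] = {}
    parent_of: dict[int, int | None] = {}

    def _spawn(agent: _Agent, start_frame: int, parent: int | None) -> int:
        nonlocal next_tid
        tid = next_tid
        next_tid += 1
        agents[tid] = agent
        buffers[tid] = {"start": start_frame, "pos": [], "int": []}
        parent_of[tid] = parent
        truth.labels[tid] = agent.population
        if parent is not None:
            truth.lineage_links.append((parent, tid))
        return tid

    # initial populations
    for _ in range(cfg.n_cells):  # epiblast: spreading cap above the margin
        theta0 = rng.uniform(*cfg.epiblast_band)
        phi0 = rng.uniform(0.0, 2 * np.pi)
        _spawn(
            _Agent(
                "epiblast", theta0, phi0, cfg.radius, None,
                cfg.intensity_mean + rng.normal(0, cfg.intensity_track_sigma),
            ),
            0,
            None,
        )
    for _ in range(cfg.n_cells):  # hypoblast: margin-bound band, staggered turns
        turn = int(round(rng.uniform(*cfg.turn_window) * cfg.n_frames))
        theta0 = cfg.margin_latitude - omega * turn
        phi0 = rng.uniform(0.0, 2 * np.pi)
        _spawn(
            _Agent(
                "hypoblast", theta0, phi0, cfg.radius, turn,
                cfg.intensity_mean + rng.normal(0, cfg.intensity_track_sigma),
            ),
            0,
            None,
        )

    def _step(agent: _Agent, frame: int) -> None:
        if agent.population == "epiblast":
            agent.theta += omega
            return
        if frame < agent.turn_frame:
            agent.theta += omega
        elif frame < agent.turn_frame + cfg.involution_frames:
            agent.r -= radial_step  # inward step at the margin
        else:
            agent.theta -= cfg.epiboly_speed / agent.r  # back toward the animal pole

    for frame in range(cfg.n_frames):
        for tid in sorted(list(agents)):
            agent = agents[tid]
            if buffers[tid]["pos"]:  # not the track's first frame: advance first
                _step(agent, frame)
            p = _shell_position(agent.r, agent.theta, agent.phi)
            if cfg.noise_sigma > 0:
                p = p + rng.normal(0.0, cfg.noise_sigma, 3)
            buffers[tid]["pos"].append(p)
            buffers[tid]["int"].append(
                agent.intensity_mean + rng.normal(0.0, cfg.intensity_frame_sigma)
            )
            # division: close this track, spawn two daughters next frame
            if (
                frame < cfg.n_frames - 2
                and len(buffers[tid]["pos"]) >= 2
                and rng.random() < cfg.division_rate
            ):
                dphi = cfg.daughter_offset / (2 * agent.r * max(np.sin(agent.theta), 1e-3))
                for sign in (+1.0, -1.0):
                    child = _Agent(
                        agent.population,
                        agent.theta,
                        agent.phi + sign * dphi,
                        agent.r,
                        agent.turn_frame,
                        agent.intensity_mean + rng.normal(0, cfg.intensity_frame_sigma),
                    )
                    child.phase = agent.phase
                    ctid = _spawn(child, frame + 1, tid)
                    # daughters continue the mother's programme
                del agents[tid]

    tracks = []
    for tid, buf in buffers.items():
        n = len(buf["pos"])
        tracks.append(
            Track(
                tid,
                buf["start"],
                np.asarray(buf["pos"]),
                np.zeros(n, np.int64),  # detection ids assigned below
                np.asarray(buf["int"]),
                parent_id=parent_of[tid],
            )
        )
    det = 1
    for tr in sorted(tracks, key=lambda t: t.track_id):
        tr.detection_ids = np.arange(det, det + tr.n_frames, dtype=np.int64)
        det += tr.n_frames
    forest = LineageForest(
        sorted(tracks, key=lambda t: t.track_id),
        frame_interval=cfg.frame_interval,
        time_origin=cfg.time_origin,
    )
    for parent, child in truth.lineage_links:
        forest.tracks[parent].child_ids.add(child)
    forest.validate()
    return forest, truth


# ---------------------------------------------------------------------------
# Analytic velocity fields
# ---------------------------------------------------------------------------


def expansion(k: float) -> tuple[np.ndarray, np.ndarray]:
    """Isotropic expansion (k > 0) or compression (k < 0), 1/frame."""
    return k * np.eye(3), np.zeros(3)


def rotation(omega: float, axis: str = "z") -> tuple[np.ndarray, np.ndarray]:
    """Rigid rotation at ``omega`` rad/frame about a coordinate axis."""
    A = np.zeros((3, 3))
    i, j = {"z": (0, 1), "y": (2, 0), "x": (1, 2)}[axis]
    A[i, j] = -omega
    A[j, i] = omega
    return A, np.zeros(3)


def shear(gamma: float, plane: str = "xy") -> tuple[np.ndarray, np.ndarray]:
    """Pure (volume-preserving, irrotational) shear in a coordinate plane."""
    A = np.zeros((3, 3))
    i, j = {"xy": (0, 1), "yz": (1, 2), "xz": (0, 2)}[plane]
    A[i, j] = gamma
    A[j, i] = gamma
    return A, np.zeros(3)


def translation(v: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Rigid translation at constant velocity ``v`` um/frame."""
    return np.zeros((3, 3)), np.asarray(v, float)


def sample_field(
    field_spec: tuple[np.ndarray, np.ndarray] | Sequence[tuple[np.ndarray, np.ndarray]],
    n_points: int = 60,
    n_frames: int = 11,
    noise_sigma: float = 0.0,
    seed: int = 0,
    extent: float = 50.0,
) -> tuple[LineageForest, np.ndarray, np.ndarray]:
    """Point cloud advected by the affine velocity field ``v = A x + b``.

    ``field_spec`` is one ``(A, b)`` pair (e.g. from :func:`expansion`)
    or a list of pairs that are summed.  Initial positions are uniform in
    the cube ``[-extent, extent]^3``.

    The sequence is built so that the *central difference* of positions
    at every interior frame equals ``A x_t + b`` exactly (three-term
    recurrence ``x_{t+1} = x_{t-1} + 2 (A x_t + b)`` started on its
    decaying characteristic branch).  Downstream, the velocity estimator
    followed by the affine fit therefore recovers ``A`` to machine
    precision at interior frames — the point of this oracle substrate.
    Returns ``(forest, A, b)`` with the ground-truth field.
    """
    from scipy.linalg import sqrtm

    if isinstance(field_spec, tuple) and isinstance(field_spec[0], np.ndarray):
        parts = [field_spec]
    else:
        parts = list(field_spec)
    A = np.sum([np.asarray(p[0], float) for p in parts], axis=0)
    b = np.sum([np.asarray(p[1], float) for p in parts], axis=0)

    rng = np.random.default_rng(seed)
    x0 = rng.uniform(-extent, extent, size=(n_points, 3))

    if np.allclose(A, 0.0):
        t = np.arange(n_frames)
        positions = x0[:, None, :] + t[None, :, None] * b[None, None, :]
    else:
        # particular solution for the affine part: either x = y + b t
        # (when A b = 0) or x = y + x* with A x* = -b
        shift = np.zeros(3)
        drift = np.zeros(3)
        if np.any(b != 0):
            if np.allclose(A @ b, 0.0):
                drift = b
            else:
                shift = -np.linalg.pinv(A) @ b
                if not np.allclose(A @ shift, -b, atol=1e-9):
                    raise ValueError(
                        "unsupported field: b neither in ker(A) nor in range(A)"
                    )
        # homogeneous part on the physical branch lambda = A + sqrt(A^2 + I)
        # (the spurious branch of the recurrence gets zero weight)
        lam = np.real(np.asarray(sqrtm(A @ A + np.eye(3)))) + A
        y = np.empty((n_points, n_frames, 3))
        y[:, 0] = x0 - shift
        y[:, 1] = y[:, 0] @ lam.T
        for t in range(2, n_frames):
            y[:, t] = y[:, t - 2] + 2.0 * (y[:, t - 1] @ A.T)
        positions = (
            y + shift + np.arange(n_frames)[None, :, None] * drift[None, None, :]
        )

    if noise_sigma > 0:
        positions = positions + rng.normal(0.0, noise_sigma, positions.shape)

    tracks = []
    det = 1
    for i in range(n_points):
        tracks.append(
            Track(
                i + 1,
                0,
                positions[i],
                np.arange(det, det + n_frames, dtype=np.int64),
            )
        )
        det += n_frames
    forest = LineageForest(tracks)
    forest.validate()
    return forest, A, b


# ---------------------------------------------------------------------------
# Track fragmentation
# ---------------------------------------------------------------------------


def fragment_tracks(
    forest: LineageForest,
    break_rate: float = 0.5,
    gap: int = 1,
    drop_rate: float = 0.0,
    seed: int = 0,
) -> tuple[LineageForest, GroundTruth]:
    """Corrupt a forest by splitting tracks, recording the true joins.

    Each track (long enough to be split) is broken with probability
    ``break_rate`` at a uniformly random interior frame.  ``gap`` is the
    frame offset between the left fragment's end and the right fragment's
    start: ``gap = 1`` splits without losing detections, larger gaps
    additionally delete the ``gap - 1`` in-between detections (emulating
    missed detections).  ``drop_rate`` independently deletes single
    interior detections, splitting at the hole.  Ground truth records
    every (left fragment, right fragment) pair.
    """
    if not 0 <= break_rate <= 1 or not 0 <= drop_rate <= 1:
        raise ValueError("rates must be in [0, 1]")
    if gap < 1:
        raise ValueError("gap must be >= 1")
    rng = np.random.default_rng(seed)
    out = forest.copy()
    truth = GroundTruth()

    for tid in sorted(forest.tracks):
        # (split frame, number of deleted detections starting there)
        breaks: list[tuple[int, int]] = []
        tr = out.tracks[tid]
        if drop_rate > 0 and tr.n_frames >= 3:
            for f in tr.frames[1:-1]:
                if rng.random() < drop_rate:
                    breaks.append((int(f), 1))
        # one seeded break per selected track (the draw happens for every
        # track so the RNG stream does not depend on eligibility)
        do_break = rng.random() < break_rate
        if do_break and tr.n_frames >= gap + 2 and not breaks:
            s = int(rng.integers(tr.start_frame + 1, tr.last_frame - gap + 2))
            breaks.append((s, gap - 1))
        left = tid
        for s, n_missing in sorted(set(breaks)):
            ltr = out.tracks[left]
            if not ltr.start_frame < s <= ltr.last_frame - n_missing:
                continue
            out, right = split_track(out, left, s)
            if n_missing > 0:
                rtr = out.tracks[right]
                if rtr.n_frames - n_missing < 1:
                    continue
                keep = slice(n_missing, rtr.n_frames)
                out.tracks[right] = Track(
                    right,
                    rtr.start_frame + n_missing,
                    rtr.positions[keep],
                    rtr.detection_ids[keep],
                    None if rtr.intensities is None else rtr.intensities[keep],
                    rtr.synthetic[keep],
                    None,
                    set(rtr.child_ids),
                )
            truth.joins.append((left, right))
            left = right
    truth.labels = {}
    out.validate()
    return out, truth
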