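"""Heuristic repair of fragmented tracks.

Tracking pipelines routinely fragment trajectories.  This module
reconnects fragments by scoring putative links between a track end and a
later track start on spatial distance plus (when available) fluorescence
intensity difference:

    score = distance / max_radius + w_I * |dI| / I_scale

Automatic linking uses *distance only* — every end/start pair closer than
a user-chosen threshold is merged, with one-to-one conflicts resolved by
an optimal assignment (maximum number of links, then minimum total
score).  For the remainder, a deterministic review queue presents the
best-scored candidates one item at a time, in depth-first or
breadth-first order and in either temporal direction, and records every
decision in a replayable log.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .model import LineageForest, merge_tracks

__all__ = [
    "LinkCandidate",
    "find_candidates",
    "auto_link",
    "CurationSession",
    "replay_decision_log",
    "curation_summary",
]


@dataclass(frozen=True)
class LinkCandidate:
    """A scored putative join between a track end and a later track start."""

    end_track_id: int
    start_track_id: int
    gap: int  # start.first_frame - end.last_frame, >= 1
    distance: float  # um between end and start positions
    intensity_diff: float | None  # |dI| in a.u., None when unavailable
    score: float


def _intensity_scale(forest: LineageForest) -> float | None:
    """Interquartile range of all intensities; None when absent/degenerate."""
    vals = [
        tr.intensities
        for tr in forest.tracks.values()
        if tr.intensities is not None
    ]
    if not vals:
        return None
    allv = np.concatenate(vals)
    allv = allv[np.isfinite(allv)]
    if allv.size < 2:
        return None
    q75, q25 = np.percentile(allv, [75, 25])
    iqr = float(q75 - q25)
    return iqr if iqr > 0 else None


def _link_ends(forest: LineageForest) -> list[int]:
    """Tracks whose last detection is a loose end (no division)."""
    return sorted(tid for tid, tr in forest.tracks.items() if not tr.child_ids)


def _link_starts(forest: LineageForest) -> list[int]:
    """Tracks whose first detection is a loose start (no parent)."""
    return sorted(tid for tid, tr in forest.tracks.items() if tr.parent_id is None)


def find_candidates(
    forest: LineageForest,
    track_id: int,
    direction: str = "forward",
    max_gap: int = 3,
    max_radius: float = 25.0,
    n_best: int = 3,
    w_intensity: float = 1.0,
    intensity_scale: float | None = None,
) -> list[LinkCandidate]:
    """Best-scored link candidates for one track end.

    ``forward`` looks for parentless track starts within ``max_gap``
    frames after the track's last detection and ``max_radius``
    micrometres of its end position; ``backward`` symmetrically looks for
    childless track ends before the track's first detection.  Candidates
    are returned ascending by score, at most ``n_best`` (default 3, the
    number of automatic suggestions presented during review).  The
    intensity term is skipped (``w = 0``) when either side carries no
    intensity; ``intensity_scale`` defaults to the interquartile range of
    all intensities in the forest.
    """
    if track_id not in forest.tracks:
        raise KeyError(f"unknown track {track_id}")
    if direction not in ("forward", "backward"):
        raise ValueError(f"direction must be forward or backward, got {direction!r}")
    tr = forest.tracks[track_id]
    if intensity_scale is None:
        intensity_scale = _intensity_scale(forest)

    out: list[LinkCandidate] = []
    if direction == "forward":
        ref_pos = tr.end_position
        ref_int = None if tr.intensities is None else float(tr.intensities[-1])
        pool = _link_starts(forest)
        for oid in pool:
            if oid == track_id:
                continue
            other = forest.tracks[oid]
            gap = other.start_frame - tr.last_frame
            if not 1 <= gap <= max_gap:
                continue
            dist = float(np.linalg.norm(other.start_position - ref_pos))
            if dist > max_radius:
                continue
            oint = None if other.intensities is None else float(other.intensities[0])
            out.append(
                _make_candidate(
                    track_id, oid, gap, dist, ref_int, oint,
                    max_radius, w_intensity, intensity_scale,
                )
            )
    else:
        ref_pos = tr.start_position
        ref_int = None if tr.intensities is None else float(tr.intensities[0])
        pool = _link_ends(forest)
        for oid in pool:
            if oid == track_id:
                continue
            other = forest.tracks[oid]
            gap = tr.start_frame - other.last_frame
            if not 1 <= gap <= max_gap:
                continue
            dist = float(np.linalg.norm(other.end_position - ref_pos))
            if dist > max_radius:
                continue
            oint = None if other.intensities is None else float(other.intensities[-1])
            out.append(
                _make_candidate(
                    oid, track_id, gap, dist, ref_int, oint,
                    max_radius, w_intensity, intensity_scale,
                )
            )
    out.sort(key=lambda c: (c.score, c.distance, c.start_track_id))
    return out[:n_best]


def _make_candidate(
    end_id: int,
    start_id: int,
    gap: int,
    dist: float,
    int_a: float | None,
    int_b: float | None,
    max_radius: float,
    w_intensity: float,
    intensity_scale: float | None,
) -> LinkCandidate:
    score = dist / max_radius
    di = None
    if int_a is not None and int_b is not None and intensity_scale:
        di = abs(int_a - int_b)
        score += w_intensity * di / intensity_scale
    return LinkCandidate(end_id, start_id, gap, dist, di, score)


# ---------------------------------------------------------------------------
# Automatic linking
# ---------------------------------------------------------------------------


def auto_link(
    forest: LineageForest,
    max_gap: int = 3,
    distance_threshold: float = 5.0,
    one_to_one: bool = True,
) -> tuple[LineageForest, list[dict]]:
    """Merge every end/start pair closer than ``distance_threshold`` um.

    Candidate pairs are childless track ends and parentless track starts
    separated by 1..``max_gap`` frames with end-to-start distance strictly
    below the threshold (the linking rule itself uses distance only; the
    intensity-aware score is reported in the log for reference).  With
    ``one_to_one`` (default), conflicts are resolved globally by an
    optimal assignment: the maximum number of links, and among those the
    minimum total score, so each end and each start is used at most once.
    Accepted links are applied with gap interpolation; the log records
    every link with its distance, gap and score.
    """
    if max_gap < 1 or distance_threshold <= 0:
        raise ValueError("max_gap >= 1 and distance_threshold > 0 required")
    iscale = _intensity_scale(forest)
    ends = _link_ends(forest)
    starts = _link_starts(forest)
    starts_by_frame: dict[int, list[int]] = {}
    for sid in starts:
        starts_by_frame.setdefault(forest.tracks[sid].start_frame, []).append(sid)

    pairs: list[LinkCandidate] = []
    for eid in ends:
        etr = forest.tracks[eid]
        eint = None if etr.intensities is None else float(etr.intensities[-1])
        for gap in range(1, max_gap + 1):
            for sid in starts_by_frame.get(etr.last_frame + gap, ()):
                if sid == eid:
                    continue
                stra = forest.tracks[sid]
                dist = float(np.linalg.norm(stra.start_position - etr.end_position))
                if dist >= distance_threshold:
                    continue
                sint = None if stra.intensities is None else float(stra.intensities[0])
                pairs.append(
                    _make_candidate(
                        eid, sid, gap, dist, eint, sint,
                        distance_threshold, 1.0, iscale,
                    )
                )

    if one_to_one:
        accepted = _optimal_assignment(pairs)
    else:
        accepted = pairs

    # apply merges in temporal order, tracking id remaps as chains collapse
    accepted = sorted(
        accepted, key=lambda c: forest.tracks[c.end_track_id].last_frame
    )
    alias: dict[int, int] = {}
    out = forest
    log: list[dict] = []
    for cand in accepted:
        eid = cand.end_track_id
        while eid in alias:
            eid = alias[eid]
        out = merge_tracks(out, eid, cand.start_track_id)
        alias[cand.start_track_id] = eid
        log.append(
            {
                "end_track_id": cand.end_track_id,
                "start_track_id": cand.start_track_id,
                "merged_into": eid,
                "gap": cand.gap,
                "distance": cand.distance,
                "intensity_diff": cand.intensity_diff,
                "score": cand.score,
            }
        )
    return out, log


def _optimal_assignment(pairs: list[LinkCandidate]) -> list[LinkCandidate]:
    """One-to-one subset of pairs: max cardinality, then min total score."""
    from scipy.optimize import linear_sum_assignment

    if not pairs:
        return []
    ends = sorted({c.end_track_id for c in pairs})
    starts = sorted({c.start_track_id for c in pairs})
    ei = {e: i for i, e in enumerate(ends)}
    si = {s: i for i, s in enumerate(starts)}
    # feasible pairs get (score - BIG) so maximising matches dominates;
    # infeasible cells cost 0 and encode "leave unmatched"
    big = 1.0 + sum(c.score for c in pairs)
    cost = np.zeros((len(ends), len(starts)))
    by_cell: dict[tuple[int, int], LinkCandidate] = {}
    for c in pairs:
        cell = (ei[c.end_track_id], si[c.start_track_id])
        if cell not in by_cell or c.score < by_cell[cell].score:
            by_cell[cell] = c
            cost[cell] = c.score - big
    rows, cols = linear_sum_assignment(cost)
    return [
        by_cell[(r, s)]
        for r, s in zip(rows, cols)
        if (r, s) in by_cell and cost[r, s] < 0
    ]


# ---------------------------------------------------------------------------
# Guided review session
# ---------------------------------------------------------------------------


class QueueExhausted(Exception):
    """Raised when the review queue has no pending item left."""


@dataclass
class _Decision:
    track_id: int
    candidates: list[dict]
    choice: str  # "rank", "explicit" or "reject"
    rank: int | None
    linked_track: int | None
    distance: float | None

    def to_dict(self) -> dict:
        return {
            "track_id": self.track_id,
            "candidates": self.candidates,
            "choice": self.choice,
            "rank": self.rank,
            "linked_track": self.linked_track,
            "distance": self.distance,
        }


class CurationSession:
    """Deterministic review queue over the loose track ends of a forest.

    ``mode`` chooses the visiting order: ``breadth-first`` handles all
    ends at the earliest frame before advancing; ``depth-first`` keeps
    following the newly created end of the track just linked, walking one
    cell's history to completion before moving on.  ``direction`` sets
    the temporal sense (``forward`` links ends to later starts,
    ``backward`` links starts to earlier ends).  ``selection`` restricts
    the queue to a group of interest.  Every decision is logged; a log
    replayed on the original forest reproduces the final forest exactly.
    """

    def __init__(
        self,
        forest: LineageForest,
        mode: str = "breadth-first",
        direction: str = "forward",
        selection: set[int] | None = None,
        max_gap: int = 3,
        max_radius: float = 25.0,
        n_best: int = 3,
    ):
        if mode not in ("breadth-first", "depth-first"):
            raise ValueError(f"unknown mode {mode!r}")
        if direction not in ("forward", "backward"):
            raise ValueError(f"unknown direction {direction!r}")
        self.forest = forest.copy()
        self.mode = mode
        self.direction = direction
        self.max_gap = max_gap
        self.max_radius = max_radius
        self.n_best = n_best
        self.decisions: list[_Decision] = []
        self._current: tuple[int, list[LinkCandidate]] | None = None
        pool = (
            _link_ends(self.forest)
            if direction == "forward"
            else _link_starts(self.forest)
        )
        if selection is not None:
            pool = [tid for tid in pool if tid in selection]
        self.queue: list[int] = self._ordered(pool)

    def _ordered(self, tids: Sequence[int]) -> list[int]:
        if self.direction == "forward":
            # earliest loose end first
            return sorted(tids, key=lambda t: (self.forest.tracks[t].last_frame, t))
        # backward: latest loose start first
        return sorted(tids, key=lambda t: (-self.forest.tracks[t].start_frame, t))

    def next_review_item(self) -> tuple[int, list[LinkCandidate]]:
        """The next track to review plus its scored candidates."""
        if self._current is not None:
            return self._current[0], list(self._current[1])
        while self.queue:
            tid = self.queue.pop(0)
            if tid not in self.forest.tracks:
                continue  # absorbed by an earlier merge
            cands = find_candidates(
                self.forest,
                tid,
                direction=self.direction,
                max_gap=self.max_gap,
                max_radius=self.max_radius,
                n_best=self.n_best,
            )
            self._current = (tid, cands)
            return tid, list(cands)
        raise QueueExhausted("no pending track ends left to review")

    def apply_decision(self, choice: int | str | tuple[str, int]) -> None:
        """Resolve the current item.

        ``choice`` is a 1-based candidate rank, ``"reject"``, or
        ``("track", track_id)`` naming an explicit alternative partner
        (the reviewer's own pick, outside the automatic suggestions).
        """
        if self._current is None:
            self.next_review_item()
        tid, cands = self._current
        cand_dicts = [
            {
                "end_track_id": c.end_track_id,
                "start_track_id": c.start_track_id,
                "distance": c.distance,
                "score": c.score,
            }
            for c in cands
        ]
        if choice == "reject":
            self.decisions.append(
                _Decision(tid, cand_dicts, "reject", None, None, None)
            )
            self._current = None
            return

        if isinstance(choice, tuple) and choice[0] == "track":
            other = int(choice[1])
            if self.direction == "forward":
                end_id, start_id = tid, other
            else:
                end_id, start_id = other, tid
            dist = float(
                np.linalg.norm(
                    self.forest.tracks[start_id].start_position
                    - self.forest.tracks[end_id].end_position
                )
            )
            rank = None
            kind = "explicit"
        elif isinstance(choice, int):
            if not 1 <= choice <= len(cands):
                raise IndexError(
                    f"rank {choice} out of range 1..{len(cands)} for track {tid}"
                )
            cand = cands[choice - 1]
            end_id, start_id = cand.end_track_id, cand.start_track_id
            dist = cand.distance
            rank = choice
            kind = "rank"
        else:
            raise ValueError(f"invalid choice {choice!r}")

        self.forest = merge_tracks(self.forest, end_id, start_id)
        linked = start_id if self.direction == "forward" else end_id
        self.decisions.append(_Decision(tid, cand_dicts, kind, rank, linked, dist))
        self._current = None
        if self.mode == "depth-first":
            # keep following the cell just extended
            self.queue.insert(0, end_id)
        else:
            self.queue = self._ordered(
                [t for t in self.queue if t in self.forest.tracks] + [end_id]
            )

    def decision_log(self) -> list[dict]:
        return [d.to_dict() for d in self.decisions]

    def write_log(self, path: str | Path) -> None:
        """JSON-lines decision log (one decision per line)."""
        with open(path, "w") as fh:
            for d in self.decisions:
                fh.write(json.dumps(d.to_dict()) + "\n")


def replay_decision_log(
    forest: LineageForest,
    log: Sequence[dict] | str | Path,
    mode: str = "breadth-first",
    direction: str = "forward",
    **session_kwargs,
) -> LineageForest:
    """Re-apply a recorded decision sequence to a forest, deterministically."""
    if not isinstance(log, (list, tuple)):
        log = [json.loads(line) for line in Path(log).read_text().splitlines() if line]
    session = CurationSession(forest, mode=mode, direction=direction, **session_kwargs)
    for entry in log:
        tid, _ = session.next_review_item()
        if tid != entry["track_id"]:
            raise ValueError(
                f"replay divergence: queue offers track {tid}, log expects "
                f"{entry['track_id']}"
            )
        if entry["choice"] == "reject":
            session.apply_decision("reject")
        elif entry["choice"] == "rank":
            session.apply_decision(entry["rank"])
        else:
            session.apply_decision(("track", entry["linked_track"]))
    return session.forest


def curation_summary(log: Sequence[dict]) -> pd.DataFrame:
    """Per-decision summary table (candidate rank chosen and link distance),
    the raw material for rank-distribution and distance box plots."""
    rows = []
    for entry in log:
        rows.append(
            {
                "track_id": entry["track_id"],
                "choice": entry["choice"],
                # explicit picks rank after the automatic suggestions
                "rank": entry["rank"]
                if entry["choice"] == "rank"
                else (len(entry["candidates"]) + 1 if entry["choice"] == "explicit" else None),
                "distance": entry["distance"],
                "n_candidates": len(entry["candidates"]),
            }
        )
    return pd.DataFrame(
        rows, columns=["track_id", "choice", "rank", "distance", "n_candidates"]
    )
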