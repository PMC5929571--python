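"""Readers and writers bridging standard tracking formats to the lineage forest.

Supported formats
-----------------
* Cell Tracking Challenge (CTC): ``res_track.txt`` with "label begin end
  parent" records plus either per-frame 16-bit label-mask TIFFs or a
  companion centroid CSV.  Positions are voxel-based and are scaled to
  micrometres with the supplied voxel size.
* TrackMate XML (spots + track edges).  Coordinates are trusted as
  calibrated physical units.
* TGMM per-frame XML (one file per frame, objects referencing a parent id
  in the previous frame).  Positions are voxel-based.
* Native per-detection CSV — the canonical tabular interchange format:
  ``detection_id,track_id,frame,x,y,z,intensity,parent_track_id``
  (plus an optional ``synthetic`` column).

Tracks with internal frame gaps in the source data are split at the gaps
on import (the model requires consecutive frames); curation can re-join
them with interpolation.  Lineage merges (two parents claiming one
object) are not representable in a forest: the earlier link is kept and
a warning is recorded.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .model import LineageForest, Track

__all__ = [
    "ImportReport",
    "read_csv",
    "write_csv",
    "read_ctc",
    "write_ctc",
    "read_trackmate",
    "read_tgmm",
]


@dataclass
class ImportReport:
    """Summary of an import: counts plus anything worth a second look."""

    n_tracks: int = 0
    n_detections: int = 0
    n_divisions: int = 0
    warnings: list[str] = field(default_factory=list)

    @classmethod
    def from_forest(cls, forest: LineageForest, warnings: list[str] | None = None):
        return cls(
            n_tracks=forest.n_tracks,
            n_detections=forest.n_detections,
            n_divisions=forest.n_divisions,
            warnings=list(warnings or []),
        )


# ---------------------------------------------------------------------------
# Chain assembly shared by every importer
# ---------------------------------------------------------------------------


def _forest_from_chains(
    chains: dict[int, dict],
    parent_of: dict[int, int],
    voxel_size: Sequence[float],
    warnings: list[str],
    frame_interval: float | None = None,
    time_origin: float | None = None,
) -> LineageForest:
    """Build a forest from per-chain records, splitting at frame gaps.

    ``chains[cid]`` holds ``frames`` (sorted), ``positions``, optional
    ``intensities`` and ``detection_ids``; ``parent_of`` maps chain id to
    parent chain id.  Chains with non-consecutive frames are split into
    fragments (the first keeps the lineage link, later fragments are
    parentless), because downstream analysis requires gap-free tracks.
    """
    forest = LineageForest(
        (), frame_interval=frame_interval, time_origin=time_origin, voxel_size=voxel_size
    )
    next_id = max(chains, default=0) + 1
    last_fragment_of: dict[int, int] = {}  # chain id -> id of its final fragment
    pending_parent: dict[int, int] = {}  # track id -> chain id of parent

    for cid in sorted(chains):
        rec = chains[cid]
        frames = np.asarray(rec["frames"], dtype=int)
        order = np.argsort(frames)
        frames = frames[order]
        positions = np.asarray(rec["positions"], float)[order]
        intensities = rec.get("intensities")
        if intensities is not None:
            intensities = np.asarray(intensities, float)[order]
        det_ids = rec.get("detection_ids")
        if det_ids is not None:
            det_ids = np.asarray(det_ids, dtype=np.int64)[order]
        if len(np.unique(frames)) != len(frames):
            raise ValueError(f"track {cid}: duplicate frames")

        breaks = np.where(np.diff(frames) > 1)[0]
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [len(frames) - 1]])
        if len(starts) > 1:
            warnings.append(
                f"track {cid}: split into {len(starts)} fragments at frame gaps"
            )
        for k, (s, e) in enumerate(zip(starts, ends)):
            if k == 0:
                tid = cid
            else:
                tid = next_id
                next_id += 1
            seg = slice(s, e + 1)
            forest.tracks[tid] = Track(
                tid,
                int(frames[s]),
                positions[seg],
                det_ids[seg] if det_ids is not None else np.zeros(e - s + 1, np.int64),
                intensities[seg] if intensities is not None else None,
            )
            if k == 0 and cid in parent_of:
                pending_parent[tid] = parent_of[cid]
            last_fragment_of[cid] = tid

    if any(
        tr.detection_ids.max(initial=0) == 0 and tr.n_frames > 0
        for tr in forest.tracks.values()
    ):
        # assign fresh globally unique detection ids where the source had none
        det = 1
        for tid in sorted(forest.tracks):
            tr = forest.tracks[tid]
            tr.detection_ids = np.arange(det, det + tr.n_frames, dtype=np.int64)
            det += tr.n_frames

    for tid, parent_cid in pending_parent.items():
        pid = last_fragment_of.get(parent_cid)
        tr = forest.tracks[tid]
        if pid is None:
            warnings.append(f"track {tid}: dangling parent reference {parent_cid}")
            continue
        parent = forest.tracks[pid]
        if tr.start_frame == parent.last_frame + 1:
            tr.parent_id = pid
            parent.child_ids.add(tid)
        else:
            warnings.append(
                f"track {tid}: parent {pid} ends at {parent.last_frame}, child "
                f"starts at {tr.start_frame}; link dropped"
            )
    for tid, tr in forest.tracks.items():
        if len(tr.child_ids) > 2:
            warnings.append(
                f"track {tid}: {len(tr.child_ids)} children (more than a binary division)"
            )
    return forest


# ---------------------------------------------------------------------------
# Native CSV
# ---------------------------------------------------------------------------

_CSV_COLUMNS = [
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


def write_csv(forest: LineageForest, path: str | Path) -> None:
    """Write the per-detection table (one row per detection, sorted)."""
    df = forest.to_dataframe()
    df = df.sort_values(["track_id", "frame"]).reset_index(drop=True)
    df.to_csv(path, index=False, float_format="%.9g")


def read_csv(path: str | Path) -> tuple[LineageForest, ImportReport]:
    """Read the native per-detection CSV."""
    df = pd.read_csv(path)
    missing = {"track_id", "frame", "x", "y", "z"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    warnings: list[str] = []
    chains: dict[int, dict] = {}
    parent_of: dict[int, int] = {}
    for tid, g in df.groupby("track_id", sort=True):
        tid = int(tid)
        rec: dict = {
            "frames": g["frame"].to_numpy(int),
            "positions": g[["x", "y", "z"]].to_numpy(float),
        }
        if "intensity" in g and not g["intensity"].isna().all():
            rec["intensities"] = g["intensity"].to_numpy(float)
        if "detection_id" in g:
            rec["detection_ids"] = g["detection_id"].to_numpy(np.int64)
        chains[tid] = rec
        if "parent_track_id" in g:
            p = int(g["parent_track_id"].iloc[0])
            if p >= 0:
                parent_of[tid] = p
    forest = _forest_from_chains(chains, parent_of, (1, 1, 1), warnings)
    if "synthetic" in df.columns:
        syn = df.set_index("detection_id")["synthetic"]
        for tr in forest.tracks.values():
            tr.synthetic = syn.reindex(tr.detection_ids).fillna(0).to_numpy(bool)
    forest.validate()
    return forest, ImportReport.from_forest(forest, warnings)


# ---------------------------------------------------------------------------
# Cell Tracking Challenge
# ---------------------------------------------------------------------------

_CTC_LINE = re.compile(r"^\s*(\d+)\s+(\d+)\s+(\d+)\s+(\d+)\s*$")


def _read_ctc_track_file(track_file: Path) -> list[tuple[int, int, int, int]]:
    records = []
    for lineno, line in enumerate(track_file.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        m = _CTC_LINE.match(line)
        if not m:
            raise ValueError(f"{track_file}:{lineno}: malformed line {line!r}")
        records.append(tuple(int(x) for x in m.groups()))
    return records


def _mask_centroids(
    mask_dir: Path, raw_dir: Path | None, voxel_size: Sequence[float]
) -> dict[tuple[int, int], tuple[np.ndarray, float | None]]:
    """(label, frame) -> (centroid in um, mean raw intensity or None).

    Mask files are 16-bit label TIFFs named with a zero-padded frame index
    (e.g. ``mask013.tif``); 2D masks are treated as z = 0.  The centroid is
    the unweighted voxel centre of mass scaled by the voxel size.
    """
    import tifffile
    from scipy import ndimage

    out: dict[tuple[int, int], tuple[np.ndarray, float | None]] = {}
    files = sorted(mask_dir.glob("*.tif")) + sorted(mask_dir.glob("*.tiff"))
    if not files:
        raise FileNotFoundError(f"no TIFF masks in {mask_dir}")
    vx = np.asarray(voxel_size, float)
    for f in files:
        m = re.search(r"(\d+)\D*$", f.stem)
        if not m:
            raise ValueError(f"cannot parse frame index from mask name {f.name}")
        frame = int(m.group(1))
        mask = tifffile.imread(f)
        raw = None
        if raw_dir is not None:
            cands = sorted(raw_dir.glob(f"*{m.group(1)}*.tif*"))
            if cands:
                raw = tifffile.imread(cands[0])
        labels = np.unique(mask)
        labels = labels[labels > 0]
        if len(labels) == 0:
            continue
        coms = ndimage.center_of_mass(np.ones_like(mask, dtype=float), mask, labels)
        for lab, com in zip(labels, coms):
            com = np.atleast_1d(np.asarray(com, float))
            if mask.ndim == 2:  # (y, x) -> (x, y, 0)
                pos = np.array([com[1], com[0], 0.0])
            else:  # (z, y, x) -> (x, y, z)
                pos = np.array([com[2], com[1], com[0]])
            inten = None
            if raw is not None:
                inten = float(raw[mask == lab].mean())
            out[(int(lab), frame)] = (pos * vx, inten)
    return out


def read_ctc(
    track_file: str | Path,
    mask_dir: str | Path | None = None,
    voxel_size: Sequence[float] = (1.0, 1.0, 1.0),
    centroid_csv: str | Path | None = None,
    raw_dir: str | Path | None = None,
) -> tuple[LineageForest, ImportReport]:
    """Read a Cell Tracking Challenge result.

    ``track_file`` holds "L B E P" records (label, first frame, last frame,
    parent label, 0 = none), both frame bounds inclusive.  Centroids come
    either from per-frame label masks in ``mask_dir`` (centre of mass of
    each label's voxels, scaled by ``voxel_size``) or from a companion
    ``centroid_csv`` with columns ``label,frame,x,y,z[,intensity]`` in
    voxel units.  A label missing from a frame inside its [B, E] range is
    bridged by linear interpolation (flagged synthetic) with a warning.
    """
    track_file = Path(track_file)
    records = _read_ctc_track_file(track_file)
    warnings: list[str] = []

    if mask_dir is not None:
        cent = _mask_centroids(Path(mask_dir), Path(raw_dir) if raw_dir else None, voxel_size)
    elif centroid_csv is not None:
        df = pd.read_csv(centroid_csv)
        need = {"label", "frame", "x", "y", "z"} - set(df.columns)
        if need:
            raise ValueError(f"{centroid_csv}: missing columns {sorted(need)}")
        vx = np.asarray(voxel_size, float)
        cent = {}
        has_int = "intensity" in df.columns and not df["intensity"].isna().all()
        for row in df.itertuples(index=False):
            pos = np.array([row.x, row.y, row.z], float) * vx
            cent[(int(row.label), int(row.frame))] = (
                pos,
                float(row.intensity) if has_int else None,
            )
    else:
        raise ValueError("read_ctc needs either mask_dir or centroid_csv")

    chains: dict[int, dict] = {}
    parent_of: dict[int, int] = {}
    any_intensity = any(v[1] is not None for v in cent.values())
    for label, begin, end, parent in records:
        frames, positions, intens = [], [], []
        missing_run: list[int] = []
        for t in range(begin, end + 1):
            hit = cent.get((label, t))
            if hit is None:
                missing_run.append(t)
                continue
            frames.append(t)
            positions.append(hit[0])
            intens.append(hit[1] if hit[1] is not None else np.nan)
        if missing_run:
            warnings.append(
                f"label {label}: missing from {len(missing_run)} frame(s) "
                f"{missing_run[:5]}{'...' if len(missing_run) > 5 else ''}; "
                "interior gaps bridged by interpolation"
            )
        if not frames:
            warnings.append(f"label {label}: no centroids found at all; skipped")
            continue
        frames_a = np.asarray(frames)
        pos_a = np.asarray(positions)
        # bridge interior gaps by linear interpolation so the track is gap-free
        full = np.arange(frames_a[0], frames_a[-1] + 1)
        if len(full) != len(frames_a):
            interp = np.column_stack(
                [np.interp(full, frames_a, pos_a[:, k]) for k in range(3)]
            )
            syn = ~np.isin(full, frames_a)
            if any_intensity:
                ints = np.interp(full, frames_a, np.asarray(intens))
            frames_a, pos_a = full, interp
        else:
            syn = np.zeros(len(full), dtype=bool)
            if any_intensity:
                ints = np.asarray(intens)
        rec = {"frames": frames_a, "positions": pos_a, "_synthetic": syn}
        if any_intensity:
            rec["intensities"] = ints
        chains[label] = rec
        if parent != 0:
            parent_of[label] = parent

    forest = _forest_from_chains(chains, parent_of, voxel_size, warnings)
    for tid, tr in forest.tracks.items():
        if tid in chains and len(chains[tid]["_synthetic"]) == tr.n_frames:
            tr.synthetic = np.asarray(chains[tid]["_synthetic"], bool)
    forest.validate()
    return forest, ImportReport.from_forest(forest, warnings)


def write_ctc(forest: LineageForest, out_dir: str | Path) -> None:
    """Write ``res_track.txt`` plus a centroid CSV (stable across runs).

    The centroid CSV stores positions in micrometres with voxel size
    (1, 1, 1), so a round trip through :func:`read_ctc` reproduces the
    forest's physical coordinates exactly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    lines = []
    rows = []
    has_intensity = any(tr.intensities is not None for tr in forest.tracks.values())
    for tid in sorted(forest.tracks):
        tr = forest.tracks[tid]
        parent = 0 if tr.parent_id is None else tr.parent_id
        lines.append(f"{tid} {tr.start_frame} {tr.last_frame} {parent}")
        for i, frame in enumerate(tr.frames):
            row = {
                "label": tid,
                "frame": int(frame),
                "x": tr.positions[i, 0],
                "y": tr.positions[i, 1],
                "z": tr.positions[i, 2],
            }
            if has_intensity:
                row["intensity"] = (
                    np.nan if tr.intensities is None else tr.intensities[i]
                )
            rows.append(row)
    (out_dir / "res_track.txt").write_text("\n".join(lines) + ("\n" if lines else ""))
    cols = ["label", "frame", "x", "y", "z"] + (["intensity"] if has_intensity else [])
    pd.DataFrame(rows, columns=cols).to_csv(
        out_dir / "res_centroids.csv", index=False, float_format="%.17g"
    )


# ---------------------------------------------------------------------------
# TrackMate
# ---------------------------------------------------------------------------


def read_trackmate(xml_file: str | Path) -> tuple[LineageForest, ImportReport]:
    """Read TrackMate XML (spots + edges); coordinates taken as calibrated.

    Spot chains become tracks; a spot with two or more outgoing edges is a
    division (each successor starts a child track).  A spot with two or
    more incoming edges cannot be represented in a forest: the edge from
    the earlier source spot is kept and the others dropped with a warning,
    leaving the later fragments parentless.
    """
    from lxml import etree

    tree = etree.parse(str(xml_file))
    root = tree.getroot()
    model = root.find("Model")
    if model is None:
        raise ValueError(f"{xml_file}: no <Model> element")

    spots: dict[int, dict] = {}
    for spot in model.iter("Spot"):
        sid = int(spot.get("ID"))
        vals = {}
        for key in ("POSITION_X", "POSITION_Y", "POSITION_Z"):
            v = spot.get(key)
            if v is None:
                raise ValueError(f"{xml_file}: spot {sid} missing {key}")
            vals[key] = float(v)
        frame = spot.get("FRAME")
        if frame is None:
            raise ValueError(f"{xml_file}: spot {sid} missing FRAME")
        spots[sid] = {
            "frame": int(float(frame)),
            "pos": np.array(
                [vals["POSITION_X"], vals["POSITION_Y"], vals["POSITION_Z"]]
            ),
            "intensity": (
                float(spot.get("MEAN_INTENSITY"))
                if spot.get("MEAN_INTENSITY") is not None
                else None
            ),
        }

    warnings: list[str] = []
    out_edges: dict[int, list[int]] = {}
    in_source: dict[int, int] = {}
    edge_spots: set[int] = set()
    for edge in model.iter("Edge"):
        s = int(float(edge.get("SPOT_SOURCE_ID")))
        t = int(float(edge.get("SPOT_TARGET_ID")))
        if s not in spots or t not in spots:
            warnings.append(f"edge {s}->{t} references unknown spot; dropped")
            continue
        if spots[s]["frame"] > spots[t]["frame"]:
            s, t = t, s  # orient edges forward in time
        if t in in_source:
            prev = in_source[t]
            keep, drop = (
                (prev, s) if spots[prev]["frame"] <= spots[s]["frame"] else (s, prev)
            )
            warnings.append(
                f"spot {t} has multiple incoming edges; kept link from {keep}, "
                f"dropped {drop} (lineage merges are not representable)"
            )
            if keep != prev:
                out_edges[prev].remove(t)
                in_source[t] = keep
                out_edges.setdefault(keep, []).append(t)
            edge_spots.update((s, t))
            continue
        in_source[t] = s
        out_edges.setdefault(s, []).append(t)
        edge_spots.update((s, t))

    # chain decomposition: a new track starts at a root spot or after a division
    chains: dict[int, dict] = {}
    parent_of: dict[int, int] = {}
    chain_of_start: dict[int, int] = {}
    next_cid = 1

    starts = [
        sid
        for sid in spots
        if (sid not in in_source) or len(out_edges.get(in_source[sid], [])) >= 2
    ]
    starts.sort(key=lambda s: (spots[s]["frame"], s))
    for s0 in starts:
        cid = next_cid
        next_cid += 1
        chain_of_start[s0] = cid
        frames, positions, intens, ids = [], [], [], []
        sid = s0
        while True:
            sp = spots[sid]
            frames.append(sp["frame"])
            positions.append(sp["pos"])
            intens.append(np.nan if sp["intensity"] is None else sp["intensity"])
            ids.append(sid)
            succ = out_edges.get(sid, [])
            if len(succ) != 1:
                break
            nxt = succ[0]
            if len(out_edges.get(sid, [])) >= 2:
                break
            sid = nxt
            if sid in chain_of_start:  # safety against cycles
                break
        rec = {
            "frames": np.asarray(frames),
            "positions": np.asarray(positions),
            "detection_ids": np.asarray(ids, np.int64) + 1,
        }
        if not np.isnan(intens).all():
            rec["intensities"] = np.asarray(intens)
        chains[cid] = rec

    # link chains across divisions
    spot_chain_end: dict[int, int] = {}
    for cid, rec in chains.items():
        spot_chain_end[int(rec["detection_ids"][-1]) - 1] = cid
    for s0, cid in chain_of_start.items():
        if s0 in in_source:
            parent_of[cid] = spot_chain_end[in_source[s0]]

    forest = _forest_from_chains(chains, parent_of, (1, 1, 1), warnings)
    forest.validate()
    return forest, ImportReport.from_forest(forest, warnings)


# ---------------------------------------------------------------------------
# TGMM
# ---------------------------------------------------------------------------


def read_tgmm(
    xml_dir: str | Path, voxel_size: Sequence[float] = (1.0, 1.0, 1.0)
) -> tuple[LineageForest, ImportReport]:
    """Read TGMM per-frame XML files (sorted by the frame index in the name).

    Each object carries an ``id``, a ``parent`` id referencing the previous
    frame (-1 for none) and a mean position ``m="x y z"`` in voxels.
    Frame-to-frame chains are assembled into tracks; an object whose parent
    has several children starts a child track (division); a dangling parent
    reference breaks the chain into a parentless fragment with a warning.
    """
    from lxml import etree

    xml_dir = Path(xml_dir)
    files = sorted(xml_dir.glob("*.xml"))
    if not files:
        raise FileNotFoundError(f"no XML files in {xml_dir}")

    def frame_of(f: Path) -> int:
        m = re.search(r"(\d+)\D*$", f.stem)
        if not m:
            raise ValueError(f"cannot parse frame index from {f.name}")
        return int(m.group(1))

    files.sort(key=frame_of)
    warnings: list[str] = []
    # nodes keyed by (frame, object id)
    pos: dict[tuple[int, int], np.ndarray] = {}
    parent: dict[tuple[int, int], tuple[int, int] | None] = {}
    children_count: dict[tuple[int, int], int] = {}
    prev_frame: int | None = None
    for f in files:
        t = frame_of(f)
        root = etree.parse(str(f)).getroot()
        for obj in root.iter("GaussianMixtureModel"):
            oid = int(obj.get("id"))
            m = obj.get("m")
            if m is None:
                raise ValueError(f"{f}: object {oid} missing position attribute 'm'")
            p = np.fromstring(m.strip(), sep=" ")
            if p.size != 3:
                raise ValueError(f"{f}: object {oid} malformed position {m!r}")
            key = (t, oid)
            pos[key] = p * np.asarray(voxel_size, float)
            par = int(obj.get("parent", "-1"))
            if par < 0 or prev_frame is None:
                parent[key] = None
            else:
                pkey = (prev_frame, par)
                if pkey not in pos:
                    warnings.append(
                        f"frame {t} object {oid}: dangling parent {par}; chain broken"
                    )
                    parent[key] = None
                else:
                    parent[key] = pkey
                    children_count[pkey] = children_count.get(pkey, 0) + 1
        prev_frame = t

    successors: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for key, pkey in parent.items():
        if pkey is not None:
            successors.setdefault(pkey, []).append(key)

    chains: dict[int, dict] = {}
    parent_key_of: dict[int, tuple[int, int]] = {}
    chain_of: dict[tuple[int, int], int] = {}
    next_cid = 1
    # track starts: no parent, or parent had >= 2 children (division)
    for key in sorted(pos):
        pkey = parent[key]
        is_start = pkey is None or children_count.get(pkey, 0) >= 2
        if not is_start:
            continue
        cid = next_cid
        next_cid += 1
        frames, positions = [], []
        cur: tuple[int, int] | None = key
        while cur is not None:
            chain_of[cur] = cid
            frames.append(cur[0])
            positions.append(pos[cur])
            succ = successors.get(cur, [])
            cur = succ[0] if len(succ) == 1 else None
        chains[cid] = {"frames": np.asarray(frames), "positions": np.asarray(positions)}
        if pkey is not None:
            parent_key_of[cid] = pkey

    parent_of: dict[int, int] = {
        cid: chain_of[pkey] for cid, pkey in parent_key_of.items()
    }

    forest = _forest_from_chains(chains, parent_of, voxel_size, warnings)
    forest.validate()
    return forest, ImportReport.from_forest(forest, warnings)
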