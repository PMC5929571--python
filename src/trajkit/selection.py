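"""Virtual dissection: composable track selections and label propagation.

Instead of physically dissecting an embryo, anatomical groups of cells
are isolated by composing *selection predicates* on the tracking data:
feature thresholds, feature-space polygons, spatial regions at a chosen
frame, clustering, and set algebra over earlier selections.  Every step
is recorded as a node of a :class:`SelectionTree`; each node stores a
serializable predicate plus the member track ids it produced, and
children always refine their parent.  A saved tree is a reusable
analysis template: :func:`replay_tree` re-evaluates every predicate on a
different data set (optionally with per-node parameter overrides).

Tracks excluded from an analysis (e.g. fragments too short to classify)
can afterwards be assigned to the selected groups by
:func:`propagate_labels`, a per-frame majority vote over the spatially
nearest labelled detections.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .model import Box, LineageForest, PolygonRegion, region_from_dict
from .features import single_features

__all__ = [
    "SelectionNode",
    "SelectionTree",
    "propagate_labels",
    "replay_tree",
]


@dataclass
class SelectionNode:
    node_id: int
    parent_id: int | None
    predicate: dict
    members: frozenset[int]
    label: str = ""


class SelectionTree:
    """Hierarchy of recorded selection operations over one forest."""

    def __init__(self, forest: LineageForest, root_label: str = "all tracks"):
        self.forest = forest
        self.nodes: dict[int, SelectionNode] = {}
        self._next_id = 0
        self._feature_cache: pd.DataFrame | None = None
        self._cluster_cache: dict[tuple, np.ndarray] = {}
        root = SelectionNode(
            self._take_id(),
            None,
            {"kind": "root"},
            frozenset(forest.tracks),
            root_label,
        )
        self.nodes[root.node_id] = root
        self.root_id = root.node_id

    # -- plumbing ------------------------------------------------------
    def _take_id(self) -> int:
        i = self._next_id
        self._next_id += 1
        return i

    @property
    def root(self) -> SelectionNode:
        return self.nodes[self.root_id]

    def feature_table(self) -> pd.DataFrame:
        """All single features of the bound forest (computed once, cached)."""
        if self._feature_cache is None:
            self._feature_cache = single_features(self.forest)
        return self._feature_cache

    def _feature_values(self, names: Sequence[str], members: Sequence[int]) -> np.ndarray:
        table = self.feature_table()
        missing = [n for n in names if n not in table.columns]
        if missing:
            raise KeyError(
                f"unknown feature(s) {missing}; available: {list(table.columns)}"
            )
        return table.loc[list(members), list(names)].to_numpy(float)

    def _add(self, parent_id: int, predicate: dict, members: set[int], label: str):
        parent = self.nodes[parent_id]
        if not members <= set(parent.members):
            raise AssertionError("selection escaped its parent set")  # invariant
        node = SelectionNode(
            self._take_id(), parent_id, predicate, frozenset(members), label
        )
        self.nodes[node.node_id] = node
        return node

    # -- selection operations ------------------------------------------
    def select_by_feature(
        self,
        parent: int | SelectionNode,
        feature: str | Sequence[str],
        interval: tuple[float | None, float | None] | None = None,
        polygon: Sequence[tuple[float, float]] | None = None,
        label: str = "",
    ) -> SelectionNode:
        """Child node of tracks whose feature values satisfy the predicate.

        Either a closed ``interval = (lo, hi)`` on one feature (``None``
        bounds are unbounded) or a ``polygon`` over two features.
        """
        parent_id = parent if isinstance(parent, int) else parent.node_id
        if (interval is None) == (polygon is None):
            raise ValueError("give exactly one of interval or polygon")
        if interval is not None:
            predicate = {
                "kind": "feature_interval",
                "feature": feature,
                "lo": interval[0],
                "hi": interval[1],
            }
        else:
            if not (isinstance(feature, (list, tuple)) and len(feature) == 2):
                raise ValueError("polygon selection needs exactly two feature names")
            predicate = {
                "kind": "feature_polygon",
                "features": list(feature),
                "vertices": [list(v) for v in polygon],
            }
        members = self._eval_predicate(predicate, self.nodes[parent_id].members)
        return self._add(parent_id, predicate, members, label)

    def select_by_position(
        self,
        parent: int | SelectionNode,
        frame: int,
        region: Box | PolygonRegion,
        label: str = "",
    ) -> SelectionNode:
        """Tracks having a detection inside ``region`` at ``frame``."""
        parent_id = parent if isinstance(parent, int) else parent.node_id
        first, last = self.forest.frame_range()
        if not first <= frame <= last:
            raise ValueError(
                f"frame {frame} outside the forest interval [{first}, {last}]"
            )
        predicate = {"kind": "position", "frame": int(frame), "region": region.to_dict()}
        members = self._eval_predicate(predicate, self.nodes[parent_id].members)
        return self._add(parent_id, predicate, members, label)

    def cluster_members(
        self,
        parent: int | SelectionNode,
        features: Sequence[str],
        k: int,
        method: str = "kmeans",
        label: str = "",
    ) -> list[SelectionNode]:
        """Partition the parent's members into ``k`` clusters.

        Deterministic k-means: initial centres are placed at the
        ``(i + 1/2)/k`` quantiles of the members' projection onto the
        first principal axis of the feature matrix, so repeated runs (and
        replays on other data) need no random seed.  Children are ordered
        by ascending cluster mean of the first feature, which makes
        cluster indices stable, comparable labels.
        """
        parent_id = parent if isinstance(parent, int) else parent.node_id
        if method != "kmeans":
            raise ValueError(f"unknown clustering method {method!r}")
        if k < 2:
            raise ValueError("k must be >= 2")
        parent_members = sorted(self.nodes[parent_id].members)
        if len(parent_members) < k:
            raise ValueError(
                f"cannot form {k} clusters from {len(parent_members)} members"
            )
        assignment = self._cluster_assign(tuple(features), k, tuple(parent_members))
        out = []
        for i in range(k):
            predicate = {
                "kind": "cluster",
                "features": list(features),
                "k": int(k),
                "method": method,
                "index": i,
            }
            members = {tid for tid, c in zip(parent_members, assignment) if c == i}
            out.append(
                self._add(parent_id, predicate, members, label or f"cluster {i}")
            )
        return out

    def _cluster_assign(
        self, features: tuple[str, ...], k: int, members: tuple[int, ...]
    ) -> np.ndarray:
        key = (features, k, members)
        if key not in self._cluster_cache:
            X = self._feature_values(features, members)
            self._cluster_cache[key] = _deterministic_kmeans(X, k)
        return self._cluster_cache[key]

    def combine_nodes(
        self,
        node_ids: Sequence[int],
        op: str,
        label: str = "",
    ) -> SelectionNode:
        """Set algebra over existing nodes, parented at their lowest
        common ancestor.  ``difference`` takes exactly two ordered nodes."""
        if op not in ("union", "intersection", "difference"):
            raise ValueError(f"unknown op {op!r}")
        if op == "difference":
            if len(node_ids) != 2:
                raise ValueError("difference takes exactly 2 nodes (ordered)")
        elif len(node_ids) < 2:
            raise ValueError("combine needs at least 2 nodes")
        for nid in node_ids:
            if nid not in self.nodes:
                raise KeyError(f"node {nid} is not in this tree")
        predicate = {"kind": "combine", "op": op, "sources": [int(n) for n in node_ids]}
        parent_id = self._lowest_common_ancestor(node_ids)
        members = self._eval_predicate(predicate, self.nodes[parent_id].members)
        return self._add(parent_id, predicate, members, label)

    # -- predicate evaluation ------------------------------------------
    def _eval_predicate(self, predicate: dict, parent_members: frozenset[int]) -> set[int]:
        kind = predicate["kind"]
        members = sorted(parent_members)
        if kind == "root":
            return set(self.forest.tracks)
        if kind == "feature_interval":
            vals = self._feature_values([predicate["feature"]], members)[:, 0]
            lo = -np.inf if predicate["lo"] is None else predicate["lo"]
            hi = np.inf if predicate["hi"] is None else predicate["hi"]
            return {m for m, v in zip(members, vals) if lo <= v <= hi}
        if kind == "feature_polygon":
            from shapely import Point, Polygon

            vals = self._feature_values(predicate["features"], members)
            poly = Polygon([tuple(v) for v in predicate["vertices"]])
            return {
                m
                for m, (u, v) in zip(members, vals)
                if poly.covers(Point(u, v))
            }
        if kind == "position":
            frame = predicate["frame"]
            first, last = self.forest.frame_range()
            if not first <= frame <= last:
                raise ValueError(
                    f"position predicate frame {frame} outside forest interval "
                    f"[{first}, {last}]"
                )
            region = region_from_dict(predicate["region"])
            out = set()
            for m in members:
                tr = self.forest.tracks[m]
                if tr.has_frame(frame) and bool(
                    region.contains(tr.position_at(frame)[None, :])[0]
                ):
                    out.add(m)
            return out
        if kind == "cluster":
            assignment = self._cluster_assign(
                tuple(predicate["features"]), predicate["k"], tuple(members)
            )
            return {
                m for m, c in zip(members, assignment) if c == predicate["index"]
            }
        if kind == "combine":
            sets = [set(self.nodes[s].members) for s in predicate["sources"]]
            if predicate["op"] == "union":
                return set().union(*sets)
            if predicate["op"] == "intersection":
                return set.intersection(*sets)
            return sets[0] - sets[1]
        raise ValueError(f"unknown predicate kind {kind!r}")

    def _ancestors(self, nid: int) -> list[int]:
        path = []
        cur: int | None = nid
        while cur is not None:
            path.append(cur)
            cur = self.nodes[cur].parent_id
        return path

    def _lowest_common_ancestor(self, node_ids: Sequence[int]) -> int:
        paths = [self._ancestors(n) for n in node_ids]
        common = set(paths[0]).intersection(*[set(p) for p in paths[1:]])
        # the LCA is the common ancestor deepest on the first path
        for nid in paths[0]:
            if nid in common:
                return nid
        return self.root_id

    # -- invariants ----------------------------------------------------
    def verify(self) -> None:
        """Re-evaluate every predicate; raise if any member set drifted."""
        for nid, node in self.nodes.items():
            if node.parent_id is None:
                continue
            parent = self.nodes[node.parent_id]
            if not node.members <= parent.members:
                raise AssertionError(f"node {nid}: members escape parent")
            recomputed = self._eval_predicate(node.predicate, parent.members)
            if recomputed != set(node.members):
                raise AssertionError(
                    f"node {nid}: predicate re-evaluation changed the member set"
                )

    # -- serialization -------------------------------------------------
    def to_json(self, path: str | Path | None = None, include_members: bool = True):
        doc = {
            "root": self.root_id,
            "nodes": [
                {
                    "node_id": n.node_id,
                    "parent_id": n.parent_id,
                    "predicate": n.predicate,
                    "label": n.label,
                    **({"members": sorted(n.members)} if include_members else {}),
                }
                for n in self.nodes.values()
            ],
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return doc

    @classmethod
    def from_json(
        cls, doc: dict | str | Path, forest: LineageForest
    ) -> "SelectionTree":
        if not isinstance(doc, dict):
            doc = json.loads(Path(doc).read_text())
        tree = cls.__new__(cls)
        tree.forest = forest
        tree.nodes = {}
        tree._feature_cache = None
        tree._cluster_cache = {}
        for nd in doc["nodes"]:
            node = SelectionNode(
                nd["node_id"],
                nd["parent_id"],
                nd["predicate"],
                frozenset(nd.get("members", [])),
                nd.get("label", ""),
            )
            tree.nodes[node.node_id] = node
        tree.root_id = doc["root"]
        tree._next_id = max(tree.nodes) + 1
        return tree


def replay_tree(
    template: SelectionTree | dict,
    new_forest: LineageForest,
    overrides: dict[int, dict] | None = None,
) -> SelectionTree:
    """Re-run a recorded selection pipeline on another data set.

    Every node's predicate is re-evaluated against ``new_forest`` in
    creation order (parents first).  ``overrides`` patches stated
    predicate parameters per node id before evaluation (e.g. a shifted
    crop box for a differently oriented embryo).  Structure and labels
    are preserved; member sets are recomputed from scratch.
    """
    doc = template.to_json(include_members=False) if isinstance(template, SelectionTree) else template
    overrides = overrides or {}
    tree = SelectionTree(new_forest)
    # map template ids -> replayed ids (root maps to root)
    id_map: dict[int, int] = {}
    nodes = sorted(doc["nodes"], key=lambda nd: nd["node_id"])
    for nd in nodes:
        predicate = dict(nd["predicate"])
        predicate.update(overrides.get(nd["node_id"], {}))
        if predicate["kind"] == "root":
            id_map[nd["node_id"]] = tree.root_id
            tree.root.label = nd.get("label", tree.root.label)
            continue
        parent_id = id_map[nd["parent_id"]]
        if predicate["kind"] == "combine":
            predicate["sources"] = [id_map[s] for s in predicate["sources"]]
        try:
            members = tree._eval_predicate(
                predicate, tree.nodes[parent_id].members
            )
        except ValueError as err:
            raise ValueError(
                f"replay failed at node {nd['node_id']} "
                f"({nd.get('label') or predicate['kind']}): {err}"
            ) from err
        node = tree._add(parent_id, predicate, members, nd.get("label", ""))
        id_map[nd["node_id"]] = node.node_id
    return tree


# ---------------------------------------------------------------------------
# Deterministic k-means
# ---------------------------------------------------------------------------


def _deterministic_kmeans(X: np.ndarray, k: int) -> np.ndarray:
    """K-means with quantile-spread initial centres along the first
    principal axis; returns labels reordered by ascending cluster mean of
    the first feature column."""
    from sklearn.cluster import KMeans

    X = np.asarray(X, float)
    mean = X.mean(axis=0)
    Xc = X - mean
    # first principal axis (sign fixed for reproducibility)
    _, _, vt = np.linalg.svd(Xc, full_matrices=False)
    pc = vt[0]
    if pc[np.argmax(np.abs(pc))] < 0:
        pc = -pc
    proj = Xc @ pc
    if np.ptp(proj) < 1e-12:
        # all points coincide along every axis: any partition is as good as
        # any other; split deterministically by position in the member order
        return (np.arange(len(X)) * k) // len(X)
    qs = np.quantile(proj, (np.arange(k) + 0.5) / k)
    if len(np.unique(qs)) < k:
        # heavily tied projections: spread the duplicate centres slightly
        qs = qs + np.linspace(0.0, 1e-9 * max(np.ptp(proj), 1.0), k)
    centers = mean + np.outer(qs, pc)
    km = KMeans(n_clusters=k, init=centers, n_init=1, max_iter=300)
    labels = km.fit_predict(X)
    # stable ordering: ascending cluster mean of the first feature
    order = np.argsort(
        [X[labels == c, 0].mean() if np.any(labels == c) else np.inf for c in range(k)],
        kind="stable",
    )
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    return remap[labels]


# ---------------------------------------------------------------------------
# Label propagation
# ---------------------------------------------------------------------------


def propagate_labels(
    forest: LineageForest,
    labeled: dict[int, str],
    unlabeled: set[int] | Sequence[int] | None = None,
    k: int = 5,
    radius: float = 40.0,
) -> tuple[dict[int, str], list[int]]:
    """Assign unlabelled tracks to the predominant group of their
    spatiotemporally nearest labelled neighbours.

    At every frame an unlabelled track exists, its ``k`` nearest labelled
    detections within ``radius`` micrometres (same frame) each cast one
    vote for their group; votes are pooled over all frames of the track
    and the modal group wins, ties broken by smaller mean neighbour
    distance.  Tracks that never see a labelled detection within the
    radius stay unassigned and are returned separately.
    """
    from scipy.spatial import cKDTree

    if not labeled:
        raise ValueError("labeled must not be empty")
    if unlabeled is None:
        unlabeled = set(forest.tracks) - set(labeled)
    unlabeled = sorted(set(int(u) for u in unlabeled))

    by_frame_pts: dict[int, list[np.ndarray]] = {}
    by_frame_grp: dict[int, list[str]] = {}
    for tid, group in labeled.items():
        tr = forest.tracks.get(tid)
        if tr is None:
            raise KeyError(f"labeled track {tid} not in forest")
        for frame, p in zip(tr.frames, tr.positions):
            by_frame_pts.setdefault(int(frame), []).append(p)
            by_frame_grp.setdefault(int(frame), []).append(group)
    trees = {
        frame: (cKDTree(np.array(pts)), by_frame_grp[frame])
        for frame, pts in by_frame_pts.items()
    }

    assignments: dict[int, str] = {}
    unassigned: list[int] = []
    for tid in unlabeled:
        tr = forest.tracks[tid]
        votes: dict[str, int] = {}
        dist_sum: dict[str, float] = {}
        for frame, p in zip(tr.frames, tr.positions):
            hit = trees.get(int(frame))
            if hit is None:
                continue
            tree, groups = hit
            kk = min(k, tree.n)
            dists, idxs = tree.query(p, k=kk, distance_upper_bound=radius)
            dists = np.atleast_1d(dists)
            idxs = np.atleast_1d(idxs)
            for d, i in zip(dists, idxs):
                if not np.isfinite(d):
                    continue
                g = groups[i]
                votes[g] = votes.get(g, 0) + 1
                dist_sum[g] = dist_sum.get(g, 0.0) + float(d)
        if not votes:
            unassigned.append(tid)
            continue
        best = min(
            votes,
            key=lambda g: (-votes[g], dist_sum[g] / votes[g], g),
        )
        assignments[tid] = best
    return assignments, unassigned
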