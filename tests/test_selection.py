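"""Selection trees, clustering, replay and label propagation."""

import numpy as np
import pytest

from trajkit.model import Box, PolygonRegion
from trajkit.selection import SelectionTree, propagate_labels, replay_tree

from conftest import make_forest, make_track


def _ray_cast_inside(poly, x, y):
    """Independent point-in-polygon oracle (ray casting)."""
    inside = False
    n = len(poly)
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            xi = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < xi:
                inside = not inside
    return inside


def _endpoint_forest(xs):
    """One single-step track per x: ends at (x, 0, 0)."""
    return make_forest(
        *[
            make_track(i + 1, 0, [[0.0, 0.0, 0.0], [float(x), 0.0, 0.0]])
            for i, x in enumerate(xs)
        ]
    )


class TestFeatureSelection:
    def test_interval_on_end_x(self):
        tree = SelectionTree(_endpoint_forest([-2, -1, 3, 5]))
        node = tree.select_by_feature(tree.root, "end_position_x", interval=(0, None))
        assert node.members == {3, 4}

    def test_unbounded_interval_is_identity(self):
        tree = SelectionTree(_endpoint_forest([-2, -1, 3, 5]))
        node = tree.select_by_feature(tree.root, "end_position_x", interval=(None, None))
        assert node.members == tree.root.members

    def test_unknown_feature(self):
        tree = SelectionTree(_endpoint_forest([1.0]))
        with pytest.raises(KeyError):
            tree.select_by_feature(tree.root, "bogus", interval=(0, 1))

    def test_polygon_against_ray_cast_oracle(self):
        rng = np.random.default_rng(11)
        tracks = []
        for i in range(30):
            # displacement_ratio in [0,1] x mean_speed: random elbows
            pos = rng.normal(0, 3, (6, 3))
            tracks.append(make_track(i + 1, 0, pos))
        forest = make_forest(*tracks)
        tree = SelectionTree(forest)
        poly = [(0.1, 0.5), (0.9, 0.2), (0.9, 3.5), (0.1, 3.0)]
        node = tree.select_by_feature(
            tree.root, ["displacement_ratio", "mean_speed"], polygon=poly
        )
        table = tree.feature_table()
        expect = {
            tid
            for tid in forest.tracks
            if _ray_cast_inside(
                poly,
                table.loc[tid, "displacement_ratio"],
                table.loc[tid, "mean_speed"],
            )
        }
        assert node.members == expect


class TestPositionSelection:
    def test_box_containing_all(self):
        forest = _endpoint_forest([1, 2, 3])
        tree = SelectionTree(forest)
        node = tree.select_by_position(
            tree.root, 1, Box((-10, -10, -10), (10, 10, 10))
        )
        assert node.members == set(forest.tracks)

    def test_half_plane_split(self):
        xs = [-4, -3, -2, -1, -0.5, 1, 2, 3, 4]
        tree = SelectionTree(_endpoint_forest(xs))
        node = tree.select_by_position(
            tree.root, 1, Box((0, -1, -1), (np.inf, 1, 1))
        )
        assert len(node.members) == 4

    def test_empty_polygon_selects_nothing(self):
        tree = SelectionTree(_endpoint_forest([1, 2]))
        tiny = PolygonRegion(((90, 90), (91, 90), (91, 91)), axis="z")
        node = tree.select_by_position(tree.root, 0, tiny)
        assert node.members == set()

    def test_frame_outside_interval_rejected(self):
        tree = SelectionTree(_endpoint_forest([1]))
        with pytest.raises(ValueError, match="outside"):
            tree.select_by_position(tree.root, 99, Box((0, 0, 0), (1, 1, 1)))


class TestClustering:
    def test_well_separated_1d(self):
        # ratio-like values in two tight groups
        xs = [0.05, 0.10, 0.12, 0.90, 0.95]
        tracks = []
        for i, r in enumerate(xs):
            # straight two-step track scaled so displacement_ratio == r is
            # awkward; cluster instead on end_position_x which equals xs
            tracks.append(make_track(i + 1, 0, [[0, 0, 0], [r, 0, 0]]))
        tree = SelectionTree(make_forest(*tracks))
        lo, hi = tree.cluster_members(tree.root, ["end_position_x"], 2)
        assert lo.members == {1, 2, 3}
        assert hi.members == {4, 5}

    def test_singletons_when_k_equals_n(self):
        tree = SelectionTree(_endpoint_forest([1, 5, 9]))
        nodes = tree.cluster_members(tree.root, ["end_position_x"], 3)
        assert sorted(len(n.members) for n in nodes) == [1, 1, 1]

    def test_children_partition_parent(self):
        rng = np.random.default_rng(5)
        tree = SelectionTree(_endpoint_forest(rng.normal(0, 4, 40)))
        nodes = tree.cluster_members(tree.root, ["end_position_x"], 4)
        union = set().union(*[n.members for n in nodes])
        assert union == tree.root.members
        assert sum(len(n.members) for n in nodes) == len(union)

    def test_too_few_members(self):
        tree = SelectionTree(_endpoint_forest([1, 2]))
        with pytest.raises(ValueError, match="clusters"):
            tree.cluster_members(tree.root, ["end_position_x"], 3)

    def test_gaussian_blobs_match_lloyd_oracle(self):
        rng = np.random.default_rng(17)
        n = 200
        labels_true = np.repeat([0, 1], n // 2)
        centers = np.array([[0.0, 0.0], [10.0, 0.0]])
        pts = centers[labels_true] + rng.normal(0, 0.5, (n, 2))
        tracks = [
            make_track(i + 1, 0, [[0, 0, 0], [pts[i, 0], pts[i, 1], 0.0]])
            for i in range(n)
        ]
        tree = SelectionTree(make_forest(*tracks))
        lo, hi = tree.cluster_members(
            tree.root, ["end_position_x", "end_position_y"], 2
        )
        got = np.array([0 if i + 1 in lo.members else 1 for i in range(n)])
        assert np.mean(got == labels_true) >= 0.99
        # brute-force Lloyd oracle run to convergence from the true centers
        c = centers.copy()
        for _ in range(100):
            d = np.linalg.norm(pts[:, None] - c[None], axis=2)
            lab = d.argmin(axis=1)
            c = np.array([pts[lab == j].mean(axis=0) for j in (0, 1)])
        assert np.mean(got == lab) >= 0.99


class TestCombineAndReplay:
    def _tree(self):
        tree = SelectionTree(_endpoint_forest([-2, -1, 1, 2, 3]))
        neg = tree.select_by_feature(tree.root, "end_position_x", interval=(None, 0))
        pos = tree.select_by_feature(tree.root, "end_position_x", interval=(0, None))
        return tree, neg, pos

    def test_union_intersection_difference(self):
        tree, neg, pos = self._tree()
        u = tree.combine_nodes([neg.node_id, pos.node_id], "union")
        assert u.members == tree.root.members
        i = tree.combine_nodes([neg.node_id, neg.node_id], "intersection")
        assert i.members == neg.members
        d = tree.combine_nodes([u.node_id, neg.node_id], "difference")
        assert d.members == pos.members
        tree.verify()

    def test_combined_node_parented_at_lca(self):
        tree, neg, pos = self._tree()
        u = tree.combine_nodes([neg.node_id, pos.node_id], "union")
        assert u.parent_id == tree.root_id

    def test_cross_tree_combination_rejected(self):
        tree, neg, _ = self._tree()
        with pytest.raises(KeyError):
            tree.combine_nodes([neg.node_id, 999], "union")

    def test_replay_on_source_is_identity(self):
        tree, neg, pos = self._tree()
        tree.combine_nodes([neg.node_id, pos.node_id], "union")
        replayed = replay_tree(tree, tree.forest)
        for nid, node in tree.nodes.items():
            assert replayed.nodes[nid].members == node.members

    def test_replay_threshold_can_go_empty(self):
        tree, neg, _ = self._tree()
        other = _endpoint_forest([5, 6, 7])  # nothing negative
        replayed = replay_tree(tree, other)
        assert replayed.nodes[neg.node_id].members == set()

    def test_replay_with_override(self):
        tree, neg, _ = self._tree()
        replayed = replay_tree(tree, tree.forest, overrides={neg.node_id: {"hi": -1.5}})
        assert replayed.nodes[neg.node_id].members == {1}

    def test_json_roundtrip(self, tmp_path):
        tree, neg, pos = self._tree()
        tree.to_json(tmp_path / "tree.json")
        loaded = SelectionTree.from_json(tmp_path / "tree.json", tree.forest)
        assert loaded.nodes[neg.node_id].members == neg.members
        loaded.verify()


class TestPropagation:
    def test_unanimous_neighborhood(self):
        f = make_forest(
            make_track(1, 0, [[0, 0, 0], [1, 0, 0]]),
            make_track(2, 0, [[2, 0, 0], [3, 0, 0]]),
            make_track(3, 0, [[1, 1, 0], [2, 1, 0]]),
        )
        got, unassigned = propagate_labels(f, {1: "A", 2: "A"}, {3})
        assert got == {3: "A"}
        assert unassigned == []

    def test_out_of_range_reported_unassigned(self):
        f = make_forest(
            make_track(1, 0, [[0, 0, 0]]),
            make_track(2, 0, [[500, 0, 0]]),
        )
        got, unassigned = propagate_labels(f, {1: "A"}, {2}, radius=40.0)
        assert got == {}
        assert unassigned == [2]

    def test_majority_vote_matches_brute_force(self):
        # 5-track toy: unlabeled track 5 sits nearer the B pair early on but
        # accumulates more A votes over its lifetime
        f = make_forest(
            make_track(1, 0, np.tile([0.0, 0, 0], (5, 1))),
            make_track(2, 0, np.tile([2.0, 0, 0], (5, 1))),
            make_track(3, 0, np.tile([30.0, 0, 0], (2, 1))),
            make_track(4, 0, np.tile([32.0, 0, 0], (2, 1))),
            make_track(5, 0, [[20.0, 0, 0]] * 2 + [[5.0, 0, 0]] * 3),
        )
        labeled = {1: "A", 2: "A", 3: "B", 4: "B"}
        got, _ = propagate_labels(f, labeled, {5}, k=2, radius=40.0)
        # brute force: tally the 2 nearest labelled detections per frame
        votes = {"A": 0, "B": 0}
        for frame in range(5):
            p = f.tracks[5].position_at(frame)
            cands = []
            for tid, grp in labeled.items():
                tr = f.tracks[tid]
                if tr.has_frame(frame):
                    cands.append((np.linalg.norm(tr.position_at(frame) - p), grp))
            for d, grp in sorted(cands)[:2]:
                if d <= 40:
                    votes[grp] += 1
        assert got[5] == max(votes, key=votes.get) == "A"

    def test_relabeling_invariance(self, embryo_sigma1):
        forest, truth = embryo_sigma1
        rng = np.random.default_rng(0)
        tids = sorted(forest.tracks)
        labeled = {t: truth.labels[t] for t in tids[: len(tids) // 2]}
        unlabeled = set(tids[len(tids) // 2 :])
        got1, un1 = propagate_labels(forest, labeled, unlabeled)
        swapped = {t: {"hypoblast": "B", "epiblast": "A"}[l] for t, l in labeled.items()}
        got2, un2 = propagate_labels(forest, swapped, unlabeled)
        assert un1 == un2
        for t in got1:
            assert {"hypoblast": "B", "epiblast": "A"}[got1[t]] == got2[t]

    def test_empty_labeled_rejected(self):
        f = make_forest(make_track(1, 0, [[0, 0, 0]]))
        with pytest.raises(ValueError):
            propagate_labels(f, {}, {1})
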