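"""Candidate scoring, automatic linking and the guided review session."""

import itertools

import numpy as np
import pytest

from trajkit.curation import (
    CurationSession,
    QueueExhausted,
    auto_link,
    curation_summary,
    find_candidates,
    replay_decision_log,
)
from trajkit.simulate import EmbryoSimConfig, fragment_tracks, simulate_embryo

from conftest import make_forest, make_track


def _frag(tid, start, xs, intensity=None, parent=None):
    xs = np.asarray(xs, float)
    inten = None if intensity is None else np.full(len(xs), float(intensity))
    return make_track(tid, start, xs, intensities=inten, parent_id=parent)


class TestFindCandidates:
    def test_dominant_candidate_ranks_first(self):
        f = make_forest(
            _frag(1, 0, np.arange(6.0), intensity=100),
            _frag(2, 6, [7.0, 8.0], intensity=100),  # close, same intensity
            _frag(3, 6, [15.0, 16.0], intensity=150),  # far, different
        )
        cands = find_candidates(f, 1, max_gap=2, max_radius=30)
        assert [c.start_track_id for c in cands] == [2, 3]
        assert cands[0].distance < cands[1].distance

    def test_empty_when_nothing_in_radius(self):
        f = make_forest(_frag(1, 0, np.arange(6.0)), _frag(2, 6, [500.0, 501.0]))
        assert find_candidates(f, 1, max_radius=10) == []

    def test_equal_distance_ordered_by_intensity(self):
        f = make_forest(
            _frag(1, 0, np.arange(6.0), intensity=100),
            _frag(2, 6, [[6.0, 2.0, 0.0], [7.0, 2.0, 0.0]], intensity=150),
            _frag(3, 6, [[6.0, -2.0, 0.0], [7.0, -2.0, 0.0]], intensity=100),
            _frag(4, 6, [[6.0, 0.0, 2.0], [7.0, 0.0, 2.0]], intensity=105),
        )
        cands = find_candidates(f, 1, max_radius=30)
        assert [c.start_track_id for c in cands] == [3, 4, 2]

    def test_backward_direction(self):
        f = make_forest(_frag(1, 0, np.arange(6.0)), _frag(2, 7, [8.0, 9.0]))
        cands = find_candidates(f, 2, direction="backward", max_gap=2, max_radius=30)
        assert len(cands) == 1
        assert cands[0].end_track_id == 1
        assert cands[0].gap == 2

    def test_children_and_parents_excluded(self):
        f = make_forest(
            _frag(1, 0, np.arange(5.0)),
            _frag(2, 5, [5.0, 6.0], parent=1),
            _frag(3, 0, np.arange(5.0) + 0.5),
        )
        # track 2 has a parent: not a loose start for track 3
        assert find_candidates(f, 3, max_gap=2, max_radius=50) == []

    def test_unknown_track(self):
        f = make_forest(_frag(1, 0, [0.0, 1.0]))
        with pytest.raises(KeyError):
            find_candidates(f, 99)


class TestAutoLink:
    def test_single_link(self):
        f = make_forest(_frag(1, 0, np.arange(6.0)), _frag(2, 6, [6.0, 7.0]))
        out, log = auto_link(f, max_gap=1, distance_threshold=5.0)
        assert out.n_tracks == 1
        assert len(log) == 1
        assert log[0]["distance"] == pytest.approx(1.0)

    def test_threshold_respected(self):
        f = make_forest(_frag(1, 0, np.arange(6.0)), _frag(2, 6, [6.0, 7.0]))
        out, log = auto_link(f, max_gap=1, distance_threshold=0.5)
        assert out.n_tracks == 2
        assert log == []

    def test_competition_resolved_toward_minimum_score(self):
        # two ends compete for one nearby start; the loser takes its own
        # next candidate
        f = make_forest(
            _frag(1, 0, np.arange(6.0)),  # ends at x = 5
            _frag(2, 0, np.arange(6.0) + 1.0),  # ends at x = 6
            _frag(3, 6, [6.0, 7.0]),  # start at 6: dist 1 from end 1, 0 from end 2
            _frag(4, 6, [4.5, 5.5]),  # start at 4.5: dist 0.5 from end 1
        )
        out, log = auto_link(f, max_gap=1, distance_threshold=5.0)
        linked = {(e["end_track_id"], e["start_track_id"]) for e in log}
        assert (2, 3) in linked  # closer pair wins the contested start
        assert (1, 4) in linked  # loser links to its next candidate

    def test_matches_bruteforce_assignment(self):
        rng = np.random.default_rng(23)
        for trial in range(20):
            n_end, n_start = rng.integers(1, 5, 2)
            ends = [
                _frag(i + 1, 0, np.column_stack([
                    np.zeros(3), np.zeros(3), np.zeros(3)
                ]) + rng.uniform(0, 10, 3))
                for i in range(n_end)
            ]
            starts = [
                _frag(100 + i, 3, np.tile(rng.uniform(0, 10, 3), (2, 1)))
                for i in range(n_start)
            ]
            f = make_forest(*(ends + starts))
            thr = 8.0
            out, log = auto_link(f, max_gap=1, distance_threshold=thr)
            got = {(e["end_track_id"], e["start_track_id"]) for e in log}
            # brute force: enumerate all one-to-one assignments of feasible
            # pairs; maximise link count, then minimise total distance
            feas = {}
            for e in ends:
                for s in starts:
                    d = float(np.linalg.norm(s.start_position - e.end_position))
                    if d < thr:
                        feas[(e.track_id, s.track_id)] = d
            best = (0, 0.0, frozenset())
            eids = [e.track_id for e in ends]
            sids = [s.track_id for s in starts]
            for r in range(min(len(eids), len(sids)), -1, -1):
                candidates = []
                for esub in itertools.permutations(sids, r):
                    for echoice in itertools.combinations(eids, r):
                        pairs = list(zip(echoice, esub))
                        if all(p in feas for p in pairs):
                            candidates.append(
                                (sum(feas[p] for p in pairs), frozenset(pairs))
                            )
                if candidates:
                    score, pairs = min(candidates)
                    best = (r, score, pairs)
                    break
            assert got == set(best[2]), f"trial {trial}"
            assert len(log) == best[0]

    def test_detection_count_conserved(self, embryo_sigma1):
        forest, _ = embryo_sigma1
        frag, _ = fragment_tracks(forest, break_rate=0.5, gap=1, seed=2)
        assert frag.n_detections == forest.n_detections
        linked, _ = auto_link(frag, max_gap=1, distance_threshold=6.0)
        synthetic = sum(
            int(tr.synthetic.sum()) for tr in linked.tracks.values()
        )
        assert linked.n_detections - synthetic == forest.n_detections

    def test_one_to_one_never_reuses_fragments(self):
        forest, _ = simulate_embryo(
            EmbryoSimConfig(seed=9, n_cells=40, n_frames=30)
        )
        frag, _ = fragment_tracks(forest, break_rate=0.8, gap=1, seed=9)
        _, log = auto_link(frag, max_gap=2, distance_threshold=10.0)
        ends = [e["end_track_id"] for e in log]
        starts = [e["start_track_id"] for e in log]
        assert len(ends) == len(set(ends))
        assert len(starts) == len(set(starts))


class TestSession:
    def _three_fragments(self):
        return make_forest(
            _frag(1, 0, np.arange(4.0)),
            _frag(2, 4, np.arange(4.0) + 4),
            _frag(3, 8, np.arange(4.0) + 8),
            _frag(4, 0, np.arange(4.0) + 100),
        )

    def test_depth_first_follows_linked_track(self):
        s = CurationSession(self._three_fragments(), mode="depth-first")
        tid, cands = s.next_review_item()
        assert tid == 1
        s.apply_decision(1)  # link 1 -> 2
        tid2, cands2 = s.next_review_item()
        assert tid2 == 1  # the extended track's new end is next
        assert cands2[0].start_track_id == 3

    def test_breadth_first_visits_frames_in_order(self):
        f = make_forest(
            _frag(1, 0, np.arange(4.0)),
            _frag(2, 0, np.arange(4.0) + 50),
            _frag(3, 0, np.arange(8.0) + 100),
        )
        s = CurationSession(f, mode="breadth-first")
        order = []
        for _ in range(3):
            tid, _ = s.next_review_item()
            order.append(tid)
            s.apply_decision("reject")
        assert order == [1, 2, 3]  # both frame-3 ends before the frame-7 end

    def test_backward_depth_first_walks_predecessor_chain(self):
        s = CurationSession(
            self._three_fragments(),
            mode="depth-first",
            direction="backward",
            selection={3},
        )
        tid, cands = s.next_review_item()
        assert tid == 3
        assert cands[0].end_track_id == 2
        s.apply_decision(1)  # merge 2 <- 3
        tid2, cands2 = s.next_review_item()
        assert tid2 == 2
        assert cands2[0].end_track_id == 1
        s.apply_decision(1)
        assert s.forest.n_tracks == 2

    def test_rank_choice_merges_and_logs(self):
        s = CurationSession(self._three_fragments())
        tid, cands = s.next_review_item()
        s.apply_decision(1)
        assert s.decisions[-1].rank == 1
        assert s.decisions[-1].distance == pytest.approx(cands[0].distance)
        assert 2 not in s.forest.tracks

    def test_reject_removes_from_queue(self):
        s = CurationSession(self._three_fragments())
        tid, _ = s.next_review_item()
        s.apply_decision("reject")
        assert s.forest.n_tracks == 4
        assert all(d.choice == "reject" for d in s.decisions)

    def test_rank_out_of_range(self):
        s = CurationSession(self._three_fragments())
        s.next_review_item()
        with pytest.raises(IndexError):
            s.apply_decision(9)

    def test_exhausted_queue_signals(self):
        s = CurationSession(make_forest(_frag(1, 0, [0.0, 1.0])))
        tid, _ = s.next_review_item()
        s.apply_decision("reject")
        with pytest.raises(QueueExhausted):
            s.next_review_item()

    def test_log_replay_reproduces_forest(self, tmp_path):
        f = self._three_fragments()
        s = CurationSession(f, mode="depth-first")
        s.next_review_item()
        s.apply_decision(1)
        s.next_review_item()
        s.apply_decision(1)
        s.next_review_item()
        s.apply_decision("reject")
        s.write_log(tmp_path / "log.jsonl")

        replayed = replay_decision_log(f, tmp_path / "log.jsonl", mode="depth-first")
        assert set(replayed.tracks) == set(s.forest.tracks)
        for tid, tr in s.forest.tracks.items():
            np.testing.assert_array_equal(
                tr.detection_ids, replayed.tracks[tid].detection_ids
            )

    def test_summary_table(self):
        s = CurationSession(self._three_fragments())
        s.next_review_item()
        s.apply_decision(1)
        s.next_review_item()
        s.apply_decision("reject")
        table = curation_summary(s.decision_log())
        assert list(table["choice"]) == ["rank", "reject"]
        assert table.loc[0, "rank"] == 1
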