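"""Track features, smoothing and group aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trajkit.features import (
    aggregate_group,
    single_features,
    smooth_tracks,
    timeseries_features,
)

from conftest import make_forest, make_track


@pytest.fixture()
def elbow_forest():
    """The worked right-angle example: (0,0,0) -> (1,0,0) -> (1,1,0)."""
    return make_forest(make_track(1, 0, [[0, 0, 0], [1, 0, 0], [1, 1, 0]]))


class TestSingleFeatures:
    def test_worked_right_angle_example(self, elbow_forest):
        row = single_features(elbow_forest).loc[1]
        assert row["path_length"] == pytest.approx(2.0)
        assert row["displacement"] == pytest.approx(np.sqrt(2), abs=1e-9)
        assert row["displacement_ratio"] == pytest.approx(np.sqrt(2) / 2, abs=1e-9)
        np.testing.assert_allclose(
            [row["centroid_x"], row["centroid_y"], row["centroid_z"]],
            [2 / 3, 1 / 3, 0],
            atol=1e-12,
        )
        assert row["mean_speed"] == pytest.approx(1.0)
        assert row["mean_angle_change"] == pytest.approx(np.pi / 2, abs=1e-9)
        assert row["time_span"] == 3

    def test_collinear_track(self):
        f = make_forest(make_track(1, 0, [0.0, 1.0, 2.0]))
        row = single_features(f).loc[1]
        assert row["displacement_ratio"] == pytest.approx(1.0, abs=1e-12)
        assert row["mean_angle_change"] == pytest.approx(0.0, abs=1e-12)

    def test_closed_loop_ratio_zero(self):
        square = [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0], [0, 0, 0]]
        f = make_forest(make_track(1, 0, square))
        assert single_features(f).loc[1, "displacement_ratio"] == pytest.approx(0.0)

    def test_stationary_track_ratio_is_one(self):
        f = make_forest(make_track(1, 0, np.zeros((4, 3))))
        assert single_features(f).loc[1, "displacement_ratio"] == 1.0

    def test_unknown_feature_lists_registry(self, elbow_forest):
        with pytest.raises(KeyError, match="displacement_ratio"):
            single_features(elbow_forest, ["not_a_feature"])

    def test_speed_span_path_identity(self, embryo_sigma1):
        forest, _ = embryo_sigma1
        table = single_features(forest, ["mean_speed", "time_span", "path_length"])
        np.testing.assert_allclose(
            table["mean_speed"] * (table["time_span"] - 1),
            table["path_length"],
            rtol=1e-12,
        )

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_ratio_bounded_random_tracks(self, seed):
        rng = np.random.default_rng(seed)
        pos = rng.normal(0, 5, size=(rng.integers(2, 30), 3))
        f = make_forest(make_track(1, 0, pos))
        r = single_features(f, ["displacement_ratio"]).loc[1, "displacement_ratio"]
        assert 0.0 <= r <= 1.0 + 1e-12

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(7)
        pos = rng.normal(0, 5, size=(20, 3))
        from scipy.spatial.transform import Rotation

        R = Rotation.random(random_state=3).as_matrix()
        shift = np.array([12.0, -7.0, 3.0])
        f1 = make_forest(make_track(1, 0, pos))
        f2 = make_forest(make_track(1, 0, pos @ R.T + shift))
        t1 = single_features(f1, ["path_length", "displacement"])
        t2 = single_features(f2, ["path_length", "displacement"])
        np.testing.assert_allclose(t1.values, t2.values, rtol=1e-9)


class TestSmoothing:
    def test_constant_track_unchanged(self):
        f = make_forest(make_track(1, 0, np.tile([1.0, 2.0, 3.0], (50, 1))))
        out = smooth_tracks(f, order=2, cutoff=0.01)
        np.testing.assert_allclose(
            out.tracks[1].positions, f.tracks[1].positions, atol=1e-9
        )

    def test_linear_track_passes_in_interior(self):
        # the settling length at cutoff 0.01 is ~600 samples, so the track
        # must be long enough for the middle third to be transient-free
        n = 3000
        pos = np.column_stack([np.arange(n, dtype=float) * 0.5, np.zeros(n), np.zeros(n)])
        f = make_forest(make_track(1, 0, pos))
        out = smooth_tracks(f)
        mid = slice(n // 3, 2 * n // 3)
        np.testing.assert_allclose(
            out.tracks[1].positions[mid], pos[mid], atol=1e-6
        )

    def test_short_track_fallback_notice(self):
        f = make_forest(make_track(1, 0, np.arange(3.0)))
        out = smooth_tracks(f)
        assert any("moving average" in msg for msg in out.log)
        # window-3 average of [0, 1, 2] keeps the middle point
        assert out.tracks[1].positions[1, 0] == pytest.approx(1.0)

    def test_white_noise_variance_reduced(self):
        rng = np.random.default_rng(42)
        noise = rng.normal(0, 1, size=(500, 3))
        f = make_forest(make_track(1, 0, noise))
        out = smooth_tracks(f)
        assert out.tracks[1].positions.var(axis=0).max() < noise.var(axis=0).min()

    def test_invalid_cutoff_rejected(self):
        f = make_forest(make_track(1, 0, np.arange(20.0)))
        with pytest.raises(ValueError):
            smooth_tracks(f, cutoff=1.5)


class TestTimeseries:
    def test_density_counts_neighbors_in_sphere(self):
        # 3 tracks within 40 um of track 1 at frame 0, one far away
        f = make_forest(
            make_track(1, 0, [[0, 0, 0]]),
            make_track(2, 0, [[10, 0, 0]]),
            make_track(3, 0, [[0, 39, 0]]),
            make_track(4, 0, [[0, 0, 30]]),
            make_track(5, 0, [[100, 100, 100]]),
        )
        ts = timeseries_features(f, ["density"])
        assert ts.loc[(1, 0), "density"] == 3
        assert ts.loc[(5, 0), "density"] == 0

    def test_density_symmetric(self, embryo_sigma1):
        forest, _ = embryo_sigma1
        from trajkit.model import crop_time

        small = crop_time(forest, 0, 2)
        ts = timeseries_features(small, ["density"], {"radius": 15.0})
        # symmetry: total neighbour count equals twice the number of pairs,
        # hence per-frame sums are even
        sums = ts["density"].groupby(level="frame").sum()
        assert (sums % 2 == 0).all()

    def test_distance_to_reference_345(self):
        f = make_forest(make_track(1, 0, [[3, 4, 0]]))
        ts = timeseries_features(
            f, ["distance_to_reference"], {"reference": (0, 0, 0)}
        )
        assert ts.loc[(1, 0), "distance_to_reference"] == pytest.approx(5.0)

    def test_distance_requires_reference(self):
        f = make_forest(make_track(1, 0, [[0, 0, 0]]))
        with pytest.raises(ValueError, match="reference"):
            timeseries_features(f, ["distance_to_reference"])

    def test_keys_subset_of_detections(self, embryo_sigma1):
        forest, _ = embryo_sigma1
        from trajkit.model import crop_time

        small = crop_time(forest, 0, 3)
        ts = timeseries_features(small, ["speed", "density"])
        det = {
            (tid, int(fr))
            for tid, tr in small.tracks.items()
            for fr in tr.frames
        }
        assert set(ts.index) <= det


class TestAggregation:
    def _series(self, values_by_track):
        idx, vals = [], []
        for tid, series in values_by_track.items():
            for frame, v in enumerate(series):
                idx.append((tid, frame))
                vals.append(float(v))
        return pd.Series(
            vals, index=pd.MultiIndex.from_tuples(idx, names=["track_id", "frame"])
        )

    def test_median(self):
        s = self._series({1: [1], 2: [2], 3: [9]})
        out = aggregate_group(s, {1, 2, 3}, "median")
        assert out.loc[0, "value"] == 2
        assert out.loc[0, "n"] == 3

    def test_single_member_identity(self):
        s = self._series({1: [5, 6, 7], 2: [0, 0, 0]})
        out = aggregate_group(s, {1}, "mean")
        np.testing.assert_allclose(out["value"].values, [5, 6, 7])

    def test_quantile_linear_interpolation(self):
        s = self._series({1: [1], 2: [2], 3: [3], 4: [4]})
        out = aggregate_group(s, {1, 2, 3, 4}, 0.25)
        # independent oracle: numpy's linear-interpolation quantile
        assert out.loc[0, "value"] == pytest.approx(
            np.quantile([1, 2, 3, 4], 0.25)
        )
        assert out.loc[0, "value"] == pytest.approx(1.75)

    def test_absent_frames_missing_from_output(self):
        s = self._series({1: [1.0, 2.0], 2: [3.0]})
        out = aggregate_group(s, {2}, "median")
        assert list(out.index) == [0]

    def test_invalid_statistic(self):
        s = self._series({1: [1.0]})
        with pytest.raises(ValueError):
            aggregate_group(s, {1}, "mode")
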