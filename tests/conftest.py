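import numpy as np
import pytest

from trajkit.model import LineageForest, Track


def make_track(track_id, start_frame, positions, intensities=None, parent_id=None,
               child_ids=None, det_start=None):
    positions = np.asarray(positions, float)
    if positions.ndim == 1:  # 1D shorthand: x values, y = z = 0
        positions = np.column_stack(
            [positions, np.zeros(len(positions)), np.zeros(len(positions))]
        )
    n = len(positions)
    if det_start is None:
        det_start = track_id * 10_000 + 1
    return Track(
        track_id,
        start_frame,
        positions,
        np.arange(det_start, det_start + n, dtype=np.int64),
        None if intensities is None else np.asarray(intensities, float),
        parent_id=parent_id,
        child_ids=child_ids,
    )


def make_forest(*tracks, **kwargs):
    forest = LineageForest(tracks, **kwargs)
    for tr in forest.tracks.values():
        if tr.parent_id is not None:
            forest.tracks[tr.parent_id].child_ids.add(tr.track_id)
    forest.validate()
    return forest


@pytest.fixture(scope="session")
def embryo_sigma1():
    """Default-condition synthetic gastrula (sigma = 1 um), seed 1."""
    from trajkit.simulate import EmbryoSimConfig, simulate_embryo

    return simulate_embryo(EmbryoSimConfig(seed=1))


@pytest.fixture(scope="session")
def embryo_noiseless():
    """Noise-free synthetic gastrula without divisions, seed 1."""
    from trajkit.simulate import EmbryoSimConfig, simulate_embryo

    return simulate_embryo(
        EmbryoSimConfig(seed=1, noise_sigma=0.0, division_rate=0.0)
    )
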