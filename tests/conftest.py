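import numpy as np
import pytest

from qrentrain import synthetic_data
from qrentrain.io_formats import Keypoint, KeypointTrack, Role, Segment


@pytest.fixture(scope="session")
def small_study():
    """A small full-modality study shared by integration tests."""
    cfg = synthetic_data.SyntheticConfig(
        n_dyads=3, pairs_per_dyad=4, seed=123,
        duration_range_ms=(500, 1500),
        generate_audio=True, p_missing_item=0.05,
    )
    return synthetic_data.generate_study(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_track(positions, confidence=None, speaker="s1",
               keypoint=Keypoint.NOSE, frame_rate=25.0):
    positions = np.asarray(positions, dtype=float)
    if confidence is None:
        confidence = np.ones(len(positions))
    return KeypointTrack(speaker_id=speaker, keypoint=keypoint,
                         positions=positions, confidence=confidence,
                         frame_rate=frame_rate)


def make_segment(seg_id="s", dyad="d1", speaker="s1", role=Role.QUESTION,
                 onset=0, offset=1000):
    return Segment(segment_id=seg_id, dyad_id=dyad, speaker_id=speaker,
                   role=role, onset=onset, offset=offset)
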