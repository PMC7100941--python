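import numpy as np
import pytest

from wormetho import synthworm as sw


@pytest.fixture(scope="session")
def forward_schedule():
    return sw.LocomotionSchedule(
        [sw.ScheduleSegment("forward", 10.0, 0.15, 0.5, 0.7)],
        seed=2, heading_noise=0.0)


@pytest.fixture(scope="session")
def forward_truth(forward_schedule):
    return sw.generate_track(forward_schedule)


@pytest.fixture(scope="session")
def escape_truth():
    """Reverse -> turn -> forward escape motif with a stimulus anchor."""
    return sw.generate_track(sw.escape_schedule(seed=1))


@pytest.fixture(scope="session")
def escape_recording(escape_truth):
    return sw.render_frames(escape_truth, sw.Optics(noise_frac=0.02, seed=1))


@pytest.fixture(scope="session")
def clean_recording(forward_truth):
    """Noiseless, texture-free render of pure forward crawling."""
    return sw.render_frames(
        forward_truth,
        sw.Optics(noise_frac=0.0, texture_amp=0.0, dtype="float32", seed=0))


def truth_skeletons_px(truth, recording):
    """Ground-truth skeletons of each frame in that frame's pixel grid."""
    shape = recording.stack[0].shape
    return np.array([
        sw.world_to_pixel(truth.skeletons_mm[i], truth.stage_mm[i],
                          truth.pixel_size_mm, shape)
        for i in range(truth.n_frames)
    ])
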