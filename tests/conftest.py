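import numpy as np
import pytest

from tubesort.imaging import measure_intensities, segment_rois
from tubesort.synthetic import (
    BuckleGroundTruth,
    ImagingGroundTruth,
    generate_buckled_membrane,
    generate_tube_frame,
)


@pytest.fixture(scope="session")
def noise_free_gt():
    return ImagingGroundTruth(noise_model="none")


@pytest.fixture(scope="session")
def noise_free_frame(noise_free_gt):
    return generate_tube_frame(noise_free_gt)


@pytest.fixture(scope="session")
def noise_free_measurement(noise_free_frame):
    return measure_intensities(noise_free_frame, segment_rois(noise_free_frame))


@pytest.fixture(scope="session")
def small_buckle():
    """Short unbiased buckle trajectory shared across read-only tests."""
    gt = BuckleGroundTruth(n_frames=40, lipid_count=400, seed=42)
    return gt, generate_buckled_membrane(gt)


def measure(frame, **kw):
    """Segment with auto hints and measure in one step (test helper)."""
    return measure_intensities(frame, segment_rois(frame, **kw))
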