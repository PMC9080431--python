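import numpy as np
import pytest
from hypothesis import settings

from arenatrack import (
    AnnotationSeries,
    BoundingBox,
    DetectionRecord,
    DetectionSeries,
    NoiseParams,
    SimulationParams,
    simulate_video,
)
from arenatrack.simulate import NOISELESS

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def noiseless_video():
    """A ten-minute synthetic video with a perfect detector."""
    sim = SimulationParams(duration=600, seed=7)
    return sim, *simulate_video(sim, NOISELESS, "v0")


@pytest.fixture(scope="session")
def noisy_video():
    """A ten-minute synthetic video with the default Beta-law detector."""
    sim = SimulationParams(duration=600, seed=11)
    return sim, *simulate_video(sim, NoiseParams(seed=11), "v0")


def series_from_probs(probs, video_id="v", boxes=None):
    """DetectionSeries from bare probabilities (unit boxes unless given)."""
    records = []
    for i, p in enumerate(probs):
        box = boxes[i] if boxes is not None else BoundingBox(0, 0, 10, 10)
        records.append(DetectionRecord(i, float(p), box))
    return DetectionSeries(video_id, records)


def annotations_from_values(values, video_id="v"):
    return AnnotationSeries(video_id, np.asarray(values))


@pytest.fixture
def make_series():
    return series_from_probs


@pytest.fixture
def make_annotations():
    return annotations_from_values
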