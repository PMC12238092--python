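import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from graspkin.events import DetectionConfig, segment_trial
from graspkin.synthetic import TrialScenario, simulate_trial
from graspkin.trial_io import TrackerLayout, TrialMeta, TrialRecording

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def layout():
    return TrackerLayout.default()


@pytest.fixture(scope="session")
def default_cfg():
    return DetectionConfig()


@pytest.fixture
def meta():
    return TrialMeta("P01", 1, 1, 0, 90)


def make_recording(positions, rate=250.0, meta_=None, labels=None):
    labels = labels or list(TrackerLayout.default().roles.values())
    return TrialRecording(
        positions=positions,
        sampling_rate=rate,
        marker_labels=labels,
        layout=TrackerLayout.default(),
        meta=meta_ or TrialMeta("P01", 1, 1, 0, 0),
    )


@pytest.fixture
def recording_factory():
    return make_recording


@pytest.fixture(scope="session")
def planted_trial():
    """One noisy synthetic trial (default sensor noise) with its scenario."""
    scn = TrialScenario(seed=12345)
    return scn, simulate_trial(scn)


@pytest.fixture(scope="session")
def noiseless_trial():
    scn = TrialScenario(seed=0, noise_sigma_cm=0.0)
    return scn, simulate_trial(scn)


@pytest.fixture(scope="session")
def segmented_batch():
    """A batch of segmented noisy trials reused by several tests."""
    out = []
    for s in range(40):
        scn = TrialScenario(seed=9000 + s)
        rec = simulate_trial(scn)
        out.append((scn, rec, segment_trial(rec)))
    return out
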