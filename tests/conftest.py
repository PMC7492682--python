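import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gazemotion.recording import GazeRecording, ScreenGeometry

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def screen():
    return ScreenGeometry()


def make_recording(x, y, pupil=None, valid=None, rate=60.0, pid="S01", mid="m01"):
    """Build a recording from plain arrays, defaulting pupil to zeros."""
    x = np.asarray(x, float)
    n = x.size
    pupil = np.zeros(n) if pupil is None else np.asarray(pupil, float)
    return GazeRecording(
        pid, mid, rate, np.arange(n) / rate,
        x, np.asarray(y, float), pupil, pupil.copy(),
        np.ones(n, bool) if valid is None else np.asarray(valid, bool),
    )


@pytest.fixture
def recording_factory():
    return make_recording


def six_plateau_recording():
    """Six 20-sample gaze plateaus separated by single-sample jumps."""
    centers = [(200, 200), (600, 300), (1000, 500), (1400, 300),
               (1000, 800), (400, 700)]
    xs, ys = [], []
    for k, (cx, cy) in enumerate(centers):
        xs += [cx] * 20
        ys += [cy] * 20
        if k < len(centers) - 1:
            nx, ny = centers[k + 1]
            xs.append((cx + nx) / 2)
            ys.append((cy + ny) / 2)
    return make_recording(np.array(xs, float), np.array(ys, float))
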