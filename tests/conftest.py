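from datetime import date, datetime

import numpy as np
import pytest

from fearscape.data_model import CameraDeployment, DetectionEvent
from fearscape.event_prep import CameraCluster


@pytest.fixture
def toy_cluster():
    return CameraCluster("K1", ("cam1", "cam2"), (0.0, 0.0), "trail")


@pytest.fixture
def toy_deployments():
    return [
        CameraDeployment("cam1", 0.0, 0.0, "trail",
                         ((date(2023, 6, 1), date(2023, 7, 20)),)),
        CameraDeployment("cam2", 50.0, 0.0, "trail",
                         ((date(2023, 6, 1), date(2023, 6, 30)),)),
    ]


def make_events(spec):
    """spec: list of (camera, species, minutes-past-noon on 2023-06-01)."""
    base = datetime(2023, 6, 1, 12, 0, 0)
    from datetime import timedelta

    return [
        DetectionEvent(cam, sp, base + timedelta(minutes=m))
        for cam, sp, m in spec
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
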