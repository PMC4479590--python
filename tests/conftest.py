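import numpy as np
import pytest

from steptree.io import BehaviourSegment, Fix, Trajectory


@pytest.fixture
def make_trajectory():
    """Factory: trajectory from (x, y) points at a fixed interval."""

    def _make(points, interval_s=60.0, animal_id="cow1", t0=0.0):
        fixes = [
            Fix(animal_id, t0 + i * interval_s, float(x), float(y))
            for i, (x, y) in enumerate(points)
        ]
        return Trajectory(animal_id, interval_s, fixes)

    return _make


@pytest.fixture
def make_segment():
    def _make(t_start, t_end, behaviour, animal_id="cow1"):
        return BehaviourSegment(animal_id, float(t_start), float(t_end), behaviour)

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
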