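import numpy as np
import pytest

from emnav.geometry import RigidTransform, Rotation


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_transform(rng, source="source", target="target", max_t=50.0):
    q = rng.normal(size=4)
    return RigidTransform(
        Rotation(q / np.linalg.norm(q)),
        rng.uniform(-max_t, max_t, size=3),
        source,
        target,
    )


@pytest.fixture
def make_transform(rng):
    def _make(source="source", target="target", max_t=50.0):
        return random_transform(rng, source, target, max_t)

    return _make


@pytest.fixture
def noncoplanar_points():
    # four points spanning 3-D: unit simplex corners scaled to tens of mm
    return np.array(
        [[0.0, 0.0, 0.0], [30.0, 0.0, 0.0], [0.0, 25.0, 0.0], [0.0, 0.0, 20.0]]
    )
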