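import numpy as np
import pytest

import morphohead as mh
from morphohead.synthetic import HeadParams


@pytest.fixture(scope="session")
def head():
    """Default synthetic head mesh with its 20 anchors."""
    return mh.make_head_mesh()


@pytest.fixture(scope="session")
def small_head():
    """Coarse head (642 vertices) for fast geometric tests."""
    return mh.make_head_mesh(HeadParams(subdivisions=3))


@pytest.fixture(scope="session")
def template(small_head):
    """Template with 60 semi-landmarks on the coarse head."""
    mesh, anchors = small_head
    return mh.generate_template_semilandmarks(mesh, anchors, n=60, radius=1.5, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_rotation(rng):
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
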