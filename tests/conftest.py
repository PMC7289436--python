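import numpy as np
import pytest

import ephapy as ep


@pytest.fixture(scope="session")
def sphere10():
    """Closed icosphere, R = 10 mm (convex null geometry for the index)."""
    mesh = ep.make_sphere(10.0, subdivisions=3)
    frame = ep.compute_vertex_frame(mesh, orientation="outward")
    return mesh, frame


@pytest.fixture(scope="session")
def flat_sheet():
    mesh = ep.make_flat_sheet(side=12.0, spacing=0.5)
    frame = ep.compute_vertex_frame(mesh)
    return mesh, frame


@pytest.fixture(scope="session")
def plates_fine():
    """Opposing plates at d = 2.5 mm, fine enough for the closed-form check."""
    mesh = ep.make_parallel_plates(separation=2.5, side=16.0, spacing=0.5)
    frame = ep.compute_vertex_frame(mesh)
    return mesh, frame


@pytest.fixture(scope="session")
def sulcus25():
    """Single sulcus, width 2.5 mm, with frame and piece labels."""
    spec = ep.SulcusSpec(width=2.5, depth=10.0, length=10.0, spacing=0.5)
    return ep.make_sulcus_phantom(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_rotation(rng):
    """Uniform random rotation matrix (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
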