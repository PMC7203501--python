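"""Shared fixtures: synthetic meshes are expensive, so session-scoped."""

import numpy as np
import pytest

from pabifurc.synthetic.geometry import (
    BifurcationSpec,
    cylinder_mesh,
    generate_bifurcation_mesh,
)


@pytest.fixture(scope="session")
def default_spec():
    return BifurcationSpec()


@pytest.fixture(scope="session")
def ymesh(default_spec):
    """Default Y-mesh with its implicit-geometry ground truth."""
    return generate_bifurcation_mesh(default_spec)


@pytest.fixture(scope="session")
def ymesh_surface(ymesh):
    return ymesh[0]


@pytest.fixture(scope="session")
def ymesh_gt(ymesh):
    return ymesh[1]


@pytest.fixture(scope="session")
def cyl14():
    """Circular cylinder, radius 14 mm, length 60 mm, fine pitch."""
    return cylinder_mesh(radius=14.0, length=60.0, pitch=0.7)


@pytest.fixture(scope="session")
def cyl10():
    """Circular cylinder, radius 10 mm, length 50 mm."""
    return cylinder_mesh(radius=10.0, length=50.0, pitch=0.6)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
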