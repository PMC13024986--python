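import math

import numpy as np
import pytest

from woundmetry import (
    SyntheticScene,
    TriangleMesh,
    datasets,
    make_anatomy,
    paint_wound,
)


@pytest.fixture
def square_mesh():
    """A 1 mm x 1 mm square in the z=0 plane, two triangles (0.01 cm2)."""
    return TriangleMesh(
        vertices=[[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]],
        faces=[[0, 1, 2], [0, 2, 3]],
    )


@pytest.fixture
def colored_square(square_mesh):
    return TriangleMesh(
        vertices=square_mesh.vertices,
        faces=square_mesh.faces,
        vertex_colors=np.tile([1.0, 0.0, 0.0], (4, 1)),
        vertex_labels=np.array([1, 1, 1, 1]),
    )


@pytest.fixture(scope="session")
def cap_scene():
    """Spherical cap wound, R=60 mm, theta=0.3 rad, default resolution."""
    return SyntheticScene("sphere_torso", {"radius": 60.0}, {"theta": 0.3})


@pytest.fixture(scope="session")
def painted_cap(cap_scene):
    mesh, truth = paint_wound(make_anatomy(cap_scene), cap_scene)
    return mesh, truth


@pytest.fixture(scope="session")
def cylinder_scene():
    """Cylinder-limb patch: R=40 mm, span pi/2 x 50 mm, default resolution."""
    return SyntheticScene(
        "cylinder_limb",
        {"radius": 40.0, "length": 200.0},
        {"delta_phi": math.pi / 2, "length": 50.0},
    )


@pytest.fixture(scope="session")
def painted_cylinder(cylinder_scene):
    mesh, truth = paint_wound(make_anatomy(cylinder_scene), cylinder_scene)
    return mesh, truth


@pytest.fixture(scope="session")
def pilot_series():
    return {(s.patient_id, s.location): s for s in datasets.load_pilot_series()}


@pytest.fixture(scope="session")
def pilot_patients():
    return {p.patient_id: p for p in datasets.load_pilot_patients()}


@pytest.fixture(scope="session")
def pilot_table():
    return datasets.pilot_cohort()
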