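import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from afogen.geometry_io import LandmarkSet, SurfaceMesh
from afogen.synthetic_leg import SyntheticLegSpec, generate_leg

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


CUBE_VERTICES = np.array(
    [
        [0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
        [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1],
    ],
    dtype=float,
)

# 12 triangles, outward CCW
CUBE_FACES = np.array(
    [
        [0, 2, 1], [0, 3, 2],  # bottom (z=0)
        [4, 5, 6], [4, 6, 7],  # top (z=1)
        [0, 1, 5], [0, 5, 4],  # front (y=0)
        [2, 3, 7], [2, 7, 6],  # back (y=1)
        [1, 2, 6], [1, 6, 5],  # right (x=1)
        [3, 0, 4], [3, 4, 7],  # left (x=0)
    ]
)


@pytest.fixture
def unit_cube() -> SurfaceMesh:
    return SurfaceMesh(CUBE_VERTICES.copy(), CUBE_FACES.copy(), name="cube")


@pytest.fixture
def perpendicular_landmarks() -> LandmarkSet:
    """A neutral landmark set whose foot axis is exactly perpendicular to
    the leg axis and whose plantar plane is exactly horizontal."""
    return LandmarkSet(
        heel=np.array([-60.0, 0.0, -50.0]),
        mh1=np.array([150.0, -40.0, -50.0]),
        mh2=np.array([180.0, 0.0, 0.0]),
        mh5=np.array([150.0, 40.0, -50.0]),
        lm=np.array([0.0, 45.0, 0.0]),
        mm=np.array([0.0, -45.0, 0.0]),
        lt=np.array([0.0, 40.0, 380.0]),
        mt=np.array([0.0, -40.0, 380.0]),
    )


@pytest.fixture(scope="session")
def neutral_leg():
    return generate_leg(SyntheticLegSpec())


@pytest.fixture(scope="session")
def deformed_leg():
    return generate_leg(SyntheticLegSpec(plantarflexion_deg=20.0, eversion_deg=10.0))


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    return Rotation.random(rng=rng).as_matrix()
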