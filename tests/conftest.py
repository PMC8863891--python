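import numpy as np
import pytest

from dryskull.geometry import TriMesh

CUBE_VERTICES = np.array(
    [
        [0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
        [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1],
    ],
    dtype=float,
)

# outward-wound triangulation: two triangles per face
CUBE_FACES = np.array(
    [
        [0, 2, 1], [0, 3, 2],  # bottom (-z)
        [4, 5, 6], [4, 6, 7],  # top (+z)
        [0, 1, 5], [0, 5, 4],  # front (-y)
        [2, 3, 7], [2, 7, 6],  # back (+y)
        [0, 4, 7], [0, 7, 3],  # left (-x)
        [1, 2, 6], [1, 6, 5],  # right (+x)
    ]
)


@pytest.fixture
def unit_cube() -> TriMesh:
    return TriMesh(CUBE_VERTICES.copy(), CUBE_FACES.copy())


def make_cube(origin=(0.0, 0.0, 0.0), side=1.0) -> tuple[np.ndarray, np.ndarray]:
    return CUBE_VERTICES * side + np.asarray(origin, float), CUBE_FACES.copy()
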