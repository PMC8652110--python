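"""Shared fixtures: analytic meshes and small generated benchmarks.

Everything is generated at run time from fixed seeds; expensive objects
are session-scoped so the suite builds each benchmark once.
"""

import numpy as np
import pytest

from surfshape import (blobby_surface, generate_hierarchy_benchmark,
                       generate_pseudo_structure, icosphere)
from surfshape.mesh import TriangleMesh


@pytest.fixture(scope="session")
def unit_sphere():
    """Unit icosphere, subdivision 4 (2562 vertices): the analytic fixture."""
    return icosphere(4, 1.0)


@pytest.fixture(scope="session")
def blob_mesh():
    """A typical bumpy single-component metaball surface."""
    return blobby_surface(generate_pseudo_structure(12, seed=3), 64)


@pytest.fixture(scope="session")
def small_blob_mesh():
    """A coarse metaball surface small enough for dense eigensolvers."""
    return blobby_surface(generate_pseudo_structure(6, seed=11), 32)


@pytest.fixture(scope="session")
def unit_cube():
    """Axis-aligned unit cube as 12 triangles, outward oriented."""
    v = np.array([[x, y, z] for x in (0, 1) for y in (0, 1) for z in (0, 1)],
                 dtype=float)
    f = np.array([
        [0, 1, 3], [0, 3, 2],          # x = 0
        [4, 6, 7], [4, 7, 5],          # x = 1
        [0, 4, 5], [0, 5, 1],          # y = 0
        [2, 3, 7], [2, 7, 6],          # y = 1
        [0, 2, 6], [0, 6, 4],          # z = 0
        [1, 5, 7], [1, 7, 3],          # z = 1
    ])
    return TriangleMesh(v, f)


@pytest.fixture(scope="session")
def tiny_benchmark():
    """3 protein classes x 2 species x 3 conformers; coarse grids for speed."""
    return generate_hierarchy_benchmark(
        3, 2, 3, deformation_scales=(1.0, 0.1), seed=4, grid_resolution=40,
        n_blobs=10)


def random_rotation(seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
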