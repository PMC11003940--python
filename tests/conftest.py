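import numpy as np
import pytest
import trimesh

from facedissect.core_io import SurfaceMesh, default_landmark_dictionary
from facedissect.synthetic_face import PopulationModel, build_template, simulate_population


@pytest.fixture(scope="session")
def dictionary():
    return default_landmark_dictionary()


@pytest.fixture(scope="session")
def small_template():
    # coarse grid keeps mesh-level tests fast; still >1000 vertices
    return build_template(41)


@pytest.fixture(scope="session")
def tiny_sample(small_template):
    return simulate_population(small_template, PopulationModel(), n_per_region=10, seed=11)


@pytest.fixture(scope="session")
def icosphere50():
    s = trimesh.creation.icosphere(subdivisions=4, radius=50.0)
    return SurfaceMesh(np.asarray(s.vertices), np.asarray(s.faces))


@pytest.fixture(scope="session")
def planar_grid():
    """Flat 100 x 60 mm rectangle triangulated into right triangles."""
    n = 40
    xs, ys = np.meshgrid(np.linspace(0, 100, n), np.linspace(0, 60, n))
    verts = np.column_stack([xs.ravel(), ys.ravel(), np.zeros(n * n)])
    idx = np.arange(n * n).reshape(n, n)
    faces = []
    for i in range(n - 1):
        for j in range(n - 1):
            a, b, c, d = idx[i, j], idx[i + 1, j], idx[i + 1, j + 1], idx[i, j + 1]
            faces += [(a, b, c), (a, c, d)]
    return SurfaceMesh(verts, np.asarray(faces)), idx
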