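"""Shared fixtures: a small folded study cortex and a flat assignment testbed."""

import numpy as np
import pytest

from safmap import CorticalRibbon, make_mesh, make_retinotopy, segment_subareas
from safmap.mesh import SurfaceMesh
from safmap.synthetic import make_area_labels


@pytest.fixture(scope="session")
def study():
    """Folded sheet with noiseless retinotopy and its 18 sub-area parcellation."""
    mesh = make_mesh(24, 45, 2.5, seed=1)
    labels = make_area_labels(mesh)
    rmap = make_retinotopy(mesh, labels, noise_sd=0.0, low_snr_fraction=0.0, seed=5)
    parc = segment_subareas(mesh, labels, rmap)
    return {"mesh": mesh, "labels": labels, "rmap": rmap, "parc": parc}


@pytest.fixture(scope="session")
def study_ribbon(study):
    return CorticalRibbon(inner=study["mesh"], thickness=2.0)


@pytest.fixture(scope="session")
def flat_mesh():
    """Flat 10x10 sheet at z=0 with 1 mm spacing."""
    return make_mesh(10, 10, 0.0, seed=0)


@pytest.fixture(scope="session")
def flat_ribbon(flat_mesh):
    return CorticalRibbon(inner=flat_mesh, thickness=2.0)


@pytest.fixture()
def star_mesh():
    """Centre vertex 0 surrounded by a 4-leaf triangle fan (1-ring = leaves)."""
    vertices = np.array(
        [[0, 0, 0], [1, 0, 0], [0, 1, 0], [-1, 0, 0], [0, -1, 0]], dtype=float
    )
    triangles = np.array([[0, 1, 2], [0, 2, 3], [0, 3, 4], [0, 4, 1]])
    return SurfaceMesh(vertices=vertices, triangles=triangles)
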