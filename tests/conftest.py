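import numpy as np
import pytest

from pbnrr.core_io import Image3D, LabelImage, TetMesh
from pbnrr.phantom import PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def phantom64():
    """Deformed 64^3 phantom shared across read-only tests."""
    return make_phantom(PhantomSpec(size=(64, 64, 64), seed=3, deform_max=4.0))


@pytest.fixture(scope="session")
def phantom_small():
    """Small undeformed phantom for fast structural tests."""
    return make_phantom(PhantomSpec(size=(32, 32, 32), seed=1, deform_max=0.0))


@pytest.fixture()
def unit_tet():
    """Right tetrahedron at the origin with unit legs."""
    verts = np.array(
        [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]
    )
    return TetMesh(vertices=verts, tets=[[0, 1, 2, 3]], tet_labels=[1])


@pytest.fixture()
def two_tet_mesh():
    """Two face-adjacent tetrahedra (connected mesh)."""
    verts = np.array(
        [
            [0.0, 0.0, 0.0],
            [1.0, 0.0, 0.0],
            [0.0, 1.0, 0.0],
            [0.0, 0.0, 1.0],
            [1.0, 1.0, 1.0],
        ]
    )
    return TetMesh(
        vertices=verts, tets=[[0, 1, 2, 3], [1, 2, 3, 4]], tet_labels=[1, 1]
    )


def textured_image(shape=(32, 32, 32), seed=0, spacing=(1.0, 1.0, 1.0)):
    rng = np.random.default_rng(seed)
    from scipy.ndimage import gaussian_filter

    data = gaussian_filter(rng.standard_normal(shape), 1.5) * 40 + 100
    return Image3D(data=data, spacing=spacing)
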