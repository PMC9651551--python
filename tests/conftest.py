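import numpy as np
import pytest

from maskfit import SceneParams, SurfaceMesh, make_scene


def grid_mesh(nx=10, ny=10, z=0.0, extent=20.0):
    """Planar triangulated grid at height z, normals along +z."""
    xs = np.linspace(-extent / 2, extent / 2, nx)
    ys = np.linspace(-extent / 2, extent / 2, ny)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    vertices = np.column_stack(
        [X.ravel(), Y.ravel(), np.full(X.size, float(z))]
    )
    idx = np.arange(nx * ny).reshape(nx, ny)
    a = idx[:-1, :-1].ravel()
    b = idx[1:, :-1].ravel()
    c = idx[1:, 1:].ravel()
    d = idx[:-1, 1:].ravel()
    faces = np.concatenate(
        [np.column_stack([a, b, c]), np.column_stack([a, c, d])]
    )
    return SurfaceMesh(vertices, faces)


def unit_cube_mesh():
    """Axis-aligned unit cube, 12 facets, outward winding."""
    import trimesh

    box = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
    return SurfaceMesh(np.asarray(box.vertices), np.asarray(box.faces))


@pytest.fixture(scope="session")
def default_scene():
    """Canonical synthetic scene at full resolution (deterministic)."""
    return make_scene(SceneParams())


@pytest.fixture(scope="session")
def quiet_scene():
    """Scene without any prescribed tissue loading (loaded == unloaded
    geometry up to its recorded misalignment)."""
    return make_scene(SceneParams(indent_depth=0.0, bulge_height=0.0))


@pytest.fixture(scope="session")
def small_params():
    """Low-resolution parameters for fast end-to-end runs."""
    return SceneParams(resolution=44)
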