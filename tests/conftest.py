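import numpy as np
import pytest

import tfct


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240117)


@pytest.fixture(scope="session")
def small_geometry():
    """Tiny helical scan used by most projector tests: 48 views, 8x48 panel."""
    return tfct.ScanGeometry(
        source_radius=300.0, source_to_detector=600.0,
        n_rows=8, n_channels=48, row_height=6.0, channel_width=4.0,
        views_per_rotation=48, n_views=48, pitch=1.0,
    )


@pytest.fixture(scope="session")
def small_grid():
    return tfct.VolumeGrid(32, 32, 32, 2.0, 2.0, 2.0)


@pytest.fixture(scope="session")
def tiny_system():
    """8^3 grid / 12-view system small enough for a dense-matrix oracle."""
    grid = tfct.VolumeGrid(8, 8, 8, 4.0, 4.0, 4.0)
    geom = tfct.ScanGeometry(
        source_radius=200.0, source_to_detector=400.0,
        n_rows=6, n_channels=12, row_height=8.0, channel_width=6.0,
        views_per_rotation=12, n_views=12, pitch=1.0,
    )
    return grid, geom


def dense_matrix(grid, geom):
    """Build the dense system matrix by projecting unit voxels (oracle only)."""
    n = int(np.prod(grid.shape))
    m = geom.n_views * geom.n_rows * geom.n_channels
    a = np.zeros((m, n))
    for idx in range(n):
        e = np.zeros(n)
        e[idx] = 1.0
        vol = tfct.Volume(e.reshape(grid.shape), grid)
        a[:, idx] = tfct.forward_project(vol, geom).data.ravel()
    return a
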