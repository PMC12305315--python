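import numpy as np
import pytest

import tractwing as tw


@pytest.fixture(scope="session")
def spec():
    """Small phantom for unit tests; acceptance tests build their own."""
    return tw.PhantomSpec(seed=11, n_streamlines_per_bundle=150, n_subjects=10)


@pytest.fixture(scope="session")
def atlas(spec):
    return tw.make_atlas(spec)


@pytest.fixture(scope="session")
def grid(atlas):
    return atlas["rw_left"].grid


@pytest.fixture(scope="session")
def bundles_left(spec):
    return tw.make_bundles(spec, side="left")


@pytest.fixture(scope="session")
def planted_labels(bundles_left):
    return np.asarray(bundles_left.labels)


@pytest.fixture(scope="session")
def drtx_density(bundles_left, planted_labels, grid):
    idx = np.flatnonzero(planted_labels == "DRTx")
    return tw.density_map(bundles_left.subset(idx), grid)


@pytest.fixture(scope="session")
def drtu_density(bundles_left, planted_labels, grid):
    idx = np.flatnonzero(planted_labels == "DRTu")
    return tw.density_map(bundles_left.subset(idx), grid)


def small_grid(shape=(10, 10, 10), spacing=1.0, origin=(0.0, 0.0, 0.0)):
    affine = np.diag([spacing, spacing, spacing, 1.0])
    affine[:3, 3] = origin
    return tw.VoxelGrid(np.zeros(shape), affine)


def binary_mask_from_indices(grid_like, indices, values=None):
    g = grid_like.empty_like()
    for k, ijk in enumerate(indices):
        g.data[tuple(ijk)] = 1.0 if values is None else values[k]
    kind = "binary" if values is None else "probability"
    return tw.Mask(g, kind=kind)
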