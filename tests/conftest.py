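import numpy as np
import pytest

from connharm import synth
from connharm.types import CorticalMesh


@pytest.fixture(scope="session")
def icosphere2():
    """Jitter-free icosphere, 162 vertices."""
    return synth.make_hemisphere_mesh(2, 30.0)


@pytest.fixture(scope="session")
def icosphere3():
    """Jitter-free icosphere, 642 vertices."""
    return synth.make_hemisphere_mesh(3, 30.0)


@pytest.fixture(scope="session")
def tiny_config():
    """Small two-hemisphere brain for fast structural tests."""
    return synth.SynthBrainConfig(
        subdivisions=2,
        n_streamlines=1500,
        n_regions_per_hemisphere=6,
        n_rsn_patches=4,
        n_bundles_plain=400,
        n_bundles_rsn=120,
        n_bundles_inter=150,
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_brain(tiny_config):
    mesh, hemisphere, parcellation = synth.make_brain(tiny_config)
    return mesh, hemisphere, parcellation


@pytest.fixture(scope="session")
def tiny_streamlines(tiny_brain, tiny_config):
    mesh, hemisphere, parcellation = tiny_brain
    rsn = synth.make_rsn(parcellation, tiny_config.n_rsn_patches, seed=17)
    return synth.make_streamlines(mesh, hemisphere, tiny_config, parcellation, rsn), rsn


@pytest.fixture(scope="session")
def tiny_connectome(tiny_brain, tiny_streamlines):
    from connharm import build

    mesh, hemisphere, _ = tiny_brain
    tracks, _ = tiny_streamlines
    wc = build.build_long_range(tracks, mesh)
    build.zscore_weights(wc)
    longrange = build.threshold_long_range(wc, 1.0)
    local = build.build_local_adjacency(mesh, 2)
    return wc, local, longrange


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def single_triangle_mesh():
    vertices = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
    triangles = np.array([[0, 1, 2]])
    return CorticalMesh(vertices, triangles, np.zeros(3, dtype=int))
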