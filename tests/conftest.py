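import numpy as np
import pytest

from subparc import synthio
from subparc.surface import extract_surface


@pytest.fixture(scope="session")
def phantom():
    return synthio.PhantomSpec()


@pytest.fixture(scope="session")
def atlas(phantom):
    probs, cortical = synthio.generate_atlas(phantom)
    return probs, cortical


@pytest.fixture(scope="session")
def snc_mesh(atlas):
    probs, _ = atlas
    return extract_surface(
        probs[("snc", "R")], 0.3, 200.0, 0.0, structure="snc", hemisphere="R"
    )


@pytest.fixture(scope="session")
def snc_parcellated(phantom, atlas, snc_mesh):
    """SNc mesh parcellated from 250-seed streamlines with dominant p = 0.9."""
    from subparc import parcellation as pc

    _, cortical = atlas
    profile = synthio.target_profile(
        phantom, "snc", "R", snc_mesh.vertices, dominant_p=0.9, fail_p=0.05
    )
    streams = synthio.generate_streamlines(
        snc_mesh.vertices, cortical, profile, 50, seed=7
    )
    streams.terminal_labels = pc.terminal_labels(streams, cortical)
    counts = pc.count_connections(
        streams, cortical, n_vertices=snc_mesh.n_vertices, n_targets=4
    )
    parc = pc.assign(counts, min_count=5)
    return streams, parc


@pytest.fixture()
def rng():
    return np.random.default_rng(20240629)
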