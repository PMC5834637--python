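import warnings

import numpy as np
import pytest

import pengcensus as pc

# Study-island conditions: clustered sub-colonies with hard-core spacing on
# a mostly barren extent, confusable artifacts from a sparse Poisson field.
STUDY_EXTENT = (0.0, 0.0, 200.0, 160.0)
STUDY_KW = dict(n_subcolonies=8, nests_per_subcolony=150,
                cluster_radius=3.0, hardcore=0.7)


def make_island(seed: int):
    """One rendered study island: (layout, orthomosaic, artifact truth)."""
    layout = pc.generate_colony_layout(
        STUDY_EXTENT, seed=seed, island_id=f"island{seed:02d}", **STUDY_KW
    )
    ortho, artifacts = pc.render_orthomosaic(layout, seed=seed + 100)
    return layout, ortho, artifacts


@pytest.fixture(scope="session")
def study_island():
    """A single full-size rendered island shared across tests."""
    return make_island(0)


@pytest.fixture(scope="session")
def small_island():
    """A small, quick island for detection/tiling unit tests."""
    layout = pc.generate_colony_layout(
        (0, 0, 24, 24), n_subcolonies=1, nests_per_subcolony=40,
        cluster_radius=3.0, hardcore=0.7, seed=7, island_id="small",
    )
    ortho, artifacts = pc.render_orthomosaic(
        layout, gsd=0.05, artifact_intensity=0.0, noise_sd=0.0, seed=8
    )
    return layout, ortho, artifacts


@pytest.fixture(autouse=True)
def _quiet_filter_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
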