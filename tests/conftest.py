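import numpy as np
import pytest

from epsquant import SceneParams, generate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def sparse_scene_params(seed: int) -> SceneParams:
    """One 3-um tube, five 1.4 x 0.5 um rods, five attachment filaments."""
    return SceneParams(
        shape=(512, 512),
        n_hyphae=1,
        n_bacteria=5,
        n_filaments=5,
        hypha_width_mean=3.0, hypha_width_sd=1e-6, hypha_width_range=(2.9, 3.1),
        bact_length_mean=1.4, bact_length_sd=1e-6, bact_length_range=(1.3, 1.5),
        bact_width_mean=0.5, bact_width_sd=1e-6, bact_width_range=(0.45, 0.55),
        target_eps_coverage=0.0,
        seed=seed,
    )


@pytest.fixture(scope="session")
def sparse_scene():
    return generate_scene(sparse_scene_params(3))


@pytest.fixture(scope="session")
def small_dense_scene():
    """A compact coculture field with EPS mesh, for pipeline-level tests."""
    return generate_scene(SceneParams(
        shape=(512, 512), n_hyphae=2, n_bacteria=4, n_filaments=4, seed=11,
    ))
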