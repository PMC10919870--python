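import numpy as np
import pytest

from disface import dvae
from disface.synth import faces, responses as resp


@pytest.fixture(scope="session")
def specs():
    return faces.default_factor_specs()


@pytest.fixture(scope="session")
def small_dataset(specs):
    """60 training faces + 20 test faces at 32 px, fully rendered."""
    return faces.sample_dataset(spec=specs, n_train=60, seed=11, side=32)


@pytest.fixture(scope="session")
def factors_only_dataset(specs):
    """Factor matrices without rasterization, for response-level tests."""
    return faces.sample_dataset(spec=specs, n_train=500, seed=12, side=32,
                                render=False)


@pytest.fixture(scope="session")
def ground_truth():
    """8 dims x 80 voxels, half single-dimension voxels, SNR 10:1."""
    return resp.make_ground_truth(n_dims=8, n_voxels=80, seed=5,
                                  single_dim_fraction=0.5, signal_sd=1.0,
                                  noise_sd=0.1)


@pytest.fixture(scope="session")
def trained_ci_model():
    """A FactorVAE trained at the CI scale (300 faces, 32 px, 30 epochs),
    shared by the sanity and acceptance tests."""
    ds = faces.sample_dataset(n_train=300, seed=3, side=32)
    cfg = dvae.ModelConfig(family="factor_vae", latent_dim=8, gamma=10.0,
                           seed=0, epochs=30, image_side=32)
    return dvae.train(cfg, ds.train_images), ds
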