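import numpy as np
import pytest

from wmagt import FixtureSpec, build_hetero_bundle, generate_fixture


@pytest.fixture(scope="session")
def small_fixture():
    """A 20x15 planted-structure dataset used across unit tests."""
    return generate_fixture(FixtureSpec(n_drugs=20, n_diseases=15, latent_dim=3,
                                        density=0.08, similarity_noise=0.05,
                                        seed=7))


@pytest.fixture(scope="session")
def small_bundle(small_fixture):
    fx = small_fixture
    return build_hetero_bundle(fx.association, fx.drug_similarity,
                               fx.disease_similarity, k=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
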