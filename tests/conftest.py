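import numpy as np
import pytest

from metstab import cell_means, generate_met, lentil_fixture, random_config


@pytest.fixture(scope="session")
def lentil():
    return lentil_fixture()


@pytest.fixture(scope="session")
def fe_matrix(lentil):
    return cell_means(lentil, "Fe")


@pytest.fixture(scope="session")
def zn_matrix(lentil):
    return cell_means(lentil, "Zn")


@pytest.fixture(scope="session")
def pa_matrix(lentil):
    return cell_means(lentil, "PA")


@pytest.fixture(scope="session")
def replicate_dataset():
    """Small noisy replicate-level trial with known generating structure."""
    config = random_config(g=8, e=5, r=3, K=2, lambdas=(20.0, 8.0), sigma_error=2.0, seed=11)
    return generate_met(config)


def random_matrix(rng, g, e, scale=10.0):
    """Arbitrary positive cell-mean matrix for oracle comparisons."""
    return 50.0 + scale * rng.standard_normal((g, e))
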