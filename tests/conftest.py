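import numpy as np
import pytest

from ssmgrn import ExpressionDataset, GeneNetwork, SSMParameters


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def tiny_params():
    """A small well-conditioned m=2, l=3 model."""
    return SSMParameters(
        F=np.array([[0.8, 0.1], [-0.2, 0.6]]),
        H=np.array([[1.0, 0.0], [0.5, 1.0], [-0.3, 0.7]]),
        Q=np.array([[0.3, 0.05], [0.05, 0.2]]),
        R=np.diag([0.4, 0.3, 0.5]),
        mu0=np.array([0.5, -0.2]),
        Sigma0=np.eye(2) * 0.7,
    )


@pytest.fixture
def toy_truth():
    """A 4-gene gold standard with 5 edges."""
    genes = ("g1", "g2", "g3", "g4")
    edges = {("g1", "g2"): 1.0, ("g1", "g3"): 1.0, ("g2", "g3"): 1.0,
             ("g3", "g4"): 1.0, ("g4", "g1"): 1.0}
    return GeneNetwork(genes=genes, edges=edges)


@pytest.fixture
def small_dataset(rng):
    return ExpressionDataset(rng.standard_normal((4, 12)))
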