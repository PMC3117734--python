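import numpy as np
import pandas as pd
import pytest

from pobn import BipartiteNetwork, GibbsConfig, ScoreConfig, make_synthetic_network


@pytest.fixture
def rng():
    return np.random.default_rng(20260918)


@pytest.fixture
def small_net():
    """2 regulators, 3 genes, 4 edges."""
    return BipartiteNetwork(
        regulators={"R1", "R2"},
        targets={"G1", "G2", "G3"},
        edges={("R1", "G1"), ("R1", "G2"), ("R2", "G2"), ("R2", "G3")},
    )


@pytest.fixture
def default_model():
    """The 4-regulator / 9-response / 11-edge ground-truth study model."""
    return make_synthetic_network(seed=3)


@pytest.fixture
def score_cfg():
    return ScoreConfig()


def random_expression(rng, n_genes=10, n_samples=12):
    return pd.DataFrame(
        rng.normal(size=(n_genes, n_samples)),
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"s{j}" for j in range(n_samples)],
    )


def random_discrete(rng, names, n_samples):
    return pd.DataFrame(
        rng.integers(0, 3, size=(len(names), n_samples)).astype(np.int8),
        index=list(names),
        columns=[f"s{j}" for j in range(n_samples)],
    )


@pytest.fixture
def quick_gibbs():
    return GibbsConfig(m=25, burn_in=30, thin=1, seed=7)
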