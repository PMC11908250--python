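import numpy as np
import pytest

from momirf import ForestParams, LatentScenario, build_forest, gen_latent


@pytest.fixture(scope="session")
def small_latent():
    """Small two-omics latent dataset with 10 true variables per side."""
    return gen_latent(LatentScenario(n=80, p=[60, 60], p_c=[10, 10], seed=42))


@pytest.fixture(scope="session")
def small_forest(small_latent):
    """30-tree forest on the small latent pair (omic2 <- omic1)."""
    X = small_latent.datasets["omic1"].values
    Y = small_latent.datasets["omic2"].values
    return build_forest(X, Y, ForestParams(ntree=30, seed=7))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(123)
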