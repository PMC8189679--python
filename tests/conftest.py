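import numpy as np
import pandas as pd
import pytest

import tfactivity as T


@pytest.fixture(scope="session")
def small_truth():
    """6 TFs x 60 genes, every TF deleted and overexpressed once."""
    cfg = T.GeneratorConfig(
        n_tfs=6, n_genes=60, targets_per_tf=(4, 8), seed=11
    )
    return T.generate_ground_truth(cfg)


@pytest.fixture(scope="session")
def small_noiseless(small_truth):
    return T.generate_expression(small_truth, 0.0, seed=12)


@pytest.fixture(scope="session")
def small_fit(small_truth, small_noiseless):
    """Converged noiseless fit on the small design (shared across tests)."""
    cfg = T.FitConfig(
        n_inits=2, max_iter=150, seed=5, stopping="train_converge", train_tol=1e-10
    )
    return T.fit_model(
        small_noiseless, small_truth.net, small_truth.signs, small_truth.key, cfg
    )


@pytest.fixture()
def toy_network():
    return T.NetworkMap.from_edges(
        [("A", "g1"), ("A", "g2"), ("A", "g3"), ("B", "g2"), ("B", "g4")]
    )


def make_expression(rng, genes, samples):
    return T.ExpressionMatrix(
        pd.DataFrame(
            rng.normal(7.0, 1.5, size=(len(genes), len(samples))),
            index=genes,
            columns=samples,
        )
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
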