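"""Shared fixtures: small synthetic datasets and trained pipelines.

Training fixtures are session-scoped so the expensive fits run once.
"""

import numpy as np
import pytest

from protogsea import (ProtoGSEA, SimConfig, preprocess, simulate_dataset)
from protogsea.data import ExpressionDataset
from protogsea.genesets import GeneSetCollection


def make_separable_toy(n=50, seed=0):
    """Two classes separated by two informative genes, one gene set.

    Class 1 cells express gene gA, class 2 cells gene gB; three noise
    genes are shared. Linearly separable by construction.
    """
    rng = np.random.default_rng(seed)
    half = n // 2
    y = np.array([1] * half + [2] * (n - half))
    X = rng.normal(0.0, 0.1, size=(n, 5))
    X[:half, 0] += 5.0   # gA high in class 1
    X[half:, 1] += 5.0   # gB high in class 2
    ds = ExpressionDataset(X=X, gene_names=["gA", "gB", "n1", "n2", "n3"],
                           y=y)
    sets = GeneSetCollection.from_members({"informative": ["gA", "gB"]},
                                          ds.gene_names)
    return ds, sets


@pytest.fixture(scope="session")
def toy_problem():
    return make_separable_toy()


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated dataset with clear enrichment signal."""
    ds, sets, truth = simulate_dataset(SimConfig(
        seed=5, n_cells=300, n_genes=600, enriched_set_size=50,
        irrelevant_set_size=50))
    return preprocess(ds), sets, truth


@pytest.fixture(scope="session")
def small_fit(small_sim):
    """A trained two-fold model on the small simulated dataset."""
    ds, sets, _ = small_sim
    model = ProtoGSEA(ds, sets, K=2, stage1_epochs=6, stage2_epochs=3,
                      hidden_layers=[32], h_dim=16, z_dim=4, seed=5)
    return model.fit()
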