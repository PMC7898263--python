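"""Shared fixtures: simulated atlases reused across test modules."""

import numpy as np
import pytest
import scipy.sparse as sp

import mammaging as mg

NULL_SEEDS = [100 + i for i in range(20)]


@pytest.fixture(scope="session")
def recovery_atlas():
    """Default recovery atlas: 3 young / 4 aged samples, four cell types,
    planted |log2FC| = 1 age effects and proportion shifts."""
    cfg = mg.recovery_config(seed=11)
    matrix, meta, truth = mg.simulate_atlas(cfg)
    return cfg, matrix, meta, truth


@pytest.fixture(scope="session")
def recovery_de(recovery_atlas):
    """Consensus DE results for every cell type of the recovery atlas."""
    _, matrix, meta, truth = recovery_atlas
    return {
        cell_type: mg.consensus_de(matrix, truth.type_of_cell, meta, cell_type)
        for cell_type in truth.planted_props.index
    }


@pytest.fixture(scope="session")
def null_runs():
    """Twenty seeded null atlases (no planted effects) passed through the
    full consensus procedure."""
    out = []
    for seed in NULL_SEEDS:
        cfg = mg.null_config(seed=seed)
        matrix, meta, truth = mg.simulate_atlas(cfg)
        out.append(mg.consensus_de(matrix, truth.type_of_cell, meta,
                                   "epithelium"))
    return out


@pytest.fixture(scope="session")
def hybrid_atlas():
    """Three luminal populations including the rare hybrid type."""
    cfg = mg.hybrid_config(seed=5)
    matrix, meta, truth = mg.simulate_atlas(cfg)
    return cfg, matrix, meta, truth


@pytest.fixture
def tiny_matrix():
    """3 genes x 2 cells with one mitochondrial gene."""
    counts = sp.csr_matrix(np.array([[5, 0], [3, 2], [5, 1]]))
    return mg.CountMatrix(counts, np.array(["geneA", "geneB", "mt-1"]),
                          np.array(["c1", "c2"]),
                          {"c1": "s1", "c2": "s1"})
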