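import numpy as np
import pytest
import scipy.sparse as sp

import cellgate as cg


@pytest.fixture
def tiny_dataset():
    """4 cells x 3 genes with hand-readable counts and a trivial embedding."""
    counts = np.array(
        [
            [5, 0, 1],
            [0, 1, 2],
            [2, 0, 0],
            [1, 3, 4],
        ]
    )
    ds = cg.CellDataset(
        counts=sp.csr_matrix(counts),
        cell_ids=[f"c{i}" for i in range(4)],
        gene_ids=["CCR7", "SELL", "CX3CR1"],
    )
    ds.attach_embedding("umap", np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [5.0, 5.0]]))
    return ds


@pytest.fixture(scope="session")
def marker_dataset():
    """Simulated 3-cluster dataset with one strong marker per cluster."""
    spec = cg.SimSpec(
        n_cells=2000,
        n_genes=80,
        n_clusters=3,
        marker_table=[
            cg.MarkerSpec("CX3CR1", frozenset({0}), 50.0),
            cg.MarkerSpec("CCR7", frozenset({1}), 20.0),
            cg.MarkerSpec("SELL", frozenset({1}), 20.0),
        ],
        seed=11,
    )
    return cg.simulate(spec), spec


@pytest.fixture
def unit_square():
    return cg.Polygon("sq", [(0.0, 0.0), (1.0, 0.0), (1.0, 1.0), (0.0, 1.0)])
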