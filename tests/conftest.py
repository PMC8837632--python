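import numpy as np
import pandas as pd
import pytest
from anndata import AnnData

from tlomap import SimParams, make_reference, simulate_volume


@pytest.fixture(scope="session")
def small_sim():
    """One small 4-zone volume shared by read-only tests."""
    params = SimParams(
        n_sections=2,
        spots_per_section=144,
        n_genes=300,
        n_cell_types=5,
        markers_per_type=10,
        seed=0,
    )
    signatures, matrix = make_reference(params)
    adata, spots, truth, cells = simulate_volume(params, matrix)
    return params, signatures, matrix, adata, spots, truth, cells


def make_adata(X, barcodes=None, genes=None, layer=None):
    """Tiny AnnData builder for hand-crafted matrices."""
    X = np.asarray(X, dtype=float)
    n, g = X.shape
    barcodes = barcodes or [f"spot{i}" for i in range(n)]
    genes = genes or [f"g{j}" for j in range(g)]
    adata = AnnData(
        X=X,
        obs=pd.DataFrame(index=pd.Index(barcodes, name="barcode")),
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )
    if layer is not None:
        adata.layers[layer] = X.copy()
    return adata
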