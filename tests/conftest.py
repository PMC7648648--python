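import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from ovatlas.normalize import normalize_log_cp10k
from ovatlas.simulate import (
    default_gradient_spec,
    nested_hierarchy_spec,
    simulate_counts,
    simulate_gradient,
)


@pytest.fixture(scope="session")
def nested_adata():
    """Standard nested benchmark scene (germ leaf vs soma branch with two
    leaves), normalized; truth labels in obs."""
    adata = simulate_counts(nested_hierarchy_spec(seed=0))
    return normalize_log_cp10k(adata)


@pytest.fixture(scope="session")
def gradient_adata():
    """Standard differentiation-gradient scene, normalized."""
    adata = simulate_gradient(default_gradient_spec(seed=0))
    return normalize_log_cp10k(adata)


@pytest.fixture()
def leaf_labels(nested_adata):
    return nested_adata.obs["tier_path"].str.split("/").str[-1].values


def make_adata(counts: np.ndarray, cell_ids=None, gene_ids=None) -> ad.AnnData:
    """Tiny AnnData straight from a dense count array."""
    counts = np.asarray(counts)
    n, g = counts.shape
    cells = cell_ids or [f"c{i:03d}" for i in range(n)]
    genes = gene_ids or [f"g{j:03d}" for j in range(g)]
    return ad.AnnData(
        X=sp.csr_matrix(counts.astype(np.int64)),
        obs=pd.DataFrame(index=pd.Index(cells, name="cell_id")),
        var=pd.DataFrame(index=pd.Index(genes, name="gene_id")),
    )


def make_lognorm_adata(values: np.ndarray, cell_ids=None, gene_ids=None) -> ad.AnnData:
    """AnnData with a directly constructed normalized layer (bypasses
    count normalization so tests can plant exact expression patterns)."""
    adata = make_adata(np.asarray(values) > 0, cell_ids, gene_ids)
    adata.layers["lognorm"] = sp.csr_matrix(np.asarray(values, dtype=float))
    return adata
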