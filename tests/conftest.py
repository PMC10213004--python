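import anndata as ad
import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from mirshift import synthetic as syn
from mirshift.sites import seed_patterns


@pytest.fixture(scope="session")
def mir132_patterns():
    return seed_patterns(syn.MIR132_3P)


@pytest.fixture(scope="session")
def small_cfg():
    """Desk-scale config: fast but large enough for rate checks."""
    return syn.SimConfig(seed=7, n_utrs=30, n_true_targets=10, n_cells_per_condition=300)


@pytest.fixture(scope="session")
def small_truth(small_cfg):
    return syn.choose_targets(small_cfg)


def make_adata(counts: np.ndarray, obs: pd.DataFrame | None = None, genes=None) -> ad.AnnData:
    """Tiny AnnData builder for hand-constructed count matrices."""
    counts = np.asarray(counts)
    n_cells, n_genes = counts.shape
    if genes is None:
        genes = [f"g{j}" for j in range(n_genes)]
    if obs is None:
        obs = pd.DataFrame(index=[f"c{i}" for i in range(n_cells)])
    adata = ad.AnnData(
        X=sparse.csr_matrix(counts.astype(np.int64)),
        obs=obs,
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )
    adata.layers["counts"] = adata.X.copy()
    return adata


@pytest.fixture(scope="session")
def sc_bundle(small_cfg, small_truth):
    """Two-condition planted single-cell bundle, QC'd and normalized."""
    from mirshift import singlecell as sc

    mats, metas = [], []
    for cond in ("CTRL", "KD"):
        m, meta = syn.gen_sc(small_cfg, small_truth, cond)
        mats.append(m)
        metas.append(meta)
    adata = ad.AnnData(
        X=sparse.vstack(mats).tocsr(),
        obs=pd.concat(metas),
        var=pd.DataFrame(index=pd.Index(small_cfg.genes, name="gene")),
    )
    adata.layers["counts"] = adata.X.copy()
    adata, _ = sc.qc_filter(adata)
    return sc.normalize(adata)
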