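import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import retinacomm as rc


def make_adata(counts, genes=None, cells=None, obs=None):
    """Small dense-counts AnnData helper (cells x genes)."""
    counts = np.asarray(counts, dtype=float)
    n_cells, n_genes = counts.shape
    genes = list(genes) if genes is not None else [f"g{i}" for i in range(n_genes)]
    cells = list(cells) if cells is not None else [f"c{i}" for i in range(n_cells)]
    obs_df = pd.DataFrame(index=pd.Index(cells, name="cell_id"))
    if obs:
        for k, v in obs.items():
            obs_df[k] = v
    return ad.AnnData(
        X=sp.csr_matrix(counts),
        obs=obs_df,
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )


@pytest.fixture(scope="session")
def small_atlas():
    """One shared default synthetic atlas (seed 11, 5 preset planted pairs)."""
    cfg = rc.default_config(seed=11, n_planted=5, effect_size=4.0, with_loops=True)
    adata, truth = rc.generate_atlas(cfg)
    return cfg, adata, truth


@pytest.fixture(scope="session")
def scored_atlas(small_atlas):
    """The shared atlas taken through QC and subclass-level scoring."""
    cfg, adata, truth = small_atlas
    adata = adata.copy()
    rc.compute_qc_metrics(adata)
    adata = rc.qc_filter(adata, rc.QC_PRESETS["whole_retina"])
    lr = rc.LRDatabase.from_frame(rc.lr_table(truth))
    table = rc.score_interactions(
        adata,
        lr,
        senders=list(cfg.sender_types),
        receivers=[n for n, _ in cfg.receiver_subclasses],
    )
    return cfg, truth, table
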