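"""Reading expression matrices, per-cell QC, filtering, and type assignment.

QC follows the usual droplet-scRNA metrics: total UMIs per cell (nUMI),
detected genes (nGene), mitochondrial fraction, and the gene/UMI
complexity ratio log10(nGene)/log10(nUMI).  Removal rules are strict
inequalities — a cell sitting exactly on a boundary is kept.  Threshold
presets for whole-retina scRNA-seq, sorted-RGC scRNA-seq, and retinal
snRNA-seq datasets ship as :data:`QC_PRESETS`; which preset fits a given
dataset is the caller's decision.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import ConfigurationError, FormatError, InsufficientOverlapError

NORM_TARGET = 1e4  # counts-per-10k


@dataclass(frozen=True)
class QCThresholds:
    """Cell-removal thresholds. A cell is removed iff any rule fires:
    nUMI < numi_min or > numi_max; nGene < ngene_min or > ngene_max;
    mito_rate > mito_max; log10GenesPerUMI < lgpu_min."""

    numi_min: float = 800
    numi_max: float = 30_000
    ngene_min: float = 350
    ngene_max: float = 7_500
    mito_max: float = 0.20
    lgpu_min: float = 0.8

    def __post_init__(self) -> None:
        if not (self.numi_min < self.numi_max and self.ngene_min < self.ngene_max):
            raise ConfigurationError("QC thresholds: min must be below max")


QC_PRESETS: dict[str, QCThresholds] = {
    "whole_retina": QCThresholds(800, 30_000, 350, 7_500, 0.20, 0.8),
    "rgc": QCThresholds(500, math.inf, 250, math.inf, 0.20, 0.8),
    "snrna_sham": QCThresholds(1_000, 50_000, 500, 10_000, 0.10, 0.8),
    "snrna_onc": QCThresholds(1_000, 30_000, 500, 7_000, 0.10, 0.8),
    "permissive": QCThresholds(0, math.inf, 0, math.inf, 1.0, -math.inf),
}

META_COLUMNS = ("cell_type", "subclass", "survival_class", "timepoint", "condition")


def _check_ids(ids, what: str) -> None:
    if len(set(ids)) != len(ids):
        raise FormatError(f"duplicate {what} ids")


def load_counts(path, fmt: str = "mtx_triplet", meta_path=None) -> ad.AnnData:
    """Load a counts matrix as AnnData (cells x genes).

    ``mtx_triplet`` expects matrix.mtx / features.tsv / barcodes.tsv in a
    directory (genes x cells on disk, per 10x convention); per-cell
    metadata is joined from ``cell_meta.tsv`` beside them, or from
    ``meta_path``, when present.  ``dense_delimited`` expects a TSV/CSV
    with gene rows and cell columns.
    """
    path = Path(path)
    if fmt == "mtx_triplet":
        mtx_path = path / "matrix.mtx" if path.is_dir() else path
        base = mtx_path.parent
        X = sp.csr_matrix(scipy.io.mmread(str(mtx_path)))
        genes = pd.read_csv(base / "features.tsv", sep="\t", header=None)[0].astype(str)
        cells = pd.read_csv(base / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
        if X.shape != (len(genes), len(cells)):
            raise FormatError(
                f"matrix is {X.shape} but features/barcodes give "
                f"({len(genes)}, {len(cells)})"
            )
        adata = ad.AnnData(
            X=X.T.tocsr(),
            obs=pd.DataFrame(index=pd.Index(cells, name="cell_id")),
            var=pd.DataFrame(index=pd.Index(genes, name="gene")),
        )
        if meta_path is None and (base / "cell_meta.tsv").exists():
            meta_path = base / "cell_meta.tsv"
    elif fmt == "dense_delimited":
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        adata = ad.AnnData(
            X=sp.csr_matrix(df.to_numpy(dtype=float).T),
            obs=pd.DataFrame(index=pd.Index(df.columns.astype(str), name="cell_id")),
            var=pd.DataFrame(index=pd.Index(df.index.astype(str), name="gene")),
        )
    else:
        raise FormatError(f"unknown format {fmt!r}")

    _check_ids(list(adata.var_names), "gene")
    _check_ids(list(adata.obs_names), "cell")
    if adata.X.size and adata.X.min() < 0:
        raise FormatError("negative counts")

    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
        meta.index = meta.index.astype(str)
        missing = set(adata.obs_names) - set(meta.index)
        if missing:
            raise FormatError(f"{len(missing)} cells missing from metadata")
        for col in META_COLUMNS:
            if col in meta.columns:
                adata.obs[col] = meta.loc[adata.obs_names, col].fillna("").values
    return adata


def normalize_expression(adata: ad.AnnData, layer: str = "norm") -> ad.AnnData:
    """Counts-per-10k then log1p, stored in ``.layers[layer]``."""
    X = sp.csr_matrix(adata.X, dtype=float)
    totals = np.asarray(X.sum(axis=1)).ravel()
    scale = np.divide(NORM_TARGET, totals, out=np.zeros_like(totals), where=totals > 0)
    norm = sp.diags(scale) @ X
    norm.data = np.log1p(norm.data)
    adata.layers[layer] = norm.tocsr()
    return adata


def compute_qc_metrics(adata: ad.AnnData, mito_prefix: str = "mt-") -> ad.AnnData:
    """Annotate .obs with n_umi, n_gene, mito_rate and log10_genes_per_umi.

    log10GenesPerUMI = log10(nGene)/log10(nUMI); it is NaN (undefined, and
    removed by any filter) for cells with nUMI <= 1.
    """
    X = sp.csr_matrix(adata.X)
    n_umi = np.asarray(X.sum(axis=1)).ravel()
    n_gene = X.getnnz(axis=1)
    is_mito = np.array(
        [g.lower().startswith(mito_prefix.lower()) for g in adata.var_names]
    )
    mito_counts = (
        np.asarray(X[:, np.where(is_mito)[0]].sum(axis=1)).ravel()
        if is_mito.any()
        else np.zeros(X.shape[0])
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        mito_rate = np.where(n_umi > 0, mito_counts / np.maximum(n_umi, 1), 0.0)
        lgpu = np.where(
            n_umi > 1, np.log10(np.maximum(n_gene, 1)) / np.log10(np.maximum(n_umi, 2)),
            np.nan,
        )
    adata.obs["n_umi"] = n_umi
    adata.obs["n_gene"] = n_gene
    adata.obs["mito_rate"] = mito_rate
    adata.obs["log10_genes_per_umi"] = lgpu
    return adata


def qc_filter(adata: ad.AnnData, thresholds: QCThresholds) -> ad.AnnData:
    """Drop cells violating any removal rule; boundaries keep the cell."""
    obs = adata.obs
    for col in ("n_umi", "n_gene", "mito_rate", "log10_genes_per_umi"):
        if col not in obs:
            raise ConfigurationError("run compute_qc_metrics before qc_filter")
    lgpu = obs["log10_genes_per_umi"].to_numpy()
    keep = (
        (obs["n_umi"].to_numpy() >= thresholds.numi_min)
        & (obs["n_umi"].to_numpy() <= thresholds.numi_max)
        & (obs["n_gene"].to_numpy() >= thresholds.ngene_min)
        & (obs["n_gene"].to_numpy() <= thresholds.ngene_max)
        & (obs["mito_rate"].to_numpy() <= thresholds.mito_max)
        & ~np.isnan(lgpu)
        & (lgpu >= thresholds.lgpu_min)
    )
    return adata[keep].copy()


def gene_filter(adata: ad.AnnData, min_cells: int = 5) -> ad.AnnData:
    """Drop genes with nonzero counts in fewer than min_cells cells."""
    n_cells = sp.csr_matrix(adata.X).getnnz(axis=0)
    return adata[:, n_cells >= min_cells].copy()


def load_markers(path) -> dict[str, list[str]]:
    """Marker map from JSON ({type: [genes]}) or two-column TSV."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            return {str(k): list(v) for k, v in json.load(fh).items()}
    df = pd.read_csv(path, sep="\t")
    if not {"cell_type", "gene"} <= set(df.columns):
        raise FormatError("marker TSV needs cell_type and gene columns")
    return {t: g["gene"].tolist() for t, g in df.groupby("cell_type", sort=True)}


def assign_cell_types(
    adata: ad.AnnData, markers: Mapping[str, list[str]], key_added: str = "assigned_type"
) -> ad.AnnData:
    """Label each cell with the type whose markers score highest.

    Score = mean normalized (cp10k log1p) expression of the type's markers
    present in the matrix.  Exact ties break lexicographically by type
    name.  The margin between best and runner-up score is stored in
    ``<key_added>_margin``.
    """
    if not markers:
        raise ConfigurationError("empty marker map")
    if "norm" not in adata.layers:
        normalize_expression(adata)
    norm = adata.layers["norm"]
    types = sorted(markers)
    scores = np.zeros((adata.n_obs, len(types)))
    var_index = pd.Index(adata.var_names)
    for j, t in enumerate(types):
        present = var_index.get_indexer([g for g in markers[t] if g in var_index])
        if len(present) == 0:
            raise ConfigurationError(f"type {t!r} has no markers in the matrix")
        scores[:, j] = np.asarray(norm[:, present].mean(axis=1)).ravel()
    best = np.argmax(scores, axis=1)  # argmax takes the first (lexicographic) max
    srt = np.sort(scores, axis=1)
    adata.obs[key_added] = [types[i] for i in best]
    adata.obs[f"{key_added}_margin"] = srt[:, -1] - (
        srt[:, -2] if len(types) > 1 else 0.0
    )
    return adata


def dataset_compatibility(a: ad.AnnData, b: ad.AnnData, min_shared: int = 50) -> float:
    """Pearson correlation of log mean-expression profiles over shared genes."""
    shared = sorted(set(a.var_names) & set(b.var_names))
    if len(shared) < min_shared:
        raise InsufficientOverlapError(
            f"only {len(shared)} shared genes (need >= {min_shared})"
        )

    def profile(adata):
        if "norm" not in adata.layers:
            normalize_expression(adata)
        sub = adata[:, shared]
        return np.asarray(sub.layers["norm"].mean(axis=0)).ravel()

    pa, pb = profile(a), profile(b)
    if pa.std() == 0 or pb.std() == 0:
        return 0.0
    return float(np.corrcoef(pa, pb)[0, 1])
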