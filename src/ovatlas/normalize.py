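"""Normalization, variable-gene selection, embedding, batch correction,
and replicate agreement.

Counts are normalized to log1p of counts-per-10k: ln(1 + c / total * 1e4),
the standard depth normalization for droplet UMI data.  Replicate
agreement is quantified as the squared Pearson correlation of per-batch
pseudobulk profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

LOGNORM_LAYER = "lognorm"


@dataclass(frozen=True)
class NormalizationConfig:
    scale_factor: float = 1e4
    # log base is natural, pseudocount 1 (log1p); both fixed by the contract

    def validate(self) -> None:
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be > 0")


@dataclass
class Embedding:
    """PCA scores with the gene list and loadings that produced them."""

    coords: np.ndarray  # cells x components
    variance_ratio: np.ndarray
    genes: list[str]
    loadings: np.ndarray  # genes x components
    cell_ids: list[str]

    def __post_init__(self) -> None:
        if np.any(np.diff(self.variance_ratio) > 1e-12):
            raise ValueError("component variances must be non-increasing")


def normalize_log_cp10k(
    adata: ad.AnnData, config: NormalizationConfig | None = None
) -> ad.AnnData:
    """Store ln(1 + count / total * scale_factor) in ``layers['lognorm']``.

    Zeros map to zeros, so the sparsity pattern is preserved.  Cells with
    zero total are an input error: they must be removed by QC first.
    """
    config = config or NormalizationConfig()
    config.validate()
    x = sp.csr_matrix(adata.X, dtype=np.float64, copy=True)
    totals = np.asarray(x.sum(axis=1)).ravel()
    if np.any(totals <= 0):
        raise ValueError(
            "cells with zero total UMI present; run QC filtering before normalization"
        )
    scale = config.scale_factor / totals
    x.data *= np.repeat(scale, np.diff(x.indptr))
    np.log1p(x.data, out=x.data)
    adata.layers[LOGNORM_LAYER] = x
    return adata


def _lognorm(adata: ad.AnnData) -> sp.csr_matrix:
    if LOGNORM_LAYER not in adata.layers:
        raise ValueError("normalize_log_cp10k must be run first")
    return sp.csr_matrix(adata.layers[LOGNORM_LAYER])


def select_variable_genes(adata: ad.AnnData, n: int) -> list[str]:
    """The n genes with the highest standardized dispersion.

    Dispersion is variance / mean of the normalized values; dispersions
    are z-scored within 20 equal-frequency mean bins so that highly
    expressed genes do not dominate.  Ties break lexicographically by
    gene id, making the selection deterministic.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if n > adata.n_vars:
        raise ValueError(f"requested {n} genes but matrix has {adata.n_vars}")
    x = _lognorm(adata)
    mean = np.asarray(x.mean(axis=0)).ravel()
    sq = np.asarray(x.multiply(x).mean(axis=0)).ravel()
    var = np.maximum(sq - mean**2, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)

    expressed = mean > 0
    z = np.full(adata.n_vars, -np.inf)
    if expressed.sum() > 0:
        order = np.argsort(mean[expressed], kind="stable")
        # bins need enough genes for a meaningful within-bin z-score
        n_bins = max(1, min(20, int(expressed.sum()) // 10))
        bins = np.array_split(np.flatnonzero(expressed)[order], n_bins)
        for idx in bins:
            d = disp[idx]
            sd = d.std()
            z[idx] = (d - d.mean()) / sd if sd > 0 else d - d.mean()

    names = np.asarray(adata.var_names)
    # sort by (-z, gene id): highest standardized dispersion first
    order = np.lexsort((names, -z))
    return list(names[order[:n]])


def embed_pca(
    adata: ad.AnnData, genes: list[str] | None = None, n_components: int = 30
) -> Embedding:
    """PCA scores of the gene-standardized normalized submatrix.

    Genes are centered and scaled to unit variance, with standardized
    values clipped at +/-10 to bound outlier influence.  The sign of each
    component is fixed so its largest-magnitude loading is positive.
    """
    x = _lognorm(adata)
    if genes is None:
        genes = list(adata.var_names)
    gidx = adata.var_names.get_indexer(genes)
    if (gidx < 0).any():
        missing = [g for g, i in zip(genes, gidx) if i < 0]
        raise KeyError(f"genes not in matrix: {missing[:5]}")
    if n_components > min(adata.n_obs, len(genes)):
        raise ValueError(
            f"n_components={n_components} exceeds min(n_cells, n_genes)="
            f"{min(adata.n_obs, len(genes))}"
        )
    dense = np.asarray(x[:, gidx].todense(), dtype=np.float64)
    mean = dense.mean(axis=0)
    sd = dense.std(axis=0)
    sd[sd == 0] = 1.0
    z = np.clip((dense - mean) / sd, -10.0, 10.0)
    z -= z.mean(axis=0)  # re-center after clipping

    u, s, vt = np.linalg.svd(z, full_matrices=False)
    u, s, vt = u[:, :n_components], s[:n_components], vt[:n_components]
    # deterministic sign: largest-magnitude loading positive
    flip = np.sign(vt[np.arange(vt.shape[0]), np.argmax(np.abs(vt), axis=1)])
    flip[flip == 0] = 1.0
    vt = vt * flip[:, None]
    u = u * flip[None, :]

    total_var = (z**2).sum()
    var_ratio = (s**2) / total_var if total_var > 0 else np.zeros_like(s)
    return Embedding(
        coords=u * s,
        variance_ratio=var_ratio,
        genes=list(genes),
        loadings=vt.T,
        cell_ids=list(adata.obs_names),
    )


def correct_batches(emb: Embedding, batches) -> Embedding:
    """Shift every batch centroid onto the global centroid.

    Within-batch geometry is preserved exactly (pure translation).
    Batches with a single cell are left uncorrected with a warning.
    """
    batches = np.asarray(batches)
    if len(batches) != emb.coords.shape[0]:
        raise ValueError("batch labels do not match embedding cells")
    uniq = np.unique(batches)
    if len(uniq) < 2:
        raise ValueError("batch correction requires at least two batches")
    coords = emb.coords.copy()
    global_mean = coords.mean(axis=0)
    for b in uniq:
        mask = batches == b
        if mask.sum() < 2:
            warnings.warn(f"batch {b!r} has a single cell; left uncorrected")
            continue
        coords[mask] += global_mean - coords[mask].mean(axis=0)
    return Embedding(
        coords=coords,
        variance_ratio=emb.variance_ratio,
        genes=emb.genes,
        loadings=emb.loadings,
        cell_ids=emb.cell_ids,
    )


def pseudobulk_correlation(adata: ad.AnnData, batch_key: str = "batch") -> pd.DataFrame:
    """Squared Pearson correlation between per-batch pseudobulk profiles.

    The pseudobulk profile of a batch is the mean normalized expression
    of each gene over the batch's cells.
    """
    x = _lognorm(adata)
    batches = adata.obs[batch_key].astype(str)
    uniq = sorted(batches.unique())
    if len(uniq) < 2:
        raise ValueError("need at least two batches")
    profiles = []
    for b in uniq:
        mask = (batches == b).values
        if mask.sum() == 0:
            raise ValueError(f"batch {b!r} has zero cells")
        profiles.append(np.asarray(x[mask].mean(axis=0)).ravel())
    r = np.corrcoef(np.vstack(profiles))
    return pd.DataFrame(r**2, index=uniq, columns=uniq)
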