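"""Cell-level quality control.

Low-quality cells (debris, empty droplets) are removed on total UMI and
detected-gene thresholds; doublets are flagged by co-expression of
mutually exclusive lineage markers (e.g. a germline marker together with
a somatic marker), on raw UMI counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

QC_COLUMNS = ["total_umi", "n_genes_detected", "doublet_flag", "doublet_reason"]


@dataclass(frozen=True)
class QcThresholds:
    """UMI / gene-count bounds; None means unbounded.

    Defaults (min_umi=500, min_genes=200) separate debris at ~10% of a
    normal library from intact cells; per-dataset values are expected to
    be overridden from the pipeline configuration.
    """

    min_umi: int = 500
    max_umi: int | None = None
    min_genes: int = 200
    max_genes: int | None = None

    def validate(self) -> None:
        if self.max_umi is not None and self.min_umi > self.max_umi:
            raise ValueError("min_umi exceeds max_umi")
        if self.max_genes is not None and self.min_genes > self.max_genes:
            raise ValueError("min_genes exceeds max_genes")


@dataclass(frozen=True)
class ExclusivePair:
    """Two genes never co-expressed in an intact cell.

    A cell with count(gene_a) >= min_count_a and count(gene_b) >=
    min_count_b is flagged as a doublet.
    """

    name: str
    gene_a: str
    gene_b: str
    min_count_a: int = 1
    min_count_b: int = 1

    def validate(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError(f"pair {self.name!r}: gene_a equals gene_b")
        if self.min_count_a < 1 or self.min_count_b < 1:
            raise ValueError(f"pair {self.name!r}: thresholds must be >= 1")


def compute_cell_qc(adata: ad.AnnData) -> pd.DataFrame:
    """Per-cell total UMI and number of detected genes (count >= 1)."""
    if adata.n_vars == 0:
        raise ValueError("matrix has zero genes")
    if adata.n_obs == 0:
        raise ValueError("matrix has zero cells")
    x = sp.csr_matrix(adata.X).copy()
    x.eliminate_zeros()
    qc = pd.DataFrame(
        {
            "total_umi": np.asarray(x.sum(axis=1)).ravel().astype(np.int64),
            "n_genes_detected": np.diff(x.indptr).astype(np.int64),
            "doublet_flag": False,
            "doublet_reason": "",
        },
        index=adata.obs_names.copy(),
    )
    return qc


def flag_marker_doublets(
    adata: ad.AnnData, pairs: list[ExclusivePair], qc: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Flag cells co-expressing both genes of any exclusive pair.

    The reason column records the first matching pair in list order.
    Thresholds apply to raw UMI counts.
    """
    if qc is None:
        qc = compute_cell_qc(adata)
    qc = qc.copy()
    x = sp.csc_matrix(adata.X)
    flag = np.zeros(adata.n_obs, dtype=bool)
    reason = np.full(adata.n_obs, "", dtype=object)
    for pair in pairs:
        pair.validate()
        for g in (pair.gene_a, pair.gene_b):
            if g not in adata.var_names:
                raise KeyError(f"pair {pair.name!r}: gene {g!r} not present in matrix")
        a = np.asarray(x[:, adata.var_names.get_loc(pair.gene_a)].todense()).ravel()
        b = np.asarray(x[:, adata.var_names.get_loc(pair.gene_b)].todense()).ravel()
        hit = (a >= pair.min_count_a) & (b >= pair.min_count_b)
        newly = hit & ~flag
        reason[newly] = pair.name
        flag |= hit
    qc["doublet_flag"] = flag
    qc["doublet_reason"] = reason
    return qc


def filter_cells(
    adata: ad.AnnData, qc: pd.DataFrame, thresholds: QcThresholds
) -> ad.AnnData:
    """Retain cells inside the UMI/gene bounds and not flagged as doublets.

    Gene set and cell order are preserved.  A threshold combination that
    retains zero cells is a warning, not an error.
    """
    thresholds.validate()
    if not qc.index.equals(adata.obs_names):
        raise ValueError("QC table does not match matrix cells")
    keep = (qc["total_umi"] >= thresholds.min_umi) & (
        qc["n_genes_detected"] >= thresholds.min_genes
    )
    if thresholds.max_umi is not None:
        keep &= qc["total_umi"] <= thresholds.max_umi
    if thresholds.max_genes is not None:
        keep &= qc["n_genes_detected"] <= thresholds.max_genes
    keep &= ~qc["doublet_flag"].astype(bool)
    if not keep.any():
        warnings.warn("QC thresholds retain zero cells")
    return adata[keep.values].copy()


def pairs_from_branch_markers(
    adata: ad.AnnData,
    branch_a: str,
    branch_b: str,
    n_pairs: int | None = None,
    fpr_per_gene: float = 1e-3,
) -> list[ExclusivePair]:
    """Build exclusive pairs from the planted marker sets of two tier-1
    branches of a simulated scene.

    Stands in for the biological knowledge behind pairs like vas/tj: the
    generator records each gene's marker assignment, baseline mean and
    on/off exclusivity in ``var`` and the dispersion and library-size
    model in ``uns``, from which the off-lineage count distribution
    follows.  The lineage-defining exclusive genes of each branch are
    used (all of them unless ``n_pairs`` caps the count), paired one
    against one; each gene's threshold is the (1 - fpr_per_gene)
    quantile of its negative-binomial off-lineage distribution, so an
    intact off-lineage cell almost never reaches it while a doublet —
    carrying roughly half the in-lineage level — usually does.
    """
    import scipy.stats

    var = adata.var
    meta = adata.uns["hierarchy"]
    median_lib = float(np.exp(meta["library_size_log_mu"]))
    dispersion = float(meta["dispersion"])
    off_scale = float(meta.get("exclusive_off_scale", 1.0))
    size = 1.0 / dispersion
    scale = median_lib / float(var["baseline_mean"].sum())

    chosen = {}
    for branch in (branch_a, branch_b):
        genes = var.index[(var["marker_of"] == branch) & var["exclusive"]]
        if len(genes) == 0:
            raise KeyError(f"no exclusive lineage genes for branch {branch!r}")
        ranked = var.loc[genes, "baseline_mean"].sort_values(ascending=False)
        chosen[branch] = ranked.index

    count = min(len(chosen[branch_a]), len(chosen[branch_b]))
    if n_pairs is not None:
        if count < n_pairs:
            raise ValueError(f"fewer than {n_pairs} exclusive genes per branch")
        count = n_pairs

    pairs = []
    for i, (ga, gb) in enumerate(zip(chosen[branch_a][:count], chosen[branch_b][:count])):
        thresholds = []
        for g in (ga, gb):
            m_off = float(var.loc[g, "baseline_mean"]) * scale * off_scale
            q = scipy.stats.nbinom.ppf(1 - fpr_per_gene, size, size / (size + m_off))
            thresholds.append(max(2, int(q) + 1))
        pairs.append(
            ExclusivePair(
                name=f"{branch_a}x{branch_b}-{i}",
                gene_a=ga,
                gene_b=gb,
                min_count_a=thresholds[0],
                min_count_b=thresholds[1],
            )
        )
    return pairs
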