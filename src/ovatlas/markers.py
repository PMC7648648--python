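"""Marker ranking, "most unique gene" tables, dot-plot summaries,
reference-based cluster annotation, and expression-matched gene-set
scores.

"Uniqueness" of a gene for a cluster is the margin between the cluster's
mean normalized expression and the maximum mean among all other clusters;
a gene belongs to at most one cluster (the argmax of its cluster means).
This margin definition is a stand-in for a visual "cluster-exclusive"
ranking and is deliberately a function of per-cluster mean profiles only.
"""

from __future__ import annotations

import warnings

import anndata as ad
import numpy as np
import pandas as pd

from ._stats import bh_adjust, log2_fold_change, rank_sum_pvalues
from .normalize import _lognorm


def _labels_array(adata: ad.AnnData, labels) -> np.ndarray:
    labels = np.asarray(labels).astype(str)
    if len(labels) != adata.n_obs:
        raise ValueError("labels do not match cells")
    return labels


def _cluster_means(dense: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    uniq = sorted(np.unique(labels))
    return pd.DataFrame(
        {u: dense[labels == u].mean(axis=0) for u in uniq}
    ).T  # clusters x genes


def rank_markers(adata: ad.AnnData, labels, cluster: str) -> pd.DataFrame:
    """Rank genes differentially expressed in ``cluster`` vs all other cells.

    Two-sided Wilcoxon rank-sum per gene with Benjamini-Hochberg
    adjustment across genes; fold-changes on the expm1 (de-logged) scale.
    Sorted by adjusted p, then |log2FC| (descending), then gene id.
    """
    labels = _labels_array(adata, labels)
    mask = labels == str(cluster)
    if mask.sum() < 3:
        raise ValueError(
            f"cluster {cluster!r} has {mask.sum()} cells (< 3); assign it by "
            "supervised marker annotation instead"
        )
    dense = np.asarray(_lognorm(adata).todense())
    x, y = dense[mask], dense[~mask]
    p = rank_sum_pvalues(x, y)
    padj = bh_adjust(p)
    lfc = log2_fold_change(x, y)
    means = _cluster_means(dense, labels)
    others = means.drop(index=str(cluster))
    uniqueness = means.loc[str(cluster)].values - others.values.max(axis=0)
    df = pd.DataFrame(
        {
            "gene": adata.var_names,
            "cluster": str(cluster),
            "log2_fold_change": lfc,
            "p_value": p,
            "p_adjusted": padj,
            "frac_in": (x > 0).mean(axis=0),
            "frac_out": (y > 0).mean(axis=0),
            "uniqueness": uniqueness,
        }
    )
    df = df.sort_values(
        by=["p_adjusted", "log2_fold_change", "gene"],
        key=lambda s: -s.abs() if s.name == "log2_fold_change" else s,
    ).reset_index(drop=True)
    return df


def top_unique_genes(adata: ad.AnnData, labels, n: int) -> dict[str, list[str]]:
    """Top-N most unique genes per cluster.

    A gene is assigned to the cluster where its mean normalized
    expression is highest; its uniqueness there is the margin over the
    runner-up cluster mean.  Each cluster's list is its assigned genes
    sorted by margin (descending), ties broken lexicographically.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    labels = _labels_array(adata, labels)
    uniq = sorted(np.unique(labels))
    if len(uniq) < 2:
        raise ValueError("need at least two clusters")
    dense = np.asarray(_lognorm(adata).todense())
    means = _cluster_means(dense, labels)  # clusters x genes
    m = means.values
    order = np.argsort(-m, axis=0, kind="stable")
    best, second = order[0], order[1]
    margin = m[best, np.arange(m.shape[1])] - m[second, np.arange(m.shape[1])]

    out: dict[str, list[str]] = {u: [] for u in uniq}
    genes = np.asarray(adata.var_names)
    df = pd.DataFrame(
        {"gene": genes, "cluster": np.asarray(means.index)[best], "margin": margin}
    )
    for u, grp in df.groupby("cluster"):
        ranked = grp.sort_values(["margin", "gene"], ascending=[False, True])
        out[u] = ranked["gene"].head(n).tolist()
    return out


def dot_plot_stats(adata: ad.AnnData, labels, genes: list[str]) -> pd.DataFrame:
    """Long-form (cluster, gene) table of expression fraction and mean.

    Fraction is the share of the cluster's cells with normalized value
    > 0; mean is over all cells in the cluster.
    """
    labels = _labels_array(adata, labels)
    missing = [g for g in genes if g not in adata.var_names]
    if missing:
        raise KeyError(f"genes not in matrix: {missing}")
    gidx = adata.var_names.get_indexer(genes)
    dense = np.asarray(_lognorm(adata)[:, gidx].todense())
    rows = []
    for u in sorted(np.unique(labels)):
        sub = dense[labels == u]
        for j, g in enumerate(genes):
            rows.append(
                {
                    "cluster": u,
                    "gene": g,
                    "frac_expressing": float((sub[:, j] > 0).mean()),
                    "mean_norm": float(sub[:, j].mean()),
                }
            )
    return pd.DataFrame(rows)


def annotate_clusters(
    adata: ad.AnnData,
    labels,
    reference: pd.DataFrame | dict,
    min_margin: float = 0.1,
) -> pd.DataFrame:
    """Assign each cluster a cell type from a signed marker reference.

    The reference maps cell type -> [(gene, sign)] with sign "+"/"-"
    (or a TSV-shaped DataFrame with columns cell_type, gene, sign).  A
    cluster's score for a type is the mean z-scored expression of the
    "+" genes minus the mean of the "-" genes; the argmax type is
    assigned when its margin over the runner-up reaches ``min_margin``
    (a single-type reference is compared against a zero baseline),
    otherwise the cluster is "unassigned".
    """
    labels = _labels_array(adata, labels)
    if isinstance(reference, pd.DataFrame):
        ref = {
            t: list(zip(grp["gene"], grp["sign"]))
            for t, grp in reference.groupby("cell_type")
        }
    else:
        ref = dict(reference)
    if not ref:
        raise ValueError("empty marker reference")
    all_genes = {g for pairs in ref.values() for g, _ in pairs}
    missing = sorted(g for g in all_genes if g not in adata.var_names)
    if missing:
        raise KeyError(f"reference genes not in matrix: {missing}")

    dense = np.asarray(_lognorm(adata).todense())
    sd = dense.std(axis=0)
    sd[sd == 0] = 1.0
    z = (dense - dense.mean(axis=0)) / sd
    zmeans = _cluster_means(z, labels)  # clusters x genes

    gidx = {g: adata.var_names.get_loc(g) for g in all_genes}
    rows = []
    for u in zmeans.index:
        scores = {}
        for t, pairs in ref.items():
            pos = [zmeans.loc[u].iloc[gidx[g]] for g, s in pairs if s == "+"]
            neg = [zmeans.loc[u].iloc[gidx[g]] for g, s in pairs if s == "-"]
            scores[t] = (np.mean(pos) if pos else 0.0) - (np.mean(neg) if neg else 0.0)
        ranked = sorted(scores.items(), key=lambda kv: -kv[1])
        best_t, best_s = ranked[0]
        runner = ranked[1][1] if len(ranked) > 1 else 0.0
        margin = best_s - runner
        assigned = best_t if margin >= min_margin else "unassigned"
        rows.append(
            {"cluster": u, "cell_type": assigned, "score": best_s, "margin": margin}
        )
    return pd.DataFrame(rows).set_index("cluster")


def score_gene_set(
    adata: ad.AnnData,
    gene_set: list[str],
    n_control_bins: int = 25,
    ctrl_size: int = 50,
    seed: int = 0,
) -> pd.Series:
    """Per-cell gene-set score against expression-matched controls.

    Score = mean normalized expression of the set genes minus the mean
    of control genes drawn (seeded) from the same average-expression
    bins, so the score reflects set-specific regulation rather than
    overall expression level.
    """
    uniq_set = list(dict.fromkeys(gene_set))
    if len(uniq_set) < len(gene_set):
        warnings.warn("duplicated genes in set were deduplicated")
    present = [g for g in uniq_set if g in adata.var_names]
    absent = [g for g in uniq_set if g not in adata.var_names]
    if not present:
        raise KeyError(f"no gene of the set is present in the matrix; missing: {absent}")
    if absent:
        warnings.warn(f"{len(absent)} set genes absent from matrix and ignored")

    x = _lognorm(adata)
    gene_mean = np.asarray(x.mean(axis=0)).ravel()
    order = np.argsort(gene_mean, kind="stable")
    n_bins = min(n_control_bins, adata.n_vars)
    bin_of = np.empty(adata.n_vars, dtype=int)
    for b, idx in enumerate(np.array_split(order, n_bins)):
        bin_of[idx] = b

    rng = np.random.default_rng(seed)
    set_idx = np.asarray(adata.var_names.get_indexer(present))
    set_mask = np.zeros(adata.n_vars, dtype=bool)
    set_mask[set_idx] = True
    controls: set[int] = set()
    for b in np.unique(bin_of[set_idx]):
        in_bin = np.flatnonzero(bin_of == b)
        candidates = in_bin[~set_mask[in_bin]]
        if len(candidates) == 0:
            # set covers the whole bin: the bin itself is the (self-matched)
            # control, so a whole-genome set scores exactly zero
            controls.update(in_bin.tolist())
            continue
        take = min(ctrl_size, len(candidates))
        controls.update(rng.choice(candidates, size=take, replace=False).tolist())
    ctrl_idx = np.asarray(sorted(controls))

    set_score = np.asarray(x[:, set_idx].mean(axis=1)).ravel()
    ctrl_score = np.asarray(x[:, ctrl_idx].mean(axis=1)).ravel()
    return pd.Series(set_score - ctrl_score, index=adata.obs_names, name="gene_set_score")
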