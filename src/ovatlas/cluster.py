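"""Iterative tiered clustering with a differential-gene quality gate.

The procedure clusters the whole dataset, asks whether the resulting
subclusters are "sufficiently distinct" — every subcluster must show at
least Q genes that are significantly up-regulated against the union of
its siblings — and, when the gate ratifies the split, recurses into each
subcluster.  The result is a tier tree: every cell carries a dotted label
("1.0.2") whose k-th prefix is its tier-k cluster.

Community detection is Leiden modularity optimization on a shared-
nearest-neighbor graph built in a node-local PCA space, swept from the
lowest resolution upward so the coarsest viable split is found first.
When the graph decomposes into more than two communities at once, the
tier split is coarsened to the top bifurcation of an average-linkage
dendrogram over community centroids (``binary_tiers``): each tier then
separates the two most distantly related groups and recursion recovers
the finer structure, which keeps the tree hierarchical even when all
subtypes are simultaneously resolvable in the graph.
"""

from __future__ import annotations

import copy
import json
import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.cluster.hierarchy
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

import igraph
import leidenalg

from ._stats import bh_adjust, log2_fold_change, rank_sum_pvalues
from .normalize import _lognorm, embed_pca, select_variable_genes

SNN_PRUNE = 1 / 15  # discard shared-neighbor edges with Jaccard below this


@dataclass(frozen=True)
class ClusteringConfig:
    quality_genes: int = 5
    de_alpha: float = 0.05
    de_min_lfc: float = 1.0
    de_min_frac: float = 0.25
    resolution_grid: tuple[float, ...] = tuple(np.round(np.arange(0.1, 1.21, 0.1), 2))
    knn_k: int = 20
    min_cells_to_split: int = 50
    max_depth: int = 5
    seed: int = 0
    n_hvg: int = 2000
    n_pcs: int = 30
    local_embedding: bool = True
    binary_tiers: bool = True
    gate_two_sided: bool = False

    def validate(self) -> None:
        if self.quality_genes < 1:
            raise ValueError("quality_genes must be >= 1")
        if not 0 < self.de_alpha < 1:
            raise ValueError("de_alpha must lie in (0, 1)")
        if any(b <= a for a, b in zip(self.resolution_grid, self.resolution_grid[1:])):
            raise ValueError("resolution_grid must be strictly increasing")


@dataclass
class SubclusterReport:
    label: int
    n_cells: int
    n_passing_genes: int
    auto_failed: bool  # subcluster too small for the test


@dataclass
class GateReport:
    subclusters: list[SubclusterReport]
    passed: bool
    resolution: float | None = None

    def to_dict(self) -> dict:
        return {
            "passed": self.passed,
            "resolution": self.resolution,
            "subclusters": [
                {
                    "label": s.label,
                    "n_cells": s.n_cells,
                    "n_passing_genes": s.n_passing_genes,
                    "auto_failed": s.auto_failed,
                }
                for s in self.subclusters
            ],
        }


@dataclass
class NodeClustering:
    labels: np.ndarray  # community index per node cell
    resolution: float
    coords: np.ndarray  # node-local embedding used for the graph


@dataclass
class TierNode:
    label: str
    parent: str | None
    cell_ids: np.ndarray
    terminal: bool
    gate: GateReport | None = None
    supervised: bool = False


@dataclass
class TierTree:
    nodes: dict[str, TierNode]
    cell_terminal: pd.Series  # cell id -> terminal label

    def terminal_labels(self) -> list[str]:
        return sorted(n.label for n in self.nodes.values() if n.terminal)

    def assert_partition(self) -> None:
        """Children partition their parent; terminal labels cover all cells."""
        for node in self.nodes.values():
            children = [c for c in self.nodes.values() if c.parent == node.label]
            if node.terminal:
                assert not children, f"terminal node {node.label} has children"
                continue
            union = np.concatenate([c.cell_ids for c in children])
            assert len(union) == len(set(union)) == len(node.cell_ids), (
                f"children of {node.label} do not partition it"
            )
            assert set(union) == set(node.cell_ids)
        for cid, term in self.cell_terminal.items():
            parts = term.split(".")
            for k in range(1, len(parts) + 1):
                prefix = ".".join(parts[:k])
                assert cid in set(self.nodes[prefix].cell_ids)

    def to_frame(self) -> pd.DataFrame:
        depth = max(len(t.split(".")) for t in self.cell_terminal.values)
        rows = {}
        for k in range(depth):
            rows[f"tier{k + 1}"] = [
                ".".join(t.split(".")[: k + 1]) if len(t.split(".")) > k else ""
                for t in self.cell_terminal.values
            ]
        df = pd.DataFrame(rows, index=self.cell_terminal.index)
        df["terminal_label"] = self.cell_terminal.values
        return df

    def to_json(self) -> str:
        payload = {
            label: {
                "parent": node.parent,
                "n_cells": int(len(node.cell_ids)),
                "terminal": bool(node.terminal),
                "supervised": bool(node.supervised),
                "gate": node.gate.to_dict() if node.gate else None,
            }
            for label, node in sorted(self.nodes.items())
        }
        return json.dumps(payload, indent=2)


# ---------------------------------------------------------------------------
# graph construction and community detection
# ---------------------------------------------------------------------------


def _snn_graph(coords: np.ndarray, k: int) -> igraph.Graph:
    """Shared-nearest-neighbor graph: Jaccard overlap of kNN sets (self
    included), pruned below 1/15."""
    n = coords.shape[0]
    nn = NearestNeighbors(n_neighbors=min(k + 1, n)).fit(coords)
    idx = nn.kneighbors(coords, return_distance=False)
    rows = np.repeat(np.arange(n), idx.shape[1])
    member = sp.csr_matrix(
        (np.ones(idx.size), (rows, idx.ravel())), shape=(n, n), dtype=np.float64
    )
    shared = member @ member.T
    shared = sp.coo_matrix(sp.triu(shared, k=1))
    setsize = idx.shape[1]
    jac = shared.data / (2 * setsize - shared.data)
    keep = jac >= SNN_PRUNE
    edges = list(zip(shared.row[keep].tolist(), shared.col[keep].tolist()))
    g = igraph.Graph(n=n, edges=edges)
    g.es["weight"] = jac[keep]
    return g


def cluster_node(
    adata: ad.AnnData, cells: np.ndarray, config: ClusteringConfig
) -> NodeClustering | None:
    """Community detection restricted to ``cells``.

    Re-embeds on node-local variable genes, builds the SNN graph, and
    runs Leiden at the lowest resolution in the grid that yields at least
    two communities.  Returns None when no resolution splits the node
    ("unsplittable") or the geometry is degenerate (identical points).
    """
    config.validate()
    n = len(cells)
    if n < 3:
        return None
    sub = adata[cells].copy()
    if config.local_embedding:
        n_hvg = min(config.n_hvg, sub.n_vars)
        genes = select_variable_genes(sub, n_hvg)
    else:
        genes = None
    n_pcs = min(config.n_pcs, n - 1, len(genes) if genes is not None else sub.n_vars)
    if n_pcs < 1:
        return None
    emb = embed_pca(sub, genes, n_pcs)
    coords = emb.coords
    if not np.any(np.ptp(coords, axis=0) > 0):
        return None  # identical points: nothing to split

    k = config.knn_k
    if k > n - 1:
        warnings.warn(f"knn_k={k} reduced to {n - 1} for a {n}-cell node")
        k = n - 1
    g = _snn_graph(coords, k)

    for res in config.resolution_grid:
        part = leidenalg.find_partition(
            g,
            leidenalg.RBConfigurationVertexPartition,
            weights="weight",
            resolution_parameter=float(res),
            seed=config.seed,
            n_iterations=2,
        )
        labels = np.asarray(part.membership)
        if len(np.unique(labels)) >= 2:
            return NodeClustering(labels=labels, resolution=float(res), coords=coords)
    return None


def coarsen_to_top_split(labels: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Merge communities into the two top-level dendrogram branches.

    Average-linkage agglomeration of community centroids; the root
    bifurcation of the dendrogram defines the (binary) tier split.
    """
    uniq = np.unique(labels)
    if len(uniq) <= 2:
        return labels
    centroids = np.vstack([coords[labels == u].mean(axis=0) for u in uniq])
    link = scipy.cluster.hierarchy.linkage(centroids, method="average")
    groups = scipy.cluster.hierarchy.fcluster(link, t=2, criterion="maxclust") - 1
    mapping = dict(zip(uniq.tolist(), groups.tolist()))
    return np.asarray([mapping[l] for l in labels])


# ---------------------------------------------------------------------------
# quality gate
# ---------------------------------------------------------------------------


def quality_gate(
    adata: ad.AnnData,
    cells: np.ndarray,
    labels: np.ndarray,
    config: ClusteringConfig,
    resolution: float | None = None,
) -> GateReport:
    """Differential-gene gate over a candidate sub-clustering.

    Each subcluster is tested gene-by-gene (two-sided Wilcoxon rank-sum)
    against the union of its siblings, with Benjamini-Hochberg adjustment
    across genes within the comparison.  A gene passes for a subcluster
    when adjusted p < de_alpha, the subcluster is on the high side with
    log2 fold-change >= de_min_lfc (|lfc| if gate_two_sided), and at
    least de_min_frac of the subcluster's cells express it.  The gate
    passes iff there are >= 2 subclusters and every one has at least
    ``quality_genes`` passing genes.  Subclusters with < 3 cells fail
    automatically (too small to test).
    """
    config.validate()
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("quality_gate needs at least two candidate subclusters")
    dense = np.asarray(_lognorm(adata)[cells].todense())
    reports: list[SubclusterReport] = []
    for u in uniq:
        mask = labels == u
        n_in = int(mask.sum())
        if n_in < 3:
            reports.append(SubclusterReport(int(u), n_in, 0, auto_failed=True))
            continue
        x, y = dense[mask], dense[~mask]
        padj = bh_adjust(rank_sum_pvalues(x, y))
        lfc = log2_fold_change(x, y)
        frac_in = (x > 0).mean(axis=0)
        high = np.abs(lfc) >= config.de_min_lfc if config.gate_two_sided else lfc >= config.de_min_lfc
        n_pass = int(((padj < config.de_alpha) & high & (frac_in >= config.de_min_frac)).sum())
        reports.append(SubclusterReport(int(u), n_in, n_pass, auto_failed=False))
    passed = all(
        (not r.auto_failed) and r.n_passing_genes >= config.quality_genes for r in reports
    )
    return GateReport(subclusters=reports, passed=passed, resolution=resolution)


# ---------------------------------------------------------------------------
# recursion
# ---------------------------------------------------------------------------


def _ordered_children(
    cells: np.ndarray, labels: np.ndarray, cell_ids: np.ndarray
) -> list[np.ndarray]:
    """Child cell-index arrays ordered by decreasing size, ties broken by
    the lexicographically smallest member cell id."""
    groups = []
    for u in np.unique(labels):
        idx = cells[labels == u]
        groups.append((-len(idx), min(cell_ids[idx]), idx))
    groups.sort(key=lambda g: (g[0], g[1]))
    return [g[2] for g in groups]


def run_tiered_clustering(adata: ad.AnnData, config: ClusteringConfig) -> TierTree:
    """Depth-first tiered clustering of the whole dataset.

    At each node: cluster -> (optionally coarsen to the top binary
    split) -> quality gate.  On a ratified split the children become
    tier nodes and recursion continues; otherwise the node is terminal.
    A dataset whose first split is rejected yields the single terminal
    node "0".
    """
    config.validate()
    if adata.n_obs == 0:
        raise ValueError("empty input")
    _lognorm(adata)  # fail fast if normalization is missing
    cell_ids = np.asarray(adata.obs_names)
    nodes: dict[str, TierNode] = {}
    terminal = {}

    def attempt_split(cells: np.ndarray, depth: int):
        if depth >= config.max_depth or len(cells) < config.min_cells_to_split:
            return None, None
        nc = cluster_node(adata, cells, config)
        if nc is None:
            return None, None
        labels = nc.labels
        if config.binary_tiers:
            labels = coarsen_to_top_split(labels, nc.coords)
        report = quality_gate(adata, cells, labels, config, resolution=nc.resolution)
        if not report.passed:
            return None, report
        return labels, report

    def recurse(cells: np.ndarray, label: str, parent: str | None, depth: int):
        labels, report = attempt_split(cells, depth)
        node = TierNode(
            label=label,
            parent=parent,
            cell_ids=cell_ids[cells],
            terminal=labels is None,
            gate=report,
        )
        nodes[label] = node
        if labels is None:
            for cid in node.cell_ids:
                terminal[cid] = label
            return
        for i, child in enumerate(_ordered_children(cells, labels, cell_ids)):
            recurse(child, f"{label}.{i}", label, depth + 1)

    all_cells = np.arange(adata.n_obs)
    root_labels, root_report = attempt_split(all_cells, 0)
    if root_labels is None:
        node = TierNode("0", None, cell_ids.copy(), terminal=True, gate=root_report)
        nodes["0"] = node
        terminal = {cid: "0" for cid in cell_ids}
    else:
        for i, child in enumerate(_ordered_children(all_cells, root_labels, cell_ids)):
            recurse(child, str(i), None, 1)

    series = pd.Series({cid: terminal[cid] for cid in cell_ids}, name="terminal_label")
    series.index.name = "cell_id"
    return TierTree(nodes=nodes, cell_terminal=series.loc[cell_ids])


def split_cluster_by_marker(
    tree: TierTree,
    adata: ad.AnnData,
    node_label: str,
    gene: str,
    min_normalized_value: float,
) -> TierTree:
    """Supervised split of a terminal node on a single marker gene.

    Cells of the node with normalized expression >= the threshold form
    one child, the remainder the sibling; both are flagged "supervised".
    An empty side makes the split a warning no-op.
    """
    if node_label not in tree.nodes:
        raise KeyError(f"no node {node_label!r} in tree")
    node = tree.nodes[node_label]
    if not node.terminal:
        raise ValueError(f"node {node_label!r} is not terminal; only terminal nodes may be split")
    if gene not in adata.var_names:
        raise KeyError(f"gene {gene!r} not present in matrix")

    x = _lognorm(adata)
    gi = adata.var_names.get_loc(gene)
    cell_pos = adata.obs_names.get_indexer(node.cell_ids)
    vals = np.asarray(x[cell_pos, gi].todense()).ravel()
    high = vals >= min_normalized_value
    if high.all() or not high.any():
        warnings.warn(
            f"marker split of {node_label!r} on {gene!r} at {min_normalized_value} "
            "leaves one side empty; no-op"
        )
        return tree

    out = copy.deepcopy(tree)
    parent = out.nodes[node_label]
    parent.terminal = False
    sides = [node.cell_ids[high], node.cell_ids[~high]]
    sides.sort(key=lambda ids: (-len(ids), min(ids)))
    for i, ids in enumerate(sides):
        child_label = f"{node_label}.{i}"
        out.nodes[child_label] = TierNode(
            label=child_label,
            parent=node_label,
            cell_ids=ids,
            terminal=True,
            supervised=True,
        )
        out.cell_terminal.loc[ids] = child_label
    return out
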