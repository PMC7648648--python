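"""Trajectory inference, pseudotime, fixed-size binning, and
pseudotime-dependent expression.

The backbone is a minimum spanning tree over cluster centroids in
embedding space (k-means groups when no clustering is available); cells
are projected onto the nearest backbone edge and pseudotime is the
geodesic distance along the tree from a root endpoint, min-max scaled to
[0, 1].  The root is selected either as an explicit cell or as the
endpoint whose cells have extremal mean expression of a marker gene —
e.g. the endpoint with the lowest expression of a differentiation gene
marks the stem-cell end.  This centroid-MST construction is a simple,
deterministic stand-in for principal-graph learning and is adequate for
linear or mildly branched trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.csgraph as csgraph
from sklearn.cluster import KMeans

from ._stats import bh_adjust, spearman_vs_vector
from .normalize import _lognorm


@dataclass(frozen=True)
class RootSpec:
    """Root endpoint selection: the backbone endpoint whose cells show
    the extremal mean expression of ``marker``."""

    marker: str
    extremum: str = "min"  # "min" or "max"

    def validate(self) -> None:
        if self.extremum not in ("min", "max"):
            raise ValueError("extremum must be 'min' or 'max'")


@dataclass(frozen=True)
class TrajectoryConfig:
    """Trajectory fitting parameters.

    The backbone lives in a deliberately low-dimensional embedding
    (``n_components`` top PCs of ``n_hvg`` variable genes): a
    differentiation continuum occupies few directions, and extra noise
    dimensions make the centroid MST snake.  ``n_groups`` k-means groups
    define the backbone when no fine-grained clustering is supplied.
    """

    n_components: int = 3
    n_hvg: int = 500
    n_groups: int = 6  # k-means groups when no clustering is supplied
    bin_size: int = 10
    seed: int = 0

    def validate(self) -> None:
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        if self.n_groups < 2:
            raise ValueError("n_groups must be >= 2")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")


@dataclass
class Trajectory:
    centroids: np.ndarray  # groups x dims
    mst: sp.csr_matrix  # symmetric edge-length matrix of the backbone tree
    edges: list[tuple[int, int, float]]
    cell_edge: np.ndarray  # (n, 2) endpoint indices of each cell's edge
    cell_s: np.ndarray  # position along the edge in [0, 1]
    cell_ids: list[str]
    group_labels: np.ndarray  # backbone group per cell

    def nearest_node(self) -> np.ndarray:
        """Backbone node each cell projects closest to."""
        return np.where(self.cell_s < 0.5, self.cell_edge[:, 0], self.cell_edge[:, 1])

    def endpoints(self) -> list[int]:
        deg = np.asarray((self.mst > 0).sum(axis=0)).ravel()
        return [int(i) for i in np.flatnonzero(deg == 1)]

    def is_path(self) -> bool:
        deg = np.asarray((self.mst > 0).sum(axis=0)).ravel()
        return bool((deg <= 2).all() and (deg == 1).sum() == 2)


def fit_trajectory(
    coords: np.ndarray,
    cell_ids,
    labels=None,
    config: TrajectoryConfig | None = None,
) -> Trajectory:
    """Build the centroid-MST backbone and project every cell onto it.

    ``labels`` supplies fine-grained cluster assignments; with none (or a
    single cluster) cells are grouped by seeded k-means instead.
    Duplicate centroids are kept; ties resolve by label order, which the
    deterministic MST construction respects.
    """
    config = config or TrajectoryConfig()
    config.validate()
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if labels is not None and len(np.unique(np.asarray(labels).astype(str))) >= 2:
        lab = np.asarray(labels).astype(str)
        uniq = sorted(np.unique(lab))
        group = np.asarray([uniq.index(l) for l in lab])
    else:
        if n < 50:
            raise ValueError(
                "need >= 2 clusters or >= 50 cells (k-means pre-grouping) to fit a backbone"
            )
        km = KMeans(n_clusters=min(config.n_groups, n), n_init=10, random_state=config.seed)
        group = km.fit_predict(coords)
    n_groups = group.max() + 1
    if n_groups < 2:
        raise ValueError("fewer than 2 centroids; supply labels or more cells")
    centroids = np.vstack([coords[group == g].mean(axis=0) for g in range(n_groups)])

    d = np.sqrt(((centroids[:, None, :] - centroids[None, :, :]) ** 2).sum(-1))
    d = np.maximum(d, 1e-12)  # keep zero-length edges representable
    mst = csgraph.minimum_spanning_tree(d)
    mst = mst + mst.T

    coo = sp.triu(mst).tocoo()
    edges = sorted(zip(coo.row.tolist(), coo.col.tolist(), coo.data.tolist()))

    # project each cell to the nearest backbone segment
    best_dist = np.full(n, np.inf)
    cell_edge = np.zeros((n, 2), dtype=int)
    cell_s = np.zeros(n)
    for u, v, length in edges:
        a, b = centroids[u], centroids[v]
        ab = b - a
        denom = (ab**2).sum()
        s = np.clip((coords - a) @ ab / denom, 0.0, 1.0) if denom > 0 else np.zeros(n)
        proj = a + s[:, None] * ab
        dist = ((coords - proj) ** 2).sum(axis=1)
        better = dist < best_dist
        best_dist[better] = dist[better]
        cell_edge[better] = (u, v)
        cell_s[better] = s[better]

    return Trajectory(
        centroids=centroids,
        mst=sp.csr_matrix(mst),
        edges=[(int(u), int(v), float(w)) for u, v, w in edges],
        cell_edge=cell_edge,
        cell_s=cell_s,
        cell_ids=list(cell_ids),
        group_labels=group,
    )


def fit_trajectory_from_adata(
    adata: ad.AnnData,
    labels=None,
    config: TrajectoryConfig | None = None,
) -> Trajectory:
    """Embed (variable genes -> PCA) and fit the backbone in one step."""
    from .normalize import embed_pca, select_variable_genes

    config = config or TrajectoryConfig()
    config.validate()
    hvg = select_variable_genes(adata, min(config.n_hvg, adata.n_vars))
    n_pcs = min(config.n_components, adata.n_obs - 1, len(hvg))
    emb = embed_pca(adata, hvg, n_pcs)
    return fit_trajectory(emb.coords, emb.cell_ids, labels=labels, config=config)


def assign_pseudotime(
    traj: Trajectory,
    root_spec: RootSpec | str,
    adata: ad.AnnData | None = None,
) -> pd.Series:
    """Pseudotime = geodesic distance along the backbone from the root,
    min-max scaled to [0, 1].

    With a marker RootSpec the root is the backbone endpoint (degree-1
    node) whose projected cells have the extremal mean normalized
    expression of the marker; with a cell id the root is that cell's
    nearest backbone node.
    """
    n_nodes = traj.centroids.shape[0]
    ncomp, _ = csgraph.connected_components(traj.mst, directed=False)
    if ncomp != 1:
        raise ValueError("backbone is disconnected; trajectory is corrupt")

    if isinstance(root_spec, RootSpec):
        root_spec.validate()
        if adata is None:
            raise ValueError("marker-based root selection needs the expression matrix")
        if root_spec.marker not in adata.var_names:
            raise KeyError(f"root marker {root_spec.marker!r} not present in matrix")
        x = _lognorm(adata)
        vals = np.asarray(
            x[adata.obs_names.get_indexer(traj.cell_ids), adata.var_names.get_loc(root_spec.marker)].todense()
        ).ravel()
        nearest = traj.nearest_node()
        candidates = [e for e in traj.endpoints() if (nearest == e).any()]
        if not candidates:
            raise ValueError("no backbone endpoint has projected cells")
        means = {e: vals[nearest == e].mean() for e in candidates}
        pick = min if root_spec.extremum == "min" else max
        root = pick(sorted(means), key=lambda e: (means[e], e))
    else:
        if root_spec not in traj.cell_ids:
            raise KeyError(f"root cell {root_spec!r} not on trajectory")
        root = int(traj.nearest_node()[traj.cell_ids.index(root_spec)])

    dist = csgraph.dijkstra(traj.mst, directed=False, indices=root)
    if not np.isfinite(dist).all():
        raise ValueError("backbone is disconnected; trajectory is corrupt")
    u, v = traj.cell_edge[:, 0], traj.cell_edge[:, 1]
    lengths = np.asarray(traj.mst[u, v]).ravel()
    pt = np.minimum(dist[u] + traj.cell_s * lengths, dist[v] + (1 - traj.cell_s) * lengths)
    if pt.max() > 0:
        pt = (pt - pt.min()) / (pt.max() - pt.min())
    return pd.Series(pt, index=pd.Index(traj.cell_ids, name="cell_id"), name="pseudotime")


def bin_by_pseudotime(pseudotime: pd.Series, bin_size: int) -> pd.Series:
    """Sort cells by pseudotime (ties by cell id) and chunk into
    consecutive bins of ``bin_size``; the final bin may be smaller."""
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    if len(pseudotime) == 0:
        raise ValueError("no cells to bin")
    order = pseudotime.reset_index()
    order.columns = ["cell_id", "pt"]
    order = order.sort_values(["pt", "cell_id"], kind="stable")
    bins = np.arange(len(order)) // bin_size
    return pd.Series(bins, index=order["cell_id"], name="bin").loc[pseudotime.index]


def pseudotime_profile(
    adata: ad.AnnData,
    bins: pd.Series,
    genes: list[str],
    smoothing_window: int = 1,
) -> pd.DataFrame:
    """Bin x gene expression profile for heatmap export.

    Per-bin mean normalized expression, an optional centered moving
    average over ``smoothing_window`` bins, then per-gene min-max scaling
    to [0, 1]; a constant gene maps to all-zero by convention.
    """
    missing = [g for g in genes if g not in adata.var_names]
    if missing:
        raise KeyError(f"genes not in matrix: {missing}")
    n_bins = int(bins.max()) + 1
    if smoothing_window > n_bins:
        raise ValueError(f"smoothing window {smoothing_window} exceeds {n_bins} bins")
    x = _lognorm(adata)
    gidx = adata.var_names.get_indexer(genes)
    cell_pos = adata.obs_names.get_indexer(bins.index)
    dense = np.asarray(x[cell_pos][:, gidx].todense())
    prof = pd.DataFrame(dense, index=bins.values, columns=genes).groupby(level=0).mean()
    prof = prof.sort_index()
    if smoothing_window > 1:
        prof = prof.rolling(smoothing_window, center=True, min_periods=1).mean()
    rng = prof.max() - prof.min()
    scaled = (prof - prof.min()).div(rng.where(rng > 0, 1.0))
    scaled.loc[:, rng == 0] = 0.0
    return scaled


def trajectory_de(adata: ad.AnnData, pseudotime: pd.Series, alpha: float = 0.05) -> pd.DataFrame:
    """Per-gene Spearman association with pseudotime, BH-adjusted.

    Genes constant across cells get rho = 0, p = 1 by convention.
    """
    if len(pseudotime) < 20:
        raise ValueError("need at least 20 cells for trajectory DE")
    pt = pseudotime.values
    if np.ptp(pt) == 0:
        raise ValueError("pseudotime is constant")
    x = _lognorm(adata)
    dense = np.asarray(x[adata.obs_names.get_indexer(pseudotime.index)].todense())
    rho, p = spearman_vs_vector(dense, pt)
    padj = bh_adjust(p)
    return pd.DataFrame(
        {
            "gene": adata.var_names,
            "rho": rho,
            "p": p,
            "p_adjusted": padj,
            "significant": padj < alpha,
        }
    ).set_index("gene")


def intersect_with_gene_list(de: pd.DataFrame, gene_list) -> pd.DataFrame:
    """Significant trajectory genes restricted to an external gene list
    (case-sensitive exact ids), statistics preserved."""
    wanted = set(gene_list)
    return de[de["significant"] & de.index.isin(wanted)].copy()
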