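"""Synthetic UMI count matrices with known hierarchical structure.

The generator emulates the structure of a droplet scRNA-seq experiment on
a tissue with a hierarchy of discrete cell types: a tree of cell types,
each non-root node carrying a disjoint set of planted marker genes that
are multiplicatively up-regulated in the cells of that node and all of
its descendants; negative-binomial counts with log-normal per-gene
baselines and per-cell library sizes; replicate batches with per-gene
multiplicative log-normal batch noise; cross-lineage doublets; and an
independent continuous differentiation gradient for trajectory tests.

Ground truth (tier path, batch, doublet status and parents, gradient
position) is recorded in ``adata.obs`` so downstream stages can be scored
against it; per-gene generative quantities (baseline mean, marker
assignment) live in ``adata.var``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp


# ---------------------------------------------------------------------------
# specifications
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NodeSpec:
    """One cell-type node in the hierarchy.

    ``n_cells_per_batch`` is the number of cells of this type captured in
    each replicate batch (0 for purely internal nodes that only group
    their children).
    """

    name: str
    parent: str | None = None
    n_cells_per_batch: int = 0


@dataclass(frozen=True)
class HierarchySpec:
    """Generative parameters for a hierarchical cell-type scene.

    Defaults describe a small droplet experiment: ~2,000 genes, three
    replicate batches, median library size ~2,500 UMI (log-normal),
    gene-level negative-binomial dispersion 0.25 (size 4, typical of
    moderately expressed genes in UMI data), mild multiplicative batch
    noise (sigma 0.1 on the log scale), and 50 planted markers per node
    at 8-fold up-regulation.

    Graded fold-change markers do not capture lineage-defining on/off
    genes (a germline gene is essentially undetectable in soma, not
    merely 8-fold lower), and the doublet-removal rule depends on such
    genes existing.  The generator therefore makes the top
    ``exclusive_genes_per_branch`` markers (by baseline) of every tier-1
    branch truly exclusive: outside their branch their expected
    expression is suppressed to ``exclusive_off_scale`` of baseline.
    """

    nodes: Sequence[NodeSpec] = ()
    markers_per_node: int = 50
    marker_fold_change: float = 8.0
    baseline_mean_log_mu: float = 0.0
    baseline_mean_log_sigma: float = 1.0
    dispersion: float = 0.25
    n_genes: int = 2000
    n_batches: int = 3
    batch_sigma: float = 0.1
    library_size_log_mu: float = float(np.log(2500.0))
    library_size_log_sigma: float = 0.35
    exclusive_genes_per_branch: int = 3
    exclusive_off_scale: float = 0.02
    seed: int = 0

    # -- validation ---------------------------------------------------------

    def root(self) -> NodeSpec:
        roots = [n for n in self.nodes if n.parent is None]
        if len(roots) != 1:
            raise ValueError(f"hierarchy must have exactly one root, found {len(roots)}")
        return roots[0]

    def node_map(self) -> dict[str, NodeSpec]:
        names = [n.name for n in self.nodes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate node names in hierarchy")
        return {n.name: n for n in self.nodes}

    def path_to_root(self, name: str) -> list[str]:
        """Node names from root down to ``name`` (inclusive)."""
        nodes = self.node_map()
        path = [name]
        seen = {name}
        while nodes[path[0]].parent is not None:
            parent = nodes[path[0]].parent
            if parent not in nodes:
                raise ValueError(f"node {path[0]!r} references unknown parent {parent!r}")
            if parent in seen:
                raise ValueError("cycle in hierarchy")
            path.insert(0, parent)
            seen.add(parent)
        return path

    def validate(self) -> None:
        if not self.nodes:
            raise ValueError("hierarchy has no nodes")
        root = self.root()
        nodes = self.node_map()
        for n in self.nodes:
            self.path_to_root(n.name)  # raises on orphans / cycles
        n_marked = sum(1 for n in self.nodes if n.name != root.name)
        if n_marked * self.markers_per_node > self.n_genes:
            raise ValueError(
                f"{n_marked} nodes x {self.markers_per_node} markers exceed {self.n_genes} genes"
            )
        if self.marker_fold_change < 1:
            raise ValueError("marker_fold_change must be >= 1")
        for val, label in [
            (self.n_genes, "n_genes"),
            (self.n_batches, "n_batches"),
            (self.dispersion, "dispersion"),
            (self.markers_per_node, "markers_per_node"),
        ]:
            if val <= 0:
                raise ValueError(f"{label} must be strictly positive")
        for n in self.nodes:
            if n.n_cells_per_batch < 0:
                raise ValueError(f"negative cell count on node {n.name!r}")
        if sum(n.n_cells_per_batch for n in self.nodes) == 0:
            raise ValueError("no node carries any cells")
        _ = nodes


@dataclass(frozen=True)
class MonotoneGene:
    """A gene whose expected expression responds monotonically to t."""

    gene: int | str
    direction: Literal["up", "down"] = "up"
    amplitude: float = 4.0
    shape: Literal["linear", "sigmoid"] = "linear"


@dataclass(frozen=True)
class GradientSpec:
    """Generative parameters for a continuous differentiation gradient."""

    n_cells: int = 500
    n_genes: int = 2000
    monotone_genes: Sequence[MonotoneGene] = ()
    baseline_mean_log_mu: float = 0.0
    baseline_mean_log_sigma: float = 1.0
    dispersion: float = 0.5
    library_size_log_mu: float = float(np.log(2500.0))
    library_size_log_sigma: float = 0.35
    seed: int = 0

    def validate(self) -> None:
        if not self.monotone_genes:
            raise ValueError("GradientSpec requires at least one monotone gene")
        for mg in self.monotone_genes:
            if mg.direction not in ("up", "down"):
                raise ValueError(f"direction must be 'up' or 'down', got {mg.direction!r}")
            if mg.amplitude < 0:
                raise ValueError("amplitude must be >= 0")
            if mg.shape not in ("linear", "sigmoid"):
                raise ValueError(f"unknown response shape {mg.shape!r}")
        if self.n_cells <= 0 or self.n_genes <= 0:
            raise ValueError("n_cells and n_genes must be strictly positive")


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _gene_names(n_genes: int) -> pd.Index:
    return pd.Index([f"G{i + 1:06d}" for i in range(n_genes)], name="gene_id")


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial draws parameterized by mean and dispersion.

    dispersion = 1/size, so variance = mean + dispersion * mean**2.
    """
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def _pack(counts: np.ndarray, obs: pd.DataFrame, var: pd.DataFrame) -> ad.AnnData:
    return ad.AnnData(X=sp.csr_matrix(counts.astype(np.int64)), obs=obs, var=var)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def simulate_counts(spec: HierarchySpec) -> ad.AnnData:
    """Simulate a hierarchical cell-type scene.

    Returns cells x genes counts with ground truth in ``obs``
    (``tier_path`` joined by "/", ``batch``, ``is_doublet``, ``t``) and
    per-gene generative metadata in ``var`` (``baseline_mean``,
    ``marker_of``).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    root = spec.root()

    baseline = rng.lognormal(spec.baseline_mean_log_mu, spec.baseline_mean_log_sigma, spec.n_genes)
    # Disjoint marker sets: one shared permutation, consumed in node order.
    perm = rng.permutation(spec.n_genes)
    marker_of = np.full(spec.n_genes, "", dtype=object)
    markers: dict[str, np.ndarray] = {}
    cursor = 0
    for node in spec.nodes:
        if node.name == root.name:
            continue
        idx = perm[cursor : cursor + spec.markers_per_node]
        cursor += spec.markers_per_node
        markers[node.name] = idx
        marker_of[idx] = node.name

    # lineage-defining on/off genes: top markers of each tier-1 branch are
    # suppressed to exclusive_off_scale of baseline outside their branch
    tier1 = [n.name for n in spec.nodes if n.parent == root.name]
    exclusive: dict[str, np.ndarray] = {}
    is_exclusive = np.zeros(spec.n_genes, dtype=bool)
    if spec.exclusive_genes_per_branch > 0:
        for branch in tier1:
            if branch not in markers:
                continue
            idx = markers[branch]
            top = idx[np.argsort(-baseline[idx], kind="stable")][
                : spec.exclusive_genes_per_branch
            ]
            exclusive[branch] = top
            is_exclusive[top] = True

    batch_factor = rng.lognormal(0.0, spec.batch_sigma, size=(spec.n_batches, spec.n_genes))
    baseline_sum = baseline.sum()

    blocks: list[np.ndarray] = []
    obs_rows: list[dict] = []
    for node in spec.nodes:
        if node.n_cells_per_batch == 0:
            continue
        path = spec.path_to_root(node.name)
        fold = np.ones(spec.n_genes)
        for anc in path:
            if anc in markers:
                fold[markers[anc]] *= spec.marker_fold_change
        for branch, idx in exclusive.items():
            if branch not in path:
                fold[idx] = spec.exclusive_off_scale
        for b in range(spec.n_batches):
            n = node.n_cells_per_batch
            lib = rng.lognormal(spec.library_size_log_mu, spec.library_size_log_sigma, n)
            rel = baseline * fold * batch_factor[b] / baseline_sum
            mean = lib[:, None] * rel[None, :]
            blocks.append(_nb_sample(rng, mean, spec.dispersion))
            for _ in range(n):
                obs_rows.append({"batch": f"b{b}", "tier_path": "/".join(path)})

    counts = np.vstack(blocks)
    obs = pd.DataFrame(obs_rows)
    # Stable ids: batch then running index within batch.
    within = obs.groupby("batch").cumcount()
    obs.index = pd.Index(
        [f"CELL-{b}-{i:05d}" for b, i in zip(obs["batch"], within)], name="cell_id"
    )
    obs["is_doublet"] = False
    obs["doublet_parents"] = ""
    obs["t"] = np.nan

    var = pd.DataFrame(
        {"baseline_mean": baseline, "marker_of": marker_of, "exclusive": is_exclusive},
        index=_gene_names(spec.n_genes),
    )
    adata = _pack(counts, obs, var)
    adata.uns["hierarchy"] = {
        "nodes": [(n.name, n.parent or "", n.n_cells_per_batch) for n in spec.nodes],
        "marker_fold_change": spec.marker_fold_change,
        "library_size_log_mu": spec.library_size_log_mu,
        "library_size_log_sigma": spec.library_size_log_sigma,
        "dispersion": spec.dispersion,
        "exclusive_off_scale": spec.exclusive_off_scale,
    }
    return adata


def tier1_branch(tier_path: str) -> str:
    """The tier-1 branch of a root-to-node path ("root/soma/EC" -> "soma")."""
    parts = str(tier_path).split("/")
    return parts[1] if len(parts) > 1 else parts[0]


def inject_doublets(adata: ad.AnnData, rate: float, seed: int = 0) -> ad.AnnData:
    """Append cross-lineage doublets at the given rate.

    Each doublet is the gene-wise sum of two uniformly sampled parents
    from distinct tier-1 branches, binomially downsampled to a library
    size drawn from the singlet library-size distribution (resampled from
    the realized singlet totals).
    """
    if not 0 <= rate < 1:
        raise ValueError(f"doublet rate must be in [0, 1), got {rate}")
    n = adata.n_obs
    n_doublets = int(round(rate * n))
    if n_doublets == 0:
        return adata.copy()

    branches = np.asarray([tier1_branch(p) for p in adata.obs["tier_path"]])
    uniq = np.unique(branches)
    if len(uniq) < 2:
        raise ValueError("doublet injection requires at least two tier-1 branches")

    rng = np.random.default_rng(seed)
    x = sp.csr_matrix(adata.X)
    totals = np.asarray(x.sum(axis=1)).ravel()

    rows = np.empty((n_doublets, adata.n_vars), dtype=np.int64)
    parent_ids = []
    batches = []
    for i in range(n_doublets):
        a = int(rng.integers(n))
        other = np.flatnonzero(branches != branches[a])
        b = int(rng.choice(other))
        summed = np.asarray(x[a].todense()).ravel() + np.asarray(x[b].todense()).ravel()
        target = totals[int(rng.integers(n))]
        total = summed.sum()
        if target < total:
            rows[i] = rng.binomial(summed, target / total)
        else:
            rows[i] = summed
        parent_ids.append(f"{adata.obs_names[a]}|{adata.obs_names[b]}")
        batches.append(adata.obs["batch"].iloc[a])

    obs = pd.DataFrame(
        {
            "batch": batches,
            "tier_path": "",
            "is_doublet": True,
            "doublet_parents": parent_ids,
            "t": np.nan,
        },
        index=pd.Index([f"CELL-DBL-{i:05d}" for i in range(n_doublets)], name="cell_id"),
    )
    doublets = _pack(rows, obs, adata.var.copy())
    out = ad.concat([adata, doublets], join="outer", merge="first", uns_merge="first")
    out.obs["is_doublet"] = out.obs["is_doublet"].astype(bool)
    out.var = adata.var.copy()
    return out


def simulate_gradient(spec: GradientSpec) -> ad.AnnData:
    """Simulate a continuous differentiation gradient.

    Per-cell position t ~ U(0, 1) is recorded in ``obs["t"]``; each
    monotone gene's expected expression is baseline * (1 + amplitude *
    g(t)) with g a monotone-increasing linear or sigmoid response
    (reflected for direction "down").
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    gene_index = _gene_names(spec.n_genes)

    baseline = rng.lognormal(spec.baseline_mean_log_mu, spec.baseline_mean_log_sigma, spec.n_genes)
    t = rng.uniform(0.0, 1.0, spec.n_cells)

    factor = np.ones((spec.n_cells, spec.n_genes))
    monotone_of = np.full(spec.n_genes, "", dtype=object)
    for mg in spec.monotone_genes:
        gi = mg.gene if isinstance(mg.gene, (int, np.integer)) else gene_index.get_loc(mg.gene)
        u = t if mg.direction == "up" else 1.0 - t
        if mg.shape == "sigmoid":
            g = 1.0 / (1.0 + np.exp(-8.0 * (u - 0.5)))
        else:
            g = u
        factor[:, gi] = 1.0 + mg.amplitude * g
        monotone_of[gi] = mg.direction

    lib = rng.lognormal(spec.library_size_log_mu, spec.library_size_log_sigma, spec.n_cells)
    mean = lib[:, None] * baseline[None, :] * factor / baseline.sum()
    counts = _nb_sample(rng, mean, spec.dispersion)

    obs = pd.DataFrame(
        {
            "batch": "b0",
            "tier_path": "root/gradient",
            "is_doublet": False,
            "doublet_parents": "",
            "t": t,
        },
        index=pd.Index([f"CELL-b0-{i:05d}" for i in range(spec.n_cells)], name="cell_id"),
    )
    var = pd.DataFrame(
        {"baseline_mean": baseline, "marker_of": "", "monotone_of": monotone_of},
        index=gene_index,
    )
    return _pack(counts, obs, var)


def simulate_combined(
    hier_spec: HierarchySpec, grad_spec: GradientSpec, gradient_branch: str = "gradient"
) -> ad.AnnData:
    """Hierarchy plus an appended gradient population in a shared gene space."""
    if hier_spec.n_genes != grad_spec.n_genes:
        raise ValueError("hierarchy and gradient must share the same gene space")
    hier = simulate_counts(hier_spec)
    grad = simulate_gradient(grad_spec)
    grad.obs["tier_path"] = f"{hier_spec.root().name}/{gradient_branch}"
    grad.obs_names = [f"CELL-GRAD-{i:05d}" for i in range(grad.n_obs)]
    out = ad.concat([hier, grad], join="outer", merge="first", uns_merge="first")
    out.var = hier.var.join(grad.var[["monotone_of"]])
    return out


# ---------------------------------------------------------------------------
# ready-made scenes
# ---------------------------------------------------------------------------


def nested_hierarchy_spec(
    n_cells_per_leaf: int = 300,
    markers_per_node: int = 50,
    fold: float = 8.0,
    n_batches: int = 3,
    seed: int = 0,
    **overrides,
) -> HierarchySpec:
    """The standard nested benchmark: germ leaf vs a soma branch with two leaves.

    ``n_cells_per_leaf`` is the total per leaf, spread evenly over batches.
    """
    if n_cells_per_leaf % n_batches:
        warnings.warn("n_cells_per_leaf not divisible by n_batches; rounding down per batch")
    per_batch = n_cells_per_leaf // n_batches
    nodes = [
        NodeSpec("root"),
        NodeSpec("germ", "root", per_batch),
        NodeSpec("soma", "root", 0),
        NodeSpec("somaA", "soma", per_batch),
        NodeSpec("somaB", "soma", per_batch),
    ]
    return HierarchySpec(
        nodes=nodes,
        markers_per_node=markers_per_node,
        marker_fold_change=fold,
        n_batches=n_batches,
        seed=seed,
        **overrides,
    )


def default_gradient_spec(
    n_cells: int = 500,
    n_genes: int = 2000,
    n_monotone: int = 300,
    amplitude: float = 10.0,
    seed: int = 0,
    **overrides,
) -> GradientSpec:
    """A strong differentiation continuum: 15% of genes respond
    monotonically with an ~11-fold dynamic range, half up and half down,
    mixing linear and sigmoid response shapes."""
    genes = []
    for i in range(n_monotone):
        genes.append(
            MonotoneGene(
                gene=i,
                direction="up" if i % 2 == 0 else "down",
                amplitude=amplitude,
                shape="linear" if i % 4 < 2 else "sigmoid",
            )
        )
    return GradientSpec(
        n_cells=n_cells, n_genes=n_genes, monotone_genes=tuple(genes), seed=seed, **overrides
    )
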