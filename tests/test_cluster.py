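"""Tests of tiered clustering: node-level community detection, the
differential-gene quality gate, the recursion, and supervised splits."""

import itertools

import igraph
import leidenalg
import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from conftest import make_lognorm_adata
from ovatlas.cluster import (
    ClusteringConfig,
    cluster_node,
    coarsen_to_top_split,
    quality_gate,
    run_tiered_clustering,
    split_cluster_by_marker,
)
from ovatlas.normalize import normalize_log_cp10k
from ovatlas.simulate import (
    HierarchySpec,
    NodeSpec,
    nested_hierarchy_spec,
    simulate_counts,
)


def homogeneous_adata(n_cells=334, seed=0):
    """One cell type, no planted structure beyond noise."""
    spec = HierarchySpec(
        nodes=[NodeSpec("root"), NodeSpec("a", "root", n_cells // 3 + 1)],
        markers_per_node=1,
        marker_fold_change=1.0,
        exclusive_genes_per_branch=0,
        seed=seed,
    )
    return normalize_log_cp10k(simulate_counts(spec))


def two_type_adata(seed=0, n=150):
    spec = HierarchySpec(
        nodes=[NodeSpec("root"), NodeSpec("a", "root", n), NodeSpec("b", "root", n)],
        n_batches=1,
        seed=seed,
    )
    return normalize_log_cp10k(simulate_counts(spec))


class TestClusterNode:
    def test_two_blobs_recovered(self):
        adata = two_type_adata()
        nc = cluster_node(adata, np.arange(adata.n_obs), ClusteringConfig(seed=0))
        assert nc is not None
        leaf = adata.obs["tier_path"].str.split("/").str[-1].values
        assert len(np.unique(nc.labels)) == 2
        # each community >= 95% pure
        for u in np.unique(nc.labels):
            counts = np.unique(leaf[nc.labels == u], return_counts=True)[1]
            assert counts.max() / counts.sum() >= 0.95

    def test_small_node_reduces_k(self):
        adata = two_type_adata(n=8)  # 16 cells < knn_k + 1
        with pytest.warns(UserWarning, match="reduced"):
            cluster_node(adata, np.arange(adata.n_obs), ClusteringConfig(seed=0))

    def test_identical_points_unsplittable(self):
        vals = np.ones((60, 30))
        adata = make_lognorm_adata(vals)
        nc = cluster_node(adata, np.arange(60), ClusteringConfig(seed=0))
        assert nc is None

    def test_deterministic(self):
        adata = two_type_adata()
        cfg = ClusteringConfig(seed=5)
        a = cluster_node(adata, np.arange(adata.n_obs), cfg)
        b = cluster_node(adata, np.arange(adata.n_obs), cfg)
        assert np.array_equal(a.labels, b.labels)
        assert a.resolution == b.resolution


class TestLeidenMatchesExhaustiveModularity:
    """On tiny graphs, Leiden's modularity partition equals the global
    optimum found by enumerating every partition."""

    def brute_force(self, g):
        n = g.vcount()
        best, best_q = None, -np.inf
        for labels in itertools.product(range(n), repeat=n):
            # canonicalize to avoid re-scoring relabelings
            seen, canon = {}, []
            for l in labels:
                canon.append(seen.setdefault(l, len(seen)))
            q = g.modularity(canon, weights="weight")
            if q > best_q + 1e-12:
                best_q, best = q, canon
        return best, best_q

    @pytest.mark.parametrize("case", ["two_triangles", "weighted_ring", "random"])
    def test_optimum_found(self, case):
        if case == "two_triangles":
            edges = [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (2, 3)]
            weights = [1.0] * 6 + [0.1]
        elif case == "weighted_ring":
            edges = [(i, (i + 1) % 6) for i in range(6)]
            weights = [2.0, 2.0, 0.1, 2.0, 2.0, 0.1]
        else:
            rng = np.random.default_rng(7)
            edges = [(i, j) for i in range(6) for j in range(i + 1, 6) if rng.random() < 0.6]
            weights = rng.uniform(0.1, 2.0, len(edges)).tolist()
        g = igraph.Graph(n=6, edges=edges)
        g.es["weight"] = weights
        _, best_q = self.brute_force(g)
        part = leidenalg.find_partition(
            g, leidenalg.ModularityVertexPartition, weights="weight", seed=0, n_iterations=-1
        )
        q = g.modularity(part.membership, weights="weight")
        assert q == pytest.approx(best_q, abs=1e-9)


class TestQualityGate:
    def planted_split(self, n_pass_a=7, n_pass_b=7, n_cells=40, n_noise=20):
        """Two groups with planted high-expressing genes per side."""
        rng = np.random.default_rng(0)
        vals = rng.uniform(0.0, 0.3, size=(2 * n_cells, n_pass_a + n_pass_b + n_noise))
        vals[:n_cells, :n_pass_a] += 3.0  # group 0 genes
        vals[n_cells:, n_pass_a : n_pass_a + n_pass_b] += 3.0  # group 1 genes
        adata = make_lognorm_adata(vals)
        labels = np.array([0] * n_cells + [1] * n_cells)
        return adata, labels

    def test_planted_split_passes(self):
        adata, labels = self.planted_split()
        rep = quality_gate(adata, np.arange(adata.n_obs), labels, ClusteringConfig())
        assert rep.passed
        assert all(s.n_passing_genes >= 7 for s in rep.subclusters)

    def test_three_genes_fail_q5(self):
        """A side with only 3 distinct genes fails the >=5-gene rule."""
        adata, labels = self.planted_split(n_pass_b=3)
        rep = quality_gate(adata, np.arange(adata.n_obs), labels, ClusteringConfig())
        assert not rep.passed
        by_label = {s.label: s for s in rep.subclusters}
        assert by_label[1].n_passing_genes == 3
        assert by_label[0].n_passing_genes >= 5

    def test_tiny_subcluster_autofails(self):
        adata, labels = self.planted_split()
        labels = labels.copy()
        labels[labels == 1] = 0
        labels[:2] = 1  # 2-cell subcluster
        rep = quality_gate(adata, np.arange(adata.n_obs), labels, ClusteringConfig())
        assert not rep.passed
        assert any(s.auto_failed for s in rep.subclusters)

    def test_random_split_of_homogeneous_rarely_passes(self):
        """False-ratification oracle: random halves of homogeneous data."""
        passes = 0
        for seed in range(5):
            adata = homogeneous_adata(seed=seed)
            rng = np.random.default_rng(seed)
            labels = rng.integers(0, 2, adata.n_obs)
            passes += quality_gate(
                adata, np.arange(adata.n_obs), labels, ClusteringConfig()
            ).passed
        assert passes == 0

    def test_monotone_in_fold_change(self):
        """The gate's verdict on the true split never degrades as the
        planted fold change grows."""
        passed = []
        for fold in (1.2, 4.0, 8.0):
            adata = normalize_log_cp10k(
                simulate_counts(
                    HierarchySpec(
                        nodes=[
                            NodeSpec("root"),
                            NodeSpec("a", "root", 60),
                            NodeSpec("b", "root", 60),
                        ],
                        marker_fold_change=fold,
                        n_batches=1,
                        exclusive_genes_per_branch=0,
                        seed=42,
                    )
                )
            )
            leaf = (adata.obs["tier_path"].str.split("/").str[-1] == "a").astype(int).values
            passed.append(
                quality_gate(adata, np.arange(adata.n_obs), leaf, ClusteringConfig()).passed
            )
        assert passed == sorted(passed)  # False may precede True, never follow


class TestRunTieredClustering:
    def test_homogeneous_single_node(self):
        for seed in (0, 1, 2):
            adata = homogeneous_adata(seed=seed)
            tree = run_tiered_clustering(adata, ClusteringConfig(seed=seed))
            assert tree.terminal_labels() == ["0"]
            assert (tree.cell_terminal == "0").all()

    def test_three_flat_types_recovered(self):
        spec = HierarchySpec(
            nodes=[NodeSpec("root")]
            + [NodeSpec(n, "root", 100) for n in ("a", "b", "c")],
            seed=0,
        )
        adata = normalize_log_cp10k(simulate_counts(spec))
        tree = run_tiered_clustering(adata, ClusteringConfig(seed=0))
        leaf = adata.obs["tier_path"].str.split("/").str[-1].values
        assert len(tree.terminal_labels()) == 3
        assert adjusted_rand_score(leaf, tree.cell_terminal.values) == pytest.approx(1.0)

    def test_nested_truth_recovered(self, nested_adata):
        tree = run_tiered_clustering(nested_adata, ClusteringConfig(seed=0))
        tree.assert_partition()
        terms = tree.terminal_labels()
        # one lone tier-1 leaf plus a tier-1 node split in two (labels up
        # to permutation of sibling order)
        assert sorted(len(t.split(".")) for t in terms) == [1, 2, 2]
        leaf = nested_adata.obs["tier_path"].str.split("/").str[-1].values
        assert adjusted_rand_score(leaf, tree.cell_terminal.values) >= 0.95
        # prefix invariant: every cell's tier-1 label prefixes its terminal label
        frame = tree.to_frame()
        for _, row in frame.iterrows():
            assert row["terminal_label"].startswith(row["tier1"])

    def test_deterministic(self, nested_adata):
        cfg = ClusteringConfig(seed=3)
        t1 = run_tiered_clustering(nested_adata, cfg)
        t2 = run_tiered_clustering(nested_adata, cfg)
        assert t1.cell_terminal.equals(t2.cell_terminal)
        assert t1.to_json() == t2.to_json()

    def test_empty_input_rejected(self, nested_adata):
        with pytest.raises(ValueError, match="empty"):
            run_tiered_clustering(nested_adata[:0].copy(), ClusteringConfig())


class TestCoarsen:
    def test_groups_nearest_communities(self):
        coords = np.array([[0.0], [0.1], [10.0], [10.1], [12.0], [12.1]])
        labels = np.array([0, 0, 1, 1, 2, 2])
        out = coarsen_to_top_split(labels, coords)
        assert len(np.unique(out)) == 2
        assert out[2] == out[4] != out[0]

    def test_two_communities_untouched(self):
        labels = np.array([0, 1, 0, 1])
        out = coarsen_to_top_split(labels, np.zeros((4, 2)))
        assert np.array_equal(out, labels)


class TestSupervisedSplit:
    @pytest.fixture()
    def rare_scene(self):
        """A 420-cell terminal node hiding a 21-cell subtype marked by a
        single gene: too few distinctive genes for the gate, so only the
        supervised split can isolate it."""
        spec = HierarchySpec(
            nodes=[
                NodeSpec("root"),
                NodeSpec("common", "root", 140),
                NodeSpec("rare", "root", 7),
            ],
            markers_per_node=1,
            marker_fold_change=40.0,
            exclusive_genes_per_branch=0,
            seed=8,
        )
        adata = normalize_log_cp10k(simulate_counts(spec))
        tree = run_tiered_clustering(adata, ClusteringConfig(seed=8))
        return adata, tree

    def test_rare_subtype_isolated(self, rare_scene):
        adata, tree = rare_scene
        assert tree.terminal_labels() == ["0"]
        marker = adata.var.index[(adata.var["marker_of"] == "rare").values][0]
        vals = np.asarray(adata.layers["lognorm"][:, adata.var_names.get_loc(marker)].todense()).ravel()
        rare = (adata.obs["tier_path"].str.split("/").str[-1] == "rare").values
        threshold = (np.median(vals[rare]) + np.median(vals[~rare])) / 2
        out = split_cluster_by_marker(tree, adata, "0", marker, threshold)
        out.assert_partition()
        small = min(out.nodes["0.0"].cell_ids, out.nodes["0.1"].cell_ids, key=len)
        rare_ids = set(adata.obs_names[rare])
        assert len(rare_ids & set(small)) >= 0.95 * len(rare_ids)
        assert out.nodes["0.0"].supervised and out.nodes["0.1"].supervised

    def test_threshold_zero_is_noop(self, rare_scene):
        adata, tree = rare_scene
        marker = adata.var.index[(adata.var["marker_of"] == "rare").values][0]
        with pytest.warns(UserWarning, match="no-op"):
            out = split_cluster_by_marker(tree, adata, "0", marker, 0.0)
        assert out.terminal_labels() == ["0"]

    def test_non_terminal_rejected(self, nested_adata):
        tree = run_tiered_clustering(nested_adata, ClusteringConfig(seed=0))
        internal = next(l for l, n in tree.nodes.items() if not n.terminal)
        with pytest.raises(ValueError, match="terminal"):
            split_cluster_by_marker(tree, nested_adata, internal, "G000001", 0.5)

    def test_absent_gene_rejected(self, rare_scene):
        adata, tree = rare_scene
        with pytest.raises(KeyError, match="ghost"):
            split_cluster_by_marker(tree, adata, "0", "ghost", 0.5)
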