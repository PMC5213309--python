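import numpy as np
import pytest
from scipy import stats

from tamnet import network, preprocess
from tamnet.simulate import ModuleSpec, SimulationConfig, generate_dataset

from conftest import make_design, make_log_matrix


class TestBuildNetwork:
    def test_perfect_correlation_edge(self, small_design):
        vals = np.vstack([np.arange(16.0), 2 * np.arange(16.0)])
        le = make_log_matrix(vals, design=small_design)
        net = network.build_cra_network(le, ["g0", "g1"], r_min=1.0)
        assert net.graph.has_edge("g0", "g1")
        assert net.graph.edges["g0", "g1"]["r"] == pytest.approx(1.0)

    def test_threshold_is_inclusive_at_r(self):
        # x=(1,2,3,4), y=(1,3,2,4) -> r = 0.8 exactly
        design = make_design(n_donors=1)
        vals = np.array([[1, 2, 3, 4], [1, 3, 2, 4]], dtype=float)
        le = make_log_matrix(vals, design=design)
        assert stats.pearsonr(vals[0], vals[1]).statistic == pytest.approx(0.8)
        net = network.build_cra_network(le, ["g0", "g1"], r_min=0.7)
        assert net.graph.has_edge("g0", "g1")
        net9 = network.build_cra_network(le, ["g0", "g1"], r_min=0.9)
        assert not net9.graph.has_edge("g0", "g1")

    def test_edges_match_pairwise_brute_force(self, default_log_expr):
        le, _ = default_log_expr
        genes = preprocess.top_variable_genes(le, 100)
        net = network.build_cra_network(le, genes, r_min=0.7)
        expected = set()
        for i, a in enumerate(genes):
            for b in genes[i + 1:]:
                r = stats.pearsonr(
                    le.values.loc[a].to_numpy(), le.values.loc[b].to_numpy()
                ).statistic
                if r >= 0.7:
                    expected.add(frozenset((a, b)))
        got = {frozenset(e) for e in net.graph.edges}
        assert got == expected

    def test_zero_variance_gene_isolated(self, small_design, caplog):
        vals = np.vstack([np.full(16, 2.0), np.arange(16.0), 2 * np.arange(16.0)])
        le = make_log_matrix(vals, design=small_design)
        with caplog.at_level("WARNING"):
            net = network.build_cra_network(le, ["g0", "g1", "g2"])
        assert net.graph.degree("g0") == 0
        assert net.graph.has_edge("g1", "g2")
        assert "zero-variance" in caplog.text

    def test_monotone_in_threshold(self, default_log_expr):
        import networkx as nx

        le, _ = default_log_expr
        genes = preprocess.top_variable_genes(le, 120)
        prev_edges, prev_comps = None, None
        for r_min in (0.5, 0.7, 0.9):
            net = network.build_cra_network(le, genes, r_min=r_min)
            n_edges = net.graph.number_of_edges()
            n_comps = nx.number_connected_components(net.graph)
            if prev_edges is not None:
                assert n_edges <= prev_edges
                assert n_comps >= prev_comps
            prev_edges, prev_comps = n_edges, n_comps


class TestDetectClusters:
    def two_triangles(self):
        import networkx as nx

        G = nx.Graph()
        for a, b in (("a", "b"), ("b", "c"), ("a", "c"), ("x", "y"), ("y", "z"), ("x", "z")):
            G.add_edge(a, b, r=0.9)
        return network.GeneNetwork(G, 0.7)

    def test_two_triangles_two_clusters(self):
        net = network.detect_clusters(self.two_triangles())
        clusters = net.clusters()
        assert set(clusters) == {"C1", "C2"}
        assert clusters["C1"] == ["a", "b", "c"]  # size tie -> smallest member first
        assert clusters["C2"] == ["x", "y", "z"]

    def test_clique_single_subcluster(self):
        import networkx as nx

        G = nx.complete_graph(["a", "b", "c", "d"])
        net = network.detect_clusters(network.GeneNetwork(G, 0.7))
        assert set(net.subclusters()) == {"C1a"}

    def test_subclusters_refine_clusters(self, default_log_expr):
        le, _ = default_log_expr
        genes = preprocess.top_variable_genes(le, 200)
        net = network.detect_clusters(network.build_cra_network(le, genes))
        for g in net.graph.nodes:
            d = net.graph.nodes[g]
            assert d["subcluster"].startswith(d["cluster"])

    def test_labels_stable_under_input_permutation(self, default_log_expr):
        le, _ = default_log_expr
        genes = preprocess.top_variable_genes(le, 80)
        net1 = network.detect_clusters(network.build_cra_network(le, genes))
        net2 = network.detect_clusters(network.build_cra_network(le, genes[::-1]))
        for g in genes:
            assert net1.graph.nodes[g]["cluster"] == net2.graph.nodes[g]["cluster"]
            assert net1.graph.nodes[g]["subcluster"] == net2.graph.nodes[g]["subcluster"]

    def test_weakly_merged_modules_split_into_communities(self):
        """Two planted modules bridged into one component are recovered as
        communities with high agreement to the planted membership."""
        from sklearn.metrics import adjusted_rand_score
        import networkx as nx

        aris = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            G = nx.Graph()
            members = {f"a{i}" for i in range(20)} | {f"b{i}" for i in range(20)}
            G.add_nodes_from(sorted(members))
            for grp in ("a", "b"):
                nodes = [f"{grp}{i}" for i in range(20)]
                for i, u in enumerate(nodes):
                    for v in nodes[i + 1:]:
                        if rng.random() < 0.8:
                            G.add_edge(u, v, r=0.9)
            # weak cross-links merge the two modules into one component
            for _ in range(4):
                u = f"a{rng.integers(20)}"
                v = f"b{rng.integers(20)}"
                G.add_edge(u, v, r=0.7)
            net = network.detect_clusters(network.GeneNetwork(G, 0.7))
            assert len(net.clusters()) == 1
            true = [n[0] for n in sorted(members)]
            pred = [net.graph.nodes[n]["subcluster"] for n in sorted(members)]
            aris.append(adjusted_rand_score(true, pred))
        assert np.mean(aris) >= 0.9


class TestMapGeneSet:
    def build(self, default_log_expr):
        le, design = default_log_expr
        genes = preprocess.top_variable_genes(le, 150)
        net = network.detect_clusters(network.build_cra_network(le, genes))
        fc = preprocess.fc_over_mean(le, design)
        return net, fc

    def test_disjoint_set_all_absent(self, default_log_expr):
        net, fc = self.build(default_log_expr)
        summary = network.map_gene_set(net, fc, ["NOT_A_GENE_1", "NOT_A_GENE_2"], "S")
        assert summary.n_present == 0
        assert summary.absent == ["NOT_A_GENE_1", "NOT_A_GENE_2"]
        assert all(v == 0 for v in summary.elevated_per_group.values())

    def test_exact_cluster_set_fully_counted(self, default_log_expr):
        net, fc = self.build(default_log_expr)
        cl = net.clusters()["C1"]
        summary = network.map_gene_set(net, fc, cl, "C1set")
        assert summary.per_cluster == {"C1": len(cl)}
        assert summary.n_present == len(cl)

    def test_elevated_counts_match_overlay(self, default_log_expr):
        net, fc = self.build(default_log_expr)
        genes = net.genes[:30]
        summary = network.map_gene_set(net, fc, genes, "S")
        for group in fc.log2.columns:
            manual = sum(1 for g in summary.present if fc.log2.loc[g, group] >= 0)
            assert summary.elevated_per_group[group] == manual


class TestHierarchicalCluster:
    def test_identical_genes_merge_at_zero(self, small_design):
        rng = np.random.default_rng(0)
        base = rng.normal(size=16)
        vals = np.vstack([base, base, rng.normal(size=16)])
        le = make_log_matrix(vals, design=small_design)
        hc = network.hierarchical_cluster(le, ["g0", "g1", "g2"])
        assert hc.gene_linkage[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_uncorrelated_genes_distance_one(self, small_design):
        # orthogonal +/- patterns with exactly zero correlation
        a = np.array([1.0, -1.0] * 8)
        b = np.array([1.0, 1.0, -1.0, -1.0] * 4)
        le = make_log_matrix(np.vstack([a, b]), design=small_design)
        hc = network.hierarchical_cluster(le, ["g0", "g1"])
        assert hc.gene_linkage[0, 2] == pytest.approx(1.0)

    def test_recovers_planted_modules_at_k2(self):
        from sklearn.metrics import adjusted_rand_score

        aris = []
        for seed in range(5):
            cfg = SimulationConfig(
                n_de_per_contrast=0,
                seed=seed,
                modules=[
                    ModuleSpec(50, {"TPC1_4h": 2.0}, 0.9, name="A"),
                    ModuleSpec(50, {"TPC1_24h": 2.0}, 0.9, name="B"),
                ],
            )
            matrix, design, truth = generate_dataset(cfg)
            le = preprocess.normalize_log_cpm(matrix)
            members = sorted(truth.module_of)
            hc = network.hierarchical_cluster(le, members)
            labels = hc.cut_genes(2)
            true = [truth.module_of[g] for g in members]
            pred = [labels[g] for g in members]
            aris.append(adjusted_rand_score(true, pred))
        assert np.mean(aris) >= 0.9
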