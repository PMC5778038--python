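import networkx as nx
import numpy as np
import pandas as pd
import pytest

from coregnet import (
    AnnotationSet,
    CorrelationMatrix,
    ExpressionDataset,
    InputError,
    SimulationConfig,
    cazy_subnetwork,
    filter_null_genes,
    generate_dataset,
    hrr_network,
    log2_normalize,
    network_stats,
    pearson_matrix,
    rank_neighbors,
)
from conftest import brute_force_hrr_edges, random_correlation

COLS = ["Ta_cellulose_1", "Ta_cellulose_2", "Ta_cellulose_3", "Ta_cellulose_4"]


def corr_of(genes, pairs):
    """Build a CorrelationMatrix from {frozenset pair: r} values."""
    n = len(genes)
    r = np.eye(n)
    for (a, b), val in pairs.items():
        i, j = genes.index(a), genes.index(b)
        r[i, j] = r[j, i] = val
    return CorrelationMatrix(genes=list(genes), r=r)


FOUR_GENE = corr_of(
    ["A", "B", "C", "D"],
    {("A", "B"): 0.9, ("A", "C"): 0.8, ("A", "D"): 0.1,
     ("B", "C"): 0.85, ("B", "D"): 0.2, ("C", "D"): 0.3},
)


class TestPearsonMatrix:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ([1, 2, 3, 4], [2, 4, 6, 8], 1.0),
            ([1, 2, 3, 4], [8, 6, 4, 2], -1.0),
            ([1, 2, 3, 4], [1, 3, 2, 4], 0.8),  # cov 4 over sd product 5
        ],
    )
    def test_known_pair_correlations(self, x, y, expected):
        ds = ExpressionDataset(
            pd.DataFrame([x, y], index=["gx", "gy"], columns=COLS, dtype=float),
            log_scale=True,
        )
        corr = pearson_matrix(ds)
        assert corr.r[0, 1] == pytest.approx(expected)
        assert corr.r[0, 1] == corr.r[1, 0]

    def test_zero_variance_genes_dropped_and_reported(self):
        ds = ExpressionDataset(
            pd.DataFrame([[1, 2, 3, 4], [5, 5, 5, 5], [2, 1, 2, 1]],
                         index=["g1", "g2", "g3"], columns=COLS, dtype=float),
            log_scale=True,
        )
        corr = pearson_matrix(ds)
        assert corr.genes == ["g1", "g3"]
        assert corr.dropped == ["g2"]

    def test_too_few_samples_rejected(self):
        ds = ExpressionDataset(
            pd.DataFrame([[1, 2]], index=["g1"], columns=COLS[:2], dtype=float),
            log_scale=True,
        )
        with pytest.raises(InputError, match="3 samples"):
            pearson_matrix(ds)

    def test_all_constant_rejected(self):
        ds = ExpressionDataset(
            pd.DataFrame([[1, 1, 1, 1]], index=["g1"], columns=COLS, dtype=float),
            log_scale=True,
        )
        with pytest.raises(InputError, match="zero variance"):
            pearson_matrix(ds)


class TestRankNeighbors:
    def test_simple_ordering(self):
        corr = corr_of(["A", "B", "C"], {("A", "B"): 0.9, ("A", "C"): 0.2, ("B", "C"): 0.5})
        ranks = rank_neighbors(corr)
        assert ranks[0, 1] == 1 and ranks[0, 2] == 2  # A prefers B
        assert ranks[2, 1] == 1 and ranks[2, 0] == 2  # C prefers B

    def test_exact_ties_broken_by_gene_id(self):
        corr = corr_of(["A", "B", "C"], {("A", "B"): 0.5, ("A", "C"): 0.5, ("B", "C"): 0.1})
        ranks = rank_neighbors(corr)
        assert ranks[0, 1] == 1  # B before C lexicographically
        assert ranks[0, 2] == 2

    def test_four_gene_rank_table(self):
        # brute-check every rank against the correlation values
        ranks = rank_neighbors(FOUR_GENE)
        expected = {
            (0, 1): 1, (0, 2): 2, (0, 3): 3,  # A: B > C > D
            (1, 0): 1, (1, 2): 2, (1, 3): 3,  # B: A > C > D
            (2, 1): 1, (2, 0): 2, (2, 3): 3,  # C: B > A > D
            (3, 2): 1, (3, 1): 2, (3, 0): 3,  # D: C > B > A
        }
        for (i, j), rank in expected.items():
            assert ranks[i, j] == rank


class TestHrrNetwork:
    def test_hand_enumerated_edges_at_hrr_two(self):
        net = hrr_network(FOUR_GENE, hrr_max=2)
        edges = {tuple(sorted(e)) for e in net.graph.edges}
        assert edges == {("A", "B"), ("A", "C"), ("B", "C")}
        assert net.graph.edges["A", "B"]["hrr"] == 1
        assert net.graph.edges["A", "C"]["hrr"] == 2
        assert net.graph.edges["A", "B"]["r"] == 0.9

    def test_hrr_one_keeps_only_mutual_best(self):
        net = hrr_network(FOUR_GENE, hrr_max=1)
        assert {tuple(sorted(e)) for e in net.graph.edges} == {("A", "B")}

    def test_large_cutoff_gives_complete_graph(self):
        net = hrr_network(FOUR_GENE, hrr_max=3)
        assert net.graph.number_of_edges() == 6

    def test_matches_brute_force_oracle_on_random_matrices(self):
        rng = np.random.default_rng(42)
        for trial in range(25):
            n = int(rng.integers(4, 20))
            genes = [f"g{i:02d}" for i in range(n)]
            tie_frac = 0.2 if trial % 3 == 0 else 0.0
            r = random_correlation(rng, n, tie_fraction=tie_frac)
            corr = CorrelationMatrix(genes=genes, r=r)
            for hrr_max in (1, 3):
                net = hrr_network(corr, hrr_max=hrr_max)
                got = {tuple(sorted(e)) for e in net.graph.edges}
                assert got == brute_force_hrr_edges(genes, r, hrr_max)

    def test_degree_bounded_by_cutoff(self):
        rng = np.random.default_rng(7)
        r = random_correlation(rng, 25)
        corr = CorrelationMatrix(genes=[f"g{i:02d}" for i in range(25)], r=r)
        for k in (1, 2, 3, 5):
            net = hrr_network(corr, hrr_max=k)
            degrees = [d for _, d in net.graph.degree()]
            assert max(degrees) <= k

    def test_edges_monotone_in_cutoff(self):
        rng = np.random.default_rng(8)
        r = random_correlation(rng, 20)
        corr = CorrelationMatrix(genes=[f"g{i:02d}" for i in range(20)], r=r)
        prev = set()
        for k in range(1, 6):
            edges = {tuple(sorted(e)) for e in hrr_network(corr, hrr_max=k).graph.edges}
            assert prev <= edges
            prev = edges

    def test_permutation_equivariant(self):
        rng = np.random.default_rng(9)
        n = 15
        genes = [f"g{i:02d}" for i in range(n)]
        r = random_correlation(rng, n)
        net = hrr_network(CorrelationMatrix(genes=genes, r=r))
        perm = rng.permutation(n)
        net_p = hrr_network(
            CorrelationMatrix(genes=[genes[i] for i in perm], r=r[np.ix_(perm, perm)])
        )
        edges = {tuple(sorted(e)) for e in net.graph.edges}
        edges_p = {tuple(sorted(e)) for e in net_p.graph.edges}
        assert edges == edges_p
        attrs = sorted((d["hrr"], round(d["r"], 12)) for _, _, d in net.graph.edges(data=True))
        attrs_p = sorted((d["hrr"], round(d["r"], 12)) for _, _, d in net_p.graph.edges(data=True))
        assert attrs == attrs_p

    def test_most_edges_stay_within_planted_modules(self):
        # module-dominated config: 30 genes in two 15-gene modules. Column
        # normalization is off because with no unstructured majority the
        # totals track the modules themselves.
        total_edges = same_module = 0
        for seed in (1, 2, 3, 4, 5):
            cfg = SimulationConfig(n_genes=30, n_modules=2, module_size=15,
                                   module_corr_strength=0.9, noise_sd=0.3, seed=seed)
            ds, truth = generate_dataset(cfg)
            logged = log2_normalize(filter_null_genes(ds)[0], normalize=False)
            net = hrr_network(pearson_matrix(logged))
            labels = truth.module_labels()
            total_edges += net.graph.number_of_edges()
            same_module += sum(
                1 for u, v in net.graph.edges
                if labels.get(u, -1) == labels.get(v, -2) and labels.get(u, -1) != -1
            )
        assert same_module / total_edges >= 0.8


def annotation_for(pairs):
    cazy = pd.DataFrame.from_dict(
        {g: (fam[:2], fam) for g, fam in pairs.items()},
        orient="index", columns=["cazy_class", "cazy_family"],
    )
    return AnnotationSet(cazy=cazy, secreted=pd.DataFrame())


class TestCazySubnetwork:
    def test_induced_subgraph_keeps_edge_attributes(self):
        net = hrr_network(FOUR_GENE, hrr_max=2)
        sub = cazy_subnetwork(net, annotation_for({"A": "GH18", "B": "AA9"}))
        assert set(sub.graph.nodes) == {"A", "B"}
        assert sub.graph.edges["A", "B"]["r"] == 0.9

    def test_no_cazy_genes_empty_network(self):
        net = hrr_network(FOUR_GENE)
        sub = cazy_subnetwork(net, annotation_for({}))
        assert sub.graph.number_of_nodes() == 0

    def test_all_cazy_identity(self):
        net = hrr_network(FOUR_GENE, hrr_max=2)
        ann = annotation_for({g: "GH5" for g in "ABCD"})
        sub = cazy_subnetwork(net, ann)
        assert nx.utils.graphs_equal(sub.graph, net.graph)


class TestNetworkStatsAndIO:
    def test_triangle_stats(self, two_clique_path_net):
        from coregnet import CoexpressionNetwork

        tri = nx.Graph([("a", "b"), ("b", "c"), ("a", "c")])
        for u, v in tri.edges:
            tri.edges[u, v].update(r=1.0, hrr=1)
        stats = network_stats(CoexpressionNetwork(tri))
        assert stats["nodes"] == 3 and stats["edges"] == 3
        assert stats["degree_distribution"] == {2: 3}
        assert stats["components"] == 1

    def test_empty_graph_stats(self):
        from coregnet import CoexpressionNetwork

        stats = network_stats(CoexpressionNetwork(nx.Graph()))
        assert stats == {
            "nodes": 0, "edges": 0, "max_degree": 0, "mean_degree": 0.0,
            "degree_distribution": {}, "components": 0,
        }

    def test_two_disjoint_edges_two_components(self):
        from coregnet import CoexpressionNetwork

        g = nx.Graph([("a", "b"), ("c", "d")])
        for u, v in g.edges:
            g.edges[u, v].update(r=1.0, hrr=1)
        assert network_stats(CoexpressionNetwork(g))["components"] == 2

    def test_edge_tsv_round_trip(self, tmp_path):
        from coregnet import CoexpressionNetwork

        net = hrr_network(FOUR_GENE, hrr_max=2)
        path = tmp_path / "edges.tsv"
        net.to_edge_tsv(path)
        back = CoexpressionNetwork.from_edge_tsv(path, nodes=net.nodes)
        assert set(back.graph.nodes) == set(net.graph.nodes)
        assert {tuple(sorted(e)) for e in back.graph.edges} == {
            tuple(sorted(e)) for e in net.graph.edges
        }
        assert back.graph.edges["A", "C"]["hrr"] == 2

    def test_graphml_written_loadable(self, tmp_path):
        net = hrr_network(FOUR_GENE, hrr_max=2)
        net.annotate(annotation_for({"A": "GH18"}))
        path = tmp_path / "net.graphml"
        net.to_graphml(path)
        back = nx.read_graphml(path)
        assert back.nodes["A"]["cazy_family"] == "GH18"
        assert back.number_of_edges() == net.graph.number_of_edges()
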