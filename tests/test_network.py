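"""Gene network reconstruction: per-group correlation, the four edge
criteria, planted-module recovery, and shortest-path behaviour."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy.sparse.csgraph import floyd_warshall

from tknet.errors import DataError
from tknet.network import (
    PerGroupCorr,
    avg_shortest_path_length,
    avg_shortest_path_lengths,
    build_network,
    edge_admissible,
    edge_table,
    pairwise_pergroup,
    pergroup_correlations,
)
from tknet.simulate import SimulationConfig, simulate_expression_groups
from tknet.stats import CombinedResult, fisher_combined


def _groups_from_arrays(arrays, genes):
    return [
        pd.DataFrame(a, index=pd.Index(genes, name="gene_id"),
                     columns=[f"g{i}_s{j}" for j in range(a.shape[1])])
        for i, a in enumerate(arrays)
    ]


class TestPerGroupCorrelations:
    def test_near_duplicate_gene_strong_combined_signal(self, rng):
        arrays = []
        for _ in range(4):
            a = rng.normal(0, 1, (1, 8))
            b = a + rng.normal(0, 0.01, (1, 8))
            arrays.append(np.vstack([a, b]))
        groups = _groups_from_arrays(arrays, ["ga", "gb"])
        pc = pergroup_correlations(groups, "ga", "gb")
        assert min(pc.r_by_group) > 0.99
        assert pc.combined.p_combined < 1e-6

    def test_single_group_equals_fisher_identity(self, rng):
        arrays = [rng.normal(0, 1, (2, 10))]
        groups = _groups_from_arrays(arrays, ["ga", "gb"])
        pc = pergroup_correlations(groups, "ga", "gb")
        assert pc.combined.p_combined == pytest.approx(pc.p_by_group[0], abs=1e-12)

    def test_null_pairs_combined_p_roughly_uniform(self, rng):
        """Independent noise: the Fisher-combined p is uniform, so about 1%
        of pairs fall below 0.01."""
        n_genes = 90  # 4005 pairs
        arrays = [rng.normal(0, 1, (n_genes, 8)) for _ in range(4)]
        groups = _groups_from_arrays(arrays, [f"g{i}" for i in range(n_genes)])
        pairs = pairwise_pergroup(groups)
        frac = (pairs["p_combined"] < 0.01).mean()
        assert 0.004 < frac < 0.02

    def test_batch_matches_single_pair_route(self, rng):
        arrays = [rng.normal(0, 1, (4, 9)) for _ in range(3)]
        genes = ["a", "b", "c", "d"]
        groups = _groups_from_arrays(arrays, genes)
        pairs = pairwise_pergroup(groups).set_index(["gene_a", "gene_b"])
        pc = pergroup_correlations(groups, "b", "d")
        row = pairs.loc[("b", "d")]
        for i in range(3):
            assert row[f"r_{i}"] == pytest.approx(pc.r_by_group[i], abs=1e-10)
        assert row["p_combined"] == pytest.approx(pc.combined.p_combined, abs=1e-10)


def _pc(rs, ps):
    return PerGroupCorr(
        "a", "b", tuple(rs), tuple(ps), combined=fisher_combined(ps)
    )


class TestEdgeAdmissible:
    def test_consistent_negative_lfc_pair_admissible(self):
        pc = _pc([0.8, 0.7, 0.9, 0.6], [0.01, 0.02, 0.005, 0.04])
        assert edge_admissible(pc, lfc_a=-1.0, lfc_b=-0.5)

    def test_single_group_p_above_cutoff_blocks(self):
        pc = _pc([0.8, 0.7, 0.9, 0.2], [0.01, 0.02, 0.005, 0.5])
        assert not edge_admissible(pc, -1.0, -0.5)

    def test_sign_inconsistency_blocks(self):
        pc = _pc([0.8, 0.7, -0.9, 0.6], [0.01, 0.02, 0.005, 0.04])
        assert not edge_admissible(pc, -1.0, -0.5)

    def test_fold_change_sign_rule(self):
        pc = _pc([0.8, 0.7, 0.9, 0.6], [0.01, 0.02, 0.005, 0.04])
        # positive correlation needs same-sign fold changes
        assert not edge_admissible(pc, lfc_a=1.0, lfc_b=-0.5)
        assert edge_admissible(pc, lfc_a=1.0, lfc_b=0.5)
        assert not edge_admissible(pc, lfc_a=0.0, lfc_b=0.5)


class TestBuildNetwork:
    def _module_groups(self, rng, n_per_module=10, loading=0.9, n_samples=10):
        genes = [f"m1_{i}" for i in range(n_per_module)] + [
            f"m2_{i}" for i in range(n_per_module)
        ]
        arrays = []
        for _ in range(4):
            f1, f2 = rng.standard_normal(n_samples), rng.standard_normal(n_samples)
            noise = rng.normal(0, np.sqrt(1 - loading**2), (2 * n_per_module, n_samples))
            X = noise.copy()
            X[:n_per_module] += loading * f1
            X[n_per_module:] += loading * f2
            arrays.append(X)
        lfc = pd.Series(
            [-0.5] * n_per_module + [0.5] * n_per_module,
            index=pd.Index(genes, name="gene_id"),
        )
        return _groups_from_arrays(arrays, genes), lfc

    def test_planted_modules_recovered_cross_module_sparse(self, rng):
        groups, lfc = self._module_groups(rng)
        g, summary = build_network(groups, lfc)
        n = 10
        n_within = n * (n - 1)  # both modules, unordered pairs x2 modules
        within_edges = sum(
            1 for a, b in g.edges if a.split("_")[0] == b.split("_")[0]
        )
        cross_edges = g.number_of_edges() - within_edges
        assert within_edges >= 0.9 * n_within
        assert cross_edges <= 0.01 * n * n + 1
        assert summary["n_members"] == len(g.nodes)

    def test_independent_noise_yields_almost_no_edges(self, rng):
        n_genes, seeds = 40, 10
        total_pairs = total_edges = 0
        for s in range(seeds):
            local = np.random.default_rng(s)
            arrays = [local.normal(0, 1, (n_genes, 9)) for _ in range(4)]
            genes = [f"g{i}" for i in range(n_genes)]
            groups = _groups_from_arrays(arrays, genes)
            lfc = pd.Series(
                local.choice([-1, 1], n_genes) * local.uniform(0.2, 1, n_genes),
                index=pd.Index(genes, name="gene_id"),
            )
            g, _ = build_network(groups, lfc)
            total_edges += g.number_of_edges()
            total_pairs += n_genes * (n_genes - 1) // 2
        assert total_edges / total_pairs <= 0.001

    def test_single_coupled_pair_gives_two_node_network(self, rng):
        arrays = []
        for _ in range(4):
            a = rng.normal(0, 1, 10)
            arrays.append(np.vstack([a, a + rng.normal(0, 0.05, 10),
                                     rng.normal(0, 1, 10)]))
        genes = ["a", "b", "noise"]
        groups = _groups_from_arrays(arrays, genes)
        lfc = pd.Series([1.0, 1.0, 1.0], index=pd.Index(genes, name="gene_id"))
        g, summary = build_network(groups, lfc)
        assert set(g.nodes) == {"a", "b"}
        assert g.number_of_edges() == 1
        assert summary["membership_fraction"] == pytest.approx(2 / 3)

    def test_invariant_to_gene_and_group_permutation(self, rng):
        groups, lfc = self._module_groups(rng, n_per_module=5)
        g1, _ = build_network(groups, lfc)
        perm = list(rng.permutation(list(lfc.index)))
        groups_p = [gr.loc[perm] for gr in reversed(groups)]
        g2, _ = build_network(groups_p, lfc.loc[perm])
        assert set(map(frozenset, g1.edges)) == set(map(frozenset, g2.edges))

    def test_every_edge_repasses_admissibility(self, rng):
        """Self-audit: recheck each reported edge through the scalar rule."""
        groups, lfc = self._module_groups(rng, n_per_module=6)
        g, _ = build_network(groups, lfc)
        for a, b in g.edges:
            pc = pergroup_correlations(groups, a, b)
            assert edge_admissible(pc, lfc[a], lfc[b])

    def test_tiny_subset_rejected(self, rng):
        groups, lfc = self._module_groups(rng, n_per_module=3)
        with pytest.raises(DataError):
            build_network(groups, lfc, gene_subset=["m1_0"])


class TestShortestPaths:
    def test_star_center_and_path_end(self):
        star = nx.star_graph(5)
        assert avg_shortest_path_length(star, 0) == 1.0
        path = nx.path_graph(3)  # a-b-c
        assert avg_shortest_path_length(path, 0) == pytest.approx(1.5)

    def test_isolated_and_missing_nodes(self):
        g = nx.Graph()
        g.add_edge("a", "b")
        g.add_node("lonely")
        with pytest.raises(DataError):
            avg_shortest_path_length(g, "lonely")
        with pytest.raises(DataError):
            avg_shortest_path_length(g, "ghost")

    def test_bounds_within_component(self, rng):
        g = nx.gnp_random_graph(30, 0.2, seed=7)
        aspl = avg_shortest_path_lengths(g)
        for comp in nx.connected_components(g):
            comp = list(comp)
            if len(comp) < 2:
                continue
            diameter = nx.diameter(g.subgraph(comp))
            for node in comp:
                assert 1.0 <= aspl[node] <= diameter

    @pytest.mark.parametrize("p_edge", [0.05, 0.2, 0.5])
    def test_matches_floyd_warshall_oracle(self, p_edge):
        """BFS distances agree exactly with the dense all-pairs oracle."""
        for trial in range(12):
            n = 5 + (trial * 7) % 46
            g = nx.gnp_random_graph(n, p_edge, seed=1000 * trial + int(p_edge * 100))
            dist = floyd_warshall(nx.to_scipy_sparse_array(g, weight=None))
            for node in g.nodes:
                if g.degree(node) == 0:
                    continue
                row = dist[node]
                finite = row[np.isfinite(row)]
                expected = (finite.sum()) / (finite.size - 1)  # exclude self
                assert avg_shortest_path_length(g, node) == pytest.approx(expected)


def test_generator_modules_have_strong_consistent_correlation():
    """Planted module genes correlate strongly within groups, with matching
    sign across groups, and noise genes produce almost no admissible edges."""
    cfg = SimulationConfig(seed=5)
    expr, _, lfc, truth = simulate_expression_groups(cfg)
    members = truth.module_members["module_2"][:10]
    mean_abs = []
    for eg in expr:
        R = np.corrcoef(eg.loc[members].to_numpy())
        mean_abs.append(np.abs(R[np.triu_indices(10, 1)]).mean())
    assert min(mean_abs) > 0.6
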