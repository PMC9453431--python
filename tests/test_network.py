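"""Fold-change matrices, tree-ensemble inference, modules, centralities."""

import itertools

import numpy as np
import pandas as pd
import pytest

import networkx as nx

from phenanchor.datatypes import CountMatrix
from phenanchor.dge import filter_low_counts, normalize_counts, size_factors
from phenanchor.network import (
    CoexpressionNetwork,
    NetworkConfig,
    centralities,
    detect_modules,
    fold_change_matrix,
    infer_network,
    possible_edge_count,
    retained_fraction,
    select_top_cv,
    threshold_network,
)


class TestFoldChangeMatrix:
    def test_control_mean_reference_near_zero(self, small_dataset, normalized_small):
        # the control columns scatter around zero by construction; the
        # arithmetic-vs-geometric (Jensen) gap grows with NB dispersion, so
        # the per-gene guarantee is checked on low-dispersion genes
        fc = fold_change_matrix(normalized_small, small_dataset.design)
        ctrl = small_dataset.design.control_samples
        ctrl_mean = fc[ctrl].mean(axis=1)
        assert ctrl_mean.abs().median() < 0.2
        tight = [
            t.gene_id
            for t in small_dataset.truths
            if t.dispersion <= 0.05 and t.baseline_mean >= 100 and t.gene_id in fc.index
        ]
        assert ctrl_mean.loc[tight].abs().max() < 0.25

    def test_threefold_sample_with_small_pseudocount(self, design32):
        genes = ["g"]
        vals = pd.DataFrame(
            np.full((1, 32), 100.0), index=genes, columns=design32.sample_ids
        )
        vals.iloc[0, design32.sample_ids.index(design32.samples_at(50.0)[0])] = 300.0
        fc = fold_change_matrix(vals, design32, pseudocount=1e-9)
        assert fc.loc["g", design32.samples_at(50.0)[0]] == pytest.approx(np.log2(3), rel=1e-6)

    def test_invariance_to_depth_doubling_after_normalization(self, small_dataset):
        # ratios are depth-scale-free once the pseudocount is negligible
        filtered = filter_low_counts(small_dataset.counts)
        all_pos = filtered.values.index[(filtered.values > 0).all(axis=1)]
        fc1 = fold_change_matrix(
            normalize_counts(filtered), small_dataset.design, pseudocount=1e-6
        )
        doubled = CountMatrix(filtered.values * 2)
        fc2 = fold_change_matrix(
            normalize_counts(doubled), small_dataset.design, pseudocount=1e-6
        )
        assert np.allclose(
            fc1.loc[all_pos].to_numpy(), fc2.loc[all_pos].to_numpy(), atol=1e-6
        )


class TestSelectTopCv:
    def test_varying_gene_beats_constant(self):
        fc = pd.DataFrame(
            [[0.0] * 6, [0.0, 2.0, -1.0, 1.5, -0.5, 1.0]],
            index=["flat", "vary"],
            columns=[f"s{i}" for i in range(6)],
        )
        assert list(select_top_cv(fc, 1).index) == ["vary"]

    def test_deterministic_ties_and_named_index(self):
        # equal-CV ties break by gene id; a named index (as after reading a
        # counts TSV) must not break selection
        fc = pd.DataFrame(
            [[0.0, 1.0], [0.0, 1.0], [0.0, 2.0]],
            index=pd.Index(["b", "a", "c"], name="gene_id"),
            columns=["s1", "s2"],
        )
        assert list(select_top_cv(fc, 2).index) == ["c", "a"]

    def test_full_selection_is_identity_set(self, small_dataset, normalized_small):
        fc = fold_change_matrix(normalized_small, small_dataset.design)
        assert set(select_top_cv(fc, fc.shape[0]).index) == set(fc.index)

    def test_responsive_module_ranks_in_top_decile(self, small_dataset, normalized_small):
        fc = fold_change_matrix(normalized_small, small_dataset.design)
        n_top = max(1, fc.shape[0] // 10)
        top = set(select_top_cv(fc, n_top).index)
        module = {t.gene_id for t in small_dataset.truths if t.klass == "ahr_module"}
        assert len(top & module) / len(top) > 0.5


def _noise_frame(rng, n_genes, n_samples, prefix="g"):
    return pd.DataFrame(
        rng.normal(0, 1, (n_genes, n_samples)),
        index=[f"{prefix}{i}" for i in range(n_genes)],
        columns=[f"s{j}" for j in range(n_samples)],
    )


class TestInferNetwork:
    def test_correlated_pair_gets_top_incoming_weight(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(700 + seed)
            fc = _noise_frame(rng, 100, 24)
            shared = rng.normal(0, 1, 24)
            fc.iloc[0] = shared
            fc.iloc[1] = shared  # perfect co-expression
            cfg = NetworkConfig(n_trees=30, seed=seed)
            edges = infer_network(fc, cfg)
            inc0 = edges[edges["target"] == "g0"].set_index("source")["weight"]
            inc1 = edges[edges["target"] == "g1"].set_index("source")["weight"]
            hits += (inc0.idxmax() == "g1") and (inc1.idxmax() == "g0")
        assert hits >= 9

    def test_joint_sample_permutation_leaves_weights_unchanged(self):
        rng = np.random.default_rng(2)
        fc = _noise_frame(rng, 12, 16)
        cfg = NetworkConfig(n_trees=25, seed=4)
        base = infer_network(fc, cfg)
        perm = rng.permutation(fc.shape[1])
        shuffled = fc.iloc[:, perm]
        again = infer_network(shuffled, cfg)
        merged = base.merge(again, on=["source", "target"], suffixes=("_a", "_b"))
        assert np.allclose(merged["weight_a"], merged["weight_b"], atol=1e-12)

    def test_seed_determinism(self):
        rng = np.random.default_rng(3)
        fc = _noise_frame(rng, 15, 20)
        cfg = NetworkConfig(n_trees=25, seed=9)
        a, b = infer_network(fc, cfg), infer_network(fc, cfg)
        assert a.equals(b)

    def test_incoming_weights_sum_to_one_or_zero(self):
        rng = np.random.default_rng(5)
        fc = _noise_frame(rng, 10, 12)
        fc.iloc[3] = 1.0  # zero-variance target
        edges = infer_network(fc, NetworkConfig(n_trees=20, seed=1))
        sums = edges.groupby("target")["weight"].sum()
        assert sums["g3"] == pytest.approx(0.0)
        others = sums.drop("g3")
        assert np.allclose(others, 1.0, atol=1e-9)

    def test_null_importances_stay_in_expectation_band(self):
        # with p independent regressors the mean incoming weight is 1/p and
        # no regressor should dominate: the max averages below 3/p across
        # seeds (requires samples comfortably exceeding features)
        p = 15
        maxima = []
        for seed in range(20):
            rng = np.random.default_rng(900 + seed)
            fc = _noise_frame(rng, p + 1, 32)
            edges = infer_network(fc, NetworkConfig(n_trees=100, seed=seed))
            inc = edges[edges["target"] == "g0"]["weight"]
            maxima.append(inc.max())
        assert np.mean(maxima) <= 3.0 / p

    def test_too_few_genes_or_samples_error(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            infer_network(_noise_frame(rng, 1, 10))
        with pytest.raises(ValueError):
            infer_network(_noise_frame(rng, 5, 2))


class TestThresholdNetwork:
    def test_strictly_greater_than_cutoff(self):
        edges = pd.DataFrame(
            {"source": ["a", "b"], "target": ["b", "a"], "weight": [0.0086, 0.00861]}
        )
        net = threshold_network(edges, NetworkConfig(edge_cutoff=0.0086))
        assert len(net.edges) == 1 and net.edges["weight"].iloc[0] == 0.00861

    def test_cutoff_above_max_empties_network(self):
        edges = pd.DataFrame({"source": ["a"], "target": ["b"], "weight": [0.5]})
        net = threshold_network(edges, NetworkConfig(edge_cutoff=0.9))
        assert len(net.edges) == 0 and set(net.isolated) == {"a", "b"}


class TestDetectModules:
    @staticmethod
    def _clique_net():
        rows = []
        for grp, genes in enumerate([list("abcde"), list("fghij")]):
            for s, t in itertools.combinations(genes, 2):
                rows.append((s, t, 1.0))
        rows.append(("e", "f", 0.01))  # weak bridge
        return CoexpressionNetwork(
            edges=pd.DataFrame(rows, columns=["source", "target", "weight"]),
            isolated=[],
        )

    def test_two_cliques_split(self):
        net = self._clique_net()
        modules = detect_modules(net)
        assert len(set(modules.values())) == 2
        assert len({modules[g] for g in "abcde"}) == 1
        assert len({modules[g] for g in "fghij"}) == 1

    def test_edgeless_network_errors(self):
        net = CoexpressionNetwork(
            edges=pd.DataFrame(columns=["source", "target", "weight"]), isolated=["x"]
        )
        with pytest.raises(ValueError):
            detect_modules(net)

    def test_modularity_beats_singletons(self):
        net = self._clique_net()
        detect_modules(net)
        g = net.undirected(weighted=True)
        from networkx.algorithms.community import modularity

        parts = {}
        for gene, m in net.module_of.items():
            parts.setdefault(m, set()).add(gene)
        q = modularity(g, parts.values(), weight="weight")
        q_singletons = modularity(g, [{n} for n in g.nodes], weight="weight")
        assert q >= q_singletons

    def test_planted_module_recovered(self, small_dataset, normalized_small):
        ds = small_dataset
        fc = fold_change_matrix(normalized_small, ds.design)
        fc = select_top_cv(fc, 60)
        cfg = NetworkConfig(n_trees=100, seed=5)
        net = threshold_network(infer_network(fc, cfg), cfg)
        modules = detect_modules(net)
        planted = {t.gene_id for t in ds.truths if t.klass == "ahr_module"}
        by_module = {}
        for gene, m in modules.items():
            by_module.setdefault(m, set()).add(gene)
        best = max(by_module.values(), key=lambda s: len(s & planted))
        jaccard = len(best & planted) / len(best | planted)
        assert jaccard >= 0.6


def _brute_force_betweenness(g: nx.Graph) -> dict:
    """Enumerate all shortest paths between node pairs directly."""
    nodes = list(g.nodes)
    n = len(nodes)
    score = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        try:
            paths = list(nx.all_shortest_paths(g, s, t))
        except nx.NetworkXNoPath:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(v in p for p in paths)
            score[v] += through / len(paths)
    norm = (n - 1) * (n - 2) / 2.0
    return {v: score[v] / norm for v in nodes}


class TestCentralities:
    def _net(self, pairs):
        return CoexpressionNetwork(
            edges=pd.DataFrame(
                [(s, t, 1.0) for s, t in pairs], columns=["source", "target", "weight"]
            ),
            isolated=[],
        )

    def test_star_center(self):
        net = self._net([("c", x) for x in "abde"])
        cent = centralities(net)
        assert cent.loc["c", "degree"] == 4
        assert cent.loc["c", "betweenness"] == pytest.approx(1.0)
        assert cent.loc["a", "betweenness"] == pytest.approx(0.0)

    def test_path_middle_node(self):
        net = self._net([("a", "b"), ("b", "c")])
        cent = centralities(net)
        assert cent.loc["b", "degree"] == 2
        assert cent.loc["b", "betweenness"] == pytest.approx(1.0)

    def test_degree_is_direction_blind(self):
        # reciprocal edges count one neighbour
        net = self._net([("a", "b"), ("b", "a"), ("b", "c")])
        cent = centralities(net)
        assert cent.loc["b", "degree"] == 2

    def test_matches_path_enumeration_on_random_graphs(self):
        rng = np.random.default_rng(1)
        for trial in range(8):
            n = int(rng.integers(5, 13))
            g = nx.gnp_random_graph(n, 0.4, seed=int(rng.integers(1e6)))
            pairs = [(f"n{a}", f"n{b}") for a, b in g.edges]
            if not pairs:
                continue
            net = self._net(pairs)
            cent = centralities(net)
            ref = _brute_force_betweenness(net.undirected(weighted=False))
            for v in cent.index:
                assert cent.loc[v, "betweenness"] == pytest.approx(ref[v], abs=1e-9)


class TestEdgeCounts:
    @pytest.mark.parametrize("n, expected", [(178, 31_506), (2, 2), (8000, 63_992_000)])
    def test_possible_edge_count(self, n, expected):
        assert possible_edge_count(n) == expected

    def test_single_gene_errors(self):
        with pytest.raises(ValueError):
            possible_edge_count(1)

    @pytest.mark.parametrize(
        "n_edges, n_genes, expected",
        [(4678, 8000, 0.007), (6, 3, 100.0), (0, 50, 0.0)],
    )
    def test_retained_fraction(self, n_edges, n_genes, expected):
        assert retained_fraction(n_edges, n_genes) == pytest.approx(expected)
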