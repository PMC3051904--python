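import itertools

import networkx as nx
import numpy as np
import pytest
from scipy import stats

from boolgba import (
    ConditionNetwork,
    ConservedNetwork,
    ExpressionMatrix,
    attribute_subnetwork,
    condition_correlations,
    connectivity_stats,
    conserved_network,
    pcit_significant_edges,
    resolution_views,
)
from boolgba.network import _log_binned_fit


def brute_force_pcit(r: np.ndarray) -> set[tuple[int, int]]:
    """Literal triple-loop implementation of the PCIT trio rule."""
    n = r.shape[0]
    eliminated = set()
    for x, y, z in itertools.permutations(range(n), 3):
        rxy, rxz, ryz = r[x, y], r[x, z], r[y, z]
        if 0.0 in (rxy, rxz, ryz):
            continue
        pxy = (rxy - rxz * ryz) / np.sqrt((1 - rxz**2) * (1 - ryz**2))
        pxz = (rxz - rxy * ryz) / np.sqrt((1 - rxy**2) * (1 - ryz**2))
        pyz = (ryz - rxy * rxz) / np.sqrt((1 - rxy**2) * (1 - rxz**2))
        eps = (pxy / rxy + pxz / rxz + pyz / ryz) / 3.0
        if abs(rxy) <= abs(eps * rxz) and abs(rxy) <= abs(eps * ryz):
            eliminated.add((min(x, y), max(x, y)))
    return {
        (i, j) for i in range(n) for j in range(i + 1, n)
    } - eliminated


def toy_conserved(edge_flags, conditions=("Normal", "Adenoma", "Carcinoma", "Inflammation")):
    return ConservedNetwork(conditions=list(conditions), edges=dict(edge_flags))


class TestConditionCorrelations:
    def test_identical_and_opposite_genes(self):
        values = np.array(
            [[1.0, 2, 3, 4, 5], [1.0, 2, 3, 4, 5], [5.0, 4, 3, 2, 1]]
        )
        values = np.hstack([values, values])
        expr = ExpressionMatrix(
            gene_ids=["a", "b", "c"],
            sample_ids=[f"s{i}" for i in range(10)],
            values=values,
            condition_of={f"s{i}": ("A" if i < 5 else "B") for i in range(10)},
        )
        genes, r = condition_correlations(expr, "A")
        assert r[0, 1] == pytest.approx(1.0)
        assert r[0, 2] == pytest.approx(-1.0)

    def test_matches_textbook_pearson_formula(self):
        x = np.array([2.0, 4, 5, 7, 9])
        y = np.array([1.0, 3, 2, 6, 8])
        values = np.vstack([np.hstack([x, x]), np.hstack([y, y])])
        expr = ExpressionMatrix(
            gene_ids=["a", "b"],
            sample_ids=[f"s{i}" for i in range(10)],
            values=values,
            condition_of={f"s{i}": ("A" if i < 5 else "B") for i in range(10)},
        )
        _, r = condition_correlations(expr, "A")
        expected = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert r[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_too_few_samples_raise(self, toy_expression):
        with pytest.raises(ValueError, match=">= 3"):
            condition_correlations(toy_expression, "Normal")


class TestPcit:
    def test_strong_trio_dominance_follows_the_rule(self):
        # expectations computed with the literal triple-loop oracle
        r = np.array([[1.0, 0.9, 0.1], [0.9, 1.0, 0.1], [0.1, 0.1, 1.0]])
        assert pcit_significant_edges(r) == brute_force_pcit(r)
        r2 = np.array([[1.0, 0.9, 0.85], [0.9, 1.0, 0.05], [0.85, 0.05, 1.0]])
        assert pcit_significant_edges(r2) == brute_force_pcit(r2)
        # the dominated weak edge in r2 is eliminated
        assert (1, 2) not in pcit_significant_edges(r2)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            data = rng.normal(size=(15, 12))
            r = np.corrcoef(data)
            assert pcit_significant_edges(r) == brute_force_pcit(r)

    def test_null_data_keeps_a_small_stable_fraction(self):
        fractions = []
        for seed in range(3):
            data = np.random.default_rng(seed).normal(size=(50, 10))
            sig = pcit_significant_edges(np.corrcoef(data))
            fractions.append(len(sig) / (50 * 49 / 2))
        assert max(fractions) < 0.5
        assert np.std(fractions) < 0.1

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(5)
        data = rng.normal(size=(12, 8))
        r = np.corrcoef(data)
        sig = pcit_significant_edges(r)
        perm = rng.permutation(12)
        r_p = r[np.ix_(perm, perm)]
        sig_p = pcit_significant_edges(r_p)
        remapped = {
            (min(perm[i], perm[j]), max(perm[i], perm[j])) for i, j in sig_p
        }
        assert remapped == sig

    def test_unit_correlation_pair_raises(self):
        r = np.array([[1.0, 1.0, 0.2], [1.0, 1.0, 0.2], [0.2, 0.2, 1.0]])
        with pytest.raises(ValueError, match="unit correlation"):
            pcit_significant_edges(r)

    def test_fewer_than_three_nodes_rejected(self):
        with pytest.raises(ValueError, match="3 nodes"):
            pcit_significant_edges(np.eye(2))


class TestConservedNetwork:
    def _nets(self, edge_sets):
        conds = ["Normal", "Adenoma", "Carcinoma", "Inflammation"]
        nodes = sorted({g for es in edge_sets for e in es for g in e})
        return [
            ConditionNetwork(
                condition=c,
                node_ids=nodes,
                correlations=np.eye(len(nodes)),
                edges={e: 0.9 for e in es},
            )
            for c, es in zip(conds, edge_sets)
        ]

    def test_conservation_counting(self):
        e1, e2 = ("a", "b"), ("b", "c")
        nets = self._nets([{e1, e2}, {e1, e2}, {e1}, {e1}])
        net = conserved_network(nets, min_conditions=3)
        assert set(net.edges) == {e1}
        assert net.conservation(e1) == 4

    def test_two_condition_edge_dropped(self):
        e = ("a", "b")
        nets = self._nets([{e}, {e}, set(), set()])
        assert set(conserved_network(nets, 3).edges) == set()

    def test_counts_equal_hand_tallied_intersections(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(8)]
        all_pairs = [(a, b) for i, a in enumerate(genes) for b in genes[i + 1:]]
        edge_sets = [
            {e for e in all_pairs if rng.random() < 0.4} for _ in range(4)
        ]
        net = conserved_network(self._nets(edge_sets), 3)
        for e in all_pairs:
            count = sum(e in es for es in edge_sets)
            assert (e in net.edges) == (count >= 3)
            if e in net.edges:
                assert net.conservation(e) == count

    def test_nesting_by_min_conditions(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(8)]
        all_pairs = [(a, b) for i, a in enumerate(genes) for b in genes[i + 1:]]
        edge_sets = [{e for e in all_pairs if rng.random() < 0.5} for _ in range(4)]
        nets = self._nets(edge_sets)
        e4 = set(conserved_network(nets, 4).edges)
        e3 = set(conserved_network(nets, 3).edges)
        union = set().union(*edge_sets)
        assert e4 <= e3 <= union

    def test_invalid_min_conditions(self):
        nets = self._nets([set()] * 4)
        with pytest.raises(ValueError, match="min_conditions"):
            conserved_network(nets, 5)


class TestResolutionViews:
    def test_pattern_rule_excludes_wrong_missing_condition(self):
        conds = ["Normal", "Adenoma", "Carcinoma", "Inflammation"]
        flags_no_adenoma = dict(zip(conds, [True, False, True, True]))
        flags_no_normal = dict(zip(conds, [False, True, True, True]))
        net = toy_conserved({("a", "b"): flags_no_adenoma, ("a", "c"): flags_no_normal})
        v1, *_ = resolution_views(net, {"a"})
        assert ("a", "b") not in v1
        assert ("a", "c") in v1

    def test_star_of_degree_one_leaves_has_empty_view3(self):
        conds = ["Normal", "Adenoma", "Carcinoma", "Inflammation"]
        full = dict(zip(conds, [True] * 4))
        net = toy_conserved({("hub", f"leaf{i}"): dict(full) for i in range(5)})
        _, v2, v3, v4 = resolution_views(net, {"hub"})
        assert v3 == set()
        assert v4 == v2

    def test_views_match_independent_predicate_oracle(self):
        rng = np.random.default_rng(3)
        conds = ["Normal", "Adenoma", "Carcinoma", "Inflammation"]
        genes = [f"g{i}" for i in range(10)]
        edges = {}
        for i, a in enumerate(genes):
            for b in genes[i + 1:]:
                flags = {c: bool(rng.random() < 0.6) for c in conds}
                if sum(flags.values()) >= 3:
                    edges[(a, b)] = flags
        net = toy_conserved(edges)
        top = {"g0", "g3", "g7"}
        v1, v2, v3, v4 = resolution_views(net, top)

        def pattern_ok(flags):
            missing = {c for c, f in flags.items() if not f}
            return missing in ({"Normal"}, {"Carcinoma"}, set())

        o1 = {e for e, f in edges.items() if pattern_ok(f)}
        o2 = {e for e in o1 if set(e) & top}
        deg = {}
        for a, b in o2:
            deg[a] = deg.get(a, 0) + 1
            deg[b] = deg.get(b, 0) + 1
        o3 = {e for e in o2 if deg[e[0]] > 2 and deg[e[1]] > 2}
        o4 = {e for e in o2 if sum(edges[e].values()) == 4}
        assert (v1, v2, v3, v4) == (o1, o2, o3, o4)
        assert v4 <= v2 <= v1 and v3 <= v2

    def test_empty_top_candidates_rejected(self):
        net = toy_conserved({})
        with pytest.raises(ValueError, match="empty"):
            resolution_views(net, set())


class TestAttributeSubnetwork:
    def _net(self):
        conds = ["Normal", "Adenoma", "Carcinoma", "Inflammation"]
        full = dict(zip(conds, [True] * 4))
        net = toy_conserved(
            {("a", "b"): dict(full), ("b", "c"): dict(full), ("a", "c"): dict(full)}
        )
        net.node_attrs = {
            "a": {"TF": True}, "b": {"TF": True}, "c": {"TF": False},
        }
        return net

    def test_mixed_edges_filtered_by_both_endpoints(self):
        net = self._net()
        assert attribute_subnetwork(net, "TF") == {("a", "b")}

    def test_fully_attributed_network_is_closed(self):
        net = self._net()
        net.node_attrs = {g: {"TF": True} for g in "abc"}
        assert attribute_subnetwork(net, "TF") == set(net.edges)

    def test_unknown_attribute_raises(self):
        with pytest.raises(KeyError, match="unknown attribute"):
            attribute_subnetwork(self._net(), "XYZ")


class TestConnectivity:
    def test_star_hub_and_handshake_lemma(self):
        conds = ["Normal", "Adenoma", "Carcinoma", "Inflammation"]
        full = dict(zip(conds, [True] * 4))
        net = toy_conserved({("hub", f"l{i}"): dict(full) for i in range(10)})
        stats_ = connectivity_stats(net)
        assert stats_.hubs[0] == "hub"
        assert stats_.degrees["hub"] == 10
        assert sum(stats_.degrees.values()) == 2 * len(net.edges)

    def test_power_law_exponent_recovered_from_generator(self):
        # degrees sampled from a discrete power law with exponent 2.5
        deg = stats.zipf(2.5).rvs(size=5000, random_state=0)
        exponent, r2 = _log_binned_fit(np.asarray(deg, dtype=float))
        assert exponent == pytest.approx(2.5, abs=0.5)
        assert r2 > 0.8

    def test_preferential_attachment_graph_fits_power_law(self):
        g = nx.barabasi_albert_graph(3000, 3, seed=0)
        conds = ["Normal", "Adenoma", "Carcinoma", "Inflammation"]
        full = dict(zip(conds, [True] * 4))
        net = toy_conserved({(f"n{a}", f"n{b}"): dict(full) for a, b in g.edges()})
        res = connectivity_stats(net)
        assert res.power_law_exponent == pytest.approx(3.0, abs=0.5)
        assert res.fit_r_squared > 0.8

    def test_single_degree_network_has_undefined_exponent(self):
        conds = ["Normal", "Adenoma", "Carcinoma", "Inflammation"]
        full = dict(zip(conds, [True] * 4))
        net = toy_conserved({("a", "b"): dict(full), ("c", "d"): dict(full)})
        res = connectivity_stats(net)
        assert res.power_law_exponent is None
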