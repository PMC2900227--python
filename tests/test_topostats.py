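"""Components, hierarchy decomposition, neighbor pairs, path preservation."""

import itertools

import networkx as nx
import numpy as np
import pytest

from wgdnet.collapse import AncestralNetwork
from wgdnet.dsubgraph import (
    ColoredEdge,
    DSClass,
    EdgeColoring,
    MASKS_OF_CLASS,
    mask_to_pattern,
)
from wgdnet.net_io import RegulatoryNetwork
from wgdnet.nullmodels import OneShotSpec, sample_oneshot_coloring
from wgdnet.topostats import (
    HierarchyLabel,
    hierarchy_decompose,
    hierarchy_enrichment,
    neighbor_pair_scores,
    pair_indices,
    path_preserved,
    path_preservation_test,
    wgd_subnetwork_components,
)


def _anc(edges):
    return AncestralNetwork.trivial(RegulatoryNetwork.from_edges(edges))


def _uniform_coloring(anc, ds, pattern=None):
    if pattern is None:
        pattern = mask_to_pattern(MASKS_OF_CLASS[ds][0])
    return EdgeColoring({
        e: ColoredEdge(ds=ds, pattern=pattern, self_loop=e[0] == e[1])
        for e in anc.edges
    })


def _coloring_from(anc, mapping):
    return EdgeColoring({
        e: ColoredEdge(ds=mapping[e],
                       pattern=mask_to_pattern(MASKS_OF_CLASS[mapping[e]][0]),
                       self_loop=e[0] == e[1])
        for e in anc.edges
    })


class TestComponents:
    def test_all_zeta_gives_empty_wgd_network(self):
        anc = _anc([("a", "b"), ("b", "c")])
        stats = wgd_subnetwork_components(_uniform_coloring(anc, DSClass.ZETA), anc)
        assert stats.n_components == 0
        assert stats.largest_component_size == 0

    def test_beta_path_is_one_component_of_three_edges(self):
        anc = _anc([("a", "b"), ("b", "c"), ("c", "d")])
        stats = wgd_subnetwork_components(_uniform_coloring(anc, DSClass.BETA), anc)
        assert stats.n_components == 1
        assert stats.largest_component_size == 3

    def test_two_separate_nontrivial_islands(self):
        anc = _anc([("a", "b"), ("c", "d"), ("x", "y")])
        col = _coloring_from(anc, {("a", "b"): DSClass.BETA,
                                   ("c", "d"): DSClass.GAMMA,
                                   ("x", "y"): DSClass.ZETA})
        stats = wgd_subnetwork_components(col, anc)
        assert stats.n_components == 2
        assert stats.sizes == [1, 1]

    def test_tf_only_restricts_to_tf_targets(self):
        # b is a TF (sends a link); d is not
        anc = _anc([("a", "b"), ("b", "c"), ("a", "d")])
        col = _uniform_coloring(anc, DSClass.EPSILON)
        full = wgd_subnetwork_components(col, anc, tf_only=False)
        tf = wgd_subnetwork_components(col, anc, tf_only=True)
        assert full.largest_component_size == 3
        assert set(tf.component_of_edge) == {("a", "b")}


class TestConnectivitySignificance:
    def test_concentrated_coloring_is_significant(self):
        """Non-trivial colors packed onto one subtree beat scattered nulls.

        The permutation null conserves the color counts, so the only
        question is arrangement: 20 contiguous β edges form one large
        component, while scattered ones fragment.
        """
        edges = [(f"n{k}", f"n{k + 1}") for k in range(100)]
        anc = _anc(edges)
        mapping = {e: (DSClass.BETA if int(e[0][1:]) < 20 else DSClass.ZETA)
                   for e in anc.edges}
        col = _coloring_from(anc, mapping)
        spec = OneShotSpec.from_coloring(col, mode="permutation")
        from wgdnet.topostats import connectivity_significance

        s_n, s_size = connectivity_significance(col, anc, spec, n_real=1000,
                                                seed=3)
        assert s_size.observed == 20
        assert s_size.p_emp <= 0.01
        assert s_n.p_emp <= 0.01


class TestHierarchy:
    def test_two_cycle_is_core(self):
        labels = hierarchy_decompose(_anc([("a", "b"), ("b", "a")]))
        assert set(labels.values()) == {HierarchyLabel.CORE}

    def test_acyclic_chain_is_side(self):
        labels = hierarchy_decompose(_anc([("r", "x"), ("x", "l")]))
        assert set(labels.values()) == {HierarchyLabel.SIDE}

    def test_upstream_core_downstream(self):
        anc = _anc([("r", "c1"), ("c1", "c2"), ("c2", "c1"), ("c2", "l")])
        labels = hierarchy_decompose(anc)
        assert labels[("r", "c1")] is HierarchyLabel.UPSTREAM
        assert labels[("c1", "c2")] is HierarchyLabel.CORE
        assert labels[("c2", "c1")] is HierarchyLabel.CORE
        assert labels[("c2", "l")] is HierarchyLabel.DOWNSTREAM

    def test_self_loop_and_intercore(self):
        anc = _anc([
            ("a", "b"), ("b", "a"),        # core 1
            ("c", "d"), ("d", "c"),        # core 2
            ("b", "c"),                    # between cores
            ("s", "s"),                    # self-loop
        ])
        labels = hierarchy_decompose(anc)
        assert labels[("b", "c")] is HierarchyLabel.INTERCORE
        assert labels[("s", "s")] is HierarchyLabel.SELF

    def test_labels_invariant_under_relabeling(self, small_dataset):
        _, _, truth = small_dataset
        anc = truth.ancestral
        labels = hierarchy_decompose(anc)
        renamed = {n: f"x_{n}" for n in anc.net.nodes}
        anc2 = AncestralNetwork.trivial(RegulatoryNetwork.from_edges(
            [(renamed[u], renamed[v]) for u, v in anc.net.edges],
            extra_nodes=[renamed[n] for n in anc.net.nodes],
        ))
        labels2 = hierarchy_decompose(anc2)
        for (u, v), lab in labels.items():
            assert labels2[(renamed[u], renamed[v])] is lab

    def test_removing_core_and_self_leaves_acyclic(self, small_dataset):
        _, _, truth = small_dataset
        anc = truth.ancestral
        labels = hierarchy_decompose(anc)
        g = nx.DiGraph()
        g.add_edges_from(e for e, lab in labels.items()
                         if lab not in (HierarchyLabel.CORE, HierarchyLabel.SELF))
        assert nx.is_directed_acyclic_graph(g)

    def test_enrichment_empty_label_is_degenerate(self):
        anc = _anc([("a", "b"), ("b", "c")])  # no core at all
        labels = hierarchy_decompose(anc)
        col = _uniform_coloring(anc, DSClass.ZETA)
        spec = OneShotSpec(class_probabilities={DSClass.ZETA: 1.0})
        scores = hierarchy_enrichment(col, labels, anc, spec, n_real=20, seed=0)
        s = scores[(HierarchyLabel.CORE, DSClass.BETA)]
        assert s.observed == 0 and s.null_sd == 0 and s.z is None

    def test_planted_upstream_beta_detected(self):
        """All β placed on upstream edges stands out against re-coloring."""
        edges = [(f"r{i}", "c1") for i in range(6)] + \
            [("c1", "c2"), ("c2", "c1")] + [("c2", f"l{i}") for i in range(6)]
        anc = _anc(edges)
        labels = hierarchy_decompose(anc)
        mapping = {e: (DSClass.BETA if labels[e] is HierarchyLabel.UPSTREAM
                       else DSClass.ZETA) for e in anc.edges}
        col = _coloring_from(anc, mapping)
        spec = OneShotSpec.from_coloring(col, mode="permutation")
        scores = hierarchy_enrichment(col, labels, anc, spec, n_real=300, seed=5)
        assert scores[(HierarchyLabel.UPSTREAM, DSClass.BETA)].z > 3


class TestNeighborPairs:
    def test_star_counts_single_adj_out_cell(self):
        anc = _anc([("a", "b"), ("a", "c")])
        col = _uniform_coloring(anc, DSClass.BETA)
        spec = OneShotSpec.from_coloring(col)
        _, matrices = neighbor_pair_scores(col, anc, spec, n_real=10, seed=0)
        adj_out = matrices["ADJ_OUT"].counts
        assert adj_out[(DSClass.BETA, DSClass.BETA)] == 1
        assert sum(adj_out.values()) == 1
        assert matrices["ADJ_IN"].total == 0

    def test_consecutive_is_ordered(self):
        anc = _anc([("a", "b"), ("b", "c")])
        col = _coloring_from(anc, {("a", "b"): DSClass.BETA,
                                   ("b", "c"): DSClass.GAMMA})
        spec = OneShotSpec.from_coloring(col)
        _, matrices = neighbor_pair_scores(col, anc, spec, n_real=10, seed=0)
        cons = matrices["CONSECUTIVE"].counts
        assert cons[(DSClass.BETA, DSClass.GAMMA)] == 1
        assert cons[(DSClass.GAMMA, DSClass.BETA)] == 0

    def test_pair_totals_match_degree_sequence(self, small_dataset):
        """Σ cells per relation equals the combinatorial pair count."""
        _, _, truth = small_dataset
        anc = truth.ancestral
        col = truth.coloring
        spec = OneShotSpec.from_coloring(col)
        _, matrices = neighbor_pair_scores(col, anc, spec, n_real=5, seed=0,
                                           classes=None)
        g = anc.net.to_networkx()
        out_deg = dict(g.out_degree())
        in_deg = dict(g.in_degree())
        expect_out = sum(d * (d - 1) // 2 for d in out_deg.values())
        expect_in = sum(d * (d - 1) // 2 for d in in_deg.values())
        n_self = sum(1 for u, v in anc.edges if u == v)
        expect_cons = sum(in_deg[n] * out_deg[n] for n in g.nodes) - n_self
        assert matrices["ADJ_OUT"].total == expect_out
        assert matrices["ADJ_IN"].total == expect_in
        assert matrices["CONSECUTIVE"].total == expect_cons

    def test_self_loop_not_consecutive_with_itself(self):
        anc = _anc([("a", "a"), ("a", "b")])
        pairs = pair_indices(anc)
        ia, ib = pairs["CONSECUTIVE"]
        edges = anc.edges
        got = {(edges[i], edges[j]) for i, j in zip(ia, ib)}
        assert (("a", "a"), ("a", "a")) not in got
        assert (("a", "a"), ("a", "b")) in got


class TestPathPreservation:
    def test_shared_copy_preserves(self):
        assert path_preserved({(1, 1)}, {(1, 1)})

    def test_disjoint_copies_break(self):
        assert not path_preserved({(1, 1)}, {(2, 1)})

    def test_exhaustive_against_brute_force_graph_search(self):
        """All 225 ordered non-empty pattern pairs vs an instantiated graph.

        For each pair, build the literal 6-node copy-level graph
        (A1,A2 -> B1,B2 -> C1,C2) and ask networkx whether any A copy
        reaches any C copy.
        """
        patterns = [frozenset(p) for p in _all_patterns() if p]
        assert len(patterns) == 15
        for p1, p2 in itertools.product(patterns, repeat=2):
            g = nx.DiGraph()
            g.add_nodes_from([f"{n}{k}" for n in "ABC" for k in (1, 2)])
            g.add_edges_from((f"A{i}", f"B{j}") for i, j in p1)
            g.add_edges_from((f"B{j}", f"C{k}") for j, k in p2)
            brute = any(
                nx.has_path(g, f"A{i}", f"C{k}")
                for i in (1, 2) for k in (1, 2)
            )
            assert path_preserved(p1, p2) == brute, (p1, p2)

    def test_statistic_and_detail(self, small_dataset):
        _, _, truth = small_dataset
        anc = truth.ancestral
        col = truth.coloring
        spec = OneShotSpec.from_coloring(col)
        score, detail = path_preservation_test(anc, col, spec, n_real=50, seed=2)
        assert 0 <= score.observed <= 1
        frac = np.mean([ok for _, _, ok in detail])
        assert frac == pytest.approx(score.observed)


def _all_patterns():
    from wgdnet.dsubgraph import LINK_POSITIONS

    out = []
    for mask in range(16):
        out.append({LINK_POSITIONS[b] for b in range(4) if mask >> b & 1})
    return out
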