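"""Homology shuffling, one-shot colorings, and enrichment scoring."""

import itertools

import numpy as np
import pytest

from wgdnet.collapse import AncestralNetwork, build_duplicate_families, collapse_network
from wgdnet.dsubgraph import DSClass, NONTRIVIAL_CLASSES, color_ancestral_network
from wgdnet.net_io import AgeClass, ParalogTable, RegulatoryNetwork
from wgdnet.nullmodels import (
    EnrichmentScore,
    OneShotSpec,
    ds_abundance_zscores,
    sample_oneshot_coloring,
    score_against_oneshot,
    shuffle_homology_classes,
)


class TestEnrichmentScore:
    def test_z_is_standardized(self):
        s = EnrichmentScore.from_null(10.0, [4.0, 6.0, 8.0], tail="upper")
        assert s.z == pytest.approx((10 - 6) / 2)

    def test_degenerate_null_has_undefined_z(self):
        s = EnrichmentScore.from_null(5.0, [5.0, 5.0, 5.0], tail="upper")
        assert s.z is None
        assert s.p_emp == 1.0

    def test_p_emp_is_never_zero(self):
        s = EnrichmentScore.from_null(1e9, np.zeros(99), tail="upper")
        assert s.p_emp == pytest.approx(1 / 100)


class TestShuffle:
    @pytest.fixture
    def net_with_tf_pairs(self):
        # 4 TFs each regulating targets; 2 TF pairs + 2 target pairs
        edges = [(f"tf{i}", f"t{j}") for i in range(4) for j in range(3)]
        net = RegulatoryNetwork.from_edges(edges)
        pairs = ParalogTable.from_records([
            ("tf0", "tf1", AgeClass.WGD), ("tf2", "tf3", AgeClass.WGD),
            ("t0", "t1", AgeClass.WGD), ("t1", "t2", AgeClass.POST_1),
        ])
        return net, pairs

    def test_strata_are_conserved(self, net_with_tf_pairs, rng):
        net, pairs = net_with_tf_pairs
        shuffled = shuffle_homology_classes(net, pairs, rng=rng)
        assert len(shuffled) == len(pairs)
        # TF pairs stay TF pairs over the same 4 TFs
        tf_pairs = [r for r in shuffled
                    if r.gene_a in net.tf_set and r.gene_b in net.tf_set]
        assert len(tf_pairs) == 2
        assert {g for r in tf_pairs for g in (r.gene_a, r.gene_b)} == net.tf_set
        # per-class pair counts conserved
        for age in (AgeClass.WGD, AgeClass.POST_1):
            assert len(shuffled.select({age})) == len(pairs.select({age}))

    def test_gene_multiplicity_preserved(self, net_with_tf_pairs, rng):
        net, pairs = net_with_tf_pairs

        def multiplicity(table, age):
            out: dict[str, int] = {}
            for r in table.select({age}):
                for g in (r.gene_a, r.gene_b):
                    out[g] = out.get(g, 0) + 1
            return out

        for _ in range(20):
            shuffled = shuffle_homology_classes(net, pairs, rng=rng)
            assert max(multiplicity(shuffled, AgeClass.WGD).values()) == 1

    def test_matches_exhaustive_expectation(self, rng):
        """Mean DS counts over shuffles vs exact enumeration of matchings.

        Fixture: 4 TFs (a,b,c,d) with a,b sharing target t and c,d sharing
        target u; 2 WGD TF pairs.  The 3 perfect matchings of {a,b,c,d}
        are enumerable, so the expected γ count under random re-pairing
        has a closed form: matching {ab, cd} gives 2 fan-ins, the other
        two matchings give 0.  E[γ] = 2/3.
        """
        edges = [("a", "t"), ("b", "t"), ("c", "u"), ("d", "u")]
        net = RegulatoryNetwork.from_edges(edges)
        pairs = ParalogTable.from_records(
            [("a", "c", AgeClass.WGD), ("b", "d", AgeClass.WGD)]
        )
        # exact: enumerate all perfect matchings of the 4 TFs
        tfs = ["a", "b", "c", "d"]
        gammas = []
        for perm in itertools.permutations(tfs):
            m = {frozenset(perm[:2]), frozenset(perm[2:])}
            if len(m) != 2:
                continue
            fams = build_duplicate_families(
                [(min(p), max(p), AgeClass.WGD) for p in m],
                {AgeClass.WGD}, net.nodes,
            )
            col = color_ancestral_network(collapse_network(net, fams))
            gammas.append(col.class_counts()[DSClass.GAMMA])
        exact_mean = np.mean(gammas)
        assert exact_mean == pytest.approx(2 / 3)

        n = 1000
        sims = []
        for _ in range(n):
            shuffled = shuffle_homology_classes(net, pairs, rng=rng)
            fams = build_duplicate_families(shuffled, {AgeClass.WGD}, net.nodes)
            col = color_ancestral_network(collapse_network(net, fams))
            sims.append(col.class_counts()[DSClass.GAMMA])
        se = np.std(sims, ddof=1) / np.sqrt(n)
        assert abs(np.mean(sims) - exact_mean) < 3 * se + 1e-9

    def test_tiny_stratum_left_unshuffled(self, caplog, rng):
        net = RegulatoryNetwork.from_edges([("a", "x"), ("b", "y")])
        pairs = ParalogTable.from_records([("a", "b", AgeClass.WGD)])
        with caplog.at_level("WARNING", logger="wgdnet"):
            shuffled = shuffle_homology_classes(net, pairs, rng=rng)
        assert shuffled == pairs
        assert any("too small" in r.message for r in caplog.records)


class TestAbundanceZscores:
    def test_observed_at_null_mean_gives_small_z(self, small_dataset):
        net, pairs, _ = small_dataset
        scores = ds_abundance_zscores(net, pairs, n_real=30, seed=3)
        assert scores  # at least the WGD group present
        z = scores[("WGD", DSClass.ZETA)]
        assert z.n_real == 30
        assert z.p_emp > 0

    def test_planted_epsilon_excess_detected(self):
        """A bi-fan-rich planted world stands out against shuffling."""
        from wgdnet.synthgen import SyntheticSpec, generate_dataset

        probs = {DSClass.ZETA: 0.80, DSClass.EPSILON: 0.20}
        spec = SyntheticSpec(
            n_tf=15, n_target=40, out_degree_exponent=0.0, out_degree_max=5,
            core_backedges=3, class_probabilities=probs, age_mix={}, seed=21,
        )
        net, pairs, _ = generate_dataset(spec)
        scores = ds_abundance_zscores(net, pairs, n_real=200, seed=4,
                                      groups=("WGD",))
        assert scores[("WGD", DSClass.EPSILON)].z > 3


class TestOneShot:
    def test_degenerate_probabilities(self, seven_edge_anc, rng):
        spec = OneShotSpec(class_probabilities={DSClass.ZETA: 1.0})
        col = sample_oneshot_coloring(seven_edge_anc, spec, rng=rng)
        assert all(ce.ds is DSClass.ZETA for ce in col.assignment.values())

    def test_permutation_mode_conserves_counts(self, seven_edge_anc, rng):
        counts = {DSClass.ZETA: 4, DSClass.BETA: 2, DSClass.GAMMA: 1}
        spec = OneShotSpec(mode="permutation", class_counts=counts)
        for _ in range(10):
            col = sample_oneshot_coloring(seven_edge_anc, spec, rng=rng)
            cc = col.class_counts()
            assert {c: n for c, n in cc.items() if n} == counts

    def test_multinomial_counts_within_binomial_bound(self, rng):
        from wgdnet.synthgen import SyntheticSpec, generate_ancestral_network

        anc = generate_ancestral_network(
            SyntheticSpec(n_tf=40, n_target=300, out_degree_exponent=0.0,
                          out_degree_max=500, seed=9)
        )
        n = len(anc.net.edges)
        assert n > 5000
        p = 0.042
        spec = OneShotSpec(class_probabilities={DSClass.ZETA: 1 - p,
                                                DSClass.GAMMA: p})
        col = sample_oneshot_coloring(anc, spec, rng=rng)
        got = col.class_counts()[DSClass.GAMMA]
        sigma = np.sqrt(n * p * (1 - p))
        assert abs(got - n * p) < 4 * sigma

    def test_probabilities_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            OneShotSpec(class_probabilities={DSClass.ZETA: 0.5})

    def test_patterns_match_classes(self, seven_edge_anc, rng):
        spec = OneShotSpec(class_probabilities={
            DSClass.ZETA: 0.4, DSClass.BETA: 0.3, DSClass.EPSILON: 0.3})
        col = sample_oneshot_coloring(seven_edge_anc, spec, rng=rng)
        from wgdnet.dsubgraph import classify_link_pattern
        for ce in col.assignment.values():
            assert classify_link_pattern(ce.pattern) is ce.ds


class TestScoreAgainstOneshot:
    def test_self_calibration(self, seven_edge_anc, rng):
        spec = OneShotSpec(class_probabilities={
            DSClass.ZETA: 0.5, DSClass.BETA: 0.25, DSClass.GAMMA: 0.25})

        def beta_count(coloring):
            return coloring.class_counts()[DSClass.BETA]

        inside = 0
        for k in range(20):
            observed = sample_oneshot_coloring(seven_edge_anc, spec, rng=rng)
            s = score_against_oneshot(beta_count, observed, seven_edge_anc,
                                      spec, n_real=100, seed=k)
            if s.z is None or abs(s.z) < 3:
                inside += 1
        assert inside >= 19

    def test_constant_statistic_degenerate(self, seven_edge_anc):
        spec = OneShotSpec(class_probabilities={DSClass.ZETA: 1.0})
        observed = sample_oneshot_coloring(seven_edge_anc, spec,
                                           rng=np.random.default_rng(0))
        s = score_against_oneshot(lambda c: 7.0, observed, seven_edge_anc,
                                  spec, n_real=50, seed=1)
        assert s.z is None and s.p_emp == 1.0
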