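"""Edge spin model: Hamiltonian, Metropolis sampler, exact oracle."""

import itertools

import numpy as np
import pytest
from scipy import special

from wgdnet.collapse import AncestralNetwork
from wgdnet.dsubgraph import DSClass
from wgdnet.net_io import RegulatoryNetwork
from wgdnet.spinmodel import (
    SPIN_STATES,
    SpinParams,
    compare_to_empirical,
    energy,
    exact_boltzmann,
    metropolis_sample,
)


def _anc(edges):
    return AncestralNetwork.trivial(RegulatoryNetwork.from_edges(edges))


Z, B, G = SPIN_STATES


class TestEnergy:
    def test_isolated_edge_field_term(self):
        anc = _anc([("a", "b")])
        params = SpinParams(j_cons=0, j_adj=0, h_beta=1.0, h_gamma=0.0)
        assert energy({("a", "b"): B}, anc, params) == pytest.approx(-1.0)
        assert energy({("a", "b"): Z}, anc, params) == pytest.approx(0.0)

    def test_consecutive_reward_is_ordered(self):
        anc = _anc([("a", "b"), ("b", "c")])
        params = SpinParams(j_cons=2.0, j_adj=0, h_beta=0, h_gamma=0)
        fwd = {("a", "b"): B, ("b", "c"): G}
        rev = {("a", "b"): G, ("b", "c"): B}
        assert energy(fwd, anc, params) == pytest.approx(-2.0)
        assert energy(rev, anc, params) == pytest.approx(0.0)

    def test_adjacent_delta_reward(self):
        anc = _anc([("a", "b"), ("a", "c")])
        params = SpinParams(j_cons=0, j_adj=1.5, h_beta=0, h_gamma=0)
        same = {("a", "b"): G, ("a", "c"): G}
        diff = {("a", "b"): G, ("a", "c"): B}
        assert energy(same, anc, params) == pytest.approx(-1.5)
        assert energy(diff, anc, params) == pytest.approx(0.0)

    def test_disjoint_root_leaf_paths_uncoupled_without_adjacency(self):
        """With J_adj=0 edges on disjoint paths share no interaction terms.

        The energy of a two-path graph then decomposes into a sum over
        paths: changing one path's states never changes the other's
        contribution.
        """
        anc = _anc([("r1", "m1"), ("m1", "l1"), ("r2", "m2"), ("m2", "l2")])
        params = SpinParams(j_cons=1.3, j_adj=0.0, h_beta=0.2, h_gamma=-0.1)

        def e(s1, s2, s3, s4):
            return energy({("r1", "m1"): s1, ("m1", "l1"): s2,
                           ("r2", "m2"): s3, ("m2", "l2"): s4}, anc, params)

        for s1, s2 in itertools.product(SPIN_STATES, repeat=2):
            delta_path1 = e(s1, s2, Z, Z) - e(B, G, Z, Z)
            assert e(s1, s2, B, G) - e(B, G, B, G) == pytest.approx(delta_path1)


class TestExactBoltzmann:
    def test_single_edge_uniform_at_zero_params(self):
        anc = _anc([("a", "b")])
        dist = exact_boltzmann(anc, SpinParams(j_cons=0, j_adj=0))
        assert dist.probs == pytest.approx([1 / 3] * 3)

    def test_probabilities_normalized(self, seven_edge_anc):
        dist = exact_boltzmann(seven_edge_anc, SpinParams(j_cons=1, j_adj=0.5,
                                                          h_beta=0.3))
        assert dist.probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_consecutive_asymmetry(self):
        anc = _anc([("a", "b"), ("b", "c")])
        dist = exact_boltzmann(anc, SpinParams(j_cons=1.0, j_adj=0))
        p_bg = dist.prob_of({("a", "b"): B, ("b", "c"): G})
        p_gb = dist.prob_of({("a", "b"): G, ("b", "c"): B})
        assert p_bg == pytest.approx(p_gb * np.e)

    def test_too_large_graph_rejected(self):
        anc = _anc([(f"a{i}", f"b{i}") for i in range(11)])
        with pytest.raises(ValueError, match="too large"):
            exact_boltzmann(anc, SpinParams())


class TestMetropolis:
    def test_uniform_stationary_law_without_interactions(self, seven_edge_anc):
        params = SpinParams(j_cons=0, j_adj=0, sweeps=20_000, burn_in=100,
                            seed=5)
        run = metropolis_sample(seven_edge_anc, params, store_configs=False)
        marg = run.marginals()
        assert np.all(np.abs(marg - 1 / 3) < 0.03)

    def test_fields_give_softmax_frequencies(self):
        """Independent edges: stationary law is softmax(0, h_beta, h_gamma)."""
        anc = _anc([(f"a{i}", f"b{i}") for i in range(5)])
        params = SpinParams(j_cons=0, j_adj=0, h_beta=0.8, h_gamma=-0.4,
                            sweeps=40_000, burn_in=200, seed=6)
        run = metropolis_sample(anc, params, store_configs=False)
        expected = special.softmax([0.0, 0.8, -0.4])
        n = run.state_counts.sum(axis=1)[0]
        sigma = np.sqrt(expected * (1 - expected) / n)
        # correlated samples: allow a generous effective-sample-size factor
        assert np.all(np.abs(run.marginals() - expected) < 10 * sigma + 0.01)

    def test_energy_bookkeeping(self, seven_edge_anc):
        params = SpinParams(j_cons=1.2, j_adj=0.7, h_beta=-0.5, h_gamma=0.3,
                            sweeps=500, burn_in=0, seed=8)
        run = metropolis_sample(seven_edge_anc, params, store_configs=False)
        final = energy(run.final_state, seven_edge_anc, params)
        assert abs(run.running_energy - final) < 1e-8

    def test_seeded_determinism(self, seven_edge_anc):
        params = SpinParams(j_cons=1, j_adj=1, sweeps=200, burn_in=10, seed=3)
        r1 = metropolis_sample(seven_edge_anc, params)
        r2 = metropolis_sample(seven_edge_anc, params)
        assert np.array_equal(r1.final_state, r2.final_state)
        assert np.array_equal(r1.magnetizations, r2.magnetizations)

    def test_magnetizations_sum_to_edge_count(self, seven_edge_anc):
        params = SpinParams(sweeps=100, burn_in=10, seed=1)
        run = metropolis_sample(seven_edge_anc, params)
        assert np.all(run.magnetizations.sum(axis=1) == 7)


class TestDetailedBalance:
    def test_single_flip_balance_under_exact_boltzmann(self):
        """π(x)·P(x→y) == π(y)·P(y→x) for single-edge proposal moves."""
        anc = _anc([("a", "b"), ("b", "c"), ("a", "c")])
        params = SpinParams(j_cons=0.8, j_adj=1.1, h_beta=0.4, h_gamma=-0.6)
        dist = exact_boltzmann(anc, params)
        rng = np.random.default_rng(0)
        states = dist.states
        n_edges = states.shape[1]
        for _ in range(200):
            x = states[rng.integers(len(states))].copy()
            e = rng.integers(n_edges)
            y = x.copy()
            y[e] = (x[e] + 1 + rng.integers(2)) % 3
            hx = energy(x, anc, params)
            hy = energy(y, anc, params)
            # proposal probability is symmetric: 1/(2 n_edges)
            flow_xy = np.exp(-hx) * min(1.0, np.exp(-(hy - hx)))
            flow_yx = np.exp(-hy) * min(1.0, np.exp(-(hx - hy)))
            assert flow_xy == pytest.approx(flow_yx, rel=1e-10)


class TestCompareToEmpirical:
    def test_identical_inputs_zero_distance(self, seven_edge_anc):
        params = SpinParams(j_cons=1, j_adj=1, sweeps=50, burn_in=10, seed=2)
        run = metropolis_sample(seven_edge_anc, params)
        # freeze the chain on its own final configuration
        run.configs = np.tile(run.final_state, (run.n_samples, 1))
        run.state_counts = np.zeros_like(run.state_counts)
        for e, s in enumerate(run.final_state):
            run.state_counts[e, s] = run.n_samples
        run.magnetizations = np.tile(
            np.bincount(run.final_state, minlength=3), (run.n_samples, 1))
        cmp = compare_to_empirical(run, run.final_coloring(), seven_edge_anc)
        assert cmp.coupled_mag_l1 == pytest.approx(0.0)
        assert all(v == pytest.approx(0.0) for v in cmp.coupled_pair_l1.values())

    def test_coupled_model_beats_uncoupled_on_its_own_data(self):
        """Planted couplings: the coupled chain tracks its own draws better.

        Fields are matched to the empirical magnetizations in both models
        (they are global constraints, not fitted structure), so the
        comparison isolates what the couplings buy: the neighbor
        co-occurrence structure.
        """
        from wgdnet.spinmodel import fit_fields_to_magnetizations
        from wgdnet.synthgen import SyntheticSpec, generate_ancestral_network

        anc = generate_ancestral_network(SyntheticSpec(
            n_tf=20, n_target=20, out_degree_exponent=0.0, out_degree_max=4,
            core_backedges=4, seed=77))
        wins = 0
        reps = 20
        for k in range(reps):
            gen = metropolis_sample(
                anc, SpinParams(j_cons=1, j_adj=1, sweeps=400, burn_in=200,
                                seed=100 + k), store_configs=False)
            empirical = gen.final_coloring()
            emp_counts = np.bincount(gen.final_state, minlength=3)
            fitted = fit_fields_to_magnetizations(
                anc, SpinParams(j_cons=1, j_adj=1, seed=200 + k), emp_counts)
            model = metropolis_sample(
                anc, SpinParams(j_cons=1, j_adj=1, h_beta=fitted.h_beta,
                                h_gamma=fitted.h_gamma, sweeps=2000,
                                burn_in=300, seed=300 + k))
            cmp = compare_to_empirical(model, empirical, anc)
            wins += cmp.coupled_total <= cmp.uncoupled_total
        assert wins / reps >= 0.9

    def test_magnetization_distance_invariant_under_edge_permutation(
            self, seven_edge_anc):
        params = SpinParams(j_cons=0.5, j_adj=0.5, sweeps=300, burn_in=50, seed=4)
        run = metropolis_sample(seven_edge_anc, params)
        empirical = run.final_coloring()
        base = compare_to_empirical(run, empirical, seven_edge_anc)
        # permute which edge carries which empirical color
        rng = np.random.default_rng(9)
        perm = rng.permutation(len(run.edges))
        permuted = {e: empirical.assignment[run.edges[perm[i]]]._replace(
            self_loop=e[0] == e[1])
            for i, e in enumerate(run.edges)}
        from wgdnet.dsubgraph import EdgeColoring
        cmp2 = compare_to_empirical(run, EdgeColoring(permuted), seven_edge_anc)
        assert cmp2.coupled_mag_l1 == pytest.approx(base.coupled_mag_l1)
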