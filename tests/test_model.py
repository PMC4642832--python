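"""Growth kernel: simulation, backward merge, transition probability, proposal."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from dmcinfer import (DMCParams, DuplicationForest, PPIGraph, backward_merge,
                      forward_step, proposal_log_prob, sample_duplicate,
                      simulate_dmc, transition_log_prob, transition_record)


def enumerate_step_outcomes(prev, anchor, duplicate):
    """All graphs one growth step can produce from ``prev`` with a fixed
    anchor and duplicate id: 3 mutation outcomes per neighbor x 2
    homodimer outcomes.  Independent of the package's kernel code."""
    neighbors = sorted(prev.neighbors(anchor))
    base_edges = set(prev.edges)
    for choices in itertools.product(("both", "keep_u", "keep_v"),
                                     repeat=len(neighbors)):
        for homodimer in (False, True):
            edges = set(base_edges)
            for w, choice in zip(neighbors, choices):
                if choice == "both":
                    edges.add(tuple(sorted((duplicate, w))))
                elif choice == "keep_v":
                    edges.discard(tuple(sorted((anchor, w))))
                    edges.add(tuple(sorted((duplicate, w))))
                # keep_u: no duplicate edge, anchor edge stays
            if homodimer:
                edges.add(tuple(sorted((anchor, duplicate))))
            yield PPIGraph(edges=edges, nodes=prev.nodes | {duplicate})


class TestSimulate:
    def test_target_two_is_the_seed(self, params07):
        h = simulate_dmc(params07, 2, seed=0)
        assert h.n_steps == 0
        assert h.final_graph == PPIGraph.seed()
        assert h.final_forest == DuplicationForest.trivial()

    def test_rejects_target_below_two(self, params07):
        with pytest.raises(ValueError):
            simulate_dmc(params07, 1, seed=0)

    @pytest.mark.parametrize("size", [3, 4, 5, 6])
    def test_no_deletion_limit_gives_complete_graph(self, size):
        # as p, p_c -> 1 every duplicated edge and homodimer edge is kept,
        # and duplicating any node of a complete graph preserves completeness
        params = DMCParams(p=1 - 1e-12, p_c=1 - 1e-12)
        for seed in range(5):
            g = simulate_dmc(params, size, seed=seed).final_graph
            assert g.num_edges == size * (size - 1) // 2

    def test_duplicate_id_convention(self, params07):
        h = simulate_dmc(params07, 8, seed=3)
        assert h.duplicates == [t + 2 for t in range(1, 7)]
        assert all(u in h.graphs[t].nodes for t, u in enumerate(h.anchors))

    def test_deterministic_given_seed(self, params07):
        a = simulate_dmc(params07, 10, seed=42)
        b = simulate_dmc(params07, 10, seed=42)
        assert a.final_graph == b.final_graph
        assert a.theta == b.theta

    def test_one_step_expected_edge_count(self, params07):
        # each duplicated pair keeps 2 edges w.p. p, else 1, so a step
        # adds p * deg(anchor) edges in expectation plus p_c for the
        # homodimer; averaging deg(anchor) over the uniform anchor gives
        # E[|E_t| | G_{t-1}] = |E| + p * 2|E|/|V| + p_c
        base = simulate_dmc(params07, 6, seed=9)
        graph, forest = base.final_graph, base.final_forest
        e, v = graph.num_edges, graph.num_nodes
        expected = e + params07.p * (2 * e / v) + params07.p_c
        rng = np.random.default_rng(123)
        counts = np.array([
            forward_step(graph, forest, params07, seed=rng)[0].num_edges
            for _ in range(10_000)
        ], dtype=float)
        se = counts.std(ddof=1) / math.sqrt(len(counts))
        assert abs(counts.mean() - expected) < 3 * se


class TestBackwardMerge:
    def test_path_merge_by_hand(self, path_pair):
        graph, forest = path_pair
        merged, mforest, anchor = backward_merge(graph, forest, 3)
        assert merged == PPIGraph.seed()
        assert mforest == DuplicationForest.trivial()
        assert anchor == 1

    def test_round_trip_on_simulated_history(self, params07):
        h = simulate_dmc(params07, 12, seed=5)
        g, f = h.final_graph, h.final_forest
        for t in range(h.n_steps, 0, -1):
            g, f, anchor = backward_merge(g, f, h.duplicates[t - 1])
            assert g == h.graphs[t - 1]
            assert f == h.forests[t - 1]
            assert anchor == h.anchors[t - 1]

    def test_non_cherry_leaf_is_rejected(self):
        # leaf 4's sibling is the internal node (1, 3)
        forest = DuplicationForest([((1, 3), 4), 2])
        graph = PPIGraph(edges=[(1, 2), (3, 4)])
        with pytest.raises(ValueError, match="not a valid duplicate"):
            backward_merge(graph, forest, 4)
        with pytest.raises(ValueError, match="not a valid duplicate"):
            backward_merge(graph, forest, 99)


class TestTransitionLogProb:
    def test_hand_computed_values(self, path_pair, triangle_pair, params07):
        seed = PPIGraph.seed()
        # path: one kept pair (w=2), no homodimer -> (1/2) * p * (1 - p_c)
        lp = transition_log_prob(seed, path_pair[0], 1, 3, params07)
        assert lp == pytest.approx(math.log(0.5 * 0.7 * 0.3))
        # triangle: kept pair plus homodimer -> (1/2) * p * p_c
        lp = transition_log_prob(seed, triangle_pair[0], 1, 3, params07)
        assert lp == pytest.approx(math.log(0.5 * 0.7 * 0.7))

    def test_single_kept_edge_factor(self, params07):
        seed = PPIGraph.seed()
        # only (3, 2) survives the pair: factor (1-p)/2, no homodimer
        curr = PPIGraph(edges=[(2, 3)], nodes=[1])
        lp = transition_log_prob(seed, curr, 1, 3, params07)
        assert lp == pytest.approx(math.log(0.5 * 0.15 * 0.3))

    def test_ungeneratable_topology_is_minus_inf(self, params07):
        seed = PPIGraph.seed()
        # node 2 adjacent to neither anchor nor duplicate: the mutation
        # step deletes at most one of the two parallel edges
        curr = PPIGraph(edges=[(1, 3)], nodes=[2])
        assert transition_log_prob(seed, curr, 1, 3, params07) == -math.inf

    def test_precondition_violations_raise(self, path_pair, params07):
        with pytest.raises(ValueError):
            transition_log_prob(PPIGraph.seed(), path_pair[0], 9, 3, params07)
        with pytest.raises(ValueError):
            transition_log_prob(PPIGraph.seed(), path_pair[0], 1, 2, params07)

    @pytest.mark.parametrize("prev_edges, anchor", [
        ([(1, 2)], 1),                               # degree 1
        ([(1, 2), (2, 3)], 2),                       # degree 2
        ([(1, 2), (2, 3), (1, 3)], 1),               # triangle, degree 2
        ([(1, 2), (1, 3), (1, 4), (1, 5)], 1),       # star, degree 4
    ])
    def test_kernel_sums_to_one_over_outcomes(self, prev_edges, anchor,
                                              params07):
        prev = PPIGraph(edges=prev_edges)
        dup = max(prev.nodes) + 1
        total = sum(
            math.exp(transition_log_prob(prev, curr, anchor, dup, params07))
            for curr in enumerate_step_outcomes(prev, anchor, dup))
        # the anchor-choice factor 1/|V| is inside the kernel, so summing
        # over outcomes at a fixed anchor gives 1/|V|; over anchors, 1
        assert total == pytest.approx(1.0 / prev.num_nodes, rel=1e-10)

    def test_kernel_normalizes_over_anchors(self, params07):
        prev = PPIGraph(edges=[(1, 2), (2, 3)])
        dup = 4
        total = sum(
            math.exp(transition_log_prob(prev, curr, anchor, dup, params07))
            for anchor in prev.nodes
            for curr in enumerate_step_outcomes(prev, anchor, dup))
        assert total == pytest.approx(1.0, rel=1e-10)

    def test_simulator_matches_kernel_frequencies(self, params07):
        # one-step histories: empirical frequency of each (G_1, anchor)
        # outcome should match exp(transition_log_prob)
        n_sims = 30_000
        rng = np.random.default_rng(2024)
        counts: dict = {}
        for _ in range(n_sims):
            h = simulate_dmc(params07, 3, seed=rng)
            key = (h.final_graph.edges, h.anchors[0])
            counts[key] = counts.get(key, 0) + 1
        seed_graph = PPIGraph.seed()
        for anchor in (1, 2):
            for curr in enumerate_step_outcomes(seed_graph, anchor, 3):
                prob = math.exp(
                    transition_log_prob(seed_graph, curr, anchor, 3,
                                        params07))
                freq = counts.get((curr.edges, anchor), 0) / n_sims
                se = math.sqrt(prob * (1 - prob) / n_sims)
                assert abs(freq - prob) < 3 * se + 1e-12

    def test_record_partitions_previous_neighborhood(self, params07):
        h = simulate_dmc(params07, 10, seed=8)
        for t in range(1, h.n_steps + 1):
            rec = transition_record(h.graphs[t - 1], h.graphs[t],
                                    h.anchors[t - 1], h.duplicates[t - 1])
            prev_nb = h.graphs[t - 1].neighbors(rec.anchor)
            assert rec.kept_both | rec.kept_one == prev_nb
            assert not rec.kept_both & rec.kept_one


class TestBackwardProposal:
    def test_proposal_log_prob_examples(self, path_pair):
        assert proposal_log_prob(path_pair[1]) == pytest.approx(math.log(0.5))
        two_cherries = DuplicationForest([(1, 3), (2, 4)])
        assert proposal_log_prob(two_cherries) == pytest.approx(
            math.log(0.25))

    def test_trivial_forest_has_no_proposal(self):
        with pytest.raises(ValueError, match="trivial forest"):
            proposal_log_prob(DuplicationForest.trivial())
        with pytest.raises(ValueError, match="trivial forest"):
            sample_duplicate(DuplicationForest.trivial(), seed=0)

    def test_sample_uniform_over_cherry_leaves(self, path_pair):
        rng = np.random.default_rng(77)
        draws = [sample_duplicate(path_pair[1], seed=rng)
                 for _ in range(10_000)]
        observed = [draws.count(1), draws.count(3)]
        assert stats.chisquare(observed).pvalue > 1e-4

    def test_support_covers_all_cherry_leaves(self):
        forest = DuplicationForest([(1, 3), (2, 4)])
        rng = np.random.default_rng(5)
        support = {sample_duplicate(forest, seed=rng) for _ in range(500)}
        assert support == {1, 2, 3, 4}
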