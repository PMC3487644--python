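"""Exact and heuristic MPT search, collapsing and deduplication."""

import numpy as np
import pytest

from cladist.fitch import min_steps, tree_length
from cladist.search import (SearchConfig, branch_and_bound,
                            collapse_unsupported, dedupe, heuristic_search)
from cladist.simulate import SimConfig, simulate
from cladist.trees import PhyloTree, random_topology

from _oracles import exhaustive_best_trees, make_matrix
from conftest import random_state_matrix


class TestBranchAndBound:
    def test_three_taxa_single_topology(self):
        m = make_matrix(["0 0", "0 1", "1 1"])
        res = branch_and_bound(m)
        assert len(res.binary_mpt_set) == 1
        t = res.binary_mpt_set[0]
        assert res.best_length == tree_length(t, m).total_length

    @pytest.mark.parametrize("seed", range(4))
    def test_agrees_with_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        m = random_state_matrix(rng, 6, 6)
        best, trees = exhaustive_best_trees(m)
        res = branch_and_bound(m)
        assert res.best_length == best
        assert set(res.binary_mpt_set) == set(trees)

    def test_seven_taxa_against_oracle(self):
        rng = np.random.default_rng(99)
        m = random_state_matrix(rng, 7, 7, p_wild=0.05, p_poly=0.0)
        best, trees = exhaustive_best_trees(m)
        res = branch_and_bound(m)
        assert res.best_length == best
        assert set(res.binary_mpt_set) == set(trees)

    def test_homoplasy_free_simulation_recovers_truth(self):
        sim = simulate(SimConfig(n_taxa=8, n_characters=30, seed=5,
                                 origin_weights=((1, 1.0),), p_missing=0,
                                 p_inapplicable=0, p_polymorphic=0))
        res = branch_and_bound(sim.matrix)
        assert sim.true_tree in set(res.binary_mpt_set)

    def test_ceiling_guard(self, reference_matrix):
        with pytest.raises(ValueError, match="heuristic_search"):
            branch_and_bound(reference_matrix)

    def test_never_below_sum_of_minima(self):
        rng = np.random.default_rng(17)
        m = random_state_matrix(rng, 7, 6)
        res = branch_and_bound(m)
        assert res.best_length >= sum(min_steps(m, j)
                                      for j in range(m.n_characters))

    def test_conflicting_quartet_gives_two_mpts_and_star(self):
        # one character supports AB|CD, one supports AC|BD
        m = make_matrix(["0 0", "0 1", "1 0", "1 1"])
        res = branch_and_bound(m)
        assert res.best_length == 3
        assert len(res.binary_mpt_set) == 2
        from cladist.consensus import strict_consensus
        assert len(strict_consensus(res.mpt_set).bipartitions()) == 0


class TestHeuristic:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exact_search_on_small_matrices(self, seed):
        rng = np.random.default_rng(400 + seed)
        m = random_state_matrix(rng, 9, 8)
        exact = branch_and_bound(m)
        heur = heuristic_search(m, SearchConfig(n_replicates=20, seed=seed))
        assert heur.best_length == exact.best_length
        assert set(heur.binary_mpt_set) == set(exact.binary_mpt_set)

    @pytest.mark.parametrize("swap", ["NNI", "SPR", "TBR"])
    def test_swap_modes_reach_optimum_on_easy_matrix(self, swap):
        sim = simulate(SimConfig(n_taxa=10, n_characters=40, seed=2,
                                 origin_weights=((1, 1.0),), p_missing=0,
                                 p_inapplicable=0, p_polymorphic=0))
        res = heuristic_search(sim.matrix,
                               SearchConfig(n_replicates=10, swap=swap, seed=1))
        assert res.best_length == tree_length(sim.true_tree, sim.matrix).total_length

    def test_seed_replay_is_identical(self):
        rng = np.random.default_rng(77)
        m = random_state_matrix(rng, 8, 6)
        cfg = SearchConfig(n_replicates=8, seed=123)
        a = heuristic_search(m, cfg)
        b = heuristic_search(m, cfg)
        assert [t.to_newick() for t in a.mpt_set] == \
            [t.to_newick() for t in b.mpt_set]
        assert a.log == b.log

    def test_requires_four_taxa(self):
        m = make_matrix(["0", "1", "0"])
        with pytest.raises(ValueError):
            heuristic_search(m)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SearchConfig(n_replicates=0)
        with pytest.raises(ValueError):
            SearchConfig(swap="ratchet")


class TestCollapse:
    def test_all_invariant_collapses_to_star(self):
        m = make_matrix(["0 0", "0 0", "0 0", "0 0"])
        t = PhyloTree.from_newick("((A,B),(C,D));")
        assert len(collapse_unsupported(t, m).bipartitions()) == 0

    def test_congruent_split_is_retained(self):
        m = make_matrix(["0", "0", "1", "1"])
        t = PhyloTree.from_newick("((A,B),(C,D));")
        collapsed = collapse_unsupported(t, m)
        assert collapsed.bipartitions() == t.bipartitions()

    def test_collapse_only_removes_bipartitions(self, rng):
        for _ in range(5):
            m = random_state_matrix(rng, 7, 4)
            t = random_topology(m.taxa, rng)
            collapsed = collapse_unsupported(t, m)
            assert collapsed.bipartitions() <= t.bipartitions()


class TestDedupe:
    def test_rotations_collapse_to_one(self):
        a = PhyloTree.from_newick("((A,B),(C,D));")
        b = PhyloTree.from_newick("((D,C),(B,A));")
        assert len(dedupe([a, b])) == 1

    def test_distinct_resolutions_kept(self):
        a = PhyloTree.from_newick("((A,B),(C,D));")
        b = PhyloTree.from_newick("((A,C),(B,D));")
        assert len(dedupe([a, b])) == 2

    def test_many_copies_one_representative(self):
        a = PhyloTree.from_newick("((A,B),(C,D));")
        assert len(dedupe([a] * 7)) == 1

    def test_mismatched_leaf_sets_rejected(self):
        a = PhyloTree.from_newick("((A,B),(C,D));")
        b = PhyloTree.from_newick("((A,B),(C,E));")
        with pytest.raises(ValueError, match="leaf sets"):
            dedupe([a, b])
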