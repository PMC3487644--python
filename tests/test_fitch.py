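"""Fitch lengths against brute-force and dendropy oracles; step bounds."""

import numpy as np
import pytest

from cladist.fitch import character_length, max_steps, min_steps, tree_length
from cladist.matrix import write_matrix
from cladist.trees import PhyloTree, enumerate_topologies, random_topology

from _oracles import (brute_character_length, brute_star_length, make_matrix)
from conftest import random_state_matrix


class TestExamples:
    def test_invariant_character_costs_nothing(self):
        m = make_matrix(["0", "0", "0", "0"])
        t = PhyloTree.from_newick("((A,B),(C,D));")
        assert character_length(t, m, 0) == 0

    def test_single_change_on_internal_branch(self):
        m = make_matrix(["0", "0", "1", "1"])
        t = PhyloTree.from_newick("((A,B),(C,D));")
        assert character_length(t, m, 0) == 1

    def test_all_missing_character_costs_nothing(self):
        m = make_matrix(["? 0", "? 1", "? 0", "? 1"])
        t = PhyloTree.from_newick("((A,B),(C,D));")
        assert character_length(t, m, 0) == 0

    def test_polymorphic_terminal_enters_as_state_set(self):
        # B={0,1} can agree with either side, saving a step
        free = make_matrix(["0", "01", "1", "1"])
        fixed = make_matrix(["0", "0", "1", "1"])
        t = PhyloTree.from_newick("((A,B),(C,D));")
        assert character_length(t, free, 0) == 1
        assert character_length(t, fixed, 0) == 1
        t2 = PhyloTree.from_newick("((A,C),(B,D));")
        assert character_length(t2, free, 0) == 1

    def test_missing_leaf_named_in_error(self):
        m = make_matrix(["0", "1", "0"])
        t = PhyloTree.from_newick("((A,B),(C,Z));")
        with pytest.raises(KeyError, match="Z"):
            character_length(t, m, 0)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(8))
    def test_matches_internal_labeling_oracle(self, seed):
        """Downpass length == exhaustive minimum over internal labelings,
        on random trees up to 7 leaves with ambiguous cells."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 8))
        m = random_state_matrix(rng, n, 4)
        t = random_topology(m.taxa, rng)
        for j in range(m.n_characters):
            assert character_length(t, m, j) == brute_character_length(t, m, j)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_dendropy_fitch(self, seed):
        import dendropy
        from dendropy.model import parsimony

        rng = np.random.default_rng(100 + seed)
        m = random_state_matrix(rng, 8, 6, p_poly=0.0)
        t = random_topology(m.taxa, rng)
        ns = dendropy.TaxonNamespace()
        dt = dendropy.Tree.get(data=t.to_newick(), schema="newick",
                               taxon_namespace=ns)
        chars = dendropy.StandardCharacterMatrix.get(
            data=write_matrix(m, "NEXUS"), schema="nexus", taxon_namespace=ns)
        tsm = chars.taxon_state_sets_map(gaps_as_missing=True)
        score = parsimony.fitch_down_pass(dt.postorder_node_iter(),
                                          taxon_state_sets_map=tsm)
        assert tree_length(t, m).total_length == score

    def test_polytomy_scoring_matches_oracle(self):
        rng = np.random.default_rng(3)
        m = random_state_matrix(rng, 6, 5)
        star = PhyloTree.from_newick("(A,B,C,D,E,F);")
        for j in range(m.n_characters):
            assert character_length(star, m, j) == brute_star_length(m, j)


class TestInvariances:
    def test_length_invariant_under_newick_rerooting(self):
        m = make_matrix(["0 1", "0 2", "1 1", "1 0", "2 0"])
        a = PhyloTree.from_newick("((A,B),(C,(D,E)));")
        b = PhyloTree.from_newick("(((E,D),C),(B,A));")
        assert a == b
        assert tree_length(a, m).per_character_steps == \
            tree_length(b, m).per_character_steps

    def test_length_invariant_under_row_permutation(self, rng):
        m = random_state_matrix(rng, 6, 5)
        t = random_topology(m.taxa, rng)
        perm = list(rng.permutation(m.n_taxa))
        from cladist.matrix import CharacterMatrix
        m2 = CharacterMatrix([m.taxa[i] for i in perm], m.characters,
                             [m.row(i) for i in perm])
        assert tree_length(t, m).total_length == tree_length(t, m2).total_length

    def test_additivity_over_characters(self, rng):
        m = random_state_matrix(rng, 6, 6)
        t = random_topology(m.taxa, rng)
        assert tree_length(t, m).total_length == sum(
            character_length(t, m, j) for j in range(m.n_characters))

    @pytest.mark.parametrize("seed", range(4))
    def test_bounds_bracket_realized_steps(self, seed):
        rng = np.random.default_rng(200 + seed)
        m = random_state_matrix(rng, 7, 5)
        for _ in range(3):
            t = random_topology(m.taxa, rng)
            score = tree_length(t, m)
            for s, lo, hi in zip(score.per_character_steps,
                                 score.per_character_min,
                                 score.per_character_max):
                assert lo <= s <= hi

    @pytest.mark.parametrize("seed", range(3))
    def test_wildcard_replacement_never_increases_steps(self, seed):
        from cladist.matrix import Cell, CellKind, CharacterMatrix

        rng = np.random.default_rng(300 + seed)
        m = random_state_matrix(rng, 6, 4, p_wild=0.0, p_poly=0.0)
        t = random_topology(m.taxa, rng)
        i = int(rng.integers(m.n_taxa))
        j = int(rng.integers(m.n_characters))
        rows = [list(m.row(r)) for r in range(m.n_taxa)]
        rows[i][j] = Cell(m.characters[j].observed_states, CellKind.MISSING)
        m2 = CharacterMatrix(m.taxa, m.characters, rows)
        assert character_length(t, m2, j) <= character_length(t, m, j)
        assert min_steps(m2, j) <= min_steps(m, j)
        assert max_steps(m2, j) <= max_steps(m, j)


class TestStepBounds:
    def test_min_steps_counts_required_states(self, reference_matrix):
        assert min_steps(reference_matrix, 12) == 2  # states 0,1,2 all fixed

    def test_min_steps_invariant_and_covered_cases(self):
        assert min_steps(make_matrix(["0", "0", "0"]), 0) == 0
        assert min_steps(make_matrix(["0", "01"]), 0) == 0  # state 0 covers both

    def test_min_steps_is_minimum_over_all_topologies(self):
        rng = np.random.default_rng(11)
        m = random_state_matrix(rng, 6, 3)
        for j in range(m.n_characters):
            best = min(character_length(t, m, j)
                       for t in enumerate_topologies(m.taxa))
            assert min_steps(m, j) == best

    def test_max_steps_examples(self):
        rows = ["1"] * 5 + ["0"] * 15
        assert max_steps(make_matrix(rows), 0) == 5  # minority count
        assert max_steps(make_matrix(["0", "0", "0"]), 0) == 0

    def test_max_steps_matches_star_oracle(self, rng):
        for _ in range(6):
            m = random_state_matrix(rng, 8, 3)
            for j in range(m.n_characters):
                assert max_steps(m, j) == brute_star_length(m, j)

    def test_max_steps_dominates_every_topology(self):
        rng = np.random.default_rng(13)
        m = random_state_matrix(rng, 6, 3)
        for j in range(m.n_characters):
            worst = max(character_length(t, m, j)
                        for t in enumerate_topologies(m.taxa))
            assert max_steps(m, j) >= worst

    def test_polymorphic_fixed_variant(self):
        # one taxon scored 0&1, everything else 0
        m = make_matrix(["01", "0", "0", "0"])
        assert min_steps(m, 0) == 0
        assert min_steps(m, 0, polymorphic_fixed=True) == 1
        assert max_steps(m, 0) == 0
        assert max_steps(m, 0, polymorphic_fixed=True) == 1
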