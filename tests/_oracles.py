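"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the implementation: parsimony length
by exhaustive enumeration of internal-node state assignments, star-tree
length by exhaustive assignment of ambiguous cells, and exact tree search
by complete topology enumeration.
"""

from itertools import product

from cladist.matrix import CellKind, CharacterMatrix
from cladist.trees import PhyloTree, enumerate_topologies


def make_matrix(rows, taxa=None):
    """Compact matrix builder: each row a whitespace string of tokens
    (digits, 'ab' for polymorphism, '?' missing, 'N' inapplicable)."""
    parsed = []
    for row in rows:
        r = []
        for tok in row.split():
            if tok == "?":
                r.append((CellKind.MISSING, ()))
            elif tok == "N":
                r.append((CellKind.INAPPLICABLE, ()))
            elif len(tok) > 1:
                r.append((CellKind.POLYMORPHIC, tuple(int(c) for c in tok)))
            else:
                r.append((CellKind.OBSERVED, (int(tok),)))
        parsed.append(r)
    if taxa is None:
        taxa = [chr(ord("A") + i) for i in range(len(rows))]
    return CharacterMatrix.from_tokens(taxa, parsed)


def brute_character_length(tree: PhyloTree, matrix: CharacterMatrix,
                           char_index: int) -> int:
    """Minimum changes over ALL joint assignments of states to internal
    nodes and resolutions of ambiguous leaves."""
    adj = tree._adj
    n = tree.n_leaves
    states = sorted(matrix.characters[char_index].observed_states) or [0]
    node_choices = []
    nodes = sorted(adj)
    for v in nodes:
        if v < n:
            cell = matrix.cell(tree.taxa[v], char_index)
            node_choices.append(sorted(cell.states) or [states[0]])
        else:
            node_choices.append(states)
    edges = [(u, v) for u in adj for v in adj[u] if u < v]
    best = None
    for combo in product(*node_choices):
        state = dict(zip(nodes, combo))
        changes = sum(1 for u, v in edges if state[u] != state[v])
        if best is None or changes < best:
            best = changes
    return best


def brute_star_length(matrix: CharacterMatrix, char_index: int) -> int:
    """Exact star-tree length: minimize over the center state and every
    assignment of ambiguous cells."""
    cells = [sorted(c.states) for c in matrix.column(char_index) if c.states]
    if not cells:
        return 0
    states = sorted({s for c in cells for s in c})
    best = None
    for center in states:
        cost = sum(0 if center in c else 1 for c in cells)
        if best is None or cost < best:
            best = cost
    return best


def exhaustive_best_trees(matrix: CharacterMatrix):
    """(best length, list of optimal resolved topologies) by scoring every
    unrooted topology with the brute-force character oracle."""
    best, trees = None, []
    for tree in enumerate_topologies(matrix.taxa):
        length = sum(brute_character_length(tree, matrix, j)
                     for j in range(matrix.n_characters))
        if best is None or length < best:
            best, trees = length, [tree]
        elif length == best:
            trees.append(tree)
    return best, trees
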