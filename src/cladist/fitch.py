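"""Fitch parsimony scoring for unordered, equally weighted characters.

The tree length of a character is the minimum number of state changes over
all assignments of states to internal nodes.  For fully resolved trees this
is computed with the classic Fitch downpass over state-set bitmasks (one
``uint8`` per cell, supporting up to 8 states); ambiguous terminals
(polymorphic, missing, inapplicable) enter the pass as their whole state
set.  Multifurcating trees and per-branch quantities use an exact
unit-cost dynamic program over states (Sankoff/Hartigan style), which agrees
with the downpass on resolved trees.

Also provided are the per-character bounds used by the fit indices:
``min_steps`` (the fewest changes on any tree: a minimum set cover of the
cells' state sets, minus one) and ``max_steps`` (the most changes any tree
can force: the length of the completely unresolved star tree).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .matrix import CharacterMatrix, CellKind
from .trees import PhyloTree

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f

__all__ = ["ParsimonyScore", "character_length", "tree_length",
           "min_steps", "max_steps"]

_INF = 10 ** 9
MAX_STATES = 8  # bitmask width contract


# ---------------------------------------------------------------------------
# encoding
# ---------------------------------------------------------------------------

def encode_matrix(matrix: CharacterMatrix) -> np.ndarray:
    """State-set bitmasks, shape (n_taxa, n_characters), dtype uint8.

    A cell whose set is empty (a wildcard in a character with no observed
    state anywhere) is encoded as a single arbitrary state so it can never
    force a change.
    """
    n, k = matrix.n_taxa, matrix.n_characters
    for ch in matrix.characters:
        if any(s < 0 or s >= MAX_STATES for s in ch.observed_states):
            raise ValueError(
                f"character {ch.index}: states outside the supported range "
                f"0..{MAX_STATES - 1}")
    M = np.zeros((n, k), dtype=np.uint8)
    for i in range(n):
        row = matrix.row(i)
        for j, cell in enumerate(row):
            mask = 0
            for s in cell.states:
                mask |= 1 << s
            M[i, j] = mask if mask else 1
    return M


@njit(cache=False)
def _fitch_counts(nodes, c1, c2, S, counts):
    """Downpass over postorder internal nodes; fills per-character change
    counts and the internal rows of the state-set buffer ``S``."""
    k = S.shape[1]
    for idx in range(nodes.shape[0]):
        v = nodes[idx]
        a = c1[idx]
        b = c2[idx]
        for j in range(k):
            inter = S[a, j] & S[b, j]
            if inter:
                S[v, j] = inter
            else:
                S[v, j] = S[a, j] | S[b, j]
                counts[j] += 1


@njit(cache=False)
def _fitch_total(nodes, c1, c2, S, bound):
    """Total change count with early exit once ``bound`` is exceeded."""
    k = S.shape[1]
    total = 0
    for idx in range(nodes.shape[0]):
        v = nodes[idx]
        a = c1[idx]
        b = c2[idx]
        for j in range(k):
            inter = S[a, j] & S[b, j]
            if inter:
                S[v, j] = inter
            else:
                S[v, j] = S[a, j] | S[b, j]
                total += 1
        if total > bound:
            return total
    return total


def postorder_arrays(adj: dict, leaf_limit: int):
    """Postorder (node, child, child) arrays for a binary unrooted adjacency,
    rooted on the pendant edge of its smallest leaf id; the final entry is a
    virtual root joining that leaf and the rest of the tree."""
    root_leaf = min(v for v in adj if v < leaf_limit)
    start = adj[root_leaf][0]
    nodes, cc1, cc2 = [], [], []
    stack = [(start, root_leaf, False)]
    while stack:
        v, p, done = stack.pop()
        if v < leaf_limit:
            continue
        kids = [w for w in adj[v] if w != p]
        if done:
            nodes.append(v)
            cc1.append(kids[0])
            cc2.append(kids[1])
        else:
            stack.append((v, p, True))
            for w in kids:
                stack.append((w, v, False))
    vroot = max(adj) + 1
    nodes.append(vroot)
    cc1.append(root_leaf)
    cc2.append(start)
    return (np.asarray(nodes, dtype=np.int64),
            np.asarray(cc1, dtype=np.int64),
            np.asarray(cc2, dtype=np.int64))


class MatrixScorer:
    """Reusable Fitch scorer for trees whose leaf ids index ``matrix.taxa``
    (or a remapping of them).  Used heavily by the search engine."""

    def __init__(self, matrix: CharacterMatrix, taxa: Sequence[str] | None = None):
        self.matrix = matrix
        self.taxa = tuple(taxa) if taxa is not None else matrix.taxa
        idx = [matrix.taxon_index(t) for t in self.taxa]
        self.leaf_states = encode_matrix(matrix)[idx, :]
        self.n_leaves = len(self.taxa)
        self.n_char = matrix.n_characters
        # buffer: leaves, up to n-2 internals, one virtual root, slack
        self._S = np.zeros((2 * self.n_leaves + 2, self.n_char), dtype=np.uint8)
        self._S[: self.n_leaves] = self.leaf_states

    def _buffer(self, adj: dict) -> np.ndarray:
        hi = max(adj) + 2
        if hi > self._S.shape[0]:
            S = np.zeros((hi, self.n_char), dtype=np.uint8)
            S[: self.n_leaves] = self.leaf_states
            self._S = S
        return self._S

    def score(self, adj: dict, bound: int = _INF) -> int:
        nodes, c1, c2 = postorder_arrays(adj, self.n_leaves)
        return int(_fitch_total(nodes, c1, c2, self._buffer(adj), bound))

    def per_character(self, adj: dict) -> np.ndarray:
        nodes, c1, c2 = postorder_arrays(adj, self.n_leaves)
        counts = np.zeros(self.n_char, dtype=np.int64)
        _fitch_counts(nodes, c1, c2, self._buffer(adj), counts)
        return counts


# ---------------------------------------------------------------------------
# exact DP over states (handles multifurcations; used for branch quantities)
# ---------------------------------------------------------------------------

def root_at_leaf(tree: PhyloTree, leaf_id: int = 0):
    """Rooted view of an unrooted tree: parent/children maps and a postorder
    list, with the given leaf as the root."""
    adj = tree._adj
    parent = {leaf_id: None}
    children: dict = {leaf_id: [adj[leaf_id][0]]}
    order = []
    stack = [(adj[leaf_id][0], leaf_id)]
    while stack:
        v, p = stack.pop()
        parent[v] = p
        kids = [w for w in adj[v] if w != p]
        children[v] = kids
        order.append(v)
        stack.extend((w, v) for w in kids)
    order.reverse()  # children before parents
    return parent, children, order


def char_state_sets(tree: PhyloTree, matrix: CharacterMatrix, char_index: int) -> dict:
    """Leaf id -> state set for one character, with wildcard cells of an
    all-wildcard character given a free single state."""
    sets = {}
    for i, t in enumerate(tree.taxa):
        s = matrix.cell(t, char_index).states
        sets[i] = s if s else frozenset({0})
    return sets


def down_costs(children: dict, order: Sequence[int], leaf_sets: dict,
               states: Sequence[int]) -> dict:
    """Sankoff downpass: ``D[v][s]`` = min changes within the subtree of v
    given v has state s (unit costs, unordered)."""
    D: dict = {}
    for v in list(leaf_sets) :
        D[v] = [0 if s in leaf_sets[v] else _INF for s in states]
    for v in order:
        if v in leaf_sets:
            continue
        tot = [0] * len(states)
        for w in children[v]:
            best = min(D[w])
            for si in range(len(states)):
                tot[si] += min(D[w][si], best + 1)
        D[v] = tot
    return D


def out_costs(parent: dict, children: dict, order: Sequence[int], D: dict,
              leaf_sets: dict, states: Sequence[int], root: int) -> dict:
    """``Out[v][t]`` = min changes in the whole tree excluding subtree(v) and
    the edge to its parent, given the parent has state t."""
    k = len(states)
    Out: dict = {}
    A: dict = {root: [0 if s in leaf_sets[root] else _INF for s in states]}
    for v in reversed(order):  # parents before children
        p = parent[v]
        base = A[p]
        sib_cost = [0] * k
        for w in children[p]:
            if w == v:
                continue
            best = min(D[w])
            for si in range(k):
                sib_cost[si] += min(D[w][si], best + 1)
        o = [base[si] + sib_cost[si] for si in range(k)]
        Out[v] = o
        if v not in leaf_sets:
            m = min(o)
            A[v] = [min(o[si], m + 1) for si in range(k)]
    return Out


def branch_min_lengths(tree: PhyloTree, matrix: CharacterMatrix) -> dict:
    """For every internal branch (keyed by bipartition side, anchored as in
    :meth:`PhyloTree.bipartitions`), the branch's minimum length: the number
    of characters forced to change on it in every optimal reconstruction."""
    if set(tree.taxa) - set(matrix.taxa):
        missing = sorted(set(tree.taxa) - set(matrix.taxa))
        raise KeyError(f"leaves absent from matrix: {missing}")
    parent, children, order = root_at_leaf(tree)
    n = tree.n_leaves
    anchor = tree.taxa[0]
    full = frozenset(tree.taxa)
    # leaves below each node
    below: dict = {}
    for v in order:
        if v < n:
            below[v] = frozenset({tree.taxa[v]})
        else:
            below[v] = frozenset().union(*(below[w] for w in children[v]))
    internal_edges = [v for v in order
                      if v >= n and parent[v] is not None and parent[v] >= n]
    forced = {v: 0 for v in internal_edges}
    for j in range(matrix.n_characters):
        states = sorted(matrix.characters[j].observed_states) or [0]
        leaf_sets = char_state_sets(tree, matrix, j)
        D = down_costs(children, order, leaf_sets, states)
        Out = out_costs(parent, children, order, D, leaf_sets, states, root=0)
        L = min(D[children[0][0]][si] + (0 if states[si] in leaf_sets[0] else 1)
                for si in range(len(states)))
        for v in internal_edges:
            same = min(D[v][si] + Out[v][si] for si in range(len(states)))
            if same > L:
                forced[v] += 1
    out = {}
    for v, count in forced.items():
        side = below[v]
        if anchor in side:
            side = full - side
        if 2 <= len(side) <= n - 2:
            out[side] = count
    return out


# ---------------------------------------------------------------------------
# public scoring API
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParsimonyScore:
    """Per-character steps and bounds for one tree on one matrix."""

    per_character_steps: tuple
    per_character_min: tuple
    per_character_max: tuple

    @property
    def total_length(self) -> int:
        return int(sum(self.per_character_steps))

    def to_dict(self) -> dict:
        return {
            "total_length": self.total_length,
            "per_character_steps": list(self.per_character_steps),
            "per_character_min": list(self.per_character_min),
            "per_character_max": list(self.per_character_max),
        }


def _check_leaves(tree: PhyloTree, matrix: CharacterMatrix) -> None:
    missing = sorted(set(tree.taxa) - set(matrix.taxa))
    if missing:
        raise KeyError(f"leaves absent from matrix: {missing}")


def _dp_char_length(tree: PhyloTree, matrix: CharacterMatrix, j: int) -> int:
    states = sorted(matrix.characters[j].observed_states) or [0]
    parent, children, order = root_at_leaf(tree)
    leaf_sets = char_state_sets(tree, matrix, j)
    D = down_costs(children, order, leaf_sets, states)
    top = children[0][0]
    return min(D[top][si] + (0 if states[si] in leaf_sets[0] else 1)
               for si in range(len(states)))


def character_length(tree: PhyloTree, matrix: CharacterMatrix, char_index: int) -> int:
    """Minimum number of changes for one character on the tree (Fitch
    downpass on resolved trees; exact state DP on multifurcating ones)."""
    _check_leaves(tree, matrix)
    if not tree.is_resolved:
        return _dp_char_length(tree, matrix, char_index)
    scorer = MatrixScorer(matrix, tree.taxa)
    return int(scorer.per_character(tree._adj)[char_index])


def tree_length(tree: PhyloTree, matrix: CharacterMatrix) -> ParsimonyScore:
    """Score all characters on the tree and attach the per-character bounds."""
    _check_leaves(tree, matrix)
    if tree.is_resolved:
        steps = MatrixScorer(matrix, tree.taxa).per_character(tree._adj)
        steps = tuple(int(x) for x in steps)
    else:
        steps = tuple(_dp_char_length(tree, matrix, j)
                      for j in range(matrix.n_characters))
    mins = tuple(min_steps(matrix, j) for j in range(matrix.n_characters))
    maxs = tuple(max_steps(matrix, j) for j in range(matrix.n_characters))
    return ParsimonyScore(steps, mins, maxs)


def _nonempty_sets(matrix: CharacterMatrix, char_index: int) -> list:
    return [c.states for c in matrix.column(char_index) if c.states]


def min_steps(matrix: CharacterMatrix, char_index: int,
              polymorphic_fixed: bool = False) -> int:
    """Fewest conceivable steps on any tree.

    Default (free) semantics: the smallest number of states that can cover
    every cell (each ambiguous cell satisfied by any one of its states),
    minus one — found exactly by exhaustive search over state subsets.
    With ``polymorphic_fixed`` a polymorphic cell is instead read as truly
    exhibiting all its states, each of which must then arise somewhere.
    """
    states = sorted(matrix.characters[char_index].observed_states)
    if not states:
        return 0
    if polymorphic_fixed:
        required = set()
        for c in matrix.column(char_index):
            if c.kind is CellKind.OBSERVED or c.kind is CellKind.POLYMORPHIC:
                required |= c.states
        return max(0, len(required) - 1)
    cells = _nonempty_sets(matrix, char_index)
    if not cells:
        return 0
    from itertools import combinations
    for size in range(1, len(states) + 1):
        for combo in combinations(states, size):
            chosen = set(combo)
            if all(chosen & s for s in cells):
                return size - 1
    return len(states) - 1  # unreachable


def max_steps(matrix: CharacterMatrix, char_index: int,
              polymorphic_fixed: bool = False) -> int:
    """Most conceivable steps: the exact length of the star (completely
    unresolved) tree, with every ambiguous cell taking its best covering
    state.  With ``polymorphic_fixed`` each polymorphic cell additionally
    contributes one change of its own."""
    states = sorted(matrix.characters[char_index].observed_states)
    if not states:
        return 0
    if polymorphic_fixed:
        singles = [c for c in matrix.column(char_index) if c.kind is CellKind.OBSERVED]
        n_poly = sum(1 for c in matrix.column(char_index)
                     if c.kind is CellKind.POLYMORPHIC)
        if not singles:
            return n_poly
        best = max(sum(1 for c in singles if s in c.states) for s in states)
        return len(singles) - best + n_poly
    cells = _nonempty_sets(matrix, char_index)
    if not cells:
        return 0
    best = max(sum(1 for cs in cells if s in cs) for s in states)
    return len(cells) - best
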