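"""Character-state optimization on rooted trees and synapomorphy mapping.

A most-parsimonious reconstruction (MPR) assigns one state per node so that
the number of changes equals the character's Fitch length.  When several
MPRs exist, ACCTRAN places changes as close to the root as possible
(favoring early gains with later reversals) and DELTRAN delays them
(favoring parallel gains); a change is *unambiguous* when both
reconstructions place it on the same branch with the same states.

Reconstructions are computed with a unit-cost dynamic program over states:
a downpass gives, for every node and state, the optimal cost of its
subtree; a preorder pass then assigns states greedily, staying within the
optimal set at each step, breaking ties toward (ACCTRAN) or away from
(DELTRAN) a change.  This guarantees every reconstruction sums exactly to
the character's length, including on multifurcating trees, where changes
are attributed only to the resolved branches.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .fitch import char_state_sets, down_costs, root_at_leaf
from .matrix import CharacterMatrix
from .trees import PhyloTree

__all__ = ["RootedTree", "Change", "optimize_character", "clade_support",
           "synapomorphy_report", "SynapomorphyReport"]

MODES = ("ACCTRAN", "DELTRAN", "unambiguous")


@dataclass(frozen=True)
class RootedTree:
    """An unrooted tree rooted on the pendant edge of an outgroup terminal.

    Rooting does not change tree length; it only polarizes changes.
    """

    tree: PhyloTree
    outgroup: str

    def __post_init__(self):
        if self.outgroup not in self.tree.taxa:
            raise ValueError(f"outgroup {self.outgroup!r} is not a leaf of the tree")

    @property
    def taxa(self):
        return self.tree.taxa

    def clades(self) -> frozenset:
        return self.tree.clades(self.outgroup)


@dataclass(frozen=True)
class Change:
    """One state change: on the branch subtending ``clade`` (a frozenset of
    terminal labels; singleton for pendant branches)."""

    char_index: int
    clade: frozenset
    from_state: int
    to_state: int

    def to_dict(self) -> dict:
        return {"character": self.char_index,
                "clade": sorted(self.clade),
                "from_state": self.from_state,
                "to_state": self.to_state}


def _require_rooted(tree) -> RootedTree:
    if isinstance(tree, RootedTree):
        return tree
    raise TypeError(
        "an unrooted tree cannot polarize changes; wrap it as "
        "RootedTree(tree, outgroup) first")


def _assign(rooted: RootedTree, matrix: CharacterMatrix, char_index: int,
            accelerate: bool):
    """Greedy optimal assignment; tie-breaks toward a change (ACCTRAN) or
    against one (DELTRAN), then toward the smallest state."""
    tree = rooted.tree
    root_id = tree.taxa.index(rooted.outgroup)
    parent, children, order = root_at_leaf(tree, root_id)
    states = sorted(matrix.characters[char_index].observed_states) or [0]
    leaf_sets = char_state_sets(tree, matrix, char_index)
    D = down_costs(children, order, leaf_sets, states)

    assignment: dict = {}
    # root leaf: choose its own state to minimize the total
    top = children[root_id][0]
    best_total, best_s = None, None
    for s in sorted(leaf_sets[root_id]):
        total = min(D[top][si] + (0 if states[si] == s else 1)
                    for si in range(len(states)))
        if best_total is None or total < best_total:
            best_total, best_s = total, s
    assignment[root_id] = best_s

    below: dict = {}
    for v in order:
        below[v] = (frozenset({tree.taxa[v]}) if v < tree.n_leaves
                    else frozenset().union(*(below[w] for w in children[v])))

    changes = []
    for v in reversed(order):  # preorder: parents first
        t = assignment[parent[v]]
        ti = states.index(t) if t in states else None
        best = min(D[v][si] + (0 if si == ti else 1)
                   for si in range(len(states)))
        opts = [states[si] for si in range(len(states))
                if D[v][si] + (0 if si == ti else 1) == best]
        if accelerate:
            non_parent = [s for s in opts if s != t]
            choice = non_parent[0] if non_parent else opts[0]
        else:
            choice = t if t in opts else opts[0]
        assignment[v] = choice
        if choice != t:
            changes.append(Change(char_index, below[v], t, choice))
    return assignment, changes


def optimize_character(tree, matrix: CharacterMatrix, char_index: int,
                       mode: str = "unambiguous"):
    """Optimize one character on a rooted tree.

    Returns ``(assignment, changes)`` for ACCTRAN/DELTRAN, where
    ``assignment`` maps node ids of the rooted traversal to states; for
    ``unambiguous`` mode the assignment is None and the changes are those
    shared by both reconstructions.
    """
    rooted = _require_rooted(tree)
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    if mode == "ACCTRAN":
        return _assign(rooted, matrix, char_index, accelerate=True)
    if mode == "DELTRAN":
        return _assign(rooted, matrix, char_index, accelerate=False)
    _, acc = _assign(rooted, matrix, char_index, accelerate=True)
    _, dele = _assign(rooted, matrix, char_index, accelerate=False)
    return None, sorted(set(acc) & set(dele),
                        key=lambda c: (sorted(c.clade), c.from_state))


@dataclass
class SynapomorphyReport:
    """All branch changes of a rooted tree, with ambiguity classes."""

    rooted: RootedTree
    by_branch: dict  # frozenset(clade) -> list of (Change, ambiguity)

    def for_clade(self, terminals: Iterable[str]) -> list:
        return list(self.by_branch.get(frozenset(terminals), []))

    def to_dict(self) -> dict:
        out = []
        for clade in sorted(self.by_branch, key=lambda c: (len(c), sorted(c))):
            for change, amb in self.by_branch[clade]:
                d = change.to_dict()
                d["ambiguity"] = amb
                out.append(d)
        return {"outgroup": self.rooted.outgroup, "changes": out}

    def to_table(self) -> str:
        lines = ["branch (terminal set)                     char  change  ambiguity"]
        for clade in sorted(self.by_branch, key=lambda c: (len(c), sorted(c))):
            name = ", ".join(sorted(clade))
            if len(name) > 40:
                name = name[:37] + "..."
            for change, amb in self.by_branch[clade]:
                lines.append(f"{name:40s}  {change.char_index:4d}  "
                             f"{change.from_state}->{change.to_state}    {amb}")
        return "\n".join(lines)


def synapomorphy_report(tree, matrix: CharacterMatrix) -> SynapomorphyReport:
    """Map every character on every branch, classifying each change as
    unambiguous, ACCTRAN-only or DELTRAN-only."""
    rooted = _require_rooted(tree)
    by_branch: dict = {}
    for j in range(matrix.n_characters):
        _, acc = _assign(rooted, matrix, j, accelerate=True)
        _, dele = _assign(rooted, matrix, j, accelerate=False)
        acc_set, del_set = set(acc), set(dele)
        for change in sorted(acc_set | del_set,
                             key=lambda c: (sorted(c.clade), c.from_state, c.to_state)):
            if change in acc_set and change in del_set:
                amb = "unambiguous"
            elif change in acc_set:
                amb = "acctran_only"
            else:
                amb = "deltran_only"
            by_branch.setdefault(change.clade, []).append((change, amb))
    for clade in by_branch:
        by_branch[clade].sort(key=lambda ca: (ca[0].char_index, ca[0].from_state))
    return SynapomorphyReport(rooted, by_branch)


def clade_support(tree, matrix: CharacterMatrix, clade: Iterable[str]) -> list:
    """Character changes on the stem branch of ``clade``, each tagged with
    its ambiguity class.  Raises if the clade is not in the tree, naming a
    conflicting bipartition."""
    rooted = _require_rooted(tree)
    term = frozenset(clade)
    clades = rooted.clades() | {frozenset({t}) for t in rooted.taxa}
    if term not in clades:
        conflict = next((sorted(c) for c in clades
                         if c & term and not (c <= term or term <= c)), None)
        raise ValueError(
            f"clade {sorted(term)} is not present in the tree"
            + (f"; conflicts with {conflict}" if conflict else ""))
    report = synapomorphy_report(rooted, matrix)
    return report.for_clade(term)
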