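"""Synthetic character matrices evolved on known trees.

The generator emulates the shape of a small morphological data set — a few
dozen unordered characters with 2–3 states over ~20 taxa, a handful of
missing/inapplicable cells and the occasional polymorphic cell — while
keeping the truth (tree and per-character change counts) available, so
search, consensus and index code can be tested end to end.

Two change models:

* ``origins`` (default): each character receives an explicit number of
  state origins, each painted on a distinct branch of the rooted tree; the
  subtree below an origin switches to a new state.  Homoplasy is therefore
  exactly controlled: a character with one origin is a clean synapomorphy,
  and the realized number of changes on the true tree never exceeds the
  origin count.
* ``mk``: a k-state Markov jump process with a per-branch expected number
  of events, for rate-based realism.

Ambiguity (missing / inapplicable / polymorphic cells) is injected after
evolution, so it can only blur, never add, signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .consensus import ensemble_indices, strict_consensus
from .fitch import root_at_leaf, tree_length
from .matrix import CharacterMatrix, CellKind
from .search import SearchConfig, SearchResult, branch_and_bound, heuristic_search
from .trees import PhyloTree, random_topology

__all__ = ["SimConfig", "SimResult", "simulate", "recovery_trial",
           "RecoveryReport"]


@dataclass(frozen=True)
class SimConfig:
    """Generator settings, defaulting to the shape of the reference data:
    20 taxa, 38 characters, roughly a third of them 3-state, sparse
    ambiguity (about half a percent each of missing and inapplicable cells,
    and polymorphism at the one-cell-in-a-matrix level), and a mild-homoplasy
    origin mixture averaging under two origins per character."""

    n_taxa: int = 20
    n_characters: int = 38
    p_three_state: float = 0.34
    tree: PhyloTree | None = None
    change_model: str = "origins"  # or "mk"
    origin_weights: tuple = ((1, 0.55), (2, 0.30), (3, 0.15))
    rate: float = 0.15  # expected events per branch under "mk"
    p_missing: float = 0.005
    p_inapplicable: float = 0.005
    p_polymorphic: float = 0.0015
    seed: int = 0

    def __post_init__(self):
        for name in ("p_three_state", "p_missing", "p_inapplicable",
                     "p_polymorphic"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_taxa < 4:
            raise ValueError("n_taxa must be >= 4")
        if self.change_model not in ("origins", "mk"):
            raise ValueError(f"unknown change_model {self.change_model!r}")


@dataclass
class SimResult:
    matrix: CharacterMatrix
    true_tree: PhyloTree
    origin_counts: tuple  # per character: state changes placed on the tree

    def truth_dict(self) -> dict:
        return {"true_tree": self.true_tree.to_newick(),
                "origin_counts": list(self.origin_counts)}


def _evolve_origins(parent, children, order, leaves, k, n_origins, rng):
    """Paint ``n_origins`` state switches on distinct branches (preorder
    inheritance); returns (leaf states, realized change count)."""
    branches = [v for v in order]  # every non-root node heads one branch
    if n_origins > len(branches):
        raise ValueError(
            f"{n_origins} origins requested but the tree has only "
            f"{len(branches)} branches")
    chosen = set(rng.choice(len(branches), size=n_origins, replace=False).tolist())
    chosen = {branches[i] for i in chosen}
    root = next(v for v in parent if parent[v] is None)
    state = {root: 0}
    changes = 0
    for v in reversed(order):  # preorder
        s = state[parent[v]]
        if v in chosen:
            s = (s + 1) % k if k > 2 else 1 - s
            changes += 1
        state[v] = s
    return {v: state[v] for v in leaves}, changes


def _evolve_mk(parent, children, order, leaves, k, rate, rng):
    root = next(v for v in parent if parent[v] is None)
    state = {root: int(rng.integers(k))}
    changes = 0
    for v in reversed(order):
        s = state[parent[v]]
        for _ in range(rng.poisson(rate)):
            s = (s + 1 + int(rng.integers(k - 1))) % k
            changes += 1
        state[v] = s
    return {v: state[v] for v in leaves}, changes


def simulate(config: SimConfig) -> SimResult:
    """Evolve a matrix on a (given or uniformly sampled) true tree.

    Identical seeds give identical output.  The per-character origin counts
    are the realized numbers of state changes along the true tree, before
    ambiguity injection; the Fitch length of the true tree can therefore
    never exceed their sum.
    """
    rng = np.random.default_rng(config.seed)
    labels = [f"t{i + 1:02d}" for i in range(config.n_taxa)]
    tree = config.tree
    if tree is None:
        tree = random_topology(labels, rng)
    else:
        labels = sorted(tree.taxa)
    parent, children, order = root_at_leaf(tree, 0)
    leaves = list(range(tree.n_leaves))

    weights = dict(config.origin_weights)
    origin_vals = sorted(weights)
    origin_p = np.array([weights[v] for v in origin_vals], dtype=float)
    origin_p /= origin_p.sum()

    columns = []
    origin_counts = []
    for _ in range(config.n_characters):
        k = 3 if rng.random() < config.p_three_state else 2
        if config.change_model == "origins":
            n_orig = int(rng.choice(origin_vals, p=origin_p))
            states, changed = _evolve_origins(parent, children, order,
                                              leaves, k, n_orig, rng)
        else:
            states, changed = _evolve_mk(parent, children, order, leaves,
                                         k, config.rate, rng)
        columns.append(states)
        origin_counts.append(changed)

    rows = []
    for i, label in enumerate(sorted(tree.taxa)):
        row = []
        for j, states in enumerate(columns):
            leaf_id = sorted(tree.taxa).index(label)  # leaves are sorted-order ids
            s = states[leaf_id]
            u = rng.random()
            if u < config.p_missing:
                row.append((CellKind.MISSING, ()))
            elif u < config.p_missing + config.p_inapplicable:
                row.append((CellKind.INAPPLICABLE, ()))
            elif u < (config.p_missing + config.p_inapplicable
                      + config.p_polymorphic):
                other = (s + 1) % 3 if s != 0 else 1
                row.append((CellKind.POLYMORPHIC, tuple(sorted({s, other}))))
            else:
                row.append((CellKind.OBSERVED, (s,)))
        rows.append(row)
    matrix = CharacterMatrix.from_tokens(sorted(tree.taxa), rows)
    return SimResult(matrix, tree, tuple(origin_counts))


@dataclass
class RecoveryReport:
    """End-to-end search outcome on simulated data with known truth."""

    sim: SimResult
    search: SearchResult
    consensus: PhyloTree
    true_tree_recovered: bool       # true topology among the resolved MPTs
    consensus_matches_truth: bool   # consensus bipartitions all in the truth
    CI: float | None
    RI: float | None

    def to_dict(self) -> dict:
        return {
            "best_length": self.search.best_length,
            "n_mpts": self.search.n_mpts,
            "true_tree_recovered": self.true_tree_recovered,
            "consensus_matches_truth": self.consensus_matches_truth,
            "CI": self.CI,
            "RI": self.RI,
        }


def recovery_trial(config: SimConfig,
                   search: SearchConfig | None = None) -> RecoveryReport:
    """Simulate, search (exact below 12 taxa, heuristic above), build the
    strict consensus and indices, and compare against the known truth."""
    sim = simulate(config)
    if search is None and sim.matrix.n_taxa <= 11:
        result = branch_and_bound(sim.matrix)
    else:
        result = heuristic_search(sim.matrix, search or SearchConfig())
    consensus = strict_consensus(result.mpt_set)
    truth = sim.true_tree.bipartitions()
    recovered = any(t.bipartitions() == truth for t in result.binary_mpt_set)
    report = ensemble_indices(list(result.binary_mpt_set), sim.matrix)
    return RecoveryReport(
        sim=sim,
        search=result,
        consensus=consensus,
        true_tree_recovered=recovered,
        consensus_matches_truth=consensus.bipartitions() <= truth,
        CI=report.CI,
        RI=report.RI,
    )
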