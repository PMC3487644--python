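"""Most-parsimonious-tree search.

Two engines over the same Fitch scorer:

* :func:`branch_and_bound` — exact for small taxon sets: stepwise taxon
  addition in a fixed order, pruning a partial tree as soon as its length
  plus a lower bound for the unplaced taxa exceeds the incumbent.  Returns
  provably all minimal-length resolved trees.
* :func:`heuristic_search` — random-addition-sequence replicates, each
  swapped to a local optimum (NNI, SPR or TBR), then closure of the
  best-length island: equal-length neighbors are explored until no new
  topology of the best length is reachable.

Both report trees after contracting every internal branch whose minimum
length over all optimal reconstructions is zero ("min-length-zero"
collapsing) and removing duplicate topologies; the resolved trees are kept
alongside, since the count of distinct MPTs depends on the collapsing rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

from .fitch import MatrixScorer, branch_min_lengths
from .matrix import CharacterMatrix, CellKind
from .trees import PhyloTree, tree_from_bipartitions, _add_leaf, _edges

__all__ = ["SearchConfig", "SearchResult", "branch_and_bound",
           "heuristic_search", "collapse_unsupported", "dedupe"]

_INF = 10 ** 9


@dataclass(frozen=True)
class SearchConfig:
    """Heuristic-search settings.

    Defaults (100 random-addition replicates, TBR swapping, up to 10,000
    trees held) are sized so that recovering a small island of optimal
    trees on a matrix of a few dozen taxa is essentially certain while the
    run stays in the seconds-to-minutes range.
    """

    n_replicates: int = 100
    swap: str = "TBR"
    seed: int = 42
    max_trees_held: int = 10_000
    collapse_rule: str = "min-length-zero"

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.max_trees_held < 1:
            raise ValueError("max_trees_held must be >= 1")
        if self.swap.upper() not in ("NNI", "SPR", "TBR"):
            raise ValueError(f"unknown swap {self.swap!r}")


@dataclass
class SearchResult:
    """Outcome of a tree search."""

    best_length: int
    mpt_set: tuple          # unique collapsed topologies
    binary_mpt_set: tuple   # unique fully resolved optimal topologies
    log: dict = field(default_factory=dict)
    exhaustive: bool = True

    @property
    def n_mpts(self) -> int:
        return len(self.mpt_set)


# ---------------------------------------------------------------------------
# adjacency-level moves
# ---------------------------------------------------------------------------

def _copy(adj: dict) -> dict:
    return {k: list(v) for k, v in adj.items()}


def _replace(lst: list, old: int, new: int) -> None:
    lst[lst.index(old)] = new


def _component(adj: dict, start: int, ban_u: int, ban_v: int) -> list:
    """Nodes reachable from ``start`` without crossing edge (ban_u, ban_v)."""
    seen = {start}
    stack = [start]
    while stack:
        x = stack.pop()
        for y in adj[x]:
            if (x, y) in ((ban_u, ban_v), (ban_v, ban_u)):
                continue
            if y not in seen:
                seen.add(y)
                stack.append(y)
    return sorted(seen)


def _detach_side(adj: dict, keep: int, cut: int, n: int):
    """Half of a bisection: the component of ``keep`` after removing edge
    (keep, cut), with the degree-2 stub suppressed.

    Returns ``(part_adj, attach, original_edge)`` where ``attach`` is the
    node to reconnect from when the side is a bare leaf (else None) and
    ``original_edge`` is the edge whose subdivision recreates the original
    attachment (None for a bare leaf)."""
    nodes = _component(adj, keep, keep, cut)
    part = {x: [y for y in adj[x] if not (x == keep and y == cut)]
            for x in nodes}
    if keep < n and len(part[keep]) == 0:  # bare leaf
        del part[keep]
        return {}, keep, None
    x, y = part[keep]  # suppress the stub (binary tree => degree 2 now)
    _replace(part[x], keep, y)
    _replace(part[y], keep, x)
    del part[keep]
    return part, None, (min(x, y), max(x, y))


def _reconnect(partA, leafA, partB, leafB, edgeA, edgeB, nodeA, nodeB) -> dict:
    """Join two detached sides, subdividing edgeA/edgeB with nodeA/nodeB
    (bare-leaf sides connect directly)."""
    new = {k: list(v) for k, v in partA.items()}
    new.update({k: list(v) for k, v in partB.items()})
    if leafA is not None:
        pa = leafA
        new[pa] = []
    else:
        a1, a2 = edgeA
        _replace(new[a1], a2, nodeA)
        _replace(new[a2], a1, nodeA)
        new[nodeA] = [a1, a2]
        pa = nodeA
    if leafB is not None:
        pb = leafB
        new[pb] = []
    else:
        b1, b2 = edgeB
        _replace(new[b1], b2, nodeB)
        _replace(new[b2], b1, nodeB)
        new[nodeB] = [b1, b2]
        pb = nodeB
    new[pa].append(pb)
    new[pb].append(pa)
    return new


def _bisection_neighbors(adj: dict, n: int, kind: str) -> Iterator[dict]:
    """TBR neighborhood (SPR: one side must reconnect at its original
    point).  The original tree itself is not yielded."""
    spr = kind == "SPR"
    for (u, v) in _edges(adj):
        partA, leafA, origA = _detach_side(adj, u, v, n)
        partB, leafB, origB = _detach_side(adj, v, u, n)
        edgesA = [None] if leafA is not None else _edges(partA)
        edgesB = [None] if leafB is not None else _edges(partB)
        for ea in edgesA:
            a_orig = (leafA is not None) or (ea == origA)
            for eb in edgesB:
                b_orig = (leafB is not None) or (eb == origB)
                if a_orig and b_orig:
                    continue  # recreates the original tree
                if spr and not (a_orig or b_orig):
                    continue
                yield _reconnect(partA, leafA, partB, leafB, ea, eb, u, v)


def _nni_neighbors(adj: dict, n: int) -> Iterator[dict]:
    for (u, v) in _edges(adj):
        if u < n or v < n:
            continue
        a, b = [x for x in adj[u] if x != v]
        cs = [x for x in adj[v] if x != u]
        for c in cs:
            new = _copy(adj)
            _replace(new[u], b, c)
            _replace(new[v], c, b)
            _replace(new[b], u, v)
            _replace(new[c], v, u)
            yield new


def neighbors(adj: dict, n: int, kind: str) -> Iterator[dict]:
    kind = kind.upper()
    if kind == "NNI":
        return _nni_neighbors(adj, n)
    if kind in ("SPR", "TBR"):
        return _bisection_neighbors(adj, n, kind)
    raise ValueError(f"unknown swap {kind!r}")


def _bipart_key(adj: dict, n: int) -> frozenset:
    """Topology identity over leaf ids: non-trivial bipartition sides not
    containing the smallest leaf."""
    leaves = frozenset(v for v in adj if v < n)
    anchor = min(leaves)
    out = set()
    for (u, v) in _edges(adj):
        if u < n or v < n:
            continue
        side = frozenset(x for x in _component(adj, v, v, u) if x < n)
        if anchor in side:
            side = leaves - side
        if 2 <= len(side) <= len(leaves) - 2:
            out.add(side)
    return frozenset(out)


# ---------------------------------------------------------------------------
# stepwise addition and local search
# ---------------------------------------------------------------------------

def _stepwise(order: Sequence[int], scorer: MatrixScorer) -> dict:
    """Greedy stepwise addition: each taxon goes to the insertion edge of
    minimal resulting length (first-found among ties, in deterministic edge
    order)."""
    n = scorer.n_leaves
    l0, l1, l2 = order[0], order[1], order[2]
    hub = n
    adj = {l0: [hub], l1: [hub], l2: [hub], hub: [l0, l1, l2]}
    nxt = n + 1
    for leaf in order[3:]:
        best_adj, best_len = None, _INF
        for edge in _edges(adj):
            cand = _add_leaf(adj, n, int(leaf), edge, nxt)
            score = scorer.score(cand, best_len)
            if score < best_len:
                best_adj, best_len = cand, score
        adj = best_adj
        nxt += 1
    return adj


def _descend(adj: dict, scorer: MatrixScorer, kind: str):
    """First-improvement branch swapping to a local optimum."""
    n = scorer.n_leaves
    cur_len = scorer.score(adj)
    improved = True
    while improved:
        improved = False
        for nb in neighbors(adj, n, kind):
            if scorer.score(nb, cur_len) < cur_len:
                adj, cur_len = nb, scorer.score(nb)
                improved = True
                break
    return adj, cur_len


def _close_island(seeds: Iterable[dict], scorer: MatrixScorer, kind: str,
                  max_trees: int):
    """Collect every topology of the current best length reachable from the
    seeds through equal-length swaps; if a better tree is stumbled upon the
    closure restarts from it."""
    n = scorer.n_leaves
    seeds = list(seeds)
    best = min(scorer.score(s) for s in seeds)
    while True:
        seen, queue = {}, []
        for s in seeds:
            if scorer.score(s) == best:
                key = _bipart_key(s, n)
                if key not in seen:
                    seen[key] = s
                    queue.append(s)
        overflow = False
        restart = False
        while queue:
            adj = queue.pop()
            for nb in neighbors(adj, n, kind):
                length = scorer.score(nb, best)
                if length < best:
                    best, seeds, restart = length, [nb], True
                    break
                if length == best:
                    key = _bipart_key(nb, n)
                    if key not in seen:
                        if len(seen) >= max_trees:
                            overflow = True
                            continue
                        seen[key] = nb
                        queue.append(nb)
            if restart:
                break
        if not restart:
            return best, list(seen.values()), overflow


# ---------------------------------------------------------------------------
# collapsing / deduplication
# ---------------------------------------------------------------------------

def collapse_unsupported(tree: PhyloTree, matrix: CharacterMatrix) -> PhyloTree:
    """Contract every internal branch that no character is forced to change
    on in at least one optimal reconstruction (minimum branch length zero).
    The result may be multifurcating."""
    lengths = branch_min_lengths(tree, matrix)
    kept = [side for side, forced in lengths.items() if forced > 0]
    return tree_from_bipartitions(tree.taxa, kept)


def dedupe(trees: Iterable[PhyloTree]) -> list:
    """One representative per distinct bipartition set, in a deterministic
    (canonical newick) order."""
    trees = list(trees)
    if not trees:
        return []
    leafset = set(trees[0].taxa)
    seen = {}
    for t in trees:
        if set(t.taxa) != leafset:
            raise ValueError("trees are over different leaf sets")
        seen.setdefault(t.bipartitions(), t)
    return sorted(seen.values(), key=lambda t: t.to_newick())


def _to_trees(adjs: Iterable[dict], taxa: Sequence[str], n: int) -> list:
    out = []
    for adj in adjs:
        labels = {v: taxa[v] for v in adj if v < n}
        out.append(PhyloTree(adj, labels))
    return out


def _finish(matrix: CharacterMatrix, best: int, best_adjs: list,
            log: dict, exhaustive: bool) -> SearchResult:
    binary = dedupe(_to_trees(best_adjs, matrix.taxa, matrix.n_taxa))
    collapsed = dedupe(collapse_unsupported(t, matrix) for t in binary)
    log = dict(log)
    log["n_binary_mpts"] = len(binary)
    log["n_collapsed_mpts"] = len(collapsed)
    return SearchResult(best_length=int(best), mpt_set=tuple(collapsed),
                        binary_mpt_set=tuple(binary), log=log,
                        exhaustive=exhaustive)


# ---------------------------------------------------------------------------
# exact search
# ---------------------------------------------------------------------------

def branch_and_bound(matrix: CharacterMatrix, ceiling: int = 14) -> SearchResult:
    """Exact search by stepwise addition with pruning; returns all
    minimal-length resolved topologies.  Refuses matrices above ``ceiling``
    taxa (the tree space grows as (2n-5)!!) — use :func:`heuristic_search`
    there."""
    n = matrix.n_taxa
    if n < 3:
        raise ValueError("branch_and_bound needs at least 3 taxa")
    if n > ceiling:
        raise ValueError(
            f"{n} taxa exceeds the exact-search ceiling of {ceiling}; "
            "use heuristic_search for matrices this large")
    scorer = MatrixScorer(matrix)

    # per-addition-step lower-bound increments: a state required by a
    # still-unplaced taxon and absent from every cell already placed (or any
    # other unplaced) must eventually cost one extra step.
    k = matrix.n_characters
    extra = np.zeros(n + 1, dtype=np.int64)
    for j in range(k):
        col = matrix.column(j)
        for placed in range(3, n):
            seen = set().union(*(col[i].states for i in range(placed)))
            required = set()
            for i in range(placed, n):
                if len(col[i].states) == 1:
                    required |= col[i].states
            extra[placed] += len(required - seen)

    hub = n
    base = {0: [hub], 1: [hub], 2: [hub], hub: [0, 1, 2]}
    greedy = _stepwise(list(range(n)), scorer)
    incumbent = scorer.score(greedy)
    best_adjs = [greedy]
    n_visited = 0

    def recurse(adj: dict, placed: int, nxt: int) -> None:
        nonlocal incumbent, best_adjs, n_visited
        for edge in _edges(adj):
            cand = _add_leaf(adj, n, placed, edge, nxt)
            n_visited += 1
            length = scorer.score(cand, incumbent)
            if placed + 1 == n:
                if length < incumbent:
                    incumbent, best_adjs = length, [cand]
                elif length == incumbent:
                    best_adjs.append(cand)
            else:
                if length + extra[placed + 1] <= incumbent:
                    recurse(cand, placed + 1, nxt + 1)

    if n == 3:
        incumbent, best_adjs = scorer.score(base), [base]
    else:
        recurse(base, 3, n + 1)
    log = {"method": "branch_and_bound", "trees_visited": n_visited,
           "best_length": int(incumbent)}
    return _finish(matrix, incumbent, best_adjs, log, exhaustive=True)


# ---------------------------------------------------------------------------
# heuristic search
# ---------------------------------------------------------------------------

def heuristic_search(matrix: CharacterMatrix,
                     config: SearchConfig | None = None) -> SearchResult:
    """Random-addition + branch-swapping search over the full matrix."""
    if config is None:
        config = SearchConfig()
    n = matrix.n_taxa
    if n < 4:
        raise ValueError("heuristic_search needs at least 4 taxa")
    scorer = MatrixScorer(matrix)
    rng = np.random.default_rng(config.seed)
    kind = config.swap.upper()

    replicates = []
    local_optima = []
    for rep in range(config.n_replicates):
        order = [int(x) for x in rng.permutation(n)]
        adj = _stepwise(order, scorer)
        adj, length = _descend(adj, scorer, kind)
        local_optima.append((length, adj))
        replicates.append({"replicate": rep, "addition_order": order,
                           "length": int(length)})

    best_rep = min(length for length, _ in local_optima)
    seeds = [adj for length, adj in local_optima if length == best_rep]
    best, best_adjs, overflow = _close_island(seeds, scorer, kind,
                                              config.max_trees_held)
    log = {
        "method": "heuristic_search",
        "seed": config.seed,
        "swap": kind,
        "n_replicates": config.n_replicates,
        "replicates": replicates,
        "replicate_best": int(best_rep),
        "max_trees_held": config.max_trees_held,
        "overflow": overflow,
    }
    return _finish(matrix, best, best_adjs, log, exhaustive=not overflow)
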