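"""Unrooted phylogenetic trees over taxon labels.

Identity is topological: two trees are equal iff they are over the same leaf
set and induce the same set of non-trivial bipartitions.  Internal nodes of a
fully resolved tree have degree 3; consensus trees may be multifurcating.

Internally a tree is an adjacency map over integer node ids with leaves
``0 .. n-1`` in sorted-taxon order; the representation is private but shared
with the scoring and search engines in this package.
"""

from __future__ import annotations

import itertools
import re
from typing import Iterable, Iterator, Sequence

__all__ = ["PhyloTree", "tree_from_bipartitions", "enumerate_topologies",
           "random_topology"]


class PhyloTree:
    """Unrooted (multifurcating) tree over unique taxon labels, ``n >= 3``."""

    __slots__ = ("taxa", "_adj", "_biparts")

    def __init__(self, adj: dict, labels: dict):
        """Build from an adjacency map ``node -> iterable of nodes`` and a
        ``leaf node -> taxon label`` map; node ids are renumbered so leaves
        are ``0..n-1`` in sorted-label order."""
        taxa = sorted(labels.values())
        if len(set(taxa)) != len(taxa):
            raise ValueError("duplicate taxon labels")
        if len(taxa) < 3:
            raise ValueError("a PhyloTree needs at least 3 leaves")
        old_leaf = {lab: node for node, lab in labels.items()}
        remap = {old_leaf[lab]: i for i, lab in enumerate(taxa)}
        nxt = len(taxa)
        for node in sorted(adj):
            if node not in remap:
                remap[node] = nxt
                nxt += 1
        new_adj = {}
        for node, nbrs in adj.items():
            new_adj[remap[node]] = tuple(sorted(remap[v] for v in nbrs))
        n = len(taxa)
        for node, nbrs in new_adj.items():
            deg = len(nbrs)
            if node < n and deg != 1:
                raise ValueError(f"leaf {taxa[node]!r} has degree {deg}")
            if node >= n and deg < 3:
                raise ValueError(f"internal node of degree {deg} (must be >= 3)")
        # connectivity
        seen = {0}
        stack = [0]
        while stack:
            for v in new_adj[stack.pop()]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        if len(seen) != len(new_adj):
            raise ValueError("adjacency is not connected")
        self.taxa = tuple(taxa)
        self._adj = new_adj
        self._biparts = None

    # -- basic properties --------------------------------------------------

    @property
    def n_leaves(self) -> int:
        return len(self.taxa)

    @property
    def is_resolved(self) -> bool:
        n = self.n_leaves
        return all(len(nbrs) == 3 for node, nbrs in self._adj.items() if node >= n)

    def _subtree_leaves(self, child: int, parent: int) -> frozenset:
        n = self.n_leaves
        out = set()
        stack = [(child, parent)]
        while stack:
            v, p = stack.pop()
            if v < n:
                out.add(self.taxa[v])
            else:
                stack.extend((w, v) for w in self._adj[v] if w != p)
        return frozenset(out)

    def bipartitions(self) -> frozenset:
        """Non-trivial bipartitions, each encoded as the side that does not
        contain the smallest taxon label."""
        if self._biparts is None:
            n = self.n_leaves
            anchor = self.taxa[0]
            out = set()
            for u in self._adj:
                for v in self._adj[u]:
                    if u < v and u >= n and v >= n:  # internal edge
                        side = self._subtree_leaves(v, u)
                        if anchor in side:
                            side = frozenset(self.taxa) - side
                        if 2 <= len(side) <= n - 2:
                            out.add(side)
            self._biparts = frozenset(out)
        return self._biparts

    def clades(self, outgroup: str) -> frozenset:
        """Bipartition sides read as clades when the tree is rooted on the
        pendant edge of ``outgroup``: for each bipartition, the side not
        containing the outgroup."""
        if outgroup not in self.taxa:
            raise KeyError(f"outgroup {outgroup!r} not in tree")
        full = frozenset(self.taxa)
        out = set()
        for side in self.bipartitions():
            out.add(side if outgroup not in side else full - side)
        return frozenset(out)

    def has_clade(self, terminals: Iterable[str], outgroup: str) -> bool:
        term = frozenset(terminals)
        if len(term) <= 1 or term == frozenset(self.taxa) - {outgroup}:
            return term <= frozenset(self.taxa)
        return term in self.clades(outgroup)

    def __eq__(self, other) -> bool:
        if not isinstance(other, PhyloTree):
            return NotImplemented
        return self.taxa == other.taxa and self.bipartitions() == other.bipartitions()

    def __hash__(self) -> int:
        return hash((self.taxa, self.bipartitions()))

    def __repr__(self) -> str:
        return f"<PhyloTree {self.n_leaves} leaves, {len(self.bipartitions())} internal splits>"

    # -- newick ------------------------------------------------------------

    @staticmethod
    def _escape(label: str) -> str:
        out = label.replace(" ", "_")
        if re.fullmatch(r"[\w.\-]+", out):
            return out
        return "'" + label.replace("'", "''") + "'"

    def to_newick(self) -> str:
        """Canonical newick: rooted for display at the neighbor of the
        smallest-label leaf, children ordered by smallest descendant label,
        spaces in labels written as underscores."""
        n = self.n_leaves
        root = self._adj[0][0]

        def key(v: int, p: int) -> str:
            return min(self._subtree_leaves(v, p))

        def render(v: int, p: int) -> str:
            if v < n:
                return self._escape(self.taxa[v])
            kids = sorted((w for w in self._adj[v] if w != p),
                          key=lambda w: key(w, v))
            return "(" + ",".join(render(w, v) for w in kids) + ")"

        kids = sorted(self._adj[root], key=lambda w: key(w, root))
        return "(" + ",".join(render(w, root) for w in kids) + ");"

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        import dendropy

        try:
            dtree = dendropy.Tree.get(data=text, schema="newick")
        except Exception as exc:
            raise ValueError(f"newick parse failed: {exc}") from None
        adj: dict = {}
        labels: dict = {}
        ids: dict = {}

        def nid(nd) -> int:
            if id(nd) not in ids:
                ids[id(nd)] = len(ids)
                adj[ids[id(nd)]] = []
            return ids[id(nd)]

        for nd in dtree.preorder_node_iter():
            i = nid(nd)
            if nd.is_leaf():
                labels[i] = nd.taxon.label if nd.taxon else (nd.label or "")
            for ch in nd.child_nodes():
                j = nid(ch)
                adj[i].append(j)
                adj[j].append(i)
        # suppress degree-2 nodes (e.g. a rooted newick's root)
        for node in [v for v, nb in adj.items() if len(nb) == 2 and v not in labels]:
            a, b = adj[node]
            adj[a] = [b if x == node else x for x in adj[a]]
            adj[b] = [a if x == node else x for x in adj[b]]
            del adj[node]
        return cls(adj, labels)


def tree_from_bipartitions(taxa: Sequence[str], biparts: Iterable[frozenset]) -> PhyloTree:
    """Build the (possibly multifurcating) tree exhibiting exactly the given
    mutually compatible non-trivial bipartitions."""
    taxa = tuple(sorted(taxa))
    anchor = taxa[0]
    full = frozenset(taxa)
    clades = set()
    for side in biparts:
        side = frozenset(side)
        if anchor in side:
            side = full - side
        if not 2 <= len(side) <= len(taxa) - 2:
            raise ValueError(f"trivial or invalid bipartition side {sorted(side)}")
        if not side <= full:
            raise ValueError("bipartition mentions taxa outside the leaf set")
        clades.add(side)
    for a, b in itertools.combinations(clades, 2):
        if a & b and not (a <= b or b <= a):
            raise ValueError("incompatible bipartitions")

    leaf_id = {t: i for i, t in enumerate(taxa)}
    nxt = len(taxa)
    adj: dict = {}

    def add_edge(u: int, v: int) -> None:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)

    root = nxt
    nxt += 1
    adj[root] = []
    node_of: dict = {}
    for clade in sorted(clades, key=lambda c: (-len(c), sorted(c))):
        node_of[clade] = nxt
        adj[nxt] = []
        nxt += 1
    # attach each clade to its minimal strict superset (or the root)
    for clade in sorted(clades, key=lambda c: (-len(c), sorted(c))):
        supersets = [c for c in clades if clade < c]
        parent = node_of[min(supersets, key=len)] if supersets else root
        add_edge(parent, node_of[clade])
    for t in taxa:
        if t == anchor:
            add_edge(root, leaf_id[t])
            continue
        containing = [c for c in clades if t in c]
        parent = node_of[min(containing, key=len)] if containing else root
        add_edge(parent, leaf_id[t])
    return PhyloTree(adj, {i: t for t, i in leaf_id.items()})


def _add_leaf(adj: dict, labels_n: int, new_leaf: int, edge: tuple, nxt: int) -> dict:
    """Return a copy of ``adj`` with ``new_leaf`` attached mid-edge."""
    u, v = edge
    new = {k: list(vs) for k, vs in adj.items()}
    w = nxt
    new[u] = [w if x == v else x for x in new[u]]
    new[v] = [w if x == u else x for x in new[v]]
    new[w] = [u, v, new_leaf]
    new[new_leaf] = [w]
    return new


def _edges(adj: dict) -> list:
    return [(u, v) for u in sorted(adj) for v in adj[u] if u < v]


def enumerate_topologies(taxa: Sequence[str]) -> Iterator[PhyloTree]:
    """Yield every distinct unrooted (binary) topology over the taxa:
    ``(2n-5)!!`` trees, by sequential leaf addition."""
    taxa = sorted(taxa)
    n = len(taxa)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    labels = {i: t for i, t in enumerate(taxa)}
    base = {0: [n], 1: [n], 2: [n], n: [0, 1, 2]}

    def grow(adj: dict, k: int, nxt: int) -> Iterator[dict]:
        if k == n:
            yield adj
            return
        for edge in _edges(adj):
            yield from grow(_add_leaf(adj, n, k, edge, nxt), k + 1, nxt + 1)

    for adj in grow(base, 3, n + 1):
        yield PhyloTree(adj, labels)


def random_topology(taxa: Sequence[str], rng) -> PhyloTree:
    """Uniform random unrooted binary topology (sequential addition with a
    uniformly chosen insertion edge at every step)."""
    taxa = sorted(taxa)
    n = len(taxa)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    adj = {0: [n], 1: [n], 2: [n], n: [0, 1, 2]}
    nxt = n + 1
    for k in range(3, n):
        edges = _edges(adj)
        edge = edges[rng.integers(len(edges))]
        adj = _add_leaf(adj, n, k, edge, nxt)
        nxt += 1
    return PhyloTree(adj, {i: t for i, t in enumerate(taxa)})
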