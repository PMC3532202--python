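"""Unrooted binary phylogenetic trees with branch lengths.

The likelihood and tree-search machinery in this package works on a compact
adjacency representation: tips are numbered ``0..n-1`` in the order of
``taxa`` (sorted labels), internal nodes take the remaining ids, and every
internal node has degree three.  Newick parsing and rooted display views go
through :mod:`dendropy`.
"""
from __future__ import annotations

import dendropy

MIN_BLEN = 1e-8
MAX_BLEN = 10.0


def edge_key(u: int, v: int) -> tuple[int, int]:
    """Canonical (sorted) key for the undirected edge {u, v}."""
    return (u, v) if u < v else (v, u)


class TreeError(ValueError):
    pass


class PhyloTree:
    """Unrooted binary tree over named tips, with branch lengths.

    Parameters
    ----------
    taxa:
        Tip labels; tip node ``i`` carries ``taxa[i]``.
    nbr:
        Adjacency mapping ``node -> list of neighbour nodes``.
    lengths:
        Mapping ``edge_key(u, v) -> branch length`` (>= 0).
    """

    __slots__ = ("taxa", "nbr", "lengths")

    def __init__(self, taxa, nbr, lengths, validate: bool = True):
        self.taxa = tuple(taxa)
        self.nbr = {u: list(vs) for u, vs in nbr.items()}
        self.lengths = dict(lengths)
        if validate:
            self.validate()

    # ------------------------------------------------------------------ basics
    @property
    def n_tips(self) -> int:
        return len(self.taxa)

    @property
    def nodes(self):
        return list(self.nbr)

    def edges(self):
        """All undirected edges as canonical (u, v) keys."""
        return list(self.lengths)

    def internal_edges(self):
        n = self.n_tips
        return [(u, v) for (u, v) in self.lengths if u >= n and v >= n]

    def length(self, u: int, v: int) -> float:
        return self.lengths[edge_key(u, v)]

    def set_length(self, u: int, v: int, t: float) -> None:
        if t < 0:
            raise TreeError(f"negative branch length {t}")
        self.lengths[edge_key(u, v)] = t

    def copy(self) -> "PhyloTree":
        return PhyloTree(self.taxa, self.nbr, self.lengths, validate=False)

    def validate(self) -> None:
        n = self.n_tips
        if n < 2:
            raise TreeError("need at least 2 tips")
        if len(set(self.taxa)) != n:
            raise TreeError("tip labels must be unique")
        for u, vs in self.nbr.items():
            deg = len(vs)
            if u < n and deg != 1:
                raise TreeError(f"tip {u} has degree {deg}")
            if u >= n and deg != 3:
                raise TreeError(f"internal node {u} has degree {deg}")
            for v in vs:
                if u not in self.nbr.get(v, ()):
                    raise TreeError("asymmetric adjacency")
                if edge_key(u, v) not in self.lengths:
                    raise TreeError(f"missing length for edge {u},{v}")
        n_edges_expected = 2 * n - 3 if n >= 3 else 1
        if len(self.lengths) != n_edges_expected:
            raise TreeError(
                f"{len(self.lengths)} edges, expected {n_edges_expected}"
            )

    # -------------------------------------------------------------- traversal
    def postorder_edges(self, start_tip: int = 0):
        """Directed edges (child-side first) of a DFS rooted at ``start_tip``'s
        neighbour; yields (u, v) meaning "u seen from v" in post-order."""
        root = self.nbr[start_tip][0]
        out = []
        stack = [(root, None)]
        while stack:
            node, parent = stack.pop()
            if parent is not None:
                out.append((node, parent))
            for w in self.nbr[node]:
                if w != parent:
                    stack.append((w, node))
        out.reverse()
        return out

    def tipset_sides(self) -> dict:
        """For every directed edge (u, v) the bitmask of tips on u's side."""
        full = (1 << self.n_tips) - 1
        sides: dict[tuple[int, int], int] = {}
        for (u, v) in self.postorder_edges():
            if u < self.n_tips:
                sides[(u, v)] = 1 << u
            else:
                m = 0
                for w in self.nbr[u]:
                    if w != v:
                        m |= sides[(w, u)]
                sides[(u, v)] = m
        # fill the reverse directions
        for (u, v) in list(sides):
            sides[(v, u)] = full & ~sides[(u, v)]
        # some reverse directions may themselves be needed directly
        for (u, v) in self.lengths:
            if (u, v) not in sides:
                sides[(u, v)] = full & ~sides[(v, u)]
        return sides

    def bipartition_set(self) -> set[frozenset]:
        """Non-trivial bipartitions as frozensets of tip labels, each given
        as the side not containing the lexicographically smallest label."""
        ref = min(range(self.n_tips), key=lambda i: self.taxa[i])
        sides = self.tipset_sides()
        out = set()
        for (u, v) in self.internal_edges():
            m = sides[(u, v)]
            if m >> ref & 1:
                m = ((1 << self.n_tips) - 1) & ~m
            out.add(frozenset(self.taxa[i] for i in range(self.n_tips) if m >> i & 1))
        return out

    def has_bipartition(self, labels: frozenset) -> bool:
        """True iff some branch (incl. pendant) separates ``labels`` exactly."""
        idx = {t: i for i, t in enumerate(self.taxa)}
        try:
            want = 0
            for lab in labels:
                want |= 1 << idx[lab]
        except KeyError as e:
            raise TreeError(f"unknown taxon {e.args[0]!r}") from None
        full = (1 << self.n_tips) - 1
        comp = full & ~want
        sides = self.tipset_sides()
        for (u, v) in self.lengths:
            m = sides[(u, v)]
            if m == want or m == comp:
                return True
        return False

    # ----------------------------------------------------------------- newick
    def to_newick(self, lengths: bool = True, precision: int = 6) -> str:
        """Canonical Newick: rooted for writing at the neighbour of the
        lexicographically smallest tip, children sorted by smallest
        descendant label.  Deterministic; used for tie-breaking."""
        n = self.n_tips
        ref = min(range(n), key=lambda i: self.taxa[i])
        fmt = (lambda t: f":{t:.{precision}f}") if lengths else (lambda t: "")
        if n == 2:
            a, b = sorted(self.taxa)
            return f"({a}{fmt(self.length(0, 1))},{b}{fmt(0.0)});"

        def rec(node, parent):
            if node < n:
                return self.taxa[node], self.taxa[node]
            parts = []
            for w in self.nbr[node]:
                if w == parent:
                    continue
                ml, s = rec(w, node)
                parts.append((ml, s + fmt(self.length(node, w))))
            parts.sort()
            return parts[0][0], "(" + ",".join(p[1] for p in parts) + ")"

        root = self.nbr[ref][0]
        parts = [(self.taxa[ref], self.taxa[ref] + fmt(self.length(ref, root)))]
        for w in self.nbr[root]:
            if w == ref:
                continue
            ml, s = rec(w, root)
            parts.append((ml, s + fmt(self.length(root, w))))
        parts.sort()
        return "(" + ",".join(p[1] for p in parts) + ");"

    def topology_id(self) -> str:
        """Length-free canonical Newick (identical iff same unrooted topology)."""
        return self.to_newick(lengths=False)

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        dtree = dendropy.Tree.get(
            data=newick, schema="newick", suppress_internal_node_taxa=True
        )
        return cls.from_dendropy(dtree)

    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree) -> "PhyloTree":
        dtree = dtree.clone(depth=1)
        dtree.resolve_polytomies()
        if len(dtree.seed_node.child_nodes()) == 2 and len(dtree.leaf_nodes()) > 2:
            dtree.deroot()
        labels = sorted(
            lf.taxon.label if lf.taxon else lf.label for lf in dtree.leaf_node_iter()
        )
        idx = {lab: i for i, lab in enumerate(labels)}
        n = len(labels)
        next_id = n
        node_id = {}
        for nd in dtree.preorder_node_iter():
            if nd.is_leaf():
                node_id[nd] = idx[nd.taxon.label if nd.taxon else nd.label]
            else:
                node_id[nd] = next_id
                next_id += 1
        nbr: dict[int, list[int]] = {i: [] for i in node_id.values()}
        lengths = {}
        for nd in dtree.preorder_node_iter():
            p = nd.parent_node
            if p is None:
                continue
            u, v = node_id[nd], node_id[p]
            nbr[u].append(v)
            nbr[v].append(u)
            t = nd.edge.length
            lengths[edge_key(u, v)] = max(float(t) if t is not None else 0.0, 0.0)
        return cls(labels, nbr, lengths)

    def to_dendropy(self, taxon_namespace=None) -> dendropy.Tree:
        return dendropy.Tree.get(
            data=self.to_newick(),
            schema="newick",
            taxon_namespace=taxon_namespace,
        )

    def __repr__(self):
        return f"PhyloTree({self.n_tips} tips)"
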