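"""Counting independent evolutionary origins of resistance classes.

Works on rooted display trees (midpoint- or outgroup-rooted).  Two
complementary summaries are reported per resistance class:

* the number of *maximal* clades whose tips all carry the class (a clade is
  maximal when its parent clade contains a non-class tip), and
* the minimum number of susceptible->resistant gains over ancestral
  labelings, computed by a Sankoff-style dynamic program in which a stem
  lineage above the root is pinned to the non-focal (susceptible) state.
  The DP minimizes (total state changes, gains) lexicographically, so the
  gain count refers to a most-parsimonious reconstruction; the
  unconstrained (free-root, gains+losses) minimum change count is reported
  alongside.

Because midpoint rooting is a display convention, clade counts can also be
swept over every possible root placement to expose root sensitivity.
"""
from __future__ import annotations

from dataclasses import dataclass

import dendropy

from .haplotypes import RESISTANT_CLASSES
from .trees import PhyloTree

_INF = float("inf")


@dataclass
class GainCount:
    """Parsimony summary for one focal class on one rooted tree."""

    gains: int                 # 0->1 transitions, stem pinned to non-focal
    total_changes: int         # changes in that same optimal labeling
    unconstrained_changes: int  # free-root minimum (gains + losses)


def _states_for_tree(tree: dendropy.Tree, states: dict) -> None:
    missing = [
        lf.taxon.label for lf in tree.leaf_node_iter() if lf.taxon.label not in states
    ]
    if missing:
        raise ValueError(f"tip states missing for: {missing[:5]}")


def count_maximal_clades(
    tree: dendropy.Tree, states: dict, focal: str
) -> tuple[int, list]:
    """Number (and tip sets) of maximal all-``focal`` clades on a rooted tree.

    A tip whose state is ``focal`` and whose parent clade is not pure counts
    as a clade of size one.  Absent classes give ``(0, [])``.
    """
    _states_for_tree(tree, states)
    pure: dict = {}
    tipsets: dict = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            lab = nd.taxon.label
            pure[nd] = states[lab] == focal
            tipsets[nd] = frozenset([lab])
        else:
            ch = nd.child_nodes()
            pure[nd] = all(pure[c] for c in ch)
            tipsets[nd] = frozenset().union(*(tipsets[c] for c in ch))
    clades = []
    for nd in tree.preorder_node_iter():
        par = nd.parent_node
        if pure[nd] and (par is None or not pure[par]):
            clades.append(tipsets[nd])
    return len(clades), clades


def min_gains(tree: dendropy.Tree, states: dict, focal: str) -> GainCount:
    """Minimum-change ancestral reconstruction with a susceptible stem.

    States are binarized to focal (1) versus everything else (0).  A stem
    ancestor above the root is fixed at 0, encoding the assumption that
    susceptibility is ancestral; the DP then minimizes total changes and,
    among those optima, the number of 0->1 gains.
    """
    _states_for_tree(tree, states)

    # cost[node][s] = (total changes, gains) below node given node state s
    cost: dict = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            obs = 1 if states[nd.taxon.label] == focal else 0
            cost[nd] = [
                (0, 0) if s == obs else (_INF, _INF) for s in (0, 1)
            ]
        else:
            out = []
            for s in (0, 1):
                tot = 0.0
                gn = 0.0
                for c in nd.child_nodes():
                    best = min(
                        (
                            cost[c][cs][0] + (1 if cs != s else 0),
                            cost[c][cs][1] + (1 if (s == 0 and cs == 1) else 0),
                        )
                        for cs in (0, 1)
                    )
                    tot += best[0]
                    gn += best[1]
                out.append((tot, gn))
            cost[nd] = out
    root = tree.seed_node
    # stem edge from a fixed susceptible ancestor to the root
    stem = min(
        (cost[root][s][0] + (1 if s == 1 else 0),
         cost[root][s][1] + (1 if s == 1 else 0))
        for s in (0, 1)
    )
    free = min(cost[root][s][0] for s in (0, 1))
    return GainCount(
        gains=int(stem[1]),
        total_changes=int(stem[0]),
        unconstrained_changes=int(free),
    )


def clade_counts_over_rootings(
    tree: PhyloTree, states: dict, focal: str
) -> tuple[int, int]:
    """(min, max) of the maximal-clade count across all root placements.

    Midpoint rooting is display-only, so origin counts quoted from a rooted
    view carry a root-choice sensitivity; this sweep makes it explicit.
    """
    n = tree.n_tips
    is_focal = []
    for i, lab in enumerate(tree.taxa):
        if lab not in states:
            raise ValueError(f"tip states missing for: {lab!r}")
        is_focal.append(states[lab] == focal)

    post = tree.postorder_edges()
    pure: dict = {}
    for (u, v) in post:
        if u < n:
            pure[(u, v)] = is_focal[u]
        else:
            pure[(u, v)] = all(pure[(w, u)] for w in tree.nbr[u] if w != v)
    for (u, v) in reversed(post):
        if (v, u) not in pure:
            pure[(v, u)] = all(pure[(w, v)] for w in tree.nbr[v] if w != u)

    count: dict = {}

    def maximal_count(u, v):
        # number of maximal pure subtrees inside the subtree at u away from v
        if (u, v) in count:
            return count[(u, v)]
        if pure[(u, v)]:
            c = 1
        elif u < n:
            c = 0
        else:
            c = sum(maximal_count(w, u) for w in tree.nbr[u] if w != v)
        count[(u, v)] = c
        return c

    totals = [
        maximal_count(u, v) + maximal_count(v, u) for (u, v) in tree.lengths
    ]
    return min(totals), max(totals)


@dataclass
class OriginReport:
    """Per-class origin summary on one rooted display tree."""

    clade_counts: dict      # class -> number of maximal clades
    clades: dict            # class -> list of tip frozensets
    gains: dict             # class -> GainCount
    root_sensitivity: dict  # class -> (min, max) clade count over rootings


def origin_report(
    rooted: dendropy.Tree,
    unrooted: PhyloTree,
    states: dict,
    classes=RESISTANT_CLASSES,
) -> OriginReport:
    counts, clades, gains, sens = {}, {}, {}, {}
    for cls in classes:
        k, cl = count_maximal_clades(rooted, states, cls)
        counts[cls] = k
        clades[cls] = cl
        gains[cls] = min_gains(rooted, states, cls) if k else GainCount(0, 0, 0)
        sens[cls] = (
            clade_counts_over_rootings(unrooted, states, cls) if k else (0, 0)
        )
    return OriginReport(counts, clades, gains, sens)


def derive_sequential_pairs(catalog) -> list:
    """Pair every super-kdr haplotype with the kdr haplotypes sharing its
    intron-identity group (evidence for sequential evolution of super-kdr
    from a kdr background).  Unpaired super-kdr haplotypes get an empty
    partner list.
    """
    groups = catalog.intron_groups()
    cls_of = {rec.name: rec.allele_class for rec in catalog}
    pairs = []
    for group in groups:
        sks = sorted(n for n in group if cls_of[n] == "super-kdr")
        kdrs = sorted(n for n in group if cls_of[n] == "kdr")
        for sk in sks:
            pairs.append((sk, kdrs))
    pairs.sort()
    return pairs
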