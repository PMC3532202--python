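"""Independent brute-force oracles used to validate the fast implementations.

Everything here is deliberately naive: likelihoods by exhaustive enumeration
of interior states, topology sets by sequential edge insertion, parsimony by
enumerating every ancestral labeling.  None of it shares code with the
package's dynamic programs.
"""
from __future__ import annotations

import itertools

import numpy as np

from kdrphylo.phylo_models import IUPAC, transition_matrix
from kdrphylo.trees import PhyloTree, edge_key


def brute_force_loglik(tree: PhyloTree, alignment, model) -> float:
    """Sum over all interior-state assignments, site by site."""
    rates = model.category_rates()
    pi = model.pi
    n = tree.n_tips
    internals = [x for x in tree.nodes if x >= n]
    row = {t: i for i, t in enumerate(alignment.taxa)}

    def tip_states(i, s):
        ch = alignment.sequences[row[tree.taxa[i]]][s]
        return IUPAC[ch]

    total = 0.0
    for s in range(alignment.n_sites):
        if not alignment.mask[s]:
            continue
        site = 0.0
        for r in rates:
            Ps = {e: transition_matrix(model, tree.lengths[e], r) for e in tree.lengths}
            if not internals:  # two-taxon tree
                lik = sum(
                    pi[a] * Ps[(0, 1)][a, b]
                    for a in tip_states(0, s)
                    for b in tip_states(1, s)
                )
            else:
                lik = 0.0
                for assign in itertools.product(range(4), repeat=len(internals)):
                    st = dict(zip(internals, assign))
                    prod = pi[st[internals[0]]]
                    for (u, v) in tree.lengths:
                        P = Ps[(u, v)]
                        if u < n and v < n:
                            raise AssertionError("tip-tip edge in >2-taxon tree")
                        elif u < n:
                            prod *= sum(P[st[v], a] for a in tip_states(u, s))
                        elif v < n:
                            prod *= sum(P[st[u], a] for a in tip_states(v, s))
                        else:
                            prod *= P[st[u], st[v]]
                    lik += prod
            site += lik / len(rates)
        total += np.log(site)
    return float(total)


def enumerate_topologies(taxa, blen: float = 0.1):
    """All unrooted binary topologies over ``taxa`` (3, 15, 105, ... trees)."""
    taxa = list(taxa)
    n = len(taxa)
    assert n >= 4
    states = [({0: [n], 1: [n], 2: [n], n: [0, 1, 2]},
               {(0, n): blen, (1, n): blen, (2, n): blen}, n + 1)]
    for tip in range(3, n):
        new = []
        for nbr, lens, nxt in states:
            for (u, v) in list(lens):
                nbr2 = {k: list(vs) for k, vs in nbr.items()}
                lens2 = dict(lens)
                w = nxt
                nbr2[u][nbr2[u].index(v)] = w
                nbr2[v][nbr2[v].index(u)] = w
                nbr2[w] = [u, v, tip]
                nbr2[tip] = [w]
                del lens2[edge_key(u, v)]
                for e in ((u, w), (v, w), (tip, w)):
                    lens2[edge_key(*e)] = blen
                new.append((nbr2, lens2, nxt + 1))
        states = new
    return [PhyloTree(taxa, nbr, lens) for nbr, lens, _ in states]


def random_unrooted_tree(n, rng, scale=0.1, floor=0.005, taxa=None):
    """Random topology by uniform sequential edge insertion, exponential
    branch lengths."""
    taxa = list(taxa) if taxa is not None else [f"t{i:02d}" for i in range(n)]
    nbr = {0: [n], 1: [n], 2: [n], n: [0, 1, 2]}
    lens = {(0, n): 1.0, (1, n): 1.0, (2, n): 1.0}
    nxt = n + 1
    for tip in range(3, n):
        u, v = list(lens)[rng.integers(len(lens))]
        w = nxt
        nxt += 1
        nbr[u].remove(v)
        nbr[v].remove(u)
        nbr[u].append(w)
        nbr[v].append(w)
        nbr[w] = [u, v, tip]
        nbr[tip] = [w]
        del lens[edge_key(u, v)]
        for e in ((u, w), (v, w), (tip, w)):
            lens[edge_key(*e)] = 1.0
    for k in lens:
        lens[k] = float(rng.exponential(scale)) + floor
    return PhyloTree(taxa, nbr, lens)


def exhaustive_gain_count(rooted, states, focal):
    """Minimum (total changes, gains) over all ancestral labelings with a
    stem ancestor fixed at non-focal; returns (gains, total, free_root_min)."""
    internals = [nd for nd in rooted.preorder_node_iter() if not nd.is_leaf()]
    leaves = list(rooted.leaf_node_iter())
    best = (float("inf"), float("inf"))
    free = float("inf")
    for assign in itertools.product((0, 1), repeat=len(internals)):
        lab = dict(zip(internals, assign))
        for lf in leaves:
            lab[lf] = 1 if states[lf.taxon.label] == focal else 0
        changes = gains = 0
        for nd in rooted.preorder_node_iter():
            p = nd.parent_node
            if p is None:
                continue
            if lab[p] != lab[nd]:
                changes += 1
                if lab[nd] == 1:
                    gains += 1
        free = min(free, changes)
        root_s = lab[rooted.seed_node]
        stem_changes = changes + (1 if root_s == 1 else 0)
        stem_gains = gains + (1 if root_s == 1 else 0)
        best = min(best, (stem_changes, stem_gains))
    return best[1], best[0], free


def exhaustive_maximal_clades(rooted, states, focal):
    """Scan every node; count those whose tips are all focal while the
    parent's tips are not."""
    def tips(nd):
        return [lf.taxon.label for lf in nd.leaf_iter()]

    def pure(nd):
        return all(states[t] == focal for t in tips(nd))

    out = []
    for nd in rooted.preorder_node_iter():
        if pure(nd) and (nd.parent_node is None or not pure(nd.parent_node)):
            out.append(frozenset(tips(nd)))
    return len(out), out
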