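"""Heuristic maximum-likelihood topology search.

Replicated random-addition starting trees (greedy parsimony placement)
followed by NNI hill climbing with branch-length re-optimization, optionally
under a monophyly constraint (the resistant-alleles-single-origin
hypothesis).  Constraint enforcement is by rejection: starting trees are
built constraint-compatible and only constraint-preserving rearrangements
are accepted, which is sound for a single monophyly constraint because NNI
changes exactly one bipartition (the central edge's).

Also provides nonparametric bootstrap support and midpoint rooting for
display.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np

from .phylo_models import IUPAC, Alignment, SubstModel, TreeLikelihood
from .trees import MIN_BLEN, PhyloTree, edge_key


logger = logging.getLogger(__name__)


class SearchError(ValueError):
    pass


@dataclass(frozen=True)
class ConstraintSpec:
    """A set of tip labels required to be monophyletic (unrooted sense)."""

    taxa: frozenset

    def __post_init__(self):
        object.__setattr__(self, "taxa", frozenset(self.taxa))
        if not self.taxa:
            raise SearchError("constraint set must be non-empty")

    def validate_against(self, labels) -> None:
        labels = set(labels)
        unknown = self.taxa - labels
        if unknown:
            raise SearchError(f"constraint names unknown taxa: {sorted(unknown)}")
        if self.taxa == labels:
            raise SearchError("constraint must be a proper subset of the taxa")


@dataclass
class SearchConfig:
    """Effort/convergence knobs for one heuristic search replicate."""

    bl_tol_search: float = 1e-2   # lnL tolerance for smoothing during NNI
    bl_tol_replicate: float = 1e-3  # polish of each replicate's end tree
    bl_tol_final: float = 1e-8    # polish of the winning tree
    bl_passes: int = 2            # smoothing passes between rearrangements
    nni_tol: float = 1e-5         # minimum lnL gain to accept a rearrangement
    max_nni_rounds: int = 200


@dataclass
class SearchResult:
    best_tree: PhyloTree
    best_lnl: float
    replicate_lnls: list
    seed: int


def satisfies_constraint(tree: PhyloTree, constraint: ConstraintSpec) -> bool:
    """True iff some branch's bipartition separates exactly the constraint
    set from its complement."""
    constraint.validate_against(tree.taxa)
    return tree.has_bipartition(constraint.taxa)


# ------------------------------------------------------------ starting trees
_FITCH_CODE = {ch: sum(1 << s for s in states) for ch, states in IUPAC.items()}


def _fitch_masks(alignment: Alignment):
    """Per-tip per-pattern state bitmasks (A=1,C=2,G=4,T=8) and weights."""
    code = {ch: i for i, ch in enumerate(IUPAC)}
    mat = np.array(
        [[code[c] for c in s] for s in alignment.sequences], np.int8
    )[:, alignment.mask]
    cols, weights = np.unique(mat, axis=1, return_counts=True)
    lut = np.array([_FITCH_CODE[ch] for ch in IUPAC], np.uint8)
    return lut[cols], weights.astype(float)  # (ntaxa, npat), (npat,)


def _fitch_combine(parts):
    out = parts[0]
    for p in parts[1:]:
        inter = out & p
        out = np.where(inter != 0, inter, out | p)
    return out


def _directed_fitch_sets(tree: PhyloTree, tipmask):
    sets = {}
    post = tree.postorder_edges()
    for (u, v) in post:
        if u < tree.n_tips:
            sets[(u, v)] = tipmask[u]
        else:
            sets[(u, v)] = _fitch_combine(
                [sets[(w, u)] for w in tree.nbr[u] if w != v]
            )
    for (u, v) in reversed(post):
        if (v, u) not in sets:
            sets[(v, u)] = _fitch_combine(
                [sets[(w, v)] for w in tree.nbr[v] if w != u]
            )
    return sets


def random_addition_tree(
    alignment: Alignment,
    rng: np.random.Generator,
    constraint: ConstraintSpec | None = None,
    init_blen: float = 0.05,
) -> PhyloTree:
    """Random-order stepwise addition with greedy parsimony placement.

    Each new tip is attached on the currently cheapest edge (number of
    extra changes estimated from directed Fitch state sets, ties broken at
    random); when a constraint is given, attachment edges are restricted so
    the constraint set stays monophyletic at every step.
    """
    taxa = list(alignment.taxa)
    if len(taxa) < 4:
        raise SearchError("need at least 4 taxa")
    tipmask_full, weights = _fitch_masks(alignment)
    order_all = sorted(range(len(taxa)))
    rng.shuffle(order_all)
    r_idx = (
        {i for i, t in enumerate(taxa) if t in constraint.taxa}
        if constraint
        else set()
    )

    first3 = order_all[:3]
    rest = order_all[3:]
    # internal node ids start at len(taxa) so they never collide with the
    # tip ids of the growing tree
    base = len(taxa)
    glob_of_local = {k: g for k, g in enumerate(first3)}
    n_local = 3
    nbr = {0: [base], 1: [base], 2: [base], base: [0, 1, 2]}
    lengths = {
        (0, base): init_blen,
        (1, base): init_blen,
        (2, base): init_blen,
    }
    next_internal = base + 1

    def local_tree(validate=False):
        return PhyloTree(
            [taxa[glob_of_local[i]] for i in range(n_local)],
            nbr,
            lengths,
            validate=validate,
        )

    for g in rest:
        t = local_tree()
        tm = tipmask_full[[glob_of_local[i] for i in range(n_local)]]
        sets = _directed_fitch_sets(t, tm)
        x = tipmask_full[g]
        restrict = bool(constraint and r_idx)
        if restrict:
            sides = t.tipset_sides()
            rcur = 0
            for i in range(n_local):
                if glob_of_local[i] in r_idx:
                    rcur |= 1 << i
            scur = ((1 << n_local) - 1) & ~rcur
            restrict = bool(rcur and scur)
        cand = []
        for (u, v) in list(lengths):
            if restrict:
                su, sv = sides[(u, v)], sides[(v, u)]
                if g in r_idx:
                    ok = (su & ~rcur) == 0 or (sv & ~rcur) == 0
                else:
                    inside_u = (su & ~rcur) == 0 and su != rcur
                    inside_v = (sv & ~rcur) == 0 and sv != rcur
                    ok = not (inside_u or inside_v)
                if not ok:
                    continue
            un = sets[(u, v)] | sets[(v, u)]
            cost = float(weights[(x & un) == 0].sum())
            cand.append((cost, rng.random(), (u, v)))
        if not cand:
            raise SearchError("no constraint-compatible attachment edge")
        cand.sort()
        u, v = cand[0][2]
        tip_id = n_local
        w = next_internal
        next_internal += 1
        nbr[u].remove(v)
        nbr[v].remove(u)
        nbr[u].append(w)
        nbr[v].append(w)
        nbr[w] = [u, v, tip_id]
        nbr[tip_id] = [w]
        old = lengths.pop(edge_key(u, v))
        lengths[edge_key(u, w)] = max(old / 2, MIN_BLEN)
        lengths[edge_key(v, w)] = max(old / 2, MIN_BLEN)
        lengths[edge_key(tip_id, w)] = init_blen
        glob_of_local[tip_id] = g
        n_local += 1

    out = local_tree(validate=True)
    if constraint and len(r_idx) >= 2 and len(taxa) - len(r_idx) >= 2:
        assert satisfies_constraint(out, constraint)
    return out


# ----------------------------------------------------------------- NNI moves
def _apply_nni(tree: PhyloTree, u: int, v: int, b: int, c: int) -> None:
    """Swap subtree b (neighbour of u) with subtree c (neighbour of v)
    across the internal edge (u, v); subtrees keep their branch lengths."""
    tree.nbr[u][tree.nbr[u].index(b)] = c
    tree.nbr[v][tree.nbr[v].index(c)] = b
    tree.nbr[b][tree.nbr[b].index(u)] = v
    tree.nbr[c][tree.nbr[c].index(v)] = u
    tb = tree.lengths.pop(edge_key(u, b))
    tc = tree.lengths.pop(edge_key(v, c))
    tree.lengths[edge_key(v, b)] = tb
    tree.lengths[edge_key(u, c)] = tc


def _nni_hill_climb(
    engine: TreeLikelihood,
    constraint: ConstraintSpec | None,
    cfg: SearchConfig,
) -> float:
    """Greedy best-first NNI with central-branch re-optimization, followed by
    a tight final branch-length polish.  Returns the final lnL."""
    tree = engine.tree
    want = comp = None
    if constraint is not None:
        idx = {t: i for i, t in enumerate(tree.taxa)}
        want = 0
        for lab in constraint.taxa:
            want |= 1 << idx[lab]
        comp = ((1 << tree.n_tips) - 1) & ~want

    ll = engine.optimize_branch_lengths(
        tol=cfg.bl_tol_search, max_passes=cfg.bl_passes
    )
    for _ in range(cfg.max_nni_rounds):
        engine.refresh_all()
        sides = tree.tipset_sides() if constraint is not None else None
        if constraint is not None:
            realizing = [
                e for e in tree.lengths if sides[e] in (want, comp)
            ]
        best = None  # (gain, move, new central length)
        for (u, v) in tree.internal_edges():
            a, b = [x for x in tree.nbr[u] if x != v]
            c, d = [x for x in tree.nbr[v] if x != u]
            Ga, lsa = engine._G[(a, u)]
            Gb, lsb = engine._G[(b, u)]
            Gc, lsc = engine._G[(c, v)]
            Gd, lsd = engine._G[(d, v)]
            Pa = np.matmul(engine._P(u, a), Ga)
            Pb = np.matmul(engine._P(u, b), Gb)
            Pc = np.matmul(engine._P(v, c), Gc)
            Pd = np.matmul(engine._P(v, d), Gd)
            scale = float(np.dot(engine.weights, lsa + lsb + lsc + lsd))
            t0 = tree.length(u, v)
            ll_cur = (
                engine.newton_opt(Pa * Pb, Pc * Pd, t0)[1] + scale
            )
            for swap_c in (c, d):
                if constraint is not None:
                    e_uv = edge_key(u, v)
                    # after swapping b with swap_c, u's side holds {a, swap_c}
                    if swap_c == c:
                        new_side = sides[(a, u)] | sides[(c, v)]
                    else:
                        new_side = sides[(a, u)] | sides[(d, v)]
                    ok = any(e != e_uv for e in realizing) or new_side in (
                        want,
                        comp,
                    )
                    if not ok:
                        continue
                if swap_c == c:
                    Hu, Hv = Pa * Pc, Pb * Pd
                else:
                    Hu, Hv = Pa * Pd, Pc * Pb
                t_new, ll_new = engine.newton_opt(Hu, Hv, t0)
                gain = ll_new + scale - ll_cur
                if gain > cfg.nni_tol and (best is None or gain > best[0]):
                    best = (gain, (u, v, b, swap_c), t_new)
        if best is None:
            break
        _, (u, v, b, c), t_new = best
        _apply_nni(tree, u, v, b, c)
        tree.set_length(u, v, max(t_new, MIN_BLEN))
        engine.invalidate_all()
        ll = engine.optimize_branch_lengths(
            tol=cfg.bl_tol_search, max_passes=cfg.bl_passes
        )
    ll = engine.optimize_branch_lengths(tol=cfg.bl_tol_replicate, max_passes=8)
    return ll


def ml_search(
    alignment: Alignment,
    model: SubstModel,
    n_replicates: int = 20,
    seed: int = 0,
    constraint: ConstraintSpec | None = None,
    config: SearchConfig | None = None,
    start_trees: list | None = None,
) -> SearchResult:
    """Replicated heuristic ML search; deterministic given ``seed``.

    Each replicate builds a random-addition starting tree (constraint-
    respecting when a constraint is given) and hill-climbs through NNI
    space.  ``start_trees`` adds user-supplied starting topologies as extra
    replicates.  The best replicate wins; exact lnL ties break toward the
    lexicographically smallest canonical Newick string.
    """
    if alignment.n_taxa < 4:
        raise SearchError("need at least 4 taxa")
    if constraint is not None:
        constraint.validate_against(alignment.taxa)
    if n_replicates < 1 and not start_trees:
        raise SearchError("need at least one search replicate")
    cfg = config or SearchConfig()
    rng = np.random.default_rng(seed)
    best_tree, best_lnl, rep_lnls = None, -np.inf, []
    starts = [None] * n_replicates + list(start_trees or [])
    for st in starts:
        tree = (
            st.copy()
            if st is not None
            else random_addition_tree(alignment, rng, constraint)
        )
        if constraint is not None and not satisfies_constraint(tree, constraint):
            raise SearchError("starting tree violates the constraint")
        engine = TreeLikelihood(tree, alignment, model)
        ll = _nni_hill_climb(engine, constraint, cfg)
        rep_lnls.append(ll)
        if ll > best_lnl or (
            ll == best_lnl
            and best_tree is not None
            and tree.topology_id() < best_tree.topology_id()
        ):
            best_tree, best_lnl = tree, ll
    # tight final polish on the winner only
    eng = TreeLikelihood(best_tree, alignment, model)
    best_lnl = max(
        best_lnl, eng.optimize_branch_lengths(tol=cfg.bl_tol_final, max_passes=40)
    )
    if constraint is not None:
        assert satisfies_constraint(best_tree, constraint)
    return SearchResult(best_tree, best_lnl, rep_lnls, seed)


# ------------------------------------------------------------- bootstrapping
def bootstrap_support(
    alignment: Alignment,
    model: SubstModel,
    n_boot: int = 100,
    search_reps_per_boot: int = 2,
    seed: int = 0,
    focal_tree: PhyloTree | None = None,
    config: SearchConfig | None = None,
) -> dict:
    """Nonparametric bootstrap support for the bipartitions of the focal
    tree (the ML tree on the original alignment unless supplied).

    Returns ``{bipartition (frozenset of labels): percent in [0, 100]}``.
    """
    rng = np.random.default_rng(seed)
    if focal_tree is None:
        focal_tree = ml_search(
            alignment, model, n_replicates=max(search_reps_per_boot, 2),
            seed=int(rng.integers(2**31)), config=config,
        ).best_tree
    focal = focal_tree.bipartition_set()
    counts = {bp: 0 for bp in focal}
    for _ in range(n_boot):
        rep_seed = int(rng.integers(2**31))
        baln = alignment.resample_sites(rng)
        res = ml_search(
            baln, model, n_replicates=search_reps_per_boot,
            seed=rep_seed, config=config,
        )
        got = res.best_tree.bipartition_set()
        logger.info("bootstrap replicate done (%d bipartitions)", len(got))
        for bp in counts:
            if bp in got:
                counts[bp] += 1
    if n_boot == 0:
        return {}
    return {bp: 100.0 * k / n_boot for bp, k in counts.items()}


# ------------------------------------------------------------------- rooting
def midpoint_root(tree: PhyloTree) -> dendropy.Tree:
    """Midpoint-rooted display view (never used for likelihoods).

    For a zero-diameter tree the root is placed on an arbitrary branch and
    a warning is attached to ``tree_out.annotations``.
    """
    dtree = tree.to_dendropy()
    if sum(tree.lengths.values()) <= 0:
        dtree.annotations.add_new("midpoint_warning", "zero-diameter tree")
        return dtree
    dtree.reroot_at_midpoint(update_bipartitions=True)
    return dtree
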