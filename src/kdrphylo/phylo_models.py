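"""Reversible nucleotide substitution models and pruning-algorithm likelihood.

Implements the model machinery behind the pipeline: time-reversible rate
matrices (JC69, K80, HKY85, GTR) with optional discrete-gamma rate
heterogeneity, transition probabilities via spectral decomposition,
Felsenstein-pruning log likelihoods with per-pattern scaling, monotone
branch-length optimization by per-edge Brent search, BIC model selection on
a fixed neighbour-joining starting topology, and sequence simulation along
a tree.

The directed-edge conditional-likelihood cache in :class:`TreeLikelihood`
is shared with the tree-search module: every directed edge ``(u, v)``
stores the likelihood of the data on ``u``'s side of the edge conditional
on the state at ``u``, so any single branch can be re-optimized cheaply and
NNI rearrangements can be scored from four cached vectors.
"""
from __future__ import annotations

import functools
import io
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize
from scipy.stats import gamma as _gamma_dist

from .trees import MAX_BLEN, MIN_BLEN, PhyloTree

NUC = "ACGT"
# IUPAC ambiguity codes -> compatible state indices; gaps are missing data
IUPAC = {
    "A": (0,), "C": (1,), "G": (2,), "T": (3,), "U": (3,),
    "R": (0, 2), "Y": (1, 3), "S": (1, 2), "W": (0, 3),
    "K": (2, 3), "M": (0, 1), "B": (1, 2, 3), "D": (0, 2, 3),
    "H": (0, 1, 3), "V": (0, 1, 2), "N": (0, 1, 2, 3),
    "-": (0, 1, 2, 3), "?": (0, 1, 2, 3),
}

FAMILIES = ("JC69", "K80", "HKY85", "GTR")


class ModelError(ValueError):
    pass


class AlignmentError(ValueError):
    pass


# --------------------------------------------------------------------- model
@dataclass(frozen=True)
class SubstModel:
    """Time-reversible nucleotide substitution model.

    The rate matrix is scaled so that one unit of branch length equals one
    expected substitution per site.  ``rel_rates`` are the GTR
    exchangeabilities in the order AC, AG, AT, CG, CT, GT (GT fixed to 1 by
    convention); K80/HKY85 use ``kappa`` instead.  ``alpha`` switches on
    discrete-gamma rate heterogeneity with ``n_categories`` equal-weight
    categories (mean rate per category).
    """

    family: str = "JC69"
    freqs: tuple = (0.25, 0.25, 0.25, 0.25)
    kappa: float = 1.0
    rel_rates: tuple = (1.0, 1.0, 1.0, 1.0, 1.0, 1.0)
    alpha: float | None = None
    n_categories: int = 4

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ModelError(f"unknown family {self.family!r}")
        f = np.asarray(self.freqs, float)
        if f.shape != (4,) or np.any(f <= 0):
            raise ModelError("freqs must be 4 positive numbers")
        object.__setattr__(self, "freqs", tuple(f / f.sum()))
        if self.family in ("JC69", "K80"):
            object.__setattr__(self, "freqs", (0.25, 0.25, 0.25, 0.25))
        if self.alpha is not None and self.alpha <= 0:
            raise ModelError("gamma shape alpha must be > 0")
        if self.n_categories < 1:
            raise ModelError("n_categories must be >= 1")
        object.__setattr__(self, "rel_rates", tuple(float(r) for r in self.rel_rates))

    @property
    def pi(self) -> np.ndarray:
        return np.asarray(self.freqs, float)

    def exchangeabilities(self) -> np.ndarray:
        """Symmetric 4x4 exchangeability matrix (zero diagonal)."""
        if self.family == "JC69":
            ac = ag = at = cg = ct = gt = 1.0
        elif self.family in ("K80", "HKY85"):
            ac = at = cg = gt = 1.0
            ag = ct = self.kappa
        else:  # GTR
            ac, ag, at, cg, ct, gt = self.rel_rates
        r = np.array(
            [[0, ac, ag, at], [ac, 0, cg, ct], [ag, cg, 0, gt], [at, ct, gt, 0]],
            float,
        )
        return r

    def q_matrix(self) -> np.ndarray:
        """Rate matrix Q, scaled to one expected substitution per unit time."""
        pi = self.pi
        q = self.exchangeabilities() * pi[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -(pi * np.diag(q)).sum()
        return q / mu

    def category_rates(self) -> np.ndarray:
        """Relative rates of the discrete-gamma categories (mean 1)."""
        if self.alpha is None:
            return np.ones(1)
        return discrete_gamma_rates(self.alpha, self.n_categories)

    def n_free_params(self) -> int:
        """Free substitution-model parameters (jModelTest-style counting)."""
        k = {"JC69": 0, "K80": 1, "HKY85": 4, "GTR": 8}[self.family]
        if self.alpha is not None:
            k += 1
        return k


def discrete_gamma_rates(alpha: float, k: int) -> np.ndarray:
    """Mean rates of ``k`` equal-probability gamma(alpha, mean 1) categories."""
    if k == 1:
        return np.ones(1)
    cuts = _gamma_dist.ppf(np.arange(1, k) / k, alpha, scale=1.0 / alpha)
    upper = _gamma_dist.cdf(cuts, alpha + 1.0, scale=1.0 / alpha)
    bounds = np.concatenate([[0.0], upper, [1.0]])
    rates = k * np.diff(bounds)
    return rates / rates.mean()


@functools.lru_cache(maxsize=64)
def _eigen(model: SubstModel):
    """Spectral decomposition of Q via the pi-symmetrized form."""
    pi = model.pi
    q = model.q_matrix()
    d = np.sqrt(pi)
    sym = q * d[:, None] / d[None, :]
    sym = 0.5 * (sym + sym.T)
    w, u = np.linalg.eigh(sym)
    left = u / d[:, None]
    right = u.T * d[None, :]
    return w, left, right


def transition_matrix(model: SubstModel, t: float, rate: float = 1.0) -> np.ndarray:
    """P(t) for one rate category; rows sum to 1, P(0) = I."""
    if t < 0:
        raise ModelError(f"branch length must be >= 0, got {t}")
    w, left, right = _eigen(model)
    p = (left * np.exp(w * t * rate)) @ right
    np.clip(p, 0.0, None, out=p)
    return p / p.sum(axis=1, keepdims=True)


def transition_matrices(model: SubstModel, t: float, rates: np.ndarray) -> np.ndarray:
    """Stacked P(t * r) over gamma categories, shape (ncat, 4, 4)."""
    if t < 0:
        raise ModelError(f"branch length must be >= 0, got {t}")
    w, left, right = _eigen(model)
    e = np.exp(np.multiply.outer(rates * t, w))  # (ncat, 4)
    p = (left[None, :, :] * e[:, None, :]) @ right
    np.clip(p, 0.0, None, out=p)
    return p / p.sum(axis=2, keepdims=True)


# ----------------------------------------------------------------- alignment
@dataclass
class Alignment:
    """Taxon-by-site nucleotide matrix with a per-site inclusion mask.

    The mask realizes the "full" (all True) versus "strict" (alignment-
    ambiguous columns excluded) matrix distinction; all likelihood code is
    mask-aware.
    """

    taxa: list
    sequences: list
    mask: np.ndarray = None

    def __post_init__(self):
        if len(self.taxa) != len(self.sequences):
            raise AlignmentError("taxa/sequences length mismatch")
        lens = {len(s) for s in self.sequences}
        if len(lens) > 1:
            raise AlignmentError(f"unequal sequence lengths: {sorted(lens)}")
        self.sequences = [s.upper() for s in self.sequences]
        for name, s in zip(self.taxa, self.sequences):
            bad = set(s) - set(IUPAC)
            if bad:
                raise AlignmentError(
                    f"record {name!r}: invalid characters {sorted(bad)}"
                )
        if self.mask is None:
            self.mask = np.ones(self.n_sites, bool)
        self.mask = np.asarray(self.mask, bool)
        if self.mask.shape != (self.n_sites,):
            raise AlignmentError("mask length must equal site count")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    @property
    def n_included(self) -> int:
        return int(self.mask.sum())

    @classmethod
    def from_fasta(cls, path, mask=None) -> "Alignment":
        from Bio import SeqIO

        taxa, seqs = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            taxa.append(rec.id)
            seqs.append(str(rec.seq))
        if not taxa:
            raise AlignmentError(f"no FASTA records in {path}")
        if len(set(taxa)) != len(taxa):
            dup = sorted({t for t in taxa if taxa.count(t) > 1})
            raise AlignmentError(f"duplicate record ids: {dup}")
        return cls(taxa, seqs, mask)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for name, seq in zip(self.taxa, self.sequences):
                fh.write(f">{name}\n{seq}\n")

    def empirical_freqs(self, pseudocount: float = 1.0) -> np.ndarray:
        counts = np.full(4, pseudocount)
        for s in self.sequences:
            for ch in s:
                states = IUPAC[ch]
                if len(states) == 1:
                    counts[states[0]] += 1
        return counts / counts.sum()

    def patterns(self):
        """Compress included sites into unique columns.

        Returns ``(tip_conditionals, weights)`` where ``tip_conditionals``
        has shape (n_taxa, 4, n_patterns) and weights are pattern counts.
        """
        code = {ch: i for i, ch in enumerate(IUPAC)}
        mat = np.array(
            [[code[ch] for ch in s] for s in self.sequences], dtype=np.int8
        )[:, self.mask]
        if mat.shape[1] == 0:
            raise AlignmentError("no included sites")
        cols, weights = np.unique(mat, axis=1, return_counts=True)
        lut = np.zeros((len(IUPAC), 4))
        for ch, states in IUPAC.items():
            for s in states:
                lut[code[ch], s] = 1.0
        tipcond = lut[cols].transpose(0, 2, 1)  # (ntaxa, 4, npat)
        return np.ascontiguousarray(tipcond), weights.astype(float)

    def resample_sites(self, rng: np.random.Generator) -> "Alignment":
        """Nonparametric bootstrap: resample included columns with
        replacement (result has all sites included)."""
        idx = np.flatnonzero(self.mask)
        pick = rng.choice(idx, size=idx.size, replace=True)
        seqs = ["".join(s[i] for i in pick) for s in self.sequences]
        return Alignment(list(self.taxa), seqs)


# --------------------------------------------------------- likelihood engine
class TreeLikelihood:
    """Pruning-algorithm likelihood with a directed-edge vector cache.

    For each directed edge ``(u, v)`` the cache holds ``(arr, logscale)``
    where ``arr[c, i, p]`` is the (rescaled) likelihood of the data on
    ``u``'s side given state ``i`` at ``u`` under gamma category ``c`` and
    site pattern ``p``; ``logscale[p]`` accumulates the log of the factored-
    out per-pattern scalers.
    """

    def __init__(self, tree: PhyloTree, alignment: Alignment, model: SubstModel):
        if set(tree.taxa) != set(alignment.taxa):
            raise AlignmentError("tree tips do not match alignment taxa")
        self.tree = tree
        self.model = model
        self.rates = model.category_rates()
        self.pi = model.pi
        tipcond, self.weights = alignment.patterns()
        row = {name: i for i, name in enumerate(alignment.taxa)}
        order = [row[name] for name in tree.taxa]
        self._tipcond = tipcond[order]  # (ntips, 4, npat)
        self.npat = tipcond.shape[2]
        self._G: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}
        self._zero_ls = np.zeros(self.npat)
        self._pcache: dict[float, np.ndarray] = {}

    # -- vector bookkeeping -------------------------------------------------
    def invalidate_all(self) -> None:
        self._G.clear()

    def _tip_vector(self, tip: int):
        arr = np.broadcast_to(
            self._tipcond[tip][None, :, :], (len(self.rates), 4, self.npat)
        )
        return arr, self._zero_ls

    def _P(self, u: int, v: int) -> np.ndarray:
        t = self.tree.length(u, v)
        p = self._pcache.get(t)
        if p is None:
            p = transition_matrices(self.model, t, self.rates)
            if len(self._pcache) > 4096:
                self._pcache.clear()
            self._pcache[t] = p
        return p

    def _compute_vector(self, u: int, v: int):
        """G[(u, v)] from the (already available) vectors of u's other
        neighbours."""
        if u < self.tree.n_tips:
            return self._tip_vector(u)
        arr = None
        ls = self._zero_ls
        for w in self.tree.nbr[u]:
            if w == v:
                continue
            gw, lw = self._G[(w, u)]
            part = np.matmul(self._P(u, w), gw)
            arr = part if arr is None else arr * part
            ls = ls + lw
        m = arr.max(axis=(0, 1))
        m[m <= 0] = 1.0
        arr = arr / m
        return arr, ls + np.log(m)

    def _ensure(self, u: int, v: int):
        """Fill G[(u, v)] (and its dependencies) iteratively."""
        if (u, v) in self._G:
            return self._G[(u, v)]
        stack = [(u, v)]
        while stack:
            a, b = stack[-1]
            if (a, b) in self._G:
                stack.pop()
                continue
            if a < self.tree.n_tips:
                self._G[(a, b)] = self._tip_vector(a)
                stack.pop()
                continue
            missing = [
                (w, a) for w in self.tree.nbr[a] if w != b and (w, a) not in self._G
            ]
            if missing:
                stack.extend(missing)
            else:
                self._G[(a, b)] = self._compute_vector(a, b)
                stack.pop()
        return self._G[(u, v)]

    def refresh_all(self) -> None:
        """Recompute every directed-edge vector from the current lengths."""
        self.invalidate_all()
        for (u, v) in self.tree.postorder_edges():
            self._G[(u, v)] = self._compute_vector(u, v)
        # reverse directions in pre-order (parents before children)
        for (u, v) in reversed(self.tree.postorder_edges()):
            if (v, u) not in self._G:
                self._G[(v, u)] = self._compute_vector(v, u)

    # -- likelihood ---------------------------------------------------------
    def _edge_ll(self, A, lsA, B, lsB, t: float) -> float:
        P = transition_matrices(self.model, t, self.rates)
        X = np.matmul(P, B)
        site = (self.pi[None, :, None] * A * X).sum(axis=(0, 1)) / len(self.rates)
        site = np.maximum(site, 1e-300)
        return float(np.dot(self.weights, np.log(site) + lsA + lsB))

    def loglik(self) -> float:
        """Log likelihood of the current tree (fills cache as needed)."""
        u = 0
        v = self.tree.nbr[0][0]
        A, lsA = self._ensure(u, v)
        B, lsB = self._ensure(v, u)
        return self._edge_ll(A, lsA, B, lsB, self.tree.length(u, v))

    def edge_loglik(self, u: int, v: int, t: float | None = None) -> float:
        A, lsA = self._ensure(u, v)
        B, lsB = self._ensure(v, u)
        if t is None:
            t = self.tree.length(u, v)
        return self._edge_ll(A, lsA, B, lsB, t)

    # -- branch-length optimization ------------------------------------------
    def _edge_ll_derivs(self, piA, B, wr, left, right, fac, t: float):
        """(lnL, dlnL/dt, d2lnL/dt2) for one edge, up to the scale constant.

        ``piA``, ``wr``, ``left``, ``right`` and the (3, ncat, 4) work array
        ``fac`` are loop invariants precomputed by :meth:`newton_opt`."""
        E = np.exp(wr * t)
        fac[0] = E
        np.multiply(E, wr, out=fac[1])
        np.multiply(fac[1], wr, out=fac[2])
        P = (fac[:, :, None, :] * left[None, None, :, :]) @ right
        X = np.matmul(P, B[None])  # (3, ncat, 4, npat)
        s, s1, s2 = (piA[None] * X).sum(axis=(1, 2)) / len(self.rates)
        s = np.maximum(s, 1e-300)
        g = s1 / s
        ll = float(np.dot(self.weights, np.log(s)))
        d1 = float(np.dot(self.weights, g))
        d2 = float(np.dot(self.weights, s2 / s - g * g))
        return ll, d1, d2

    def newton_opt(self, A, B, t0: float, xatol: float = 1e-7):
        """Safeguarded Newton maximization of the one-branch lnL given the
        two flanking conditional vectors; returns (t_best, lnL_best) with the
        log-scalers of A and B *not* included.  Only improving steps are
        accepted, so callers inherit monotonicity."""
        w, left, right = _eigen(self.model)
        wr = np.multiply.outer(self.rates, w)
        piA = self.pi[None, :, None] * A
        fac = np.empty((3,) + wr.shape)
        args = (piA, B, wr, left, right, fac)
        t = min(max(t0, MIN_BLEN), MAX_BLEN)
        ll, d1, d2 = self._edge_ll_derivs(*args, t)
        best_t, best_ll = t, ll
        for _ in range(12):
            if d2 < 0 and np.isfinite(d1):
                step = -d1 / d2
            else:
                step = np.sign(d1) * max(0.1 * t, 1e-3)
            # converged at an interior stationary point or pinned bound
            if abs(step) < xatol or (t <= MIN_BLEN and d1 < 0) or (
                t >= MAX_BLEN and d1 > 0
            ):
                break
            nt = min(max(t + step, MIN_BLEN), MAX_BLEN)
            nll, nd1, nd2 = self._edge_ll_derivs(*args, nt)
            halvings = 0
            while nll < best_ll and halvings < 8:
                nt = 0.5 * (nt + best_t)
                nll, nd1, nd2 = self._edge_ll_derivs(*args, nt)
                halvings += 1
            if nll < best_ll:
                break
            gain = nll - best_ll
            t, ll, d1, d2 = nt, nll, nd1, nd2
            best_t, best_ll = nt, nll
            if gain < 1e-9:
                break
        return best_t, best_ll

    def _optimize_edge_now(self, u: int, v: int, xatol: float) -> float:
        A, lsA = self._G[(u, v)]
        B, lsB = self._G[(v, u)]
        scale = float(np.dot(self.weights, lsA + lsB))
        best_t, best_ll = self.newton_opt(A, B, self.tree.length(u, v), xatol)
        self.tree.set_length(u, v, best_t)
        return best_ll + scale

    def optimize_branch_lengths(
        self, tol: float = 1e-6, max_passes: int = 20, xatol: float = 1e-7
    ) -> float:
        """Cycle per-edge Brent optimizations until the lnL gain of a full
        pass drops below ``tol``.  Monotone in lnL by construction (every
        edge is optimized against exact, current conditional vectors)."""
        ll_prev = self.loglik()
        # make sure every vector needed by the sweep exists
        self.refresh_all()
        ll = ll_prev
        for _ in range(max_passes):
            ll = self._smooth_pass(xatol)
            if ll - ll_prev < tol:
                break
            ll_prev = ll
        return ll

    def _smooth_pass(self, xatol: float) -> float:
        tip0 = 0
        root = self.tree.nbr[tip0][0]
        last = self._optimize_edge_now(tip0, root, xatol)
        stack = [(tip0, root, iter([w for w in self.tree.nbr[root] if w != tip0]))]
        while stack:
            u, v, it = stack[-1]
            w = next(it, None)
            if w is None:
                self._G[(v, u)] = self._compute_vector(v, u)
                stack.pop()
                continue
            self._G[(v, w)] = self._compute_vector(v, w)
            last = self._optimize_edge_now(v, w, xatol)
            stack.append((v, w, iter([x for x in self.tree.nbr[w] if x != v])))
        return last


# ------------------------------------------------------------- public ops
def tree_loglik(tree: PhyloTree, alignment: Alignment, model: SubstModel) -> float:
    """Pruning-algorithm log likelihood of ``alignment`` on ``tree``."""
    return TreeLikelihood(tree, alignment, model).loglik()


def optimize_branch_lengths(
    tree: PhyloTree,
    alignment: Alignment,
    model: SubstModel,
    tol: float = 1e-6,
    max_passes: int = 20,
):
    """Optimize all branch lengths; returns ``(tree', lnL)``, lnL never below
    the input tree's."""
    t2 = tree.copy()
    eng = TreeLikelihood(t2, alignment, model)
    ll = eng.optimize_branch_lengths(tol=tol, max_passes=max_passes)
    return t2, ll


# ------------------------------------------------------------- simulation
def simulate_alignment(
    tree: PhyloTree,
    model: SubstModel,
    n_sites: int,
    seed,
    rng: np.random.Generator | None = None,
) -> Alignment:
    """Simulate an alignment of ``n_sites`` on ``tree`` under ``model``.

    Root state drawn from the stationary frequencies at an arbitrary
    internal node; per-site gamma category drawn once; deterministic given
    the seed.
    """
    if n_sites < 1:
        raise ModelError("n_sites must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    rates = model.category_rates()
    cat = rng.integers(0, len(rates), size=n_sites)
    pi = model.pi
    order = tree.postorder_edges()
    root = order[-1][1] if tree.n_tips > 2 else tree.nbr[0][0]
    states = {root: rng.choice(4, size=n_sites, p=pi)}
    # walk edges parent-before-child (reverse of post-order)
    for (child, parent) in reversed(order):
        assert parent in states and child not in states
        t = tree.length(child, parent)
        ps = states[parent]
        cs = np.empty(n_sites, dtype=np.int64)
        for c in range(len(rates)):
            m = cat == c
            if not m.any():
                continue
            P = transition_matrix(model, t, rates[c])
            cum = P.cumsum(axis=1)
            u = rng.random(m.sum())
            cs[m] = (u[:, None] > cum[ps[m]]).sum(axis=1)
        states[child] = cs
    seqs = ["".join(NUC[s] for s in states[i]) for i in range(tree.n_tips)]
    return Alignment(list(tree.taxa), seqs)


# --------------------------------------------------------- model selection
@dataclass
class ModelFit:
    """One fitted candidate: model with estimated parameters, its lnL on the
    (branch-length-optimized) fixed topology, and the BIC."""

    model: SubstModel
    lnl: float
    n_free_params: int
    bic: float
    tree: PhyloTree = None


def jc_distance_matrix(alignment: Alignment) -> np.ndarray:
    """Pairwise JC69-corrected distances over included, unambiguous sites."""
    code = {ch: i for i, ch in enumerate(IUPAC)}
    mat = np.array([[code[c] for c in s] for s in alignment.sequences], np.int8)
    mat = mat[:, alignment.mask]
    ok = mat < 4  # unambiguous A/C/G/T only
    n = alignment.n_taxa
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ok[i] & ok[j]
            tot = both.sum()
            p = (mat[i, both] != mat[j, both]).sum() / tot if tot else 0.0
            p = min(p, 0.74999)
            d[i, j] = d[j, i] = -0.75 * np.log1p(-4.0 * p / 3.0)
    return d


def nj_tree(alignment: Alignment) -> PhyloTree:
    """Neighbour-joining starting topology from JC distances (scikit-bio)."""
    from skbio import DistanceMatrix
    from skbio.tree import nj

    d = jc_distance_matrix(alignment)
    # NJ needs strictly valid ids and >= 3 taxa
    if alignment.n_taxa < 4:
        raise AlignmentError("need >= 4 taxa for a neighbour-joining tree")
    dm = DistanceMatrix(d, ids=list(alignment.taxa))
    t = nj(dm)
    buf = io.StringIO()
    t.write(buf)
    return PhyloTree.from_newick(buf.getvalue())


def fit_model(
    alignment: Alignment,
    tree: PhyloTree,
    family: str,
    gamma: bool = False,
    n_categories: int = 4,
    max_rounds: int = 2,
    bl_tol: float = 1e-4,
) -> ModelFit:
    """Fit one substitution model on a fixed topology.

    Base frequencies are empirical (+1 pseudocount); exchangeabilities and
    the gamma shape are maximized numerically, alternating with branch-
    length optimization.
    """
    freqs = tuple(alignment.empirical_freqs())
    model = SubstModel(
        family=family,
        freqs=freqs,
        kappa=2.0,
        alpha=0.5 if gamma else None,
        n_categories=n_categories,
    )
    work = tree.copy()

    def free_param_vector(m: SubstModel):
        x = []
        if m.family in ("K80", "HKY85"):
            x.append(np.log(m.kappa))
        elif m.family == "GTR":
            x.extend(np.log(np.asarray(m.rel_rates[:5]) / m.rel_rates[5]))
        if m.alpha is not None:
            x.append(np.log(m.alpha))
        return np.array(x)

    def model_from_vector(x, m: SubstModel):
        i = 0
        kw = {}
        if m.family in ("K80", "HKY85"):
            kw["kappa"] = float(np.exp(x[i]))
            i += 1
        elif m.family == "GTR":
            kw["rel_rates"] = tuple(np.exp(x[i : i + 5])) + (1.0,)
            i += 5
        if m.alpha is not None:
            kw["alpha"] = float(np.clip(np.exp(x[i]), 0.02, 100.0))
        return replace(m, **kw)

    lnl = None
    for _ in range(max_rounds):
        eng = TreeLikelihood(work, alignment, model)
        lnl = eng.optimize_branch_lengths(tol=bl_tol)
        x0 = free_param_vector(model)
        if x0.size:
            def neg(x):
                m = model_from_vector(x, model)
                return -TreeLikelihood(work, alignment, m).loglik()

            res = minimize(neg, x0, method="Nelder-Mead",
                           options={"xatol": 1e-3, "fatol": 1e-4, "maxiter": 200})
            model = model_from_vector(res.x, model)
        else:
            break
    eng = TreeLikelihood(work, alignment, model)
    lnl = eng.optimize_branch_lengths(tol=bl_tol)
    k = model.n_free_params() + len(work.lengths)
    bic = -2.0 * lnl + k * np.log(alignment.n_included)
    return ModelFit(model=model, lnl=lnl, n_free_params=k, bic=bic, tree=work)


DEFAULT_CANDIDATES = tuple(
    (fam, g) for fam in FAMILIES for g in (False, True)
)


def select_model_bic(
    alignment: Alignment,
    candidates=DEFAULT_CANDIDATES,
    tree: PhyloTree | None = None,
) -> ModelFit:
    """Fit every candidate (family, gamma) pair on a fixed NJ starting
    topology and return the minimum-BIC fit; ties go to fewer parameters."""
    candidates = list(candidates)
    if not candidates:
        raise ModelError("empty candidate set")
    if tree is None:
        tree = nj_tree(alignment)
    fits = [fit_model(alignment, tree, fam, gamma=g) for fam, g in candidates]
    return min(fits, key=lambda f: (round(f.bic, 9), f.n_free_params))
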