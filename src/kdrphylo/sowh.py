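"""Parametric-bootstrap test of the single-origin (monophyly) hypothesis.

The observed statistic is the log-likelihood difference
``delta = lnL(best tree) - lnL(best tree with resistant alleles constrained
to be monophyletic)``.  Its null distribution is built by simulating
replicate alignments on the constrained tree (with model parameters fitted
on that tree) and re-running both searches on every replicate — the
SOWH-style test.  The p-value is the fraction of replicate deltas at least
as large as the observed one (ties count against rejection).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .phylo_models import Alignment, SubstModel, fit_model, simulate_alignment
from .tree_search import ConstraintSpec, SearchConfig, SearchResult, ml_search


logger = logging.getLogger(__name__)


class SearchQualityError(RuntimeError):
    """The constrained search beat the unconstrained one — the unconstrained
    search failed to find a tree at least as good as a point of its own
    search space."""


def observed_delta(lnl_best: float, lnl_constrained: float, tol: float = 1e-6) -> float:
    """delta = lnL(best) - lnL(best constrained); must be >= 0.

    A negative value beyond ``tol`` is a search failure and raises
    :class:`SearchQualityError` rather than being silently clamped.
    """
    d = lnl_best - lnl_constrained
    if d < -tol:
        raise SearchQualityError(
            f"constrained lnL {lnl_constrained} exceeds unconstrained {lnl_best}"
        )
    return max(d, 0.0)


def p_value(observed: float, replicate_deltas) -> tuple[float, str, bool]:
    """Monte-Carlo position of the observed delta in the null distribution.

    Returns ``(p, display, is_bound)``: ``p`` is the plain proportion of
    replicate deltas >= observed; when that count is zero the display string
    is the bound ``"< 1/n"`` and ``is_bound`` is True.
    """
    deltas = np.asarray(list(replicate_deltas), float)
    if deltas.size == 0:
        raise ValueError("replicate delta list is empty")
    n = deltas.size
    k = int((deltas >= observed).sum())
    if k == 0:
        return 0.0, f"p < {1.0 / n:g}", True
    p = k / n
    return p, f"p = {p:g}", False


def paired_searches(
    alignment: Alignment,
    model: SubstModel,
    constraint: ConstraintSpec,
    n_replicates: int,
    seed: int,
    config: SearchConfig | None = None,
) -> tuple[SearchResult, SearchResult]:
    """Unconstrained and constrained ML searches with a coupling guarantee.

    If the constrained search happens to find a higher likelihood than the
    unconstrained one (heuristic noise), the unconstrained search is
    restarted from the constrained tree — a valid point of the unconstrained
    space — so the returned pair always satisfies
    ``unconstrained lnL >= constrained lnL``.
    """
    rng = np.random.default_rng(seed)
    s_u, s_c = (int(x) for x in rng.integers(2**31, size=2))
    res_u = ml_search(alignment, model, n_replicates, seed=s_u, config=config)
    res_c = ml_search(
        alignment, model, n_replicates, seed=s_c, constraint=constraint,
        config=config,
    )
    if res_c.best_lnl > res_u.best_lnl:
        res_u2 = ml_search(
            alignment, model, n_replicates=0, seed=s_u, config=config,
            start_trees=[res_c.best_tree],
        )
        if res_u2.best_lnl >= res_u.best_lnl:
            res_u = res_u2
        # numerical guard: identical topology may polish a hair differently
        if res_c.best_lnl > res_u.best_lnl:
            res_u = SearchResult(
                res_c.best_tree.copy(), res_c.best_lnl, res_u.replicate_lnls, s_u
            )
    return res_u, res_c


@dataclass
class SOWHResult:
    """Outcome of the parametric-bootstrap monophyly test."""

    observed_delta: float
    lnl_best: float
    lnl_constrained: float
    replicate_deltas: list
    p_value: float
    p_display: str
    p_is_bound: bool
    n_reps: int
    seed: int
    generating_model: SubstModel = None
    constrained_tree_newick: str = None
    corrected_p: float = None  # (r+1)/(n+1) Monte-Carlo correction

    def __post_init__(self):
        assert self.observed_delta >= 0
        assert all(d >= 0 for d in self.replicate_deltas)
        assert 0.0 <= self.p_value <= 1.0


def sowh_test(
    alignment: Alignment,
    model: SubstModel,
    constraint: ConstraintSpec,
    n_reps: int = 100,
    seed: int = 0,
    search_reps: int = 2,
    observed_search_reps: int | None = None,
    config: SearchConfig | None = None,
    refit_model: bool = True,
) -> SOWHResult:
    """Run the full parametric-bootstrap monophyly test.

    Parameters
    ----------
    search_reps:
        Random-addition replicates per heuristic search on the simulated
        null data sets (and, unless ``observed_search_reps`` is given, on
        the observed data too; equal effort keeps observed and null deltas
        exchangeable, which is what calibrates the test).
    refit_model:
        Re-estimate the model's free parameters on the constrained tree
        before simulating (recommended); otherwise ``model`` is used as the
        generating model unchanged.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    constraint.validate_against(alignment.taxa)
    rng = np.random.default_rng(seed)
    obs_seed = int(rng.integers(2**31))
    res_u, res_c = paired_searches(
        alignment, model, constraint,
        observed_search_reps or search_reps, obs_seed, config,
    )
    delta_obs = observed_delta(res_u.best_lnl, res_c.best_lnl)

    # generating model: parameters re-fitted on the constrained topology
    if refit_model and model.n_free_params() > 0:
        gen_fit = fit_model(
            alignment, res_c.best_tree, model.family,
            gamma=model.alpha is not None, n_categories=model.n_categories,
        )
        gen_model, gen_tree = gen_fit.model, gen_fit.tree
    else:
        gen_model = model
        gen_tree = res_c.best_tree

    n_sites = alignment.n_included
    deltas = []
    for i in range(n_reps):
        sim_seed = int(rng.integers(2**31))
        sim = simulate_alignment(gen_tree, gen_model, n_sites, seed=sim_seed)
        try:
            r_u, r_c = paired_searches(
                sim, gen_model, constraint, search_reps,
                int(rng.integers(2**31)), config,
            )
            deltas.append(observed_delta(r_u.best_lnl, r_c.best_lnl))
            logger.info("SOWH replicate %d/%d: delta=%.4f", i + 1, n_reps, deltas[-1])
        except Exception as e:
            raise RuntimeError(f"SOWH replicate {i} failed: {e}") from e
    p, disp, bound = p_value(delta_obs, deltas)
    k = int((np.asarray(deltas) >= delta_obs).sum())
    return SOWHResult(
        observed_delta=delta_obs,
        lnl_best=res_u.best_lnl,
        lnl_constrained=res_c.best_lnl,
        replicate_deltas=deltas,
        p_value=p,
        p_display=disp,
        p_is_bound=bound,
        n_reps=n_reps,
        seed=seed,
        generating_model=gen_model,
        constrained_tree_newick=gen_tree.to_newick(),
        corrected_p=(k + 1) / (n_reps + 1),
    )
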