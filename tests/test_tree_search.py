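import pytest

from kdrphylo.phylo_models import (
    SubstModel,
    optimize_branch_lengths,
    simulate_alignment,
)
from kdrphylo.tree_search import (
    ConstraintSpec,
    SearchError,
    bootstrap_support,
    midpoint_root,
    ml_search,
    random_addition_tree,
    satisfies_constraint,
)
from kdrphylo.trees import PhyloTree

from .oracles import enumerate_topologies, random_unrooted_tree

HKY = SubstModel("HKY85", freqs=(0.35, 0.15, 0.15, 0.35), kappa=3.0)


class TestSatisfiesConstraint:
    def test_quartet_cases(self):
        good = PhyloTree.from_newick("((R1:1,R2:1):1,(S1:1,S2:1):1);")
        bad = PhyloTree.from_newick("((R1:1,S1:1):1,(R2:1,S2:1):1);")
        cons = ConstraintSpec(frozenset({"R1", "R2"}))
        assert satisfies_constraint(good, cons)
        assert not satisfies_constraint(bad, cons)

    def test_size_n_minus_one_always_true(self):
        # complement is a single tip whose pendant branch realizes the split
        for t in enumerate_topologies(["a", "b", "c", "d"]):
            cons = ConstraintSpec(frozenset({"a", "b", "c"}))
            assert satisfies_constraint(t, cons)

    def test_unknown_taxon_rejected(self, rng):
        t = random_unrooted_tree(5, rng)
        with pytest.raises(SearchError):
            satisfies_constraint(t, ConstraintSpec(frozenset({"zz"})))

    def test_full_set_not_a_proper_subset(self, rng):
        t = random_unrooted_tree(4, rng)
        with pytest.raises(SearchError):
            satisfies_constraint(t, ConstraintSpec(frozenset(t.taxa)))


class TestMlSearch:
    def test_quartet_matches_exhaustive(self, rng):
        true = PhyloTree.from_newick(
            "((A:0.1,B:0.1):0.2,(C:0.1,D:0.1):0.2);"
        )
        aln = simulate_alignment(true, HKY, 2000, seed=17)
        res = ml_search(aln, HKY, n_replicates=2, seed=5)
        best = max(
            optimize_branch_lengths(t, aln, HKY, tol=1e-8)[1]
            for t in enumerate_topologies(["A", "B", "C", "D"])
        )
        assert res.best_lnl == pytest.approx(best, abs=1e-6)
        assert res.best_tree.topology_id() == true.topology_id()

    def test_replicate_lnls_recorded_and_best_is_max(self, rng):
        t = random_unrooted_tree(6, rng)
        aln = simulate_alignment(t, HKY, 300, seed=23)
        res = ml_search(aln, HKY, n_replicates=3, seed=7)
        assert len(res.replicate_lnls) == 3
        # final polish may only improve on the best replicate
        assert res.best_lnl >= max(res.replicate_lnls) - 1e-9

    def test_deterministic_given_seed(self, rng):
        t = random_unrooted_tree(7, rng)
        aln = simulate_alignment(t, HKY, 200, seed=29)
        r1 = ml_search(aln, HKY, n_replicates=2, seed=11)
        r2 = ml_search(aln, HKY, n_replicates=2, seed=11)
        assert r1.best_tree.to_newick() == r2.best_tree.to_newick()
        assert r1.best_lnl == r2.best_lnl

    def test_too_few_taxa_rejected(self):
        from kdrphylo.phylo_models import Alignment

        aln = Alignment(["a", "b", "c"], ["ACG", "ACG", "ACT"])
        with pytest.raises(SearchError):
            ml_search(aln, HKY, seed=0)

    def test_constrained_result_satisfies_constraint(self, rng):
        t = random_unrooted_tree(8, rng)
        aln = simulate_alignment(t, HKY, 250, seed=31)
        cons = ConstraintSpec(frozenset(t.taxa[:3]))
        res = ml_search(aln, HKY, n_replicates=2, seed=13, constraint=cons)
        assert satisfies_constraint(res.best_tree, cons)

    def test_constrained_never_beats_unconstrained_much(self, rng):
        t = random_unrooted_tree(8, rng)
        aln = simulate_alignment(t, HKY, 250, seed=37)
        cons = ConstraintSpec(frozenset(t.taxa[:4]))
        res_u = ml_search(aln, HKY, n_replicates=3, seed=17)
        res_c = ml_search(aln, HKY, n_replicates=3, seed=17, constraint=cons)
        # the constrained optimum lies inside the unconstrained space
        assert res_c.best_lnl <= res_u.best_lnl + 1e-6


class TestRandomAddition:
    def test_constrained_start_trees_respect_constraint(self, rng):
        t = random_unrooted_tree(10, rng)
        aln = simulate_alignment(t, HKY, 100, seed=41)
        cons = ConstraintSpec(frozenset(t.taxa[2:7]))
        for _ in range(5):
            start = random_addition_tree(aln, rng, cons)
            assert satisfies_constraint(start, cons)

    def test_covers_all_taxa(self, rng):
        t = random_unrooted_tree(9, rng)
        aln = simulate_alignment(t, HKY, 60, seed=43)
        start = random_addition_tree(aln, rng)
        assert sorted(start.taxa) == sorted(t.taxa)


class TestBootstrap:
    def test_support_range_and_site_preservation(self, rng):
        t = random_unrooted_tree(6, rng)
        aln = simulate_alignment(t, HKY, 150, seed=47)
        b = aln.resample_sites(rng)
        assert b.n_sites == aln.n_included
        sup = bootstrap_support(
            aln, HKY, n_boot=5, search_reps_per_boot=1, seed=3,
            focal_tree=ml_search(aln, HKY, 1, seed=1).best_tree,
        )
        assert all(0.0 <= v <= 100.0 for v in sup.values())

    def test_saturated_signal_gives_full_support(self, rng):
        # strongly informative, internally consistent data: every true
        # bipartition should reach 100%
        true = random_unrooted_tree(6, rng, scale=0.1, floor=0.05)
        aln = simulate_alignment(true, SubstModel("JC69"), 4000, seed=53)
        sup = bootstrap_support(
            aln, SubstModel("JC69"), n_boot=5, search_reps_per_boot=2, seed=5,
            focal_tree=true,
        )
        assert set(sup) == true.bipartition_set()
        assert all(v == 100.0 for v in sup.values())

    def test_zero_replicates_empty_map(self, rng):
        t = random_unrooted_tree(5, rng)
        aln = simulate_alignment(t, HKY, 80, seed=59)
        assert bootstrap_support(aln, HKY, n_boot=0, seed=1, focal_tree=t) == {}


class TestMidpointRoot:
    def test_two_tips_rooted_at_middle(self):
        t = PhyloTree(["a", "b"], {0: [1], 1: [0]}, {(0, 1): 2.0})
        rooted = midpoint_root(t)
        kids = rooted.seed_node.child_nodes()
        assert len(kids) == 2
        assert all(abs(k.edge.length - 1.0) < 1e-9 for k in kids)

    def test_symmetric_quartet_rooted_on_internal_branch(self):
        t = PhyloTree.from_newick("((A:1,B:1):0.5,(C:1,D:1):0.5);")
        rooted = midpoint_root(t)
        sides = {
            frozenset(lf.taxon.label for lf in c.leaf_iter())
            for c in rooted.seed_node.child_nodes()
        }
        assert sides == {frozenset({"A", "B"}), frozenset({"C", "D"})}

    def test_rooting_does_not_change_likelihood(self, rng):
        from kdrphylo.phylo_models import tree_loglik

        t = random_unrooted_tree(6, rng)
        aln = simulate_alignment(t, HKY, 100, seed=61)
        before = tree_loglik(t, aln, HKY)
        rooted = midpoint_root(t)
        back = PhyloTree.from_dendropy(rooted)
        assert tree_loglik(back, aln, HKY) == pytest.approx(before, abs=1e-6)

    def test_zero_diameter_flagged(self):
        t = PhyloTree.from_newick("((A:0,B:0):0,(C:0,D:0):0);")
        rooted = midpoint_root(t)
        assert any(
            a.name == "midpoint_warning" for a in rooted.annotations
        )
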