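import numpy as np
import pytest

from kdrphylo.phylo_models import (
    Alignment,
    AlignmentError,
    ModelError,
    SubstModel,
    discrete_gamma_rates,
    fit_model,
    nj_tree,
    optimize_branch_lengths,
    select_model_bic,
    simulate_alignment,
    transition_matrices,
    transition_matrix,
    tree_loglik,
)
from kdrphylo.trees import PhyloTree

from .oracles import brute_force_loglik, random_unrooted_tree

GTR = SubstModel(
    "GTR", freqs=(0.1, 0.2, 0.3, 0.4), rel_rates=(1.0, 2.0, 3.0, 0.5, 4.0, 1.0)
)
MODELS = [
    SubstModel("JC69"),
    SubstModel("K80", kappa=3.0),
    SubstModel("HKY85", freqs=(0.35, 0.15, 0.15, 0.35), kappa=3.0),
    GTR,
    SubstModel("HKY85", freqs=(0.3, 0.2, 0.2, 0.3), kappa=2.0, alpha=0.5),
]


class TestTransitionMatrix:
    @pytest.mark.parametrize("model", MODELS, ids=lambda m: m.family + ("G" if m.alpha else ""))
    @pytest.mark.parametrize("t", [0.0, 0.01, 0.3, 2.5])
    def test_rows_sum_to_one_and_p0_identity(self, model, t):
        P = transition_matrix(model, t)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-10)
        if t == 0.0:
            assert np.allclose(P, np.eye(4), atol=1e-12)

    def test_jc_closed_form(self):
        P = transition_matrix(SubstModel("JC69"), 0.1)
        diag = 0.25 + 0.75 * np.exp(-4 * 0.1 / 3)
        off = 0.25 - 0.25 * np.exp(-4 * 0.1 / 3)
        assert np.allclose(np.diag(P), diag, atol=1e-12)
        assert P[0, 1] == pytest.approx(off, abs=1e-12)

    def test_jc_stationary_limit(self):
        P = transition_matrix(SubstModel("JC69"), 50.0)
        assert np.allclose(P, 0.25, atol=1e-9)

    @pytest.mark.parametrize("model", MODELS[:4], ids=lambda m: m.family)
    def test_chapman_kolmogorov(self, model):
        a, b = 0.07, 0.23
        Pa = transition_matrix(model, a)
        Pb = transition_matrix(model, b)
        Pab = transition_matrix(model, a + b)
        assert np.allclose(Pa @ Pb, Pab, atol=1e-8)

    def test_detailed_balance_gtr(self):
        P = transition_matrix(GTR, 0.37)
        pi = GTR.pi
        assert np.allclose(pi[:, None] * P, (pi[:, None] * P).T, atol=1e-10)

    def test_negative_branch_rejected(self):
        with pytest.raises(ModelError):
            transition_matrix(SubstModel("JC69"), -0.1)

    def test_unit_mean_rate_scaling(self):
        # expected substitutions per unit branch length must be one
        for m in MODELS[:4]:
            q = m.q_matrix()
            assert -(m.pi * np.diag(q)).sum() == pytest.approx(1.0, abs=1e-12)

    def test_category_matrices_match_scalar(self):
        m = MODELS[4]
        rates = m.category_rates()
        stack = transition_matrices(m, 0.2, rates)
        for c, r in enumerate(rates):
            assert np.allclose(stack[c], transition_matrix(m, 0.2, r), atol=1e-12)


def test_discrete_gamma_mean_one():
    for alpha in (0.2, 0.5, 1.0, 5.0):
        r = discrete_gamma_rates(alpha, 4)
        assert r.mean() == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.diff(r) > 0)


class TestTreeLoglik:
    def test_two_identical_one_site_jc_zero_branch(self):
        aln = Alignment(["a", "b"], ["A", "A"])
        tree = PhyloTree(["a", "b"], {0: [1], 1: [0]}, {(0, 1): 0.0})
        assert tree_loglik(tree, aln, SubstModel("JC69")) == pytest.approx(
            np.log(0.25), abs=1e-10
        )

    @pytest.mark.parametrize("n", [4, 5])
    @pytest.mark.parametrize("model", MODELS, ids=lambda m: m.family + ("G" if m.alpha else ""))
    def test_matches_brute_force(self, n, model, rng):
        tree = random_unrooted_tree(n, rng, scale=0.2)
        aln = simulate_alignment(tree, model, 20, seed=int(rng.integers(2**31)))
        # sprinkle missing data
        aln.sequences[0] = "N" + aln.sequences[0][1:]
        aln.sequences[1] = aln.sequences[1][:3] + "-" + aln.sequences[1][4:]
        aln = Alignment(aln.taxa, aln.sequences)
        assert tree_loglik(tree, aln, model) == pytest.approx(
            brute_force_loglik(tree, aln, model), abs=1e-8
        )

    def test_mask_excludes_sites(self, rng):
        tree = random_unrooted_tree(4, rng)
        aln = simulate_alignment(tree, SubstModel("JC69"), 30, seed=1)
        mask = np.ones(30, bool)
        mask[10:] = False
        masked = Alignment(aln.taxa, aln.sequences, mask)
        truncated = Alignment(aln.taxa, [s[:10] for s in aln.sequences])
        assert tree_loglik(tree, masked, GTR) == pytest.approx(
            tree_loglik(tree, truncated, GTR), abs=1e-9
        )

    def test_invariant_under_taxon_reordering(self, rng):
        # pulley principle: likelihood independent of traversal entry point,
        # exercised by permuting alignment rows (tree is matched by name)
        tree = random_unrooted_tree(5, rng)
        aln = simulate_alignment(tree, GTR, 25, seed=2)
        perm = list(reversed(range(5)))
        aln2 = Alignment([aln.taxa[i] for i in perm], [aln.sequences[i] for i in perm])
        assert tree_loglik(tree, aln, GTR) == pytest.approx(
            tree_loglik(tree, aln2, GTR), abs=1e-10
        )

    def test_label_mismatch_is_error(self, rng):
        tree = random_unrooted_tree(4, rng)
        aln = simulate_alignment(tree, SubstModel("JC69"), 10, seed=3)
        aln.taxa[0] = "zzz"
        with pytest.raises(AlignmentError):
            tree_loglik(tree, aln, SubstModel("JC69"))


class TestOptimizeBranchLengths:
    @pytest.mark.parametrize("p", [0.05, 0.10, 0.20])
    def test_two_sequence_jc_closed_form(self, p):
        n = 100
        k = int(p * n)
        s1 = "A" * n
        s2 = "C" * k + "A" * (n - k)
        aln = Alignment(["a", "b"], [s1, s2])
        tree = PhyloTree(["a", "b"], {0: [1], 1: [0]}, {(0, 1): 0.5})
        t2, _ = optimize_branch_lengths(tree, aln, SubstModel("JC69"), tol=1e-10)
        expect = -0.75 * np.log(1 - 4 * p / 3)
        assert t2.lengths[(0, 1)] == pytest.approx(expect, abs=1e-6)

    def test_identical_sequences_shrink_to_floor(self):
        aln = Alignment(["a", "b"], ["ACGTACGT" * 5] * 2)
        tree = PhyloTree(["a", "b"], {0: [1], 1: [0]}, {(0, 1): 0.3})
        t2, _ = optimize_branch_lengths(tree, aln, SubstModel("JC69"), tol=1e-10)
        assert t2.lengths[(0, 1)] <= 1e-6

    def test_monotone_ascent(self, rng):
        tree = random_unrooted_tree(8, rng, scale=0.3)
        model = MODELS[2]
        aln = simulate_alignment(tree, model, 200, seed=4)
        start = tree.copy()
        for k in start.lengths:
            start.lengths[k] = 0.05
        ll0 = tree_loglik(start, aln, model)
        _, ll1 = optimize_branch_lengths(start, aln, model)
        assert ll1 >= ll0


class TestSimulate:
    def test_zero_branch_lengths_identical_taxa(self, rng):
        tree = random_unrooted_tree(5, rng)
        for k in tree.lengths:
            tree.lengths[k] = 0.0
        aln = simulate_alignment(tree, GTR, 50, seed=9)
        assert len(set(aln.sequences)) == 1

    def test_same_seed_identical(self, rng):
        tree = random_unrooted_tree(6, rng)
        a = simulate_alignment(tree, GTR, 40, seed=11)
        b = simulate_alignment(tree, GTR, 40, seed=11)
        assert a.sequences == b.sequences

    def test_stationary_frequencies_on_long_branch(self):
        tree = PhyloTree(["a", "b"], {0: [1], 1: [0]}, {(0, 1): 8.0})
        aln = simulate_alignment(tree, GTR, 10000, seed=13)
        counts = np.zeros(4)
        for ch, i in zip("ACGT", range(4)):
            counts[i] = aln.sequences[1].count(ch)
        freq = counts / counts.sum()
        se = np.sqrt(GTR.pi * (1 - GTR.pi) / 10000)
        assert np.all(np.abs(freq - GTR.pi) < 3 * se + 1e-9)


class TestModelSelection:
    def test_bic_formula(self, rng):
        tree = random_unrooted_tree(6, rng)
        aln = simulate_alignment(tree, SubstModel("JC69"), 350, seed=21)
        fit = fit_model(aln, tree, "JC69")
        k = len(tree.lengths)  # JC69 has no free substitution parameters
        assert fit.bic == pytest.approx(-2 * fit.lnl + k * np.log(350), abs=1e-9)

    def test_single_candidate_returned(self, rng):
        tree = random_unrooted_tree(5, rng)
        aln = simulate_alignment(tree, SubstModel("JC69"), 100, seed=22)
        fit = select_model_bic(aln, candidates=[("K80", False)], tree=tree)
        assert fit.model.family == "K80"

    def test_empty_candidates_rejected(self, rng):
        tree = random_unrooted_tree(5, rng)
        aln = simulate_alignment(tree, SubstModel("JC69"), 100, seed=23)
        with pytest.raises(ModelError):
            select_model_bic(aln, candidates=[], tree=tree)

    def test_jc_data_prefers_jc_over_gtr(self, rng):
        # long alignment simulated under JC: BIC must prefer JC to GTR in
        # most replicates (parameter-count penalty)
        wins = 0
        for i in range(5):
            tree = random_unrooted_tree(6, rng, scale=0.15)
            aln = simulate_alignment(tree, SubstModel("JC69"), 2000, seed=100 + i)
            fit = select_model_bic(
                aln, candidates=[("JC69", False), ("GTR", False)], tree=tree
            )
            wins += fit.model.family == "JC69"
        assert wins >= 4

    def test_nj_tree_recovers_clear_topology(self, rng):
        tree = random_unrooted_tree(6, rng, scale=0.08, floor=0.03)
        aln = simulate_alignment(tree, SubstModel("JC69"), 3000, seed=31)
        assert nj_tree(aln).topology_id() == tree.topology_id()


def test_alignment_rejects_malformed_input(tmp_path):
    bad = tmp_path / "bad.fasta"
    bad.write_text(">a\nACGT\n>b\nACG\n")
    with pytest.raises(AlignmentError):
        Alignment.from_fasta(bad)
    dup = tmp_path / "dup.fasta"
    dup.write_text(">a\nACGT\n>a\nACGT\n")
    with pytest.raises(AlignmentError, match="duplicate"):
        Alignment.from_fasta(dup)
    with pytest.raises(AlignmentError, match="record 'x'"):
        Alignment(["x"], ["AZGT"])
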