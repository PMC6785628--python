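"""Rate heterogeneity, transition matrices, pruning and branch-length ML."""
import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import integrate
from scipy.stats import gamma as gamma_dist

from mitosel.alignment import Alignment
from mitosel.enumeration import enum_site_log_likelihoods
from mitosel.likelihood import (LikelihoodError, leaf_state_matrix,
                                log_likelihood, optimize_branch_lengths,
                                site_log_likelihoods)
from mitosel.models import (discrete_gamma_rates, jc_model, model_config,
                            model_from_config)
from mitosel.trees import PhyloTree


class TestDiscreteGamma:
    def test_single_category(self):
        assert discrete_gamma_rates(1.3, 1) == pytest.approx([1.0])

    @given(st.floats(0.05, 50), st.integers(2, 8))
    def test_mean_one_and_increasing(self, alpha, k):
        r = discrete_gamma_rates(alpha, k)
        assert r.mean() == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.diff(r) > 0)

    def test_matches_quadrature_oracle(self):
        # independent oracle: numerically integrate x * pdf over each
        # equal-mass bin (shape from a fitted mitogenome partition)
        alpha, k = 0.5895, 4
        edges = gamma_dist.ppf(np.linspace(0, 1, k + 1), a=alpha,
                               scale=1 / alpha)
        expected = []
        for lo, hi in zip(edges[:-1], edges[1:]):
            val, _ = integrate.quad(
                lambda x: x * gamma_dist.pdf(x, a=alpha, scale=1 / alpha),
                lo, min(hi, 1e3), limit=200)
            expected.append(val * k)
        assert discrete_gamma_rates(alpha, k) == pytest.approx(
            expected, rel=1e-6)

    def test_nonpositive_alpha_rejected(self):
        with pytest.raises(ValueError):
            discrete_gamma_rates(0.0, 4)

    def test_huge_alpha_collapses_to_equal_rates(self):
        r = discrete_gamma_rates(87.4913, 4)
        assert np.all(np.isfinite(r))
        assert r.mean() == pytest.approx(1.0, abs=1e-12)


class TestTransitionMatrices:
    def test_t0_is_identity(self, nt_gtr_ig):
        assert np.allclose(nt_gtr_ig.transition_matrix(0.0), np.eye(4))

    def test_rows_sum_to_one(self, nt_gtr_ig):
        P = nt_gtr_ig.transition_matrix(0.37)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-10)
        assert np.all(P >= 0)

    @pytest.mark.parametrize("t", [0.01, 0.3, 2.5])
    def test_jc_diagonal_closed_form(self, t):
        P = jc_model(4).transition_matrix(t)
        expected = 0.25 + 0.75 * np.exp(-4.0 * t / 3.0)
        assert np.allclose(np.diag(P), expected, atol=1e-10)

    def test_chapman_kolmogorov(self, nt_gtr_ig):
        P1 = nt_gtr_ig.transition_matrix(0.4)
        P2 = nt_gtr_ig.transition_matrix(0.9)
        P12 = nt_gtr_ig.transition_matrix(1.3)
        assert np.allclose(P1 @ P2, P12, atol=1e-9)

    def test_negative_time_rejected(self, nt_gtr_ig):
        with pytest.raises(ValueError):
            nt_gtr_ig.transition_matrix(-0.1)

    def test_detailed_balance_gtr(self, nt_gtr_ig):
        flux = nt_gtr_ig.pi[:, None] * nt_gtr_ig.Q
        assert np.allclose(flux, flux.T, atol=1e-12)


class TestModelConfig:
    def test_gtr_round_trip(self, nt_gtr_ig):
        import json
        cfg = json.loads(json.dumps(model_config(nt_gtr_ig)))
        back = model_from_config(cfg)
        assert np.allclose(back.Q, nt_gtr_ig.Q)
        assert np.allclose(back.pi, nt_gtr_ig.pi)
        assert back.heterogeneity == nt_gtr_ig.heterogeneity

    def test_empirical_aa_by_name(self, mtmam_g4):
        back = model_from_config(model_config(mtmam_g4))
        assert np.allclose(back.Q, mtmam_g4.Q)


class TestPruning:
    def test_single_leaf_is_log_pi(self):
        t = PhyloTree.from_newick("(a:0.0);")
        model = jc_model(4)
        aln = Alignment(["a"], np.array([["G"]]))
        ll = site_log_likelihoods(t, aln, model)
        assert ll[0] == pytest.approx(np.log(0.25))

    @pytest.mark.parametrize("n_leaves", [3, 4, 5])
    def test_matches_enumeration_nt(self, rng, nt_gtr_ig, n_leaves):
        from conftest import random_bifurcating_newick
        t = PhyloTree.from_newick(random_bifurcating_newick(rng, n_leaves))
        data = rng.choice(list("ACGT-"), size=(n_leaves, 6))
        aln = Alignment(t.leaf_labels, data)
        fast = site_log_likelihoods(t, aln, nt_gtr_ig)
        states = leaf_state_matrix(aln, nt_gtr_ig, t.leaf_labels)
        slow = enum_site_log_likelihoods(t, states, t.leaf_labels, nt_gtr_ig)
        assert np.allclose(fast, slow, rtol=1e-9)

    def test_matches_enumeration_aa(self, rng, mtmam_g4):
        t = PhyloTree.from_newick("((a:0.2,b:0.4):0.1,(c:0.3,d:0.1):0.2);")
        data = rng.choice(list("ARNDCQEGHILKMFPSTWYV"), size=(4, 5))
        aln = Alignment(t.leaf_labels, data, "aa")
        fast = site_log_likelihoods(t, aln, mtmam_g4)
        states = leaf_state_matrix(aln, mtmam_g4, t.leaf_labels)
        slow = enum_site_log_likelihoods(t, states, t.leaf_labels, mtmam_g4)
        assert np.allclose(fast, slow, rtol=1e-9)

    def test_root_invariance_reversible(self, rng, nt_gtr_ig):
        # same unrooted tree written with two different rootings
        data = rng.choice(list("ACGT"), size=(4, 40))
        aln = Alignment(["a", "b", "c", "d"], data)
        t1 = PhyloTree.from_newick("((a:0.1,b:0.2):0.3,(c:0.25,d:0.15):0.0);")
        t2 = PhyloTree.from_newick("(a:0.1,(b:0.2,((c:0.25,d:0.15):0.3)x:0.0)y:0.0);")
        l1 = log_likelihood(t1, aln, nt_gtr_ig)
        l2 = log_likelihood(t2, aln, nt_gtr_ig)
        assert l1 == pytest.approx(l2, abs=1e-8)

    def test_scaling_does_not_change_result(self, rng, nt_gtr_ig, quartet_tree):
        data = rng.choice(list("ACGT"), size=(4, 10))
        aln = Alignment(quartet_tree.leaf_labels, data)
        on = site_log_likelihoods(quartet_tree, aln, nt_gtr_ig, scale=True)
        off = site_log_likelihoods(quartet_tree, aln, nt_gtr_ig, scale=False)
        assert np.allclose(on, off, atol=1e-8)

    def test_taxon_mismatch_rejected(self, quartet_tree, nt_gtr_ig):
        aln = Alignment(["a", "b"], np.array([["A"], ["C"]]))
        with pytest.raises(LikelihoodError):
            site_log_likelihoods(quartet_tree, aln, nt_gtr_ig)


class TestBranchLengthFit:
    def test_identical_sequences_go_to_zero(self):
        t = PhyloTree.from_newick("(a:0.3,b:0.3);")
        aln = Alignment(["a", "b"], np.array([list("ACGTACGT")] * 2))
        fitted, lnl, _ = optimize_branch_lengths(t, aln, jc_model(4))
        assert fitted.total_length() == pytest.approx(0.0, abs=1e-6)

    def test_two_sequence_jc_mle_closed_form(self, rng):
        # closed form: t_hat = -(3/4) ln(1 - 4p/3) for mismatch fraction p
        n, diff = 600, 90
        seq1 = rng.choice(list("ACGT"), size=n)
        seq2 = seq1.copy()
        idx = rng.choice(n, size=diff, replace=False)
        for i in idx:
            seq2[i] = rng.choice([c for c in "ACGT" if c != seq1[i]])
        t = PhyloTree.from_newick("(a:0.1,b:0.1);")
        aln = Alignment(["a", "b"], np.array([seq1, seq2]))
        fitted, _, _ = optimize_branch_lengths(t, aln, jc_model(4))
        p = diff / n
        expected = -0.75 * np.log(1 - 4 * p / 3)
        assert fitted.total_length() == pytest.approx(expected, abs=1e-6)

    def test_refit_is_fixed_point(self, rng, quartet_tree, nt_gtr_ig):
        data = rng.choice(list("ACGT"), size=(4, 200))
        aln = Alignment(quartet_tree.leaf_labels, data)
        t1, lnl1, _ = optimize_branch_lengths(quartet_tree, aln, nt_gtr_ig)
        t2, lnl2, _ = optimize_branch_lengths(t1, aln, nt_gtr_ig,
                                              multistart=False)
        assert lnl2 >= lnl1 - 1e-6
        assert abs(lnl2 - lnl1) < 1e-4

    def test_fit_improves_on_start(self, rng, quartet_tree, nt_gtr_ig):
        data = rng.choice(list("ACGT"), size=(4, 100))
        aln = Alignment(quartet_tree.leaf_labels, data)
        start = log_likelihood(quartet_tree, aln, nt_gtr_ig)
        _, lnl, _ = optimize_branch_lengths(quartet_tree, aln, nt_gtr_ig)
        assert lnl >= start - 1e-9
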