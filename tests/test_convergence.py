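"""Convergence/parallelism classification, pair probabilities, significance."""
import numpy as np
import pytest
from scipy.stats import binom, poisson

from mitosel.ancestral import BranchSubstitution, branch_substitutions, \
    marginal_reconstruction
from mitosel.convergence import (ConvergenceError, classify_change_pair,
                                 convergence_significance,
                                 per_site_pair_probabilities,
                                 poisson_binomial_tail, scan_branch_pairs,
                                 significance_stars, branch_pair_test)
from mitosel.enumeration import mc_pair_pattern_frequencies
from mitosel.models import jc_model
from mitosel.simulate import simulate_aa_alignment
from mitosel.trees import PhyloTree

#: two focal long terminal branches (x, y), each pinned by close relatives
NULL_TREE = ("(((a1:0.05,a2:0.05):0.1,((c1:0.05,c2:0.05):0.05,x#1:0.3):0.1)"
             ":0.05,((e1:0.05,e2:0.05):0.1,((g1:0.05,g2:0.05):0.05,y#1:0.3)"
             ":0.1):0.05);")


def _sub(branch, site, parent, child):
    return BranchSubstitution(branch, site, parent, child, 0.95, 1.0)


class TestClassification:
    def test_parallel_like_L251F(self):
        # Two branches sharing L -> F at one site: parallel evolution
        assert classify_change_pair(_sub(1, 251, "L", "F"),
                                    _sub(2, 251, "L", "F")) == "parallel"

    def test_convergent_like_ST250A(self):
        # S -> A on one branch, T -> A on the other: convergent evolution
        assert classify_change_pair(_sub(1, 250, "S", "A"),
                                    _sub(2, 250, "T", "A")) == "convergent"

    def test_different_derived_states(self):
        assert classify_change_pair(_sub(1, 10, "L", "F"),
                                    _sub(2, 10, "L", "Y")) == "none"

    def test_derived_equal_to_one_ancestor(self):
        # only one branch actually changed state: not convergence
        assert classify_change_pair(_sub(1, 10, "S", "A"),
                                    _sub(2, 10, "A", "A")) == "none"

    def test_site_mismatch_rejected(self):
        with pytest.raises(ConvergenceError):
            classify_change_pair(_sub(1, 10, "L", "F"), _sub(2, 11, "L", "F"))


class TestScan:
    def test_pair_combinatorics_and_planted_event(self, mtmam_g4):
        t = PhyloTree.from_newick(NULL_TREE)
        aln, _, _ = simulate_aa_alignment(t, mtmam_g4, 50, seed=0)
        recon = marginal_reconstruction(t, aln, mtmam_g4)
        focal = [t.node_of_label(n) for n in ("x", "y", "a1")]
        subs = [_sub(focal[0], 5, "L", "F"), _sub(focal[1], 5, "L", "F"),
                _sub(focal[2], 9, "T", "S")]
        pairs = scan_branch_pairs(recon, t, focal, subs)
        assert len(pairs) == 3
        events = pairs[tuple(sorted(focal[:2]))]
        assert len(events) == 1
        assert events[0].type == "parallel" and events[0].notation == "L5F"
        # a site with a change on only one branch yields nothing
        assert all(e.site != 9 for evs in pairs.values() for e in evs)

    def test_single_focal_branch_rejected(self, mtmam_g4):
        t = PhyloTree.from_newick(NULL_TREE)
        aln, _, _ = simulate_aa_alignment(t, mtmam_g4, 10, seed=0)
        recon = marginal_reconstruction(t, aln, mtmam_g4)
        with pytest.raises(ConvergenceError):
            scan_branch_pairs(recon, t, [t.node_of_label("x")], [])

    def test_nested_pair_skipped_with_warning(self, mtmam_g4):
        t = PhyloTree.from_newick(NULL_TREE)
        aln, _, _ = simulate_aa_alignment(t, mtmam_g4, 10, seed=0)
        recon = marginal_reconstruction(t, aln, mtmam_g4)
        x = t.node_of_label("x")
        anc = int(t.parent[x])
        with pytest.warns(UserWarning, match="root-to-tip"):
            pairs = scan_branch_pairs(recon, t, [x, anc], [])
        assert pairs == {}


class TestPairProbabilities:
    def test_zero_length_branch_gives_zero(self, mtmam_g4):
        t = PhyloTree.from_newick(NULL_TREE)
        x = t.node_of_label("x")
        t.branch_length[x] = 0.0
        aln, _, _ = simulate_aa_alignment(t, mtmam_g4, 30, seed=1)
        recon = marginal_reconstruction(t, aln, mtmam_g4)
        probs = per_site_pair_probabilities(
            t, recon, (x, t.node_of_label("y")))
        assert np.allclose(probs, 0.0, atol=1e-12)

    def test_two_state_closed_form(self):
        # symmetric 2-state chain, delta posteriors at state 0 on both
        # parents: P_parallel = p01(t1) * p01(t2), P_convergent = 0
        model = jc_model(2)
        # zero-length non-focal branches pin both parent posteriors at "0"
        t = PhyloTree.from_newick("((a:0.3,b:0.0):0.0,(c:0.5,d:0.0):0.0);")
        aln_data = np.array([["0"], ["0"], ["0"], ["0"]])
        from mitosel.alignment import Alignment
        aln = Alignment(t.leaf_labels, aln_data, "aa")
        recon = marginal_reconstruction(t, aln, model)
        a, c = t.node_of_label("a"), t.node_of_label("c")
        probs = per_site_pair_probabilities(t, recon, (a, c))

        def p01(tt):     # off-diagonal of the 2-state symmetric chain
            return 0.5 - 0.5 * np.exp(-2.0 * tt)

        assert probs[0, 0] == pytest.approx(p01(0.3) * p01(0.5), abs=1e-10)
        assert probs[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_matches_monte_carlo_oracle(self, mtmam_g4):
        t = PhyloTree.from_newick(NULL_TREE)
        aln, _, _ = simulate_aa_alignment(t, mtmam_g4, 40, seed=2)
        recon = marginal_reconstruction(t, aln, mtmam_g4)
        pair = (t.node_of_label("x"), t.node_of_label("y"))
        probs = per_site_pair_probabilities(t, recon, pair)
        rng = np.random.default_rng(99)
        n = 100_000
        for site in (0, 7, 23):
            mc_par, mc_conv = mc_pair_pattern_frequencies(
                t, recon, pair, site, n, rng)
            for mc, exact in ((mc_par, probs[site, 0]),
                              (mc_conv, probs[site, 1])):
                se = max(np.sqrt(exact * (1 - exact) / n), 1e-6)
                assert abs(mc - exact) <= 3 * se + 1e-9

    def test_nested_pair_rejected(self, mtmam_g4):
        t = PhyloTree.from_newick(NULL_TREE)
        aln, _, _ = simulate_aa_alignment(t, mtmam_g4, 10, seed=1)
        recon = marginal_reconstruction(t, aln, mtmam_g4)
        x = t.node_of_label("x")
        with pytest.raises(ConvergenceError):
            per_site_pair_probabilities(t, recon, (x, int(t.parent[x])))


class TestSignificance:
    def test_zero_observed_gives_one(self):
        assert convergence_significance(0, np.full(50, 0.01)) == 1.0

    def test_poisson_tail_closed_form(self):
        # E=0.5 spread over many sites, observed 2
        probs = np.full(5000, 0.5 / 5000)
        p = convergence_significance(2, probs, method="poisson")
        expected = 1 - np.exp(-0.5) * 1.5
        assert p == pytest.approx(expected, abs=1e-6)
        assert p == pytest.approx(0.0902, abs=1e-4)

    def test_binomial_tail_closed_form(self):
        probs = np.full(100, 0.01)
        p = convergence_significance(3, probs)
        assert p == pytest.approx(binom.sf(2, 100, 0.01), abs=1e-6)
        assert p == pytest.approx(0.0794, abs=1e-4)

    def test_poisson_binomial_matches_poisson_for_tiny_probs(self):
        probs = np.full(2000, 1e-4)
        exact = convergence_significance(2, probs)
        approx = poisson.sf(1, probs.sum())
        assert exact == pytest.approx(approx, rel=5e-3)

    def test_monotone_decreasing_in_observed_count(self):
        probs = np.full(200, 0.02)
        ps = [convergence_significance(n, probs) for n in range(6)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_observed_beyond_sites_rejected(self):
        with pytest.raises(ConvergenceError):
            convergence_significance(3, np.array([0.1, 0.2]))

    def test_adjustments(self):
        probs = np.full(100, 0.05)
        p_raw = convergence_significance(4, probs)
        p_mid = convergence_significance(4, probs, adjust="mid")
        _, p_eq = poisson_binomial_tail(4, probs)
        assert p_mid == pytest.approx(p_raw - 0.5 * p_eq)
        rng = np.random.default_rng(0)
        p_rand = convergence_significance(4, probs, adjust="randomized",
                                          rng=rng)
        assert p_raw - p_eq <= p_rand <= p_raw

    def test_stars(self):
        assert significance_stars(0.03) == "*"
        assert significance_stars(0.004) == "**"
        assert significance_stars(0.0004) == "***"
        assert significance_stars(0.2) == ""


class TestCalibration:
    def test_expected_counts_match_observed_on_null(self, mtmam_g4):
        """On data simulated under the model itself, the summed per-site
        parallel probabilities should predict the observed parallel count."""
        t = PhyloTree.from_newick(NULL_TREE)
        bx, by = t.node_of_label("x"), t.node_of_label("y")
        obs, exp = [], []
        for rep in range(12):
            aln, _, _ = simulate_aa_alignment(t, mtmam_g4, 800, seed=rep)
            recon = marginal_reconstruction(t, aln, mtmam_g4)
            scan = branch_substitutions(recon, t, aln)
            result = branch_pair_test(
                recon, t, (bx, by),
                scan_branch_pairs(recon, t, [bx, by],
                                  scan.substitutions)[(min(bx, by),
                                                       max(bx, by))])
            obs.append(result.n_parallel)
            exp.append(result.expected_parallel)
        mean_obs, mean_exp = np.mean(obs), np.mean(exp)
        se = np.sqrt(mean_exp / len(obs))
        assert abs(mean_obs - mean_exp) <= 3 * se

    def test_planted_changes_shrink_p(self, mtmam_g4):
        """More forced parallel changes at fixed expectation -> smaller p."""
        probs = np.full(500, 0.01)
        ps = [convergence_significance(n, probs) for n in (5, 8, 11)]
        assert ps[0] > ps[1] > ps[2]
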