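"""Codon model construction, pruning likelihood, fits, LRTs."""

import itertools
import math

import numpy as np
import pytest

import panretain as pr
from panretain._codons import CODON_INDEX, SENSE_CODONS
from panretain.codonmodel import (
    SiteClassMix,
    TransitionCache,
    TreeLikelihood,
    model_a_caches,
    model_a_lrt,
)
from panretain.simulate import evolve_codons


class TestF1x4:
    def test_uniform_composition_gives_equal_frequencies(self):
        pi = pr.f1x4_frequencies(["ACGT" * 50])
        assert np.allclose(pi, 1 / 61)

    def test_sums_to_one(self):
        pi = pr.f1x4_frequencies(["ATGAAACCCGGGTTTACGT"])
        assert pi.sum() == pytest.approx(1.0)

    def test_matches_counting_oracle(self):
        rng = np.random.default_rng(31)
        seq = "".join(rng.choice(list("ACGT"), 300))
        pi = pr.f1x4_frequencies([seq])
        counts = {nt: seq.count(nt) / len(seq) for nt in "ACGT"}
        raw = np.array(
            [counts[c[0]] * counts[c[1]] * counts[c[2]] for c in SENSE_CODONS]
        )
        assert np.allclose(pi, raw / raw.sum(), atol=1e-12)


class TestRateMatrix:
    def test_omega_zero_kills_nonsynonymous_rates(self, uniform_pi):
        from panretain._codons import GENETIC_CODE

        q = pr.build_q(2.0, 0.0, uniform_pi)
        for i, ci in enumerate(SENSE_CODONS):
            for j, cj in enumerate(SENSE_CODONS):
                if i != j and GENETIC_CODE[ci] != GENETIC_CODE[cj]:
                    assert q[i, j] == 0.0

    def test_rows_sum_to_zero(self, uniform_pi):
        q = pr.build_q(3.0, 0.7, uniform_pi)
        assert np.abs(q.sum(axis=1)).max() < 1e-12

    def test_detailed_balance(self):
        pi = pr.f1x4_frequencies(["ATGAAACCCGGGTTTAACCGGTT" * 10])
        q = pr.build_q(2.5, 0.4, pi)
        flux = pi[:, None] * q
        assert np.abs(flux - flux.T).max() < 1e-14

    def test_unit_expected_rate(self, uniform_pi):
        q = pr.build_q(2.0, 0.5, uniform_pi)
        assert -float(uniform_pi @ np.diag(q)) == pytest.approx(1.0)

    def test_transition_matrix_rows_are_distributions(self, uniform_pi):
        p = TransitionCache(2.0, 0.5, uniform_pi).p_matrix(0.3)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-10)
        assert p.min() >= 0


def brute_force_star_loglik(aln, blens, kappa, omega, pi):
    """Exhaustive sum over the 61 root states of a star tree."""
    tc = TransitionCache(kappa, omega, pi)
    pmats = {name: tc.p_matrix(t) for name, t in blens.items()}
    n_sites = len(next(iter(aln.values()))) // 3
    total = 0.0
    for k in range(n_sites):
        site = 0.0
        for r in range(61):
            term = pi[r]
            for name, seq in aln.items():
                term *= pmats[name][r, CODON_INDEX[seq[3 * k:3 * k + 3]]]
            site += term
        total += math.log(site)
    return total


class TestPruningLikelihood:
    def test_equals_enumeration_on_three_taxon_star(self, uniform_pi):
        lt = pr.read_newick_labeled("(A:0.1,B:0.25,C:0.4);")
        aln = {"A": "ATGTTT", "B": "ATATTC", "C": "CTGTTT"}
        tl = TreeLikelihood(aln, lt)
        got = tl.loglik_branch(pr.CodonModelParams(2.0, {0: 0.5}, uniform_pi))
        want = brute_force_star_loglik(
            aln, {"A": 0.1, "B": 0.25, "C": 0.4}, 2.0, 0.5, uniform_pi
        )
        assert got == pytest.approx(want, abs=1e-8)

    def test_equals_enumeration_on_four_taxon_tree(self, uniform_pi):
        """Brute force sums over both internal states of ((A,B),(C,D))."""
        lt = pr.read_newick_labeled("((A:0.1,B:0.2):0.15,(C:0.3,D:0.05):0.1);")
        aln = {"A": "ATG", "B": "ACG", "C": "ATA", "D": "CTA"}
        tl = TreeLikelihood(aln, lt)
        got = tl.loglik_branch(pr.CodonModelParams(1.5, {0: 0.3}, uniform_pi))
        tc = TransitionCache(1.5, 0.3, uniform_pi)
        pa, pb = tc.p_matrix(0.1), tc.p_matrix(0.2)
        pc, pd = tc.p_matrix(0.3), tc.p_matrix(0.05)
        pu, pv = tc.p_matrix(0.15), tc.p_matrix(0.1)
        ia, ib = CODON_INDEX["ATG"], CODON_INDEX["ACG"]
        ic, id_ = CODON_INDEX["ATA"], CODON_INDEX["CTA"]
        total = 0.0
        for root in range(61):
            for u in range(61):
                for v in range(61):
                    total += (
                        uniform_pi[root]
                        * pu[root, u] * pa[u, ia] * pb[u, ib]
                        * pv[root, v] * pc[v, ic] * pd[v, id_]
                    )
        assert got == pytest.approx(math.log(total), abs=1e-8)

    def test_zero_branches_identical_codon_gives_log_pi(self):
        pi = pr.f1x4_frequencies(["ATGAAACCCGGGTTTAAC" * 5])
        lt = pr.read_newick_labeled("((A:0,B:0):0,C:0);")
        tl = TreeLikelihood({"A": "ATG", "B": "ATG", "C": "ATG"}, lt)
        got = tl.loglik_branch(pr.CodonModelParams(2.0, {0: 0.5}, pi))
        assert got == pytest.approx(math.log(pi[CODON_INDEX["ATG"]]), abs=1e-10)

    def test_invariant_under_root_placement(self, uniform_pi):
        """The model is reversible, so the likelihood must not depend on
        where the (unrooted) tree is rooted."""
        aln = {"A": "ATGTTTAAC", "B": "ACGTTCAAC", "C": "ATATTTAGC", "D": "CTATTTAAC"}
        params = pr.CodonModelParams(2.0, {0: 0.4}, uniform_pi)
        t1 = pr.read_newick_labeled("((A:0.1,B:0.2):0.15,(C:0.3,D:0.05):0.0);")
        t2 = pr.read_newick_labeled("((C:0.3,D:0.05):0.15,(A:0.1,B:0.2):0.0);")
        l1 = TreeLikelihood(aln, t1).loglik_branch(params)
        l2 = TreeLikelihood(aln, t2).loglik_branch(params)
        assert l1 == pytest.approx(l2, abs=1e-8)

    def test_invariant_under_column_order(self, uniform_pi, small_labeled_tree):
        aln, _ = evolve_codons(
            small_labeled_tree, 2.0, {0: 0.3, 1: 0.8}, uniform_pi, 40, seed=2
        )
        params = pr.CodonModelParams(2.0, {0: 0.3, 1: 0.8}, uniform_pi)
        base = TreeLikelihood(aln, small_labeled_tree).loglik_branch(params)
        perm = np.random.default_rng(0).permutation(40)
        shuffled = {
            name: "".join(seq[3 * k:3 * k + 3] for k in perm)
            for name, seq in aln.items()
        }
        other = TreeLikelihood(shuffled, small_labeled_tree).loglik_branch(params)
        assert base == pytest.approx(other, abs=1e-9)

    def test_unmatched_tip_rejected(self, uniform_pi):
        lt = pr.read_newick_labeled("(A:0.1,B:0.1,C:0.1);")
        with pytest.raises(ValueError, match="C"):
            TreeLikelihood({"A": "ATG", "B": "ATG"}, lt)

    def test_zero_length_alignment_rejected(self, uniform_pi):
        lt = pr.read_newick_labeled("(A:0.1,B:0.1);")
        with pytest.raises(ValueError):
            TreeLikelihood({"A": "", "B": ""}, lt)


class TestBranchModelFits:
    def test_two_ratio_nests_one_ratio(self, uniform_pi, small_labeled_tree):
        aln, _ = evolve_codons(
            small_labeled_tree, 2.0, {0: 0.3, 1: 0.9}, uniform_pi, 120, seed=5
        )
        one = pr.fit_branch_model(aln, small_labeled_tree, seed=0, n_restarts=1)
        two = pr.fit_branch_model(
            aln, small_labeled_tree, ratio_spec={0: "bg", 1: "fg"},
            seed=0, n_restarts=1,
        )
        assert two.lnL >= one.lnL - 1e-6
        assert one.np == 2 and two.np == 3

    def test_degenerate_alignment_flagged(self, uniform_pi, small_labeled_tree):
        aln = {name: "ATGTTT" for name in "ABCD"}
        fit = pr.fit_branch_model(aln, small_labeled_tree, seed=0, n_restarts=1)
        assert fit.flat_likelihood and not fit.converged


class TestModelA:
    def test_proportions_sum_to_one_and_ratio_constraint(self):
        mix = SiteClassMix.from_thetas(0.7, 0.6, 0.1, 3.0, 2.0, np.full(61, 1 / 61))
        assert mix.proportions.sum() == pytest.approx(1.0)
        assert mix.p2a / mix.p2b == pytest.approx(mix.p0 / mix.p1)

    def test_null_is_nested_in_alternative(self, uniform_pi, small_labeled_tree):
        mix = SiteClassMix.from_thetas(0.8, 0.6, 0.1, 1.0, 2.0, uniform_pi)
        aln, _ = evolve_codons(
            small_labeled_tree, 2.0, None, uniform_pi, 100, seed=9, site_mix=mix
        )
        f0, fa, res = model_a_lrt(aln, small_labeled_tree, seed=0, n_restarts=1)
        assert fa.lnL >= f0.lnL - 1e-6
        assert fa.np == f0.np + 1
        assert 0.0 <= res.p_value <= 1.0

    def test_shared_scaling_speeds_selected_classes(self, uniform_pi):
        """With a common per-branch-type scale, the foreground class-2
        matrix must evolve faster (shorter self-probability) than class 0."""
        mix = SiteClassMix.from_thetas(0.8, 0.6, 0.1, 8.0, 2.0, uniform_pi)
        caches = model_a_caches(mix)
        p_slow = caches[("fg", 0)].p_matrix(0.5)
        p_fast = caches[("fg", 2)].p_matrix(0.5)
        assert np.diag(p_fast).mean() < np.diag(p_slow).mean()

    def test_positive_selection_recovered(self, uniform_pi):
        """10% of sites at omega = 4 on the foreground: the fit finds
        omega2 >> 1 and flags those sites by posterior > 0.6."""
        nwk = ("((A:0.3,B:0.3):0.2,(((C#1:0.4,D#1:0.4)#1:0.2,"
               "(E#1:0.4,F#1:0.4)#1:0.2)#1:0.3,(G:0.3,H:0.3):0.2):0.1);")
        lt = pr.read_newick_labeled(nwk)
        mix = SiteClassMix.from_thetas(0.9, 0.67, 0.1, 4.0, 2.0, uniform_pi)
        aln, truth = evolve_codons(lt, 2.0, None, uniform_pi, 500, seed=3, site_mix=mix)
        f0, fa, res = model_a_lrt(aln, lt, seed=1, n_restarts=1)
        assert fa.estimates.omega2 > 2.0
        assert res.p_value < 0.01
        _, called = pr.neb_site_posteriors(aln, lt, fa)
        true_sites = set(np.flatnonzero(truth.site_class >= 2) + 1)
        recall = len(true_sites & set(called)) / len(true_sites)
        assert recall >= 0.5


class TestLrt:
    def test_table_one_branch_test(self):
        res = pr.lrt(-8204.98, -8199.87, 1)
        assert res.stat == pytest.approx(10.22, abs=1e-9)
        assert res.p_value == pytest.approx(0.0014, abs=5e-5)

    @pytest.mark.parametrize(
        "stat,df,p",
        [(1.6, 1, 0.2059), (1.02, 2, 0.6005), (3.89, 1, 0.0486)],
    )
    def test_printed_statistics_reproduce_p_values(self, stat, df, p):
        res = pr.lrt(0.0, stat / 2.0, df)
        assert res.p_value == pytest.approx(p, abs=5e-5)

    def test_df2_closed_form(self):
        res = pr.lrt(0.0, 0.51, 2)
        assert res.p_value == pytest.approx(math.exp(-0.51), abs=1e-12)

    def test_equal_likelihoods_give_p_one(self):
        res = pr.lrt(-10.0, -10.0, 1)
        assert res.stat == 0.0 and res.p_value == 1.0

    def test_slightly_negative_clamped(self):
        res = pr.lrt(-10.0, -10.0000001, 1)
        assert res.stat == 0.0

    def test_substantially_negative_rejected(self):
        with pytest.raises(ValueError):
            pr.lrt(-10.0, -11.0, 1)

    def test_df_below_one_rejected(self):
        with pytest.raises(ValueError):
            pr.lrt(-10.0, -9.0, 0)

    def test_p_strictly_decreasing_in_stat(self):
        ps = [pr.lrt(0.0, s / 2.0, 1).p_value for s in (0.5, 1.0, 2.0, 5.0, 10.0)]
        assert all(a > b for a, b in zip(ps, ps[1:]))
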