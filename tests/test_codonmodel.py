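"""Codon model likelihoods: rate matrices, pruning, fitting, LRTs, Holm."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dupsel.codon import CodonAlignment, standard_code
from dupsel.codonmodel import (CodonModelParams, CodonModelSpec, LikelihoodEngine,
                               branch_site_lrt, build_rate_matrix, fit,
                               holm_bonferroni, null_distribution_p,
                               site_class_posteriors, transition_matrix,
                               tree_log_likelihood)
from dupsel.trees import PhyloTree

CODE = standard_code()
IDX = {c: i for i, c in enumerate(CODE.sense_codons)}


@pytest.fixture(scope="module")
def dirichlet_pi():
    return np.random.default_rng(7).dirichlet(np.ones(61) * 3)


class TestRateMatrix:
    def test_rows_sum_to_zero_and_mean_rate_one(self, equal_pi):
        params = CodonModelParams(kappa=2.0, pi=equal_pi, omega0=0.5)
        Q = build_rate_matrix(params, 0.5)
        assert np.abs(Q.sum(axis=1)).max() < 1e-12
        assert -(equal_pi * np.diag(Q)).sum() == pytest.approx(1.0)

    def test_omega_zero_silences_nonsynonymous_rates(self, equal_pi):
        params = CodonModelParams(kappa=2.0, pi=equal_pi, omega0=0.0)
        Q = build_rate_matrix(params, 0.0, scale=False)
        codons = CODE.sense_codons
        for i, j in zip(*np.nonzero(Q > 0)):
            assert CODE.translate(codons[i]) == CODE.translate(codons[j])

    def test_equal_frequencies_kappa_one_gives_uniform_offdiagonals(self, equal_pi):
        params = CodonModelParams(kappa=1.0, pi=equal_pi, omega0=1.0)
        Q = build_rate_matrix(params, 1.0, scale=False)
        vals = Q[Q > 0]
        assert np.allclose(vals, vals[0])

    def test_detailed_balance(self, dirichlet_pi):
        params = CodonModelParams(kappa=2.7, pi=dirichlet_pi, omega0=0.4)
        Q = build_rate_matrix(params, 0.4)
        flux = dirichlet_pi[:, None] * Q
        assert np.abs(flux - flux.T).max() < 1e-14


class TestTransitionMatrix:
    def test_identity_at_zero(self, equal_pi):
        Q = build_rate_matrix(CodonModelParams(kappa=2.0, pi=equal_pi, omega0=0.5), 0.5)
        assert np.allclose(transition_matrix(Q, 0.0), np.eye(61))

    def test_stochastic_rows_and_nonnegative(self, dirichlet_pi):
        Q = build_rate_matrix(CodonModelParams(kappa=2.0, pi=dirichlet_pi, omega0=0.5), 0.5)
        P = transition_matrix(Q, 0.3)
        assert np.abs(P.sum(axis=1) - 1.0).max() < 1e-10
        assert P.min() >= 0.0

    def test_chapman_kolmogorov(self, equal_pi):
        Q = build_rate_matrix(CodonModelParams(kappa=2.0, pi=equal_pi, omega0=0.5), 0.5)
        assert np.allclose(transition_matrix(Q, 0.2),
                           transition_matrix(Q, 0.1) @ transition_matrix(Q, 0.1),
                           atol=1e-12)

    def test_long_branch_converges_to_stationarity(self, dirichlet_pi):
        Q = build_rate_matrix(CodonModelParams(kappa=2.0, pi=dirichlet_pi, omega0=0.5), 0.5)
        P = transition_matrix(Q, 50.0)
        assert np.abs(P - dirichlet_pi[None, :]).max() < 1e-5

    def test_negative_branch_length_rejected(self, equal_pi):
        Q = build_rate_matrix(CodonModelParams(kappa=2.0, pi=equal_pi, omega0=0.5), 0.5)
        with pytest.raises(ValueError):
            transition_matrix(Q, -0.1)


class TestPruningLikelihood:
    def test_zero_path_identical_sequences(self, equal_pi):
        aln = CodonAlignment(ids=["A", "B"], seqs=["AAA", "AAA"])
        tree = PhyloTree.from_newick("(A:0,B:0);")
        params = CodonModelParams(kappa=2.0, pi=equal_pi, omega0=0.5)
        ll = tree_log_likelihood(aln, tree, CodonModelSpec("M0", "equal"), params)
        assert ll == pytest.approx(np.log(1 / 61))

    def test_matches_brute_force_enumeration(self, dirichlet_pi, small_alignment):
        """3-taxon 2-codon pruning equals explicit summation over root states."""
        tree = PhyloTree.from_newick("((A:0.2,B:0.3)n:0.15,C:0.25);")
        params = CodonModelParams(kappa=2.3, pi=dirichlet_pi, omega0=0.4)
        ll = tree_log_likelihood(small_alignment, tree,
                                 CodonModelSpec("M0", "equal"), params)
        Q = build_rate_matrix(params, 0.4)
        PA, PB, PN, PC = (transition_matrix(Q, t) for t in (0.2, 0.3, 0.15, 0.25))
        expected = 0.0
        for site in range(2):
            a, b, c = (IDX[small_alignment.sequence(s)[3 * site:3 * site + 3]]
                       for s in "ABC")
            like = 0.0
            for r in range(61):
                for n in range(61):
                    like += (dirichlet_pi[r] * PN[r, n] * PA[n, a] * PB[n, b] * PC[r, c])
            expected += np.log(like)
        assert ll == pytest.approx(expected, abs=1e-10)

    def test_root_placement_invariance(self, dirichlet_pi, small_alignment):
        tree = PhyloTree.from_newick("((A:0.2,B:0.3)n:0.15,C:0.25);")
        params = CodonModelParams(kappa=2.3, pi=dirichlet_pi, omega0=0.4)
        spec = CodonModelSpec("M0", "equal")
        ref = tree_log_likelihood(small_alignment, tree, spec, params)
        for key in ("A", "B", "C", "n"):
            moved = tree.rerooted_on_branch(key, fraction=0.3)
            assert tree_log_likelihood(small_alignment, moved, spec, params) == \
                pytest.approx(ref, abs=1e-8)

    def test_branch_site_fast_path_equals_general_pruning(self, dirichlet_pi):
        aln = CodonAlignment(ids=list("ABCD"),
                             seqs=["AAATTG", "AACCTG", "GAATTA", "AAATTG"])
        params = CodonModelParams(kappa=2.0, pi=dirichlet_pi, omega0=0.3,
                                  omega2=3.0, p0=0.6, p1=0.3)
        base = PhyloTree.from_newick("((A:0.2,B:0.3)n:0.15,C:0.25,D:0.1);")
        spec = CodonModelSpec("branch_site_alt", "equal")
        for mark in ("A", "n", "C"):
            tree = base.with_foreground(mark)
            fast = LikelihoodEngine(aln, tree, spec, pi=params.pi)
            general = LikelihoodEngine(aln, tree, spec, pi=params.pi,
                                       canonicalize=False)
            assert fast.branch_site_loglike(params) == \
                pytest.approx(general.branch_site_loglike(params), abs=1e-9)


class TestFitting:
    def test_m0_parameter_recovery(self, m0_sim, m0_fit):
        assert m0_fit.converged
        assert abs(m0_fit.params.omega0 - 0.3) < 0.12
        assert abs(m0_fit.params.kappa - 2.0) < 0.7

    def test_fit_is_deterministic_given_seed(self, m0_sim):
        spec = CodonModelSpec("M0", "F3x4")
        f1 = fit(m0_sim["aln"], m0_sim["tree"], spec, seed=3, n_starts=2)
        f2 = fit(m0_sim["aln"], m0_sim["tree"], spec, seed=3, n_starts=2)
        assert f1.lnL == pytest.approx(f2.lnL, abs=1e-6)
        assert f1.params.kappa == pytest.approx(f2.params.kappa, rel=1e-6)

    def test_nested_models_respect_lnl_ordering(self, m0_sim):
        tree = m0_sim["tree"].with_foreground("ab")
        bl = None
        fn = fit(m0_sim["aln"], tree, CodonModelSpec("branch_site_null", "F3x4"),
                 seed=2, n_starts=2)
        fa = fit(m0_sim["aln"], tree, CodonModelSpec("branch_site_alt", "F3x4"),
                 seed=2, n_starts=2, init_params=fn.params)
        assert fa.lnL >= fn.lnL - 1e-6


class TestLRT:
    def test_chi2_reference_points(self):
        assert null_distribution_p(3.841458820694124) == pytest.approx(0.05, abs=1e-6)
        assert null_distribution_p(0.0) == 1.0

    def test_lrt_statistic_and_report_fields(self, m0_sim, m0_fit):
        res = branch_site_lrt(m0_sim["aln"], m0_sim["tree"], "ab", seed=4,
                              m0_fit=m0_fit)
        assert res.df == 1
        assert res.stat >= 0.0
        assert res.stat == pytest.approx(
            max(0.0, 2 * (res.lnL_alt - res.lnL_null)), abs=1e-9)
        assert 0.0 <= res.p_raw <= 1.0


class TestScanBranches:
    def test_single_branch_adjusted_equals_raw(self, m0_sim, m0_fit):
        from dupsel.codonmodel import scan_branches

        results = scan_branches(m0_sim["aln"], m0_sim["tree"], ["ab"],
                                seed=7, m0_fit=m0_fit)
        assert len(results) == 1
        assert results[0].p_adjusted == pytest.approx(results[0].p_raw)

    def test_multi_branch_scan_orders_and_adjusts(self, m0_sim, m0_fit):
        from dupsel.codonmodel import holm_bonferroni, scan_branches

        results = scan_branches(m0_sim["aln"], m0_sim["tree"], ["ab", "C"],
                                seed=7, m0_fit=m0_fit)
        assert [r.foreground_branch for r in results] == ["ab", "C"]
        expected = holm_bonferroni([r.p_raw for r in results])
        assert [r.p_adjusted for r in results] == pytest.approx(expected)
        for r in results:
            assert r.p_adjusted >= r.p_raw - 1e-12

    def test_empty_branch_set_rejected(self, m0_sim):
        from dupsel.codonmodel import scan_branches

        with pytest.raises(ValueError):
            scan_branches(m0_sim["aln"], m0_sim["tree"], [], seed=1)


class TestHolmBonferroni:
    def test_textbook_example(self):
        assert holm_bonferroni([0.001, 0.02, 0.04]) == pytest.approx([0.003, 0.04, 0.04])

    def test_single_p_identity(self):
        assert holm_bonferroni([0.123]) == pytest.approx([0.123])

    def test_capping_at_one(self):
        assert holm_bonferroni([0.5, 0.5, 0.5]) == pytest.approx([1.0, 1.0, 1.0])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            holm_bonferroni([0.1, 1.2])

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=8))
    def test_matches_statsmodels_and_is_monotone(self, pvals):
        from statsmodels.stats.multitest import multipletests

        adj = holm_bonferroni(pvals)
        _, expected, _, _ = multipletests(pvals, method="holm")
        assert np.allclose(adj, expected, atol=1e-12)
        assert all(a >= p - 1e-12 for a, p in zip(adj, pvals))
        order = np.argsort(pvals, kind="stable")
        assert np.all(np.diff(np.asarray(adj)[order]) >= -1e-12)


class TestSiteClassPosteriors:
    def test_rows_sum_to_one_and_m0_rejected(self, m0_sim, m0_fit):
        tree = m0_sim["tree"].with_foreground("ab")
        fa = fit(m0_sim["aln"], tree, CodonModelSpec("branch_site_alt", "F3x4"),
                 seed=5, n_starts=2)
        table = site_class_posteriors(fa)
        cls = table[["class_0", "class_1", "class_2a", "class_2b"]].to_numpy()
        assert np.allclose(np.nansum(cls, axis=1), 1.0, atol=1e-9)
        with pytest.raises(ValueError):
            site_class_posteriors(m0_fit)
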