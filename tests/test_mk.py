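"""McDonald-Kreitman counting, correction, test statistics and suite bounds."""

import math

import numpy as np
import pytest

from dupsel.ancestral import ReconstructedSequence, ReconstructionSuite
from dupsel.codon import CodonAlignment
from dupsel.mk import (MKResult, PopulationSample, SaturationError,
                       count_divergence, count_polymorphisms, jc_correct,
                       mk_test, mk_vs_reconstruction_suite, mk_vs_reference,
                       pairwise_mk)


def _sample(seqs, label="g"):
    ids = [f"h{i}" for i in range(len(seqs))]
    return PopulationSample(label, CodonAlignment(ids=ids, seqs=seqs))


class TestPolymorphismCounting:
    def test_invariant_sample_counts_nothing(self):
        assert count_polymorphisms(_sample(["AAATTT"] * 4)) == (0.0, 0.0)

    def test_single_synonymous_segregating_column(self):
        assert count_polymorphisms(_sample(["TTT", "TTC"])) == (1.0, 0.0)

    def test_triallelic_column_uses_minimum_spanning_arrangement(self):
        # AAG-AAA-AAA/AGA: Lys-Lys synonymous plus Lys-Arg nonsynonymous
        ps, pn = count_polymorphisms(_sample(["AAA", "AAG", "AGA"]))
        assert (ps, pn) == (1.0, 1.0)

    def test_gap_columns_are_skipped(self):
        aln = CodonAlignment(ids=["a", "b"], seqs=["---TTT", "AAATTC"], allow_gaps=True)
        ps, pn = count_polymorphisms(PopulationSample("g", aln))
        assert (ps, pn) == (1.0, 0.0)


class TestDivergenceCounting:
    def test_identical_fixed_sample(self):
        assert count_divergence(_sample(["AAA", "AAA"]), "AAA") == (0.0, 0.0)

    def test_single_fixed_synonymous_difference(self):
        assert count_divergence(_sample(["TTT", "TTT"]), "TTC") == (1.0, 0.0)

    def test_two_step_fixed_difference_uses_pathway_average(self):
        assert count_divergence(_sample(["GCA", "GCA"]), "GTT") == (1.0, 1.0)

    def test_polymorphic_columns_do_not_count_as_divergence(self):
        ds, dn = count_divergence(_sample(["TTT", "TTC"]), "TTA")
        assert (ds, dn) == (0.0, 0.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            count_divergence(_sample(["AAA", "AAA"]), "AAAAAA")


class TestJukesCantor:
    def test_zero_count_maps_to_zero(self):
        assert jc_correct(0.0, 100.0) == 0.0

    def test_closed_form_value(self):
        assert jc_correct(10.0, 100.0) == pytest.approx(10.732563, abs=1e-5)

    def test_correction_inflates(self):
        for p in (0.01, 0.1, 0.3, 0.6):
            assert jc_correct(p * 50, 50) >= p * 50

    def test_saturation_raises(self):
        with pytest.raises(SaturationError):
            jc_correct(80.0, 100.0)


class TestMKTest:
    def test_pairwise_row_neutrality_index(self):
        # pooled GSS1/GSS2-style table: NI = (15/142)/(6/5.1)
        res = mk_test(142.0, 15.0, 5.1, 6.0)
        assert round(res.NI, 2) == 0.09

    def test_outgroup_row_chi_square(self):
        res = mk_test(86, 12, 899.0, 378.1)
        assert round(res.chi2, 1) == 13.5

    def test_proportional_table_is_null(self):
        res = mk_test(10, 5, 20, 10)
        assert res.NI == pytest.approx(1.0)
        assert res.chi2 == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_chi2_invariant_to_transposition_and_swaps(self):
        base = mk_test(30, 12, 50, 8).chi2
        assert mk_test(12, 30, 8, 50).chi2 == pytest.approx(base)
        assert mk_test(50, 8, 30, 12).chi2 == pytest.approx(base)

    def test_ni_reciprocal_under_row_swap(self):
        res = mk_test(30, 12, 50, 8)
        swapped = mk_test(50, 8, 30, 12)
        assert res.NI * swapped.NI == pytest.approx(1.0)

    def test_zero_cells_flag_ni_undefined(self):
        res = mk_test(0.0, 5.0, 10.0, 3.0)
        assert not res.ni_defined and math.isnan(res.NI)
        with pytest.raises(ValueError):
            mk_test(0, 0, 0, 0)


class TestPairwiseMK:
    def test_polymorphism_cells_pool(self):
        a = _sample(["TTTAAAGGG", "TTCAAAGGG"], "A")   # 1 syn poly
        b = _sample(["TTTAAAGGA", "TTTAGAGGA"], "B")   # 1 nsyn poly
        res = pairwise_mk(a, b)
        assert res.counts.Ps == 1.0 and res.counts.Pn == 1.0

    def test_identical_samples_flag_undefined(self):
        a = _sample(["TTTAAA", "TTCAAA"], "A")
        b = _sample(["TTTAAA", "TTCAAA"], "B")
        res = pairwise_mk(a, b)
        assert res.counts.Ds_raw == 0.0 and res.counts.Dn_raw == 0.0
        assert not res.ni_defined and not res.chi2_defined

    def test_divergence_only_at_jointly_fixed_columns(self):
        a = _sample(["TTTAAA", "TTTAAA"], "A")
        b = _sample(["TTCAAA", "TTAAAA"], "B")  # first column polymorphic in B
        res = pairwise_mk(a, b)
        assert res.counts.Ds_raw == 0.0 and res.counts.Dn_raw == 0.0


def _fake_suite(seqs, labels):
    members = [
        ReconstructedSequence(node_id="anc", model_label=lbl, map_codons=s,
                              site_posteriors=np.ones(len(s) // 3),
                              posterior_matrix=np.zeros((len(s) // 3, 61)))
        for s, lbl in zip(seqs, labels)
    ]
    return ReconstructionSuite(node_id="anc", members=members)


class TestSuiteAggregation:
    def test_single_member_collapses_to_point(self):
        sample = _sample(["TTTAAAGGGCCC", "TTCAAAGGGCCC", "TTTAAAGGGCCC"])
        suite = _fake_suite(["TTTAGAGGACCC"], ["M0"])
        rng = mk_vs_reconstruction_suite(sample, suite)
        member = rng.members[0]
        assert rng.Ds_range == (member.counts.Ds, member.counts.Ds)
        assert rng.NI_max == (member.NI if member.ni_defined else rng.NI_max)
        assert rng.chi2_min == member.chi2

    def test_bounds_are_max_ni_and_min_chi2(self):
        sample = _sample(["TTTAAAGGGCCCAAT", "TTCAAAGGGCCCAAT",
                          "TTTAAAGGGCCCAAC"])
        suite = _fake_suite(["TTTAGAGGACCCAAT", "TTTAGAGGACGCAAT"], ["m1", "m2"])
        rng = mk_vs_reconstruction_suite(sample, suite)
        nis = [m.NI for m in rng.members if m.ni_defined]
        chis = [m.chi2 for m in rng.members if m.chi2_defined]
        if nis:
            assert rng.NI_max == pytest.approx(max(nis))
        assert rng.chi2_min == pytest.approx(min(chis))
        assert rng.Ds_range[0] <= rng.Ds_range[1]
        assert rng.Dn_range[0] <= rng.Dn_range[1]

    def test_identical_members_give_zero_width_ranges(self):
        sample = _sample(["TTTAAAGGGCCC", "TTCAAAGGGCCC"])
        suite = _fake_suite(["TTTAGAGGACCC", "TTTAGAGGACCC"], ["m1", "m2"])
        rng = mk_vs_reconstruction_suite(sample, suite)
        assert rng.Ds_range[0] == rng.Ds_range[1]
        assert rng.Dn_range[0] == rng.Dn_range[1]


class TestTablePoolingIdentity:
    """Per-gene polymorphism cells must add up to the pairwise pooled cells."""

    @pytest.mark.parametrize("pa,pb,pooled", [
        ((56, 3), (86, 12), (142, 15)),
        ((56, 3), (97, 8), (153, 11)),
        ((86, 12), (97, 8), (183, 20)),
    ])
    def test_published_pooling_arithmetic(self, pa, pb, pooled):
        assert (pa[0] + pb[0], pa[1] + pb[1]) == pooled

    def test_pooling_identity_on_synthetic_samples(self):
        from dupsel.simulate import PopulationScenario, simulate_population_sample

        base = "AAATTTGGGCCCATTGTTCAA" * 10
        a = simulate_population_sample(PopulationScenario(base, 12, 0.08, 0.04,
                                                          seed=5, gene_label="A"))
        b = simulate_population_sample(PopulationScenario(base, 8, 0.05, 0.05,
                                                          seed=6, gene_label="B"))
        pa = count_polymorphisms(a)
        pb = count_polymorphisms(b)
        pooled = pairwise_mk(a, b)
        assert pooled.counts.Ps == pytest.approx(pa[0] + pb[0])
        assert pooled.counts.Pn == pytest.approx(pa[1] + pb[1])
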