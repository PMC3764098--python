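"""Clone methylation calling, conversion QC, pooled rates, and the two
restriction-protection clone-classification strategies."""

import math

import numpy as np
import pytest

from dldm import bisulfite, sim
from dldm.bisulfite import AMBIGUOUS, CONVERTED, METHYLATED

from conftest import make_allele


class TestAlignClone:
    def test_identical_sequences_pair_equal(self):
        pairs = bisulfite.align_clone("ACGT", "ACGT")
        assert pairs == [(0, "A", "A"), (1, "C", "C"), (2, "G", "G"), (3, "T", "T")]

    def test_single_mismatch_located(self):
        pairs = bisulfite.align_clone("ACGT", "ATGT")
        mism = [(i, r, c) for i, r, c in pairs if r != c]
        assert mism == [(1, "C", "T")]

    def test_length_mismatch_is_hard_error(self):
        with pytest.raises(ValueError, match="5.*4|4.*5"):
            bisulfite.align_clone("ACGTA", "ACGT")


class TestCallMethylation:
    @pytest.mark.parametrize(
        "ref,clone,expected",
        [
            ("CCCC", "TTTT", [CONVERTED] * 4),
            ("CCCC", "CCCC", [METHYLATED] * 4),
            ("ACGA", "AGGA", [AMBIGUOUS]),  # clone G at a reference C
            ("CACT", "TACT", [CONVERTED, METHYLATED]),
        ],
    )
    def test_call_rules(self, ref, clone, expected):
        vec = bisulfite.call_methylation(bisulfite.align_clone(ref, clone))
        assert list(vec.calls) == expected

    def test_non_c_reference_positions_ignored(self):
        vec = bisulfite.call_methylation(bisulfite.align_clone("AGTA", "AGTA"))
        assert vec.positions == () and vec.calls == ()

    def test_contexts_reported(self):
        # C0 in "CG" -> CpG; C3 followed by A then G -> CHG; C6 -> CHH
        vec = bisulfite.call_methylation(bisulfite.align_clone("CGACAGCAA", "CGACAGCAA"))
        assert vec.contexts == ("CpG", "CHG", "CHH")


class TestRates:
    def test_fully_converted_rate_is_one(self):
        vecs = [
            bisulfite.call_methylation(bisulfite.align_clone("CCC", "TTT"))
            for _ in range(3)
        ]
        assert bisulfite.conversion_rate(vecs) == 1.0

    def test_one_retained_in_200(self):
        ref = "C" * 200
        clone = "C" + "T" * 199
        vec = bisulfite.call_methylation(bisulfite.align_clone(ref, clone))
        assert bisulfite.conversion_rate([vec]) == pytest.approx(0.995)

    def test_conversion_rate_tracks_simulated_efficiency(self, small_locus):
        vecs = []
        for i in range(250):  # 10,000 control cytosines at conv_eff 0.998
            allele = make_allele(small_locus, np.zeros(40))
            clone = sim.bisulfite_convert(allele, conv_eff=0.998, seed=1000 + i)
            vecs.append(
                bisulfite.call_methylation(
                    bisulfite.align_clone(small_locus.sequence, clone), f"c{i}"
                )
            )
        rate = bisulfite.conversion_rate(vecs)
        se = math.sqrt(0.998 * 0.002 / 10_000)
        assert abs(rate - 0.998) < 3 * se

    def test_undefined_rate_flagged(self):
        vec = bisulfite.call_methylation(bisulfite.align_clone("AAA", "AAA"))
        with pytest.warns(UserWarning):
            assert math.isnan(bisulfite.conversion_rate([vec]))

    def test_half_methylated_pool(self):
        ref = "C" * 10
        v1 = bisulfite.call_methylation(bisulfite.align_clone(ref, "C" * 10), "a")
        v2 = bisulfite.call_methylation(bisulfite.align_clone(ref, "T" * 10), "b")
        assert bisulfite.average_methylation_rate([v1, v2]) == 0.5
        assert bisulfite.average_methylation_rate([v2]) == 0.0

    def test_pooled_rate_matches_generating_density(self, small_locus):
        # every allele "on" with d_on = 0.36, perfect conversion
        params = sim.SimParams(n_alleles=250, f_on=1.0, d_on=0.36, conv_eff=1.0, seed=8)
        alleles = sim.assign_epialleles(small_locus, params)
        vecs = [
            bisulfite.call_methylation(
                bisulfite.align_clone(
                    small_locus.sequence, sim.bisulfite_convert(a, 1.0, seed=i)
                ),
                a.allele_id,
            )
            for i, a in enumerate(alleles)
        ]
        rate = bisulfite.average_methylation_rate(vecs)
        n_total = 250 * 40
        se = math.sqrt(0.36 * 0.64 / n_total)
        assert abs(rate - 0.36) < 3 * se

    def test_rate_invariant_to_ordering_and_splitting(self):
        ref = "CCCCC"
        clones = ["CTCTC", "TTTTC", "CCCCC", "TTTTT"]
        vecs = [
            bisulfite.call_methylation(bisulfite.align_clone(ref, c), f"c{i}")
            for i, c in enumerate(clones)
        ]
        pooled = bisulfite.average_methylation_rate(vecs)
        assert bisulfite.average_methylation_rate(vecs[::-1]) == pooled
        # cytosine-count-weighted merge of the two halves reproduces the pool
        r1 = bisulfite.average_methylation_rate(vecs[:2])
        r2 = bisulfite.average_methylation_rate(vecs[2:])
        assert (r1 * 10 + r2 * 10) / 20 == pytest.approx(pooled)


class TestStrategy1:
    def test_intact_gatc_reads_cut(self):
        assert bisulfite.strategy1_classify("AAGATCAA", [2]) == "cut"

    def test_converted_sites_read_noncut(self):
        assert bisulfite.strategy1_classify("AAGATTAAGATT", [2, 8]) == "noncut"

    def test_one_intact_site_suffices(self):
        assert bisulfite.strategy1_classify("AAGATTAAGATC", [2, 8]) == "cut"

    def test_no_reference_gatc_is_na(self):
        assert bisulfite.strategy1_classify("AAGATC", []) == "n/a"

    def test_cut_iff_allele_had_methylated_site_c(self, gatc_locus):
        """Exhaustive check: the post-bisulfite Strategy-1 call of a
        perfectly converted clone equals whether the allele carried 5mC at
        at least one GATC-site cytosine."""
        params = sim.SimParams(n_alleles=200, f_on=0.5, d_on=0.6, d_off=0.0, seed=13)
        alleles = sim.assign_epialleles(gatc_locus, params)
        pos_index = {p: i for i, p in enumerate(gatc_locus.cytosine_positions)}
        for i, allele in enumerate(alleles):
            clone = sim.bisulfite_convert(allele, conv_eff=1.0, mC_conv=0.0, seed=i)
            call = bisulfite.strategy1_classify(clone, gatc_locus.gatc_sites)
            had_meth_site = any(
                allele.state[pos_index[g + 3]] == 1 for g in gatc_locus.gatc_sites
            )
            assert call == ("cut" if had_meth_site else "noncut")


class TestStrategy2:
    def test_all_off_population_gives_empty_pool(self, gatc_locus):
        params = sim.SimParams(n_alleles=10, f_on=0.0, d_on=1.0, seed=1)
        alleles = sim.assign_epialleles(gatc_locus, params)
        with pytest.warns(UserWarning, match="empty"):
            assert bisulfite.strategy2_enrich(alleles) == []

    def test_fully_methylated_population_all_survive(self, gatc_locus):
        params = sim.SimParams(n_alleles=10, f_on=1.0, d_on=1.0, seed=1)
        alleles = sim.assign_epialleles(gatc_locus, params)
        assert bisulfite.strategy2_enrich(alleles) == alleles

    def test_mixed_population_matches_site_state_oracle(self, gatc_locus):
        params = sim.SimParams(n_alleles=200, f_on=0.3, d_on=0.8, d_off=0.02, seed=17)
        alleles = sim.assign_epialleles(gatc_locus, params)
        pos_index = {p: i for i, p in enumerate(gatc_locus.cytosine_positions)}
        expected = [
            a
            for a in alleles
            if all(a.state[pos_index[g + 3]] == 1 for g in gatc_locus.gatc_sites)
        ]
        assert bisulfite.strategy2_enrich(alleles) == expected


def test_truth_recovery_with_perfect_conversion(small_locus):
    """With conv_eff=1 and mC_conv=0, calls reproduce each generating state
    vector exactly (methylated where state=1, converted where state=0)."""
    params = sim.SimParams(
        n_alleles=100, f_on=0.4, d_on=0.7, d_off=0.0, conv_eff=1.0, seed=23
    )
    alleles = sim.assign_epialleles(small_locus, params)
    for i, allele in enumerate(alleles):
        clone = sim.bisulfite_convert(allele, conv_eff=1.0, mC_conv=0.0, seed=i)
        vec = bisulfite.call_methylation(
            bisulfite.align_clone(small_locus.sequence, clone), allele.allele_id
        )
        recovered = np.array([c == METHYLATED for c in vec.calls], dtype=np.uint8)
        assert (recovered == allele.state).all()


class TestLollipop:
    def test_rows_sorted_and_symbols_in_position_order(self):
        ref = "CACC"
        v_mixed = bisulfite.call_methylation(bisulfite.align_clone(ref, "CATC"), "b")
        v_open = bisulfite.call_methylation(bisulfite.align_clone(ref, "TATT"), "a")
        text = bisulfite.lollipop_text([v_mixed, v_open])
        lines = text.splitlines()
        assert lines[0] == "a\t○○○"
        assert lines[1] == "b\t●○●"

    def test_summary_counts(self):
        vec = bisulfite.call_methylation(bisulfite.align_clone("CCCC", "CTGC"), "z")
        s = bisulfite.summarize_clone(vec)
        assert (s.n_cytosines, s.n_methylated) == (3, 2)
        assert s.methylation_fraction == pytest.approx(2 / 3)
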