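"""Synthetic-data generator: reference construction, RIP mutation, epiallele
populations, bisulfite conversion, digestion, reads and qPCR."""

import math

import numpy as np
import pytest

from dldm import sim
from dldm.srna import five_prime_end

from conftest import make_allele


class TestGenerateReference:
    def test_empty_sequence(self):
        loc = sim.generate_reference(0)
        assert loc.sequence == ""
        assert loc.cytosine_positions == () and loc.gatc_sites == ()

    def test_zero_gc_has_no_c_or_g(self):
        loc = sim.generate_reference(300, gc_fraction=0.0, seed=3)
        assert set(loc.sequence) <= {"A", "T"}
        assert loc.cytosine_positions == ()

    def test_planted_motif_is_present_and_indexed(self):
        loc = sim.generate_reference(50, planted_gatc=[10], seed=1)
        assert loc.sequence[10:14] == "GATC"
        assert 10 in loc.gatc_sites
        assert 13 in loc.cytosine_positions

    @pytest.mark.parametrize("positions", [[48], [-1], [10, 12]])
    def test_bad_planted_motifs_rejected(self, positions):
        with pytest.raises(ValueError):
            sim.generate_reference(50, planted_gatc=positions)

    def test_indexes_address_what_they_claim(self):
        loc = sim.generate_reference(2000, planted_gatc=[100, 700], seed=7)
        assert all(loc.sequence[i] == "C" for i in loc.cytosine_positions)
        assert all(loc.sequence[g : g + 4] == "GATC" for g in loc.gatc_sites)
        assert list(loc.cytosine_positions) == sorted(set(loc.cytosine_positions))


class TestApplyRip:
    def test_p_mut_zero_is_noop(self):
        loc = sim.generate_reference(200, seed=5)
        assert sim.apply_rip(loc, (0, 200), 0.0).sequence == loc.sequence

    def test_caca_becomes_tata(self):
        loc = sim.SimulatedLocus.from_sequence("x", "CACA")
        assert sim.apply_rip(loc, (0, 4), 1.0).sequence == "TATA"

    def test_tpg_event_on_bottom_strand(self):
        # top-strand TpG is the bottom strand's CpA; the G mutates to A
        loc = sim.SimulatedLocus.from_sequence("x", "ATGA")
        assert sim.apply_rip(loc, (0, 4), 1.0).sequence == "ATAA"

    def test_outside_interval_untouched(self):
        loc = sim.SimulatedLocus.from_sequence("x", "CACACACA")
        out = sim.apply_rip(loc, (4, 8), 1.0)
        assert out.sequence[:4] == "CACA" and out.sequence[4:] == "TATA"

    def test_interval_out_of_range(self):
        loc = sim.SimulatedLocus.from_sequence("x", "CACA")
        with pytest.raises(ValueError):
            sim.apply_rip(loc, (0, 10), 1.0)


class TestAssignEpialleles:
    def test_all_off_with_zero_density_is_all_zero(self, small_locus):
        params = sim.SimParams(n_alleles=20, f_on=0.0, d_on=0.9, d_off=0.0, seed=1)
        alleles = sim.assign_epialleles(small_locus, params)
        assert all(a.label == "off" and not a.state.any() for a in alleles)

    def test_all_on_full_density_is_all_one(self, small_locus):
        params = sim.SimParams(n_alleles=20, f_on=1.0, d_on=1.0, seed=1)
        alleles = sim.assign_epialleles(small_locus, params)
        assert all(a.label == "on" and a.state.all() for a in alleles)

    def test_on_fraction_is_binomial(self, small_locus):
        n, f = 10_000, 0.15
        params = sim.SimParams(n_alleles=n, f_on=f, d_on=1.0, seed=11)
        alleles = sim.assign_epialleles(small_locus, params)
        observed = sum(a.label == "on" for a in alleles) / n
        se = math.sqrt(f * (1 - f) / n)
        assert abs(observed - f) < 3 * se

    def test_seeded_reproducibility(self, small_locus):
        params = sim.SimParams(n_alleles=30, f_on=0.3, d_on=0.8, seed=42)
        a = sim.assign_epialleles(small_locus, params)
        b = sim.assign_epialleles(small_locus, params)
        assert [x.label for x in a] == [y.label for y in b]
        assert all((x.state == y.state).all() for x, y in zip(a, b))
        assert (
            sim.bisulfite_convert(a[0], 0.99, seed=7)
            == sim.bisulfite_convert(b[0], 0.99, seed=7)
        )


class TestBisulfiteConvert:
    def test_full_conversion_replaces_every_c(self, small_locus):
        allele = make_allele(small_locus, np.zeros(40))
        converted = sim.bisulfite_convert(allele, conv_eff=1.0)
        assert "C" not in converted
        assert len(converted) == len(small_locus.sequence)

    def test_methylated_allele_fully_protected(self, small_locus):
        allele = make_allele(small_locus, np.ones(40))
        assert sim.bisulfite_convert(allele, conv_eff=1.0, mC_conv=0.0) == (
            small_locus.sequence
        )

    def test_retained_c_fraction_matches_failure_rate(self, small_locus):
        # 250 unmethylated alleles x 40 C = 10,000 cytosines at conv_eff 0.995
        retained = total = 0
        for i in range(250):
            allele = make_allele(small_locus, np.zeros(40))
            out = sim.bisulfite_convert(allele, conv_eff=0.995, seed=i)
            retained += out.count("C")
            total += 40
        rate = retained / total
        se = math.sqrt(0.005 * 0.995 / total)
        assert abs(rate - 0.005) < 3 * se


class TestDigestAlleles:
    def test_methylated_site_resists_bfuci_but_not_dpnii(self, gatc_locus):
        # state: methylate both GATC-site cytosines only
        site_positions = {g + 3 for g in gatc_locus.gatc_sites}
        state = [1 if p in site_positions else 0 for p in gatc_locus.cytosine_positions]
        allele = make_allele(gatc_locus, state)
        assert sim.digest_alleles([allele], "BfuCI").outcomes == ["intact"]
        assert sim.digest_alleles([allele], "DpnII").outcomes == ["cleaved"]

    def test_one_unmethylated_site_is_cleaved_by_bfuci(self, gatc_locus):
        g0 = gatc_locus.gatc_sites[0]
        state = [
            1 if p == g0 + 3 else 0 for p in gatc_locus.cytosine_positions
        ]  # second site left unmethylated
        allele = make_allele(gatc_locus, state)
        assert sim.digest_alleles([allele], "BfuCI").outcomes == ["cleaved"]

    def test_no_gatc_site_means_intact_with_warning(self, small_locus):
        allele = make_allele(small_locus, np.zeros(40))
        with pytest.warns(UserWarning, match="no GATC sites"):
            res = sim.digest_alleles([allele], "DpnII")
        assert res.outcomes == ["intact"] and res.survivors == [allele]

    def test_bfuci_survivors_match_bruteforce_oracle(self, gatc_locus):
        params = sim.SimParams(n_alleles=300, f_on=0.4, d_on=0.7, d_off=0.05, seed=9)
        alleles = sim.assign_epialleles(gatc_locus, params)
        survivors = sim.digest_alleles(alleles, "BfuCI").survivors
        pos_index = {p: i for i, p in enumerate(gatc_locus.cytosine_positions)}
        expected = [
            a
            for a in alleles
            if all(a.state[pos_index[g + 3]] == 1 for g in gatc_locus.gatc_sites)
        ]
        assert survivors == expected


class TestSimulateReads:
    def test_zero_reads_empty(self, small_locus):
        assert sim.simulate_reads(small_locus, {"+": [1.0]}, 0) == []

    def test_concentrated_intensity_lands_in_one_window(self):
        loc = sim.generate_reference(1000, seed=2)
        profile = np.zeros(10)
        profile[4] = 1.0
        reads = sim.simulate_reads(loc, {"+": profile, "-": profile}, 500, seed=3)
        assert all(400 <= five_prime_end(r) < 500 for r in reads)

    def test_all_zero_intensity_rejected(self, small_locus):
        with pytest.raises(ValueError, match="zero"):
            sim.simulate_reads(small_locus, {"+": [0.0, 0.0]}, 10)

    def test_rdna_fraction_binomial(self):
        loc = sim.generate_reference(2000, seed=4)
        rdna = [("rdna_chr", 0, 5000)]
        reads = sim.simulate_reads(
            loc, {"+": np.ones(20)}, 10_000, rdna_intervals=rdna,
            rdna_fraction=0.1, seed=5,
        )
        n_rdna = sum(r.chrom == "rdna_chr" for r in reads)
        se = math.sqrt(0.1 * 0.9 * 10_000)
        assert abs(n_rdna - 1000) < 3 * se
        assert len(reads) == 10_000


class TestSimulateQpcr:
    def test_unit_quantity_hits_reference_ct(self):
        assert sim.simulate_qpcr(1.0, 2.0, 0.0) == pytest.approx(20.0)

    def test_halving_costs_one_cycle(self):
        assert sim.simulate_qpcr(0.5, 2.0, 0.0) == pytest.approx(21.0)

    def test_log_law_two_halvings(self):
        ct1 = sim.simulate_qpcr(0.5, 2.0, 0.0)
        ct2 = sim.simulate_qpcr(0.25, 2.0, 0.0)
        assert ct2 - ct1 == pytest.approx(1.0)
        assert ct2 - sim.simulate_qpcr(1.0, 2.0, 0.0) == pytest.approx(2.0)

    @pytest.mark.parametrize("q", [0.0, -1.0])
    def test_nonpositive_quantity_rejected(self, q):
        with pytest.raises(ValueError):
            sim.simulate_qpcr(q, 2.0, 0.0)


def test_on_fraction_round_trip_exact(small_locus):
    """With d_on=1, d_off=0 and perfect conversion, a clone retains a C iff
    its allele was 'on', so the retained-C clone fraction equals the on
    fraction exactly."""
    params = sim.SimParams(n_alleles=400, f_on=0.2, d_on=1.0, d_off=0.0, seed=21)
    alleles = sim.assign_epialleles(small_locus, params)
    clones = [
        sim.bisulfite_convert(a, conv_eff=1.0, mC_conv=0.0, seed=i)
        for i, a in enumerate(alleles)
    ]
    with_c = sum("C" in c for c in clones)
    assert with_c == sum(a.label == "on" for a in alleles)
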