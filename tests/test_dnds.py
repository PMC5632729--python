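from itertools import permutations

import numpy as np
import pytest
from Bio.Data.CodonTable import unambiguous_dna_by_id

from plastcomp import codonize, concatenate_and_rate, ng86_pair
from plastcomp.dnds import pathway_counts, syn_site_fraction
from plastcomp.model import SyntenicLocus
from plastcomp.synthetic import simulate_codon_pairs

_TABLE = unambiguous_dna_by_id[1]
_FW = dict(_TABLE.forward_table)
_STOPS = set(_TABLE.stop_codons)
SENSE = sorted(set("".join(c) for c in
                   (a + b + d for a in "ACGT" for b in "ACGT" for d in "ACGT"))
               - _STOPS)


def oracle_pathways(c1, c2):
    """Independent recursive pathway enumeration (stop-free paths averaged;
    falls back to all paths when every order hits a stop)."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    results = []

    def rec(cur, remaining, sd, nd):
        if not remaining:
            results.append((sd, nd))
            return
        for pos in remaining:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in _STOPS:
                continue
            step_syn = _FW[cur] == _FW[nxt]
            rec(nxt, [p for p in remaining if p != pos],
                sd + step_syn, nd + (not step_syn))

    rec(c1, diff, 0, 0)
    if not results:
        for order in permutations(diff):
            cur, sd, nd = c1, 0, 0
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
                syn = (cur not in _STOPS and nxt not in _STOPS
                       and _FW.get(cur) == _FW.get(nxt))
                sd, nd = sd + syn, nd + (not syn)
                cur = nxt
            results.append((sd, nd))
    sd = sum(r[0] for r in results) / len(results)
    nd = sum(r[1] for r in results) / len(results)
    return sd, nd


def _aligned_coding(s1, s2):
    l = SyntenicLocus("g", "coding", s1.replace("-", ""), s2.replace("-", ""))
    l.aln1, l.aln2 = s1, s2
    return l


class TestPathwayCounts:
    def test_all_sense_codon_pairs_match_bruteforce_enumeration(self):
        for c1 in SENSE:
            for c2 in SENSE:
                assert pathway_counts(c1, c2) == pytest.approx(
                    oracle_pathways(c1, c2)), (c1, c2)

    def test_symmetric_in_codon_order(self):
        rng = np.random.default_rng(3)
        for _ in range(300):
            c1 = SENSE[rng.integers(0, len(SENSE))]
            c2 = SENSE[rng.integers(0, len(SENSE))]
            assert pathway_counts(c1, c2) == pytest.approx(
                pathway_counts(c2, c1))

    def test_counts_sum_to_number_of_differences(self):
        for c1, c2 in [("AAA", "AAA"), ("AAA", "AAG"), ("AAA", "AGG"),
                       ("AAA", "GGG"), ("TTT", "AGC")]:
            d = sum(a != b for a, b in zip(c1, c2))
            sd, nd = pathway_counts(c1, c2)
            assert sd + nd == pytest.approx(d)


class TestSites:
    def test_synonymous_sites_of_fourfold_codon(self):
        # GGx is four-fold degenerate at position 3 only
        assert syn_site_fraction("GGG") == pytest.approx(1.0)

    def test_site_counts_partition_three_per_codon(self):
        for codon in SENSE:
            s = syn_site_fraction(codon)
            assert 0.0 <= s <= 3.0

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            syn_site_fraction("TAA")


class TestNG86Pair:
    def test_identical_sequences_give_zero_rates(self):
        rec = ng86_pair([("ATG", "ATG"), ("GGG", "GGG")])
        assert rec.nd == rec.sd == 0 and rec.dn == rec.ds == 0.0
        assert rec.omega is None  # ds = 0: ratio undefined

    def test_single_synonymous_difference(self):
        rec = ng86_pair([("TTT", "TTC")])  # both Phe
        assert rec.sd == pytest.approx(1.0)
        assert rec.nd == pytest.approx(0.0)
        assert rec.dn == 0.0
        # a single codon has ~1/3 synonymous site, so ps saturates the
        # Jukes-Cantor correction; the record must say so rather than guess
        assert rec.saturated and rec.ds is None

    def test_site_counts_sum_to_three_per_codon(self):
        pairs = [("ATG", "ATG"), ("GGG", "GGA"), ("TTT", "TTC")]
        rec = ng86_pair(pairs)
        assert rec.n_sites + rec.s_sites == pytest.approx(3 * len(pairs))

    def test_saturated_distances_flagged(self):
        rec = ng86_pair([("AAA", "GGG")] * 10 + [("CCC", "TTT")] * 10)
        assert rec.saturated

    def test_no_pairs_rejected(self):
        with pytest.raises(ValueError):
            ng86_pair([])

    def test_symmetry_of_full_record(self):
        rng = np.random.default_rng(5)
        pairs = [(SENSE[rng.integers(0, len(SENSE))],
                  SENSE[rng.integers(0, len(SENSE))]) for _ in range(50)]
        a = ng86_pair(pairs)
        b = ng86_pair([(y, x) for x, y in pairs])
        assert (a.nd, a.sd, a.n_sites, a.s_sites) == \
            pytest.approx((b.nd, b.sd, b.n_sites, b.s_sites))


class TestCodonize:
    def test_gapped_codons_skipped_neighbors_kept(self):
        l = _aligned_coding("ATGAAACCCGGGTAA", "ATG---CCCGGGTAA")
        pairs = codonize(l)
        assert pairs == [("ATG", "ATG"), ("CCC", "CCC"), ("GGG", "GGG")]

    def test_terminal_stop_pair_removed(self):
        l = _aligned_coding("ATGAAATAA", "ATGAAATAA")
        assert len(codonize(l)) == 2

    def test_internal_stop_in_one_sequence_skipped_with_warning(self):
        l = _aligned_coding("ATGTAACCCTAA", "ATGCAACCCTAA")
        with pytest.warns(UserWarning):
            pairs = codonize(l)
        assert ("TAA", "CAA") not in pairs and len(pairs) == 2

    def test_internal_stop_in_both_flags_pseudogene(self):
        l = _aligned_coding("ATGTAACCCTAA", "ATGTAACCCTAA")
        with pytest.raises(ValueError):
            codonize(l)

    def test_unaligned_locus_rejected(self):
        with pytest.raises(ValueError):
            codonize(SyntenicLocus("g", "coding", "ATGTAA", "ATGTAA"))


class TestConcatenation:
    def test_counts_are_additive_across_genes(self):
        g1 = _aligned_coding("ATGAAACCCGGGTAA", "ATGAAGCCCGGGTAA")
        g2 = _aligned_coding("ATGTTTACTTAA", "ATGTTCAGTTAA")
        r1 = ng86_pair(codonize(g1))
        r2 = ng86_pair(codonize(g2))
        rc = concatenate_and_rate([g1, g2])
        assert rc.nd == pytest.approx(r1.nd + r2.nd)
        assert rc.sd == pytest.approx(r1.sd + r2.sd)
        assert rc.n_sites == pytest.approx(r1.n_sites + r2.n_sites)
        assert rc.s_sites == pytest.approx(r1.s_sites + r2.s_sites)
        assert rc.n_codons == r1.n_codons + r2.n_codons

    def test_empty_intersection_rejected(self):
        with pytest.raises(ValueError):
            concatenate_and_rate([])


class TestOmegaRecovery:
    def test_planted_omega_ordering_and_magnitude(self):
        estimates = {}
        for omega in (0.1, 0.5, 1.0):
            pairs, _ = simulate_codon_pairs(
                1000, omega, np.random.default_rng(19))
            estimates[omega] = ng86_pair(pairs).omega
        assert estimates[0.1] < estimates[0.5] < estimates[1.0]
        for omega, est in estimates.items():
            assert 0.5 * omega <= est <= 1.5 * omega
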