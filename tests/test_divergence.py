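import numpy as np
import pytest

from plastcomp import (
    AlignParams,
    align_locus,
    count_events,
    detect_inverted_repeat,
    canonicalize,
    divergence_statistics,
    divergence_table,
    extract_syntenic_loci,
    rank_hotspots,
    sv_percent,
    trim_terminal_gaps,
)
from plastcomp.model import DivergenceRecord, SyntenicLocus
from plastcomp import synthetic as syn


def gotoh_score(s1, s2, match=1.0, mismatch=-1.0, open_=-4.0, extend=-1.0):
    """Brute-force optimal global affine-gap score (first gap position costs
    ``open_``, later positions ``extend``)."""
    n, m = len(s1), len(s2)
    NEG = float("-inf")
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in s2 (s1 consumed)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in s1
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = open_ + (i - 1) * extend
    for j in range(1, m + 1):
        Y[0][j] = open_ + (j - 1) * extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = match if s1[i - 1] == s2[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + sub
            X[i][j] = max(M[i - 1][j] + open_, X[i - 1][j] + extend,
                          Y[i - 1][j] + open_)
            Y[i][j] = max(M[i][j - 1] + open_, Y[i][j - 1] + extend,
                          X[i][j - 1] + open_)
    return max(M[n][m], X[n][m], Y[n][m])


def alignment_score(a, b, match=1.0, mismatch=-1.0, open_=-4.0, extend=-1.0):
    score, in_gap = 0.0, False
    for x, y in zip(a, b):
        if x == "-" or y == "-":
            score += extend if in_gap else open_
            in_gap = True
        else:
            in_gap = False
            score += match if x == y else mismatch
    return score


def walker_counts(a, b):
    """Independent single-pass re-implementation of event counting."""
    conserved = subs = events = 0
    prev_gap = False
    for x, y in zip(a, b):
        gap = x == "-" or y == "-"
        if gap and not prev_gap:
            events += 1
        prev_gap = gap
        if not gap and "N" not in (x, y):
            conserved += x == y
            subs += x != y
    return conserved, subs, events


class TestAlignLocus:
    def test_identical_sequences_align_gapless(self):
        l = SyntenicLocus("s", "spacer", "ACGTACGTAA", "ACGTACGTAA")
        align_locus(l)
        assert l.aln1 == l.aln2 == "ACGTACGTAA"

    @pytest.mark.parametrize("s1,s2", [
        ("ACGTACGT", "ACGACGT"),
        ("TTTTGGGCCC", "TTTTCCC"),
        ("ACACACGT", "ACACGT"),
    ])
    def test_score_is_optimal_against_dp_oracle(self, s1, s2):
        l = SyntenicLocus("s", "spacer", s1, s2)
        align_locus(l)
        assert alignment_score(l.aln1, l.aln2) == pytest.approx(gotoh_score(s1, s2))
        assert l.aln1.replace("-", "") == s1
        assert l.aln2.replace("-", "") == s2

    def test_single_deletion_yields_single_one_base_gap(self):
        l = SyntenicLocus("s", "spacer", "ACGTACGT", "ACGACGT")
        align_locus(l)
        assert l.aln2.count("-") == 1 and "-" not in l.aln1

    def test_codon_aware_gap_falls_on_codon_boundary(self):
        s1 = "ATGAAACCCGGGTTTTAA"
        s2 = "ATGAAAGGGTTTTAA"  # one whole codon missing
        l = SyntenicLocus("g", "coding", s1, s2)
        align_locus(l)
        assert len(l.aln1) % 3 == 0
        gap_start = l.aln2.index("-")
        assert l.aln2[gap_start:gap_start + 3] == "---"
        assert l.aln2.count("-") == 3
        assert gap_start % 3 == 0

    def test_frameshifted_coding_locus_flagged_and_aligned_as_nucleotide(self):
        l = SyntenicLocus("g", "coding", "ATGAAACCCGGGTTTTAA", "ATGAAACCGGGTTTTAA")
        with pytest.warns(UserWarning):
            align_locus(l)
        assert l.flagged

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_locus(SyntenicLocus("s", "spacer", "", "ACGT"))


class TestTrimAndCount:
    def _aligned(self, a, b):
        l = SyntenicLocus("x", "spacer", a.replace("-", ""), b.replace("-", ""))
        l.aln1, l.aln2 = a, b
        return l

    def test_terminal_gap_columns_removed(self):
        l = self._aligned("---ACGT", "GGGACGT")
        trim_terminal_gaps(l)
        assert (l.aln1, l.aln2) == ("ACGT", "ACGT")

    def test_trim_is_idempotent(self):
        l = self._aligned("AC-GT", "ACTGT")
        trim_terminal_gaps(l)
        first = (l.aln1, l.aln2)
        trim_terminal_gaps(l)
        assert (l.aln1, l.aln2) == first

    def test_overhangs_on_both_ends_leave_core(self):
        l = self._aligned("--ACGTAC", "GGACGT--")
        trim_terminal_gaps(l)
        assert (l.aln1, l.aln2) == ("ACGT", "ACGT")

    def test_full_trim_flags_locus(self):
        l = self._aligned("AA--", "--GG")
        with pytest.warns(UserWarning):
            trim_terminal_gaps(l)
        assert l.flagged and l.aln1 == ""

    @pytest.mark.parametrize("a,b,expected", [
        ("ACGT", "ACGT", (4, 0, 0)),
        ("AC--GTA", "ACTTGCA", (4, 1, 1)),
        ("ACNGT", "ACCGT", (4, 0, 0)),  # the N column is ignored
        ("AC--G--T", "ACTTGCCT", (4, 0, 2)),
    ])
    def test_hand_counted_events(self, a, b, expected):
        assert count_events(self._aligned(a, b)) == expected

    def test_counting_matches_walker_oracle_on_random_alignments(self):
        rng = np.random.default_rng(13)
        for _ in range(200):
            cols = []
            for _ in range(rng.integers(1, 80)):
                kind = rng.random()
                x = "ACGTN"[rng.integers(0, 5)]
                y = "ACGTN"[rng.integers(0, 5)]
                if kind < 0.15:
                    cols.append((x, "-"))
                elif kind < 0.3:
                    cols.append(("-", y))
                else:
                    cols.append((x, y))
            a = "".join(c[0] for c in cols)
            b = "".join(c[1] for c in cols)
            assert count_events(self._aligned(a, b)) == walker_counts(a, b)

    def test_count_events_symmetric_in_sequence_order(self):
        a, b = "AC--GTANCT", "ACTTGCAN-T"
        b = b.replace("N-", "NC")  # keep no gap-gap columns
        assert count_events(self._aligned(a, b)) == \
            count_events(self._aligned(b, a))


class TestSVPercent:
    @pytest.mark.parametrize("c,s,i,expected", [
        (95, 3, 2, 5.0),
        (100, 0, 0, 0.0),
        (0, 1, 0, 100.0),
    ])
    def test_formula(self, c, s, i, expected):
        assert sv_percent(c, s, i) == pytest.approx(expected)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            sv_percent(0, 0, 0)

    def test_zero_iff_no_mutations(self):
        assert sv_percent(50, 0, 0) == 0.0
        assert sv_percent(50, 1, 0) > 0.0


class TestExtractSyntenicLoci:
    def test_identical_genomes_pair_every_locus_identically(self, ancestor):
        p, truth = ancestor
        part = detect_inverted_repeat(p, 1000)
        loci = extract_syntenic_loci(p, p, part, part)
        assert loci
        assert all(l.seq1 == l.seq2 for l in loci)
        coding = {l.name for l in loci if l.locus_class == "coding"}
        assert {"ndhF", "rbcL", "matK", "ycf1"} <= coding

    def test_gene_missing_in_one_genome_drops_locus_and_its_spacers(self, compact_cfg):
        pA, tA = syn.generate_ancestor(compact_cfg)
        pDel, tDel = syn.apply_scenario(
            compact_cfg, syn.Scenario("C", delete=("ndhD",)))
        partA = detect_inverted_repeat(pA, 1000)
        partD = detect_inverted_repeat(pDel, 1000)
        loci = extract_syntenic_loci(pA, pDel, partA, partD)
        names = {l.name for l in loci}
        assert "ndhD" not in names
        assert not any("ndhD" in n for n in names)

    def test_short_noncoding_loci_filtered(self, ancestor):
        p, truth = ancestor
        part = detect_inverted_repeat(p, 1000)
        loci = extract_syntenic_loci(p, p, part, part, min_noncoding_len=150)
        assert all(min(len(l.seq1), len(l.seq2)) >= 150
                   for l in loci if l.locus_class != "coding")

    def test_ir_resident_loci_counted_once(self, ancestor):
        p, truth = ancestor
        part = detect_inverted_repeat(p, 1000)
        with_part = {l.name for l in extract_syntenic_loci(p, p, part, part)}
        without = {l.name for l in extract_syntenic_loci(p, p)}
        # the IRb-side spacer stays; its IRa mirror is dropped only when the
        # partition is known
        assert "rrn16-trnI" in with_part and "trnI-rrn16" not in with_part
        assert {"rrn16-trnI", "trnI-rrn16"} <= without


class TestHotspotsAndStatistics:
    def _rec(self, name, sv, cls="spacer", gc=30.0, indels=0, subs=0):
        return DivergenceRecord(name, cls, 100, subs, indels, sv, gc)

    def test_topk_by_sv(self):
        recs = [self._rec("a", 5.0), self._rec("b", 2.0), self._rec("c", 9.0)]
        top = rank_hotspots(recs, 2)
        assert [r.name for r in top] == ["c", "a"]

    def test_ties_break_alphabetically(self):
        recs = [self._rec("b", 5.0), self._rec("a", 5.0), self._rec("c", 1.0)]
        assert [r.name for r in rank_hotspots(recs, 2)] == ["a", "b"]

    def test_coding_records_never_rank_as_hotspots(self):
        recs = [self._rec("gene", 50.0, cls="coding"), self._rec("sp", 1.0)]
        assert [r.name for r in rank_hotspots(recs, 5)] == ["sp"]

    def test_fewer_records_than_k_warns(self):
        with pytest.warns(UserWarning):
            assert len(rank_hotspots([self._rec("a", 1.0)], 10)) == 1

    def test_perfectly_antimonotone_gives_spearman_minus_one(self):
        recs = [self._rec(f"l{i}", sv=float(i), gc=float(100 - i))
                for i in range(10)]
        stats = divergence_statistics(recs)
        assert stats["spearman"]["sv_vs_gc"]["r"] == pytest.approx(-1.0)

    def test_independent_columns_show_no_signal(self):
        rng = np.random.default_rng(42)
        recs = [self._rec(f"l{i}", sv=float(rng.random()),
                          gc=float(rng.random()),
                          indels=int(rng.integers(0, 10)),
                          subs=int(rng.integers(0, 10)))
                for i in range(200)]
        stats = divergence_statistics(recs)
        res = stats["spearman"]["sv_vs_gc"]
        assert abs(res["r"]) < 0.15 and res["p"] > 0.05

    def test_identical_groups_give_mannwhitney_p_near_one(self):
        recs = ([self._rec(f"c{i}", sv=float(i % 5), cls="coding")
                 for i in range(10)]
                + [self._rec(f"n{i}", sv=float(i % 5)) for i in range(10)])
        stats = divergence_statistics(recs)
        assert stats["mann_whitney"]["coding_vs_noncoding_sv"]["p"] > 0.9

    def test_constant_variable_reports_undefined_correlation(self):
        recs = [self._rec(f"l{i}", sv=1.0, gc=float(i)) for i in range(6)]
        res = divergence_statistics(recs)["spearman"]["sv_vs_gc"]
        assert res["r"] is None and "undefined" in res["note"]


class TestSVRecovery:
    def test_measured_sv_tracks_generator_prediction(self):
        rng = np.random.default_rng(77)
        anc = syn._random_seq(800, rng, 0.64)
        diffs = []
        for _ in range(60):
            s1, s2, truth = syn.evolve_locus(anc, rng, p_sub=0.01,
                                             indel_rate=1.0)
            l = SyntenicLocus("x", "spacer", s1, s2)
            trim_terminal_gaps(align_locus(l))
            c, s, e = count_events(l)
            diffs.append(sv_percent(c, s, e) - truth.expected_sv_percent)
        se = np.std(diffs, ddof=1) / np.sqrt(len(diffs))
        assert abs(np.mean(diffs)) <= max(3 * se, 1e-9)
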