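import numpy as np
import pytest

from plastcomp import bin_by_length, context_proportions, detect_inverted_repeat, find_repeats
from plastcomp.model import AnnotatedPlastome, GeneFeature, RepeatHit, revcomp
from plastcomp import synthetic as syn

COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def brute_force_repeats(seq, min_len=30, max_hamming=3, min_identity=90.0):
    """Independent all-(anti)diagonal enumerator of maximal mismatch-bounded
    repeat pairs, trimmed to matching end columns (plain Python loops)."""
    n = len(seq)
    out = set()

    def windows(match_flags):
        """Maximal windows with <= max_hamming mismatches over a 0/1 list."""
        T = len(match_flags)
        mism = [i for i, ok in enumerate(match_flags) if not ok]
        wins = []
        if len(mism) <= max_hamming:
            if T:
                wins.append((0, T - 1))
        else:
            q = [-1] + mism + [T]
            for i in range(len(mism) - max_hamming + 1):
                wins.append((q[i] + 1, q[i + max_hamming + 1] - 1))
        trimmed = set()
        for lo, hi in wins:
            while lo <= hi and not match_flags[lo]:
                lo += 1
            while hi >= lo and not match_flags[hi]:
                hi -= 1
            if hi >= lo:
                trimmed.add((lo, hi))
        return trimmed

    def ok(a, b, comp):
        if "N" in (a, b):
            return False
        return (COMP[b] == a) if comp else (a == b)

    for d in range(1, n):  # forward
        flags = [ok(seq[i], seq[i + d], False) for i in range(n - d)]
        for lo, hi in windows(flags):
            L = hi - lo + 1
            m = sum(1 for t in range(lo, hi + 1) if not flags[t])
            if L >= min_len and L <= d and 100 * (1 - m / L) >= min_identity:
                out.add(("forward", lo, lo + L, lo + d, lo + d + L, m))

    for kind in ("palindromic", "reverse"):
        comp = kind == "palindromic"
        for A in range(1, 2 * n - 2):  # anti-diagonals: c1 + c2 = A
            c_lo, c_hi = max(0, A - (n - 1)), (A - 1) // 2
            if c_hi < c_lo:
                continue
            flags = [ok(seq[c], seq[A - c], comp)
                     for c in range(c_lo, c_hi + 1)]
            for lo, hi in windows(flags):
                L = hi - lo + 1
                m = sum(1 for t in range(lo, hi + 1) if not flags[t])
                s1 = c_lo + lo
                e1 = c_lo + hi + 1
                s2 = A - (c_lo + hi)
                if L >= min_len and 100 * (1 - m / L) >= min_identity:
                    out.add((kind, s1, e1, s2, s2 + L, m))
    return out


def _as_set(hits):
    return {(h.kind, h.span1[0], h.span1[1], h.span2[0], h.span2[1],
             h.mismatches) for h in hits}


def _random_with_planted(seed, n=1500):
    """Random sequence with planted forward/palindromic/reverse pairs,
    including one mismatched copy."""
    rng = np.random.default_rng(seed)
    s = list(rng.choice(list("ACGT"), size=n, p=[0.3, 0.2, 0.2, 0.3]))
    frag = list(rng.choice(list("ACGT"), size=40))
    s[100:140] = frag
    s[400:440] = frag                       # exact forward pair
    pal = [COMP[b] for b in frag[:35]][::-1]
    s[700:735] = pal                        # palindromic partner of s[105:140]
    mism = list(frag[:33])[::-1]
    mism[5] = {"A": "C", "C": "A", "G": "T", "T": "G"}[mism[5]]
    s[1000:1033] = mism                     # reverse partner with 1 mismatch
    return "".join(s)


class TestFindRepeats:
    def test_planted_exact_duplication_recovered_at_planted_coordinates(self, ancestor):
        p, truth = ancestor
        part = detect_inverted_repeat(p, 1000)
        hits = find_repeats(p, part=part)
        assert _as_set(hits) == _as_set(truth.planted_repeats)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_bruteforce_oracle(self, seed):
        seq = _random_with_planted(seed)
        got = _as_set(find_repeats(seq))
        expected = brute_force_repeats(seq)
        assert got == expected
        assert expected  # the construction really plants detectable repeats

    def test_revcomp_preserves_per_kind_counts(self):
        seq = _random_with_planted(17)
        fwd = find_repeats(seq)
        rc = find_repeats(revcomp(seq))
        for kind in ("forward", "palindromic", "reverse"):
            assert sum(h.kind == kind for h in fwd) == \
                sum(h.kind == kind for h in rc)

    def test_ir_self_match_excluded_only_with_partition(self, ancestor):
        p, truth = ancestor
        part = detect_inverted_repeat(p, 1000)
        from plastcomp.repeats import _is_ir_self_match

        with_part = find_repeats(p, kinds=("palindromic",), part=part)
        without = find_repeats(p, kinds=("palindromic",))
        ir_hits = [h for h in without if _is_ir_self_match(h, part)]
        assert ir_hits, "the IR pair itself must surface as palindromic hits"
        assert all(h.length >= part.ir_length for h in ir_hits)
        assert len(without) == len(with_part) + len(ir_hits)
        assert not any(_is_ir_self_match(h, part) for h in with_part)

    def test_min_len_below_seedable_size_rejected(self):
        with pytest.raises(ValueError):
            find_repeats("ACGT" * 100, min_len=7)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            find_repeats("ACGT" * 100, kinds=("inverted",))


class TestBinsAndContexts:
    def test_length_bin_boundaries(self):
        hits = [RepeatHit("forward", (0, L), (500, 500 + L), L, 0)
                for L in (30, 49, 50, 90)]
        assert bin_by_length(hits) == {"30-49": 2, "50-69": 1, "70-89": 0,
                                       ">=90": 1}

    def test_empty_bins(self):
        assert bin_by_length([]) == {"30-49": 0, "50-69": 0, "70-89": 0,
                                     ">=90": 0}

    def test_context_requires_both_copies_in_class(self):
        seq = "G" * 400
        p = AnnotatedPlastome("ctx", seq, [
            GeneFeature("cdsA", "protein_coding", "+", [(0, 100)]),
            GeneFeature("cdsB", "protein_coding", "+", [(200, 300)]),
        ], circular=False)
        hits = [
            RepeatHit("forward", (10, 50), (210, 250), 40, 0),   # both coding
            RepeatHit("forward", (10, 50), (310, 350), 40, 0),   # one coding
            RepeatHit("forward", (110, 150), (310, 350), 40, 0),  # both out
        ]
        props = context_proportions(hits, p)
        assert props == {"coding": pytest.approx(100 / 3),
                         "non_coding": pytest.approx(100 / 3),
                         "spanning": pytest.approx(100 / 3)}
        assert sum(props.values()) == pytest.approx(100.0)

    def test_empty_proportions_are_zero(self):
        p = AnnotatedPlastome("x", "ACGT" * 10, [], circular=False)
        assert set(context_proportions([], p).values()) == {0.0}
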