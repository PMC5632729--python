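"""Dispersed-repeat census: forward, palindromic and reverse repeat pairs.

Criteria follow a REPuter-style search: copy length >= 30 bp, hamming
distance <= 3 and identity >= 90%, all enforced jointly. A reported pair is
a maximal mismatch-bounded window — extending either end one base would
exceed the mismatch budget or run off the sequence — subsequently trimmed so
that both boundary columns are matches, and deduplicated. Self-overlapping
(tandem) pairs are excluded, as is the inverted-repeat pair of the
quadripartite architecture itself when a partition is supplied.

The search seeds on exact 12-mers shared between the sequence and itself,
its reverse complement, or its plain reversal; each seed names one
(anti)diagonal, which is then scanned exhaustively. Low-complexity seeds
(internal period <= 2) are skipped to keep homopolymer tracts from flooding
the diagonal set; a tandem array is SSR territory, not a dispersed repeat.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from .context import coding_intervals, span_context
from .model import AnnotatedPlastome, RegionPartition, RepeatHit

KINDS = ("forward", "palindromic", "reverse")

_COMP_TABLE = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCA\x01"):
    _COMP_TABLE[_a] = _b


def _codes(seq: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Byte codes with N remapped so that N never matches anything:
    (plain with N->0, plain with N->1, complement with N->1)."""
    raw = np.frombuffer(seq.encode(), dtype=np.uint8)
    n0 = raw.copy()
    n0[raw == ord("N")] = 0
    n1 = raw.copy()
    n1[raw == ord("N")] = 1
    comp1 = _COMP_TABLE[raw]
    return n0, n1, comp1


def _max_windows(mis: np.ndarray, T: int, h: int,
                 min_len: int = 1) -> list[tuple[int, int, int]]:
    """Maximal subwindows of [0, T) with at most h mismatches and raw length
    >= min_len.

    ``mis`` holds the sorted mismatch positions. Returns (left, right
    inclusive, n_mismatches) triples.
    """
    if T < min_len:
        return []
    p = np.asarray(mis, dtype=np.int64)
    if p.size <= h:
        return [(0, T - 1, int(p.size))]
    q = np.concatenate(([-1], p, [T]))
    lefts = q[0:p.size - h + 1] + 1
    rights = q[h + 1:p.size + 2] - 1
    keep = (rights - lefts + 1) >= min_len
    return [(int(l), int(r), h) for l, r in zip(lefts[keep], rights[keep])]


def _trim(left: int, right: int, mis: np.ndarray) -> tuple[int, int, int] | None:
    """Shrink a window until both boundary columns match; returns the
    trimmed window and its mismatch count. ``mis`` is sorted."""
    lo_i = int(np.searchsorted(mis, left))
    hi_i = int(np.searchsorted(mis, right, side="right"))
    while lo_i < hi_i and mis[lo_i] == left:
        left += 1
        lo_i += 1
    while hi_i > lo_i and mis[hi_i - 1] == right:
        right -= 1
        hi_i -= 1
    if right < left:
        return None
    return left, right, hi_i - lo_i


def _seed_kmer_ok(kmer: str) -> bool:
    if "N" in kmer:
        return False
    for period in (1, 2):
        if all(kmer[i] == kmer[i % period] for i in range(len(kmer))):
            return False
    return True


def _kmer_index(seq: str, k: int, occ_cap: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i:i + k]
        if _seed_kmer_ok(kmer):
            index.setdefault(kmer, []).append(i)
    return {km: pos for km, pos in index.items() if len(pos) <= occ_cap}


def find_repeats(p: AnnotatedPlastome | str, min_len: int = 30,
                 max_hamming: int = 3, kinds: tuple[str, ...] = KINDS,
                 min_identity: float = 90.0, k: int = 12,
                 part: RegionPartition | None = None,
                 occ_cap: int = 500) -> list[RepeatHit]:
    """All maximal dispersed repeat pairs meeting the joint criteria.

    ``part`` (a canonical partition) enables exclusion of the IR pair
    itself: palindromic hits whose copies reciprocally overlap IRb and IRa
    by >= 90% are dropped.
    """
    if min_len < 8:
        raise ValueError("min_len < 8: seeding impossible")
    for kind in kinds:
        if kind not in KINDS:
            raise ValueError(f"unknown repeat kind {kind!r}")
    seq = p.sequence if isinstance(p, AnnotatedPlastome) else p.upper()
    n = len(seq)
    if n < min_len * 2:
        return []
    v0, v1, c1 = _codes(seq)
    index = _kmer_index(seq, k, occ_cap)

    hits: list[RepeatHit] = []
    seen: set[tuple] = set()

    def emit(kind: str, s1: int, e1: int, s2: int, e2: int, mism: int) -> None:
        L = e1 - s1
        if L < min_len or mism > max_hamming:
            return
        if 100.0 * (1.0 - mism / L) < min_identity:
            return
        key = (kind, s1, e1, s2, e2)
        if key in seen:
            return
        seen.add(key)
        hits.append(RepeatHit(kind, (s1, e1), (s2, e2), L, mism))

    if "forward" in kinds:
        diagonals: set[int] = set()
        for positions in index.values():
            for i, j in combinations(positions, 2):
                diagonals.add(j - i)
        for d in sorted(diagonals):
            T = n - d
            mis = np.flatnonzero(v0[:T] != v1[d:])
            for left, right, _ in _max_windows(mis, T, max_hamming, min_len):
                t = _trim(left, right, mis)
                if t is None:
                    continue
                lo, hi, m = t
                if hi - lo + 1 > d:  # copies overlap: tandem, excluded
                    continue
                emit("forward", lo, hi + 1, lo + d, hi + 1 + d, m)

    for kind in ("palindromic", "reverse"):
        if kind not in kinds:
            continue
        partner = c1 if kind == "palindromic" else v1
        # seeds: k-mer of seq vs k-mer of revcomp(seq)/reverse(seq)
        if kind == "palindromic":
            from .model import revcomp
            other = revcomp(seq)
        else:
            other = seq[::-1]
        antidiagonals: set[int] = set()
        for j in range(n - k + 1):
            q = other[n - j - k:n - j]
            if not _seed_kmer_ok(q):
                continue
            for i in index.get(q, ()):
                if i != j:
                    antidiagonals.add(i + j + k - 1)
        for A in sorted(antidiagonals):
            c_lo = max(0, A - (n - 1))
            c_hi = (A - 1) // 2
            if c_hi < c_lo:
                continue
            cs = np.arange(c_lo, c_hi + 1)
            mis = cs[v0[cs] != partner[A - cs]] - c_lo
            T = c_hi - c_lo + 1
            for left, right, _ in _max_windows(mis, T, max_hamming, min_len):
                t = _trim(left, right, mis)
                if t is None:
                    continue
                lo, hi, m = t
                s1, e1 = c_lo + lo, c_lo + hi + 1
                s2, e2 = A - (c_lo + hi), A - (c_lo + lo) + 1
                emit(kind, s1, e1, s2, e2, m)

    if part is not None:
        hits = [h for h in hits if not _is_ir_self_match(h, part)]
    hits.sort(key=lambda h: (h.span1, h.span2, h.kind))
    return hits


def _reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    denom = max(a[1] - a[0], b[1] - b[0])
    return inter / denom if denom else 0.0


def _is_ir_self_match(h: RepeatHit, part: RegionPartition) -> bool:
    if h.kind != "palindromic":
        return False
    return (_reciprocal_overlap(h.span1, part.irb) >= 0.9
            and _reciprocal_overlap(h.span2, part.ira) >= 0.9)


def bin_by_length(hits: list[RepeatHit]) -> dict[str, int]:
    """Copy-length histogram in the bins 30-49, 50-69, 70-89, >=90 bp."""
    out = {"30-49": 0, "50-69": 0, "70-89": 0, ">=90": 0}
    for h in hits:
        if h.length < 50:
            out["30-49"] += 1
        elif h.length < 70:
            out["50-69"] += 1
        elif h.length < 90:
            out["70-89"] += 1
        else:
            out[">=90"] += 1
    return out


def classify_hit_contexts(hits: list[RepeatHit],
                          p: AnnotatedPlastome) -> list[RepeatHit]:
    merged = coding_intervals(p)
    for h in hits:
        h.context1 = span_context(h.span1, merged, p.length)
        h.context2 = span_context(h.span2, merged, p.length)
    return hits


def context_proportions(hits: list[RepeatHit],
                        p: AnnotatedPlastome) -> dict[str, float]:
    """Percentage of hits per joint context class (both copies coding ->
    coding; both non-coding -> non_coding; else spanning)."""
    classify_hit_contexts(hits, p)
    counts = {"coding": 0, "non_coding": 0, "spanning": 0}
    for h in hits:
        counts[h.context] += 1
    total = len(hits)
    if total == 0:
        return {k: 0.0 for k in counts}
    return {k: 100.0 * v / total for k, v in counts.items()}
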