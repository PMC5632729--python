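"""Quadripartite architecture: IR detection, canonical orientation, Table-1
style region metrics.

The inverted-repeat pair is found by seed-and-extend on exact 31-mers between
the (doubled, hence circular) sequence and its reverse complement. Seeds that
belong to one inverted match share the anti-diagonal ``i + j`` of their paired
endpoints, so each candidate IR is a single anti-diagonal extended base by
base. A mismatch is consumed during extension only when the next ``anchor``
bases beyond it match exactly; on a mismatch-free genome the detected
boundaries therefore coincide with the planted junctions exactly, while
near-identical IR copies (identity >= 1 - max_mismatch_rate) are still
recovered in full.
"""

from __future__ import annotations

from dataclasses import replace

from .model import (
    AnnotatedPlastome,
    GeneFeature,
    RegionPartition,
    circular_slice,
    revcomp,
)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


class IRNotFoundError(ValueError):
    """Raised when no inverted pair of at least ``min_ir_len`` exists."""


def at_content(seq: str) -> float:
    """AT percentage over unambiguous bases; N excluded from both numerator
    and denominator."""
    a = seq.count("A") + seq.count("a")
    t = seq.count("T") + seq.count("t")
    denom = a + t + seq.count("C") + seq.count("c") + seq.count("G") + seq.count("g")
    if denom == 0:
        raise ValueError("AT content undefined for an all-N/empty sequence")
    return 100.0 * (a + t) / denom


def gc_content(seq: str) -> float:
    return 100.0 - at_content(seq)


def _extend_antidiagonal(d: str, A: int, lo: int, hi: int, max_len: int,
                         anchor: int) -> tuple[int, int, list[int]]:
    """Extend copy1 interval [lo, hi] (inclusive) along anti-diagonal A.

    Position c of copy1 pairs with position A - c of copy2. Returns the
    extended interval and the copy1-side mismatch positions consumed.
    """
    m = len(d)

    def match(c: int) -> bool:
        o = A - c
        if c < 0 or c >= m or o < 0 or o >= m:
            return False
        return d[c] == _COMP[d[o]] and d[c] != "N"

    mismatches: list[int] = []
    # rightward: keep copy1 strictly before copy2 (hi < A - hi)
    while hi - lo + 1 < max_len:
        c = hi + 1
        if c >= A - c:
            break
        if match(c):
            hi = c
        elif all(match(c + t) for t in range(1, anchor + 1)) and c + anchor < A - (c + anchor):
            mismatches.append(c)
            hi = c
        else:
            break
    # leftward
    while hi - lo + 1 < max_len:
        c = lo - 1
        if match(c):
            lo = c
        elif all(match(c - t) for t in range(1, anchor + 1)):
            mismatches.append(c)
            lo = c
        else:
            break
    return lo, hi, sorted(mismatches)


def detect_inverted_repeat(p: AnnotatedPlastome, min_ir_len: int = 1000,
                           max_mismatch_rate: float = 0.001, k: int = 31,
                           anchor: int = 20) -> RegionPartition:
    """Locate the maximal near-identical inverted-repeat pair and partition
    the genome into LSC / IRb / SSC / IRa.

    The shorter inter-IR segment is labelled SSC, the longer LSC. Intervals
    are returned in the input's coordinates (an interval whose end exceeds
    the genome length wraps the origin); :func:`canonicalize` rotates to the
    standard LSC-first linearization. Ties between equally long candidates
    break toward the smaller start coordinate.
    """
    s = p.sequence
    n = len(s)
    if n < 2 * min_ir_len:
        raise IRNotFoundError(
            f"{p.identifier}: sequence ({n} bp) shorter than 2 x min_ir_len"
        )
    d = s + s if p.circular else s
    m = len(d)
    rc_d = revcomp(d)

    index: dict[str, list[int]] = {}
    for i in range(m - k + 1):
        kmer = d[i:i + k]
        if "N" in kmer:
            continue
        index.setdefault(kmer, []).append(i)

    seeds: dict[int, tuple[int, int]] = {}  # anti-diagonal -> leftmost seed
    for j in range(m - k + 1):
        q = rc_d[m - j - k:m - j]  # == revcomp(d[j:j+k])
        for i in index.get(q, ()):
            if i + k > j:  # require copy1 strictly before copy2
                continue
            A = i + j + k - 1
            if A not in seeds or i < seeds[A][0]:
                seeds[A] = (i, j)

    max_len = n // 2
    candidates: list[tuple[int, int, int, int]] = []  # (-L, lo, A, n_mis)
    for A, (i, j) in seeds.items():
        lo, hi, mis = _extend_antidiagonal(d, A, i, i + k - 1, max_len, anchor)
        L = hi - lo + 1
        # enforce the global identity bound by trimming outermost mismatches
        while mis and len(mis) > max_mismatch_rate * L:
            first, last = mis[0], mis[-1]
            if first - lo <= hi - last:
                lo, mis = first + 1, mis[1:]
            else:
                hi, mis = last - 1, mis[:-1]
            L = hi - lo + 1
        if L >= min_ir_len:
            candidates.append((-L, lo % n, A, len(mis)))
    if not candidates:
        raise IRNotFoundError(
            f"{p.identifier}: no inverted repeat >= {min_ir_len} bp detected"
        )

    best = None
    for negL, lo_mod, A, n_mis in sorted(candidates):
        L = -negL
        x = lo_mod                      # copy1 start (mod n)
        hi = None
        # reconstruct copy2 start from the anti-diagonal: copy1 = [lo, lo+L)
        y = (A - (lo_mod + L - 1)) % n  # copy2 start (mod n)
        # copies must be disjoint on the circle
        if (y - x) % n < L or (x - y) % n < L:
            continue
        best = (x, y, L)
        break
    if best is None:
        raise IRNotFoundError(f"{p.identifier}: only self-overlapping inverted matches found")
    x, y, L = best

    g_xy = (y - (x + L)) % n  # gap after copy X, before copy Y
    g_yx = (x - (y + L)) % n  # gap after copy Y, before copy X
    if g_xy >= g_yx:
        lsc = (x + L, x + L + g_xy)
        irb, ssc, ira = (y, y + L), (y + L, y + L + g_yx), (x, x + L)
    else:
        lsc = (y + L, y + L + g_yx)
        irb, ssc, ira = (x, x + L), (x + L, x + L + g_xy), (y, y + L)
    norm = lambda iv: (iv[0] % n, iv[0] % n + (iv[1] - iv[0]))
    return RegionPartition(norm(lsc), norm(irb), norm(ssc), norm(ira))


def _rotate_feature(f: GeneFeature, offset: int, n: int) -> GeneFeature:
    segs = []
    for a, b in f.segments:
        a2 = (a - offset) % n
        segs.append((a2, a2 + (b - a)))
    return replace(f, segments=sorted(segs))


def _flip_feature(f: GeneFeature, n: int) -> GeneFeature:
    segs = []
    for a, b in f.segments:
        a2 = (n - b) % n
        segs.append((a2, a2 + (b - a)))
    strand = "-" if f.strand == "+" else "+"
    return replace(f, segments=sorted(segs), strand=strand)


def _rotate(p: AnnotatedPlastome, part: RegionPartition,
            offset: int) -> tuple[AnnotatedPlastome, RegionPartition]:
    n = p.length
    seq = p.sequence[offset:] + p.sequence[:offset]
    feats = [_rotate_feature(f, offset, n) for f in p.features]
    feats.sort(key=lambda f: (f.start, f.name))

    def riv(iv):
        a = (iv[0] - offset) % n
        return (a, a + (iv[1] - iv[0]))

    part2 = RegionPartition(riv(part.lsc), riv(part.irb), riv(part.ssc), riv(part.ira))
    return AnnotatedPlastome(p.identifier, seq, feats, p.circular), part2


def _flip(p: AnnotatedPlastome, part: RegionPartition
          ) -> tuple[AnnotatedPlastome, RegionPartition]:
    n = p.length
    seq = revcomp(p.sequence)
    feats = [_flip_feature(f, n) for f in p.features]

    def fiv(iv):
        a = (n - iv[1]) % n
        return (a, a + (iv[1] - iv[0]))

    # reverse-complementing swaps the IR labels (IRb content becomes IRa)
    part2 = RegionPartition(fiv(part.lsc), fiv(part.ira), fiv(part.ssc), fiv(part.irb))
    return AnnotatedPlastome(p.identifier, seq, feats, p.circular), part2


def canonicalize(p: AnnotatedPlastome, part: RegionPartition
                 ) -> tuple[AnnotatedPlastome, RegionPartition]:
    """Rotate (and flip if needed) to the order LSC -> IRb -> SSC -> IRa with
    the LSC starting at coordinate 0.

    SSC orientation: ndhF (when annotated) ends up on the SSC side nearer
    J_SB; with no ndh gene, the orientation with the lexicographically
    smaller SSC string is chosen. Idempotent on already-canonical input.
    """
    n = p.length
    p2, part2 = _rotate(p, part, part.lsc[0] % n)

    ndhf = next((f for f in p2.features if f.name == "ndhF"), None)
    flip = False
    s0, e0 = part2.ssc
    if ndhf is not None:
        center = (ndhf.start + ndhf.end) / 2.0
        flip = not (center - s0) % n < (e0 - s0) / 2.0
    else:
        ssc_seq = circular_slice(p2.sequence, s0, e0)
        flip = revcomp(ssc_seq) < ssc_seq
    if flip:
        p2, part2 = _flip(p2, part2)
        p2, part2 = _rotate(p2, part2, part2.lsc[0] % n)
    part2.validate(n)
    return p2, part2


def structure_summary(p: AnnotatedPlastome, part: RegionPartition) -> dict:
    """Table-1 style metrics: region lengths and AT contents."""
    s = p.sequence
    reg = lambda iv: circular_slice(s, iv[0], iv[1])
    return {
        "plastome": p.identifier,
        "total_bp": p.length,
        "lsc_bp": part.lsc_length,
        "ssc_bp": part.ssc_length,
        "ir_bp": part.ir_length,
        "at_total": round(at_content(s), 2),
        "at_lsc": round(at_content(reg(part.lsc)), 2),
        "at_ssc": round(at_content(reg(part.ssc)), 2),
        "at_ir": round(at_content(reg(part.irb)), 2),
    }
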