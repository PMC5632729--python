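"""Simple-sequence-repeat (microsatellite) census.

A locus is a maximal perfect tandem run of a primitive 1-6 bp unit meeting
its unit-count threshold (defaults: mononucleotide >= 8 units, dinucleotide
>= 5, tri- through hexanucleotide >= 3, the inclusive reading of a GMATo-style
"Min-length" setting). Runs are reported once under their primitive unit;
circular wrap-around runs are counted once; runs are broken at N.
"""

from __future__ import annotations

from collections import Counter

import numpy as np

from .model import AnnotatedPlastome, SSRLocus
from .context import coding_intervals, span_context

#: minimum unit counts per unit size (inclusive)
DEFAULT_THRESHOLDS: dict[int, int] = {1: 8, 2: 5, 3: 3, 4: 3, 5: 3, 6: 3}

CLASS_NAMES = {1: "mono", 2: "di", 3: "tri", 4: "tetra", 5: "penta", 6: "hexa"}


def expand_thresholds(mono: int = 8, di: int = 5, multi: int = 3) -> dict[int, int]:
    return {1: mono, 2: di, 3: multi, 4: multi, 5: multi, 6: multi}


def is_primitive(motif: str) -> bool:
    """True when the motif is not itself a repetition of a shorter unit."""
    u = len(motif)
    for d in range(1, u):
        if u % d == 0 and motif == motif[:d] * (u // d):
            return False
    return True


def find_ssrs(p: AnnotatedPlastome | str,
              thresholds: dict[int, int] | None = None,
              circular: bool | None = None) -> list[SSRLocus]:
    """All maximal perfect tandem runs meeting their class threshold.

    Accepts a plastome or a bare sequence string. Returns loci sorted by
    span start; a wrap-around run on a circular sequence carries a span whose
    end exceeds the sequence length.
    """
    if isinstance(p, AnnotatedPlastome):
        seq, circ = p.sequence, p.circular if circular is None else circular
    else:
        seq, circ = p.upper(), bool(circular)
    thresholds = dict(DEFAULT_THRESHOLDS if thresholds is None else thresholds)
    if any(t < 1 for t in thresholds.values()):
        raise ValueError("SSR unit-count thresholds must be >= 1")
    n = len(seq)
    if n == 0:
        return []
    scan = seq + seq if circ else seq
    arr = np.frombuffer(scan.encode(), dtype=np.uint8)
    valid = arr != ord("N")

    loci: list[SSRLocus] = []
    for u in sorted(thresholds):
        if u < 1 or u > 6 or len(scan) <= u:
            continue
        m = (arr[u:] == arr[:-u]) & valid[u:] & valid[:-u]
        edges = np.flatnonzero(np.diff(np.concatenate(
            ([0], m.view(np.int8), [0]))))
        for a, b in zip(edges[0::2], edges[1::2]):
            total = int(b - a) + u        # periodic region length
            start = int(a)
            count = total // u
            if count < thresholds[u]:
                continue
            motif = scan[start:start + u]
            if "N" in motif or not is_primitive(motif):
                continue
            if circ:
                if start >= n or u * count > n:
                    continue
                # circular maximality at the linearization edge
                if start == 0:
                    prev = seq[(start - 1) % n]
                    if prev != "N" and prev == seq[(start - 1 + u) % n]:
                        continue
            loci.append(SSRLocus(motif, count, (start, start + u * count)))
    loci.sort(key=lambda l: (l.span, l.motif))
    return loci


def classify_context(loci: list[SSRLocus], p: AnnotatedPlastome) -> list[SSRLocus]:
    """Set each locus's context: coding (entirely within gene exons),
    non_coding (entirely outside) or spanning."""
    merged = coding_intervals(p)
    for locus in loci:
        locus.context = span_context(locus.span, merged, p.length)
    return loci


def ssr_summary(loci: list[SSRLocus]) -> dict:
    """Totals by motif class (mono..hexa) and by motif identity.

    Reverse-complement motifs are NOT merged (A- and T-runs count
    separately), matching a GMATo-style census.
    """
    by_class = {CLASS_NAMES[u]: 0 for u in range(1, 7)}
    by_motif: Counter[str] = Counter()
    by_context: Counter[str] = Counter()
    for locus in loci:
        by_class[CLASS_NAMES[locus.unit_size]] += 1
        by_motif[locus.motif] += 1
        if locus.context:
            by_context[locus.context] += 1
    return {
        "total": len(loci),
        "by_class": by_class,
        "by_motif": dict(sorted(by_motif.items())),
        "by_context": dict(sorted(by_context.items())),
    }
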