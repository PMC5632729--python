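"""Genomic-context classification shared by the SSR and repeat modules.

"Coding" context means lying entirely within annotated gene exons (CDS, tRNA
or rRNA segments of functional genes); pseudogene remnants do not count as
coding sequence.
"""

from __future__ import annotations

from bisect import bisect_right

from .model import AnnotatedPlastome

CODING_CATEGORIES = ("protein_coding", "tRNA", "rRNA")


def coding_intervals(p: AnnotatedPlastome) -> list[tuple[int, int]]:
    """Merged, sorted exon intervals of functional genes; origin-spanning
    segments are split at the origin."""
    n = p.length
    raw: list[tuple[int, int]] = []
    for f in p.features:
        if f.pseudogene or f.category not in CODING_CATEGORIES:
            continue
        for a, b in f.segments:
            a %= n
            if a + (b - a) <= n:
                raw.append((a, a + (b - a)))
            else:
                raw.append((a, n))
                raw.append((0, (a + (b - a)) - n))
    raw.sort()
    merged: list[tuple[int, int]] = []
    for a, b in raw:
        if merged and a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return merged


def _linear_class(span: tuple[int, int], merged: list[tuple[int, int]]) -> str:
    a, b = span
    starts = [s for s, _ in merged]
    i = bisect_right(starts, a) - 1
    if i >= 0 and merged[i][1] >= b:
        return "coding"
    overlaps = any(s < b and a < e for s, e in merged)
    return "spanning" if overlaps else "non_coding"


def span_context(span: tuple[int, int], merged: list[tuple[int, int]],
                 n: int) -> str:
    """Classify a (possibly origin-wrapping) span against merged exon
    intervals: coding if fully inside, non_coding if fully outside, else
    spanning."""
    a, b = span
    a %= n
    b = a + (span[1] - span[0])
    parts = [(a, b)] if b <= n else [(a, n), (0, b - n)]
    classes = {_linear_class(part, merged) for part in parts}
    if classes == {"coding"}:
        return "coding"
    if classes == {"non_coding"}:
        return "non_coding"
    return "spanning"
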