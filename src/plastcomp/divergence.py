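"""Pairwise sequence-divergence screen: syntenic locus extraction, global
alignment, substitution/InDel counting, SV% and mutational-hotspot ranking.

SV% = (substitutions + InDel events) /
      (conserved sites + substitutions + InDel events) x 100,

where one InDel event is one maximal run of contiguous gap columns,
regardless of its length. Terminal gap columns are excluded before counting.
Non-coding loci shorter than 150 bp in either genome are discarded upstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices
from scipy import stats

from .model import (
    AnnotatedPlastome,
    DivergenceRecord,
    GeneFeature,
    RegionPartition,
    SyntenicLocus,
    circular_slice,
    revcomp,
)

_GAP = "-"
_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class AlignParams:
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -4.0
    gap_extend: float = -1.0


def _interval_in(span: tuple[int, int], region: tuple[int, int]) -> bool:
    return region[0] <= span[0] and span[1] <= region[1]


def _locus_entries(p: AnnotatedPlastome, part: RegionPartition | None,
                   min_noncoding_len: int):
    """Per-genome locus dictionaries: coding, spacer, intron.

    Loci entirely within IRa are dropped (one IR copy only) when a
    partition is available.
    """
    n = p.length
    seq = p.sequence

    def in_ira(span):
        return part is not None and _interval_in(span, part.ira)

    def region_tag(span):
        if part is None:
            return None
        tag = part.region_of(((span[0] + span[1]) // 2) % n)
        return "IR" if tag in ("IRb", "IRa") else tag

    coding: dict[str, tuple[str, str | None, GeneFeature]] = {}
    for f in p.features:
        if f.category != "protein_coding" or f.pseudogene:
            continue
        span = (f.start, f.end)
        if in_ira(span) or f.name in coding:
            continue
        coding[f.name] = (f.spliced_sequence(seq), region_tag(span), f)

    introns: dict[str, tuple[str, str | None]] = {}
    for f in p.features:
        if len(f.segments) < 2 or f.pseudogene:
            continue
        span = (f.start, f.end)
        if in_ira(span):
            continue
        segs = sorted(f.segments)
        gaps = [(segs[i][1], segs[i + 1][0]) for i in range(len(segs) - 1)]
        if f.strand == "-":
            gaps = gaps[::-1]  # transcription order
        for idx, (a, b) in enumerate(gaps):
            if b <= a:
                continue
            s = circular_slice(seq, a, b)
            if f.strand == "-":
                s = revcomp(s)
            name = f"{f.name} intron" if len(gaps) == 1 else f"{f.name} intron{idx + 1}"
            if name not in introns:
                introns[name] = (s, region_tag((a, b)))

    # spacers between consecutive annotated genes along the genome
    bounds = sorted(p.features, key=lambda f: (f.start, f.end, f.name))
    spacers: dict[str, tuple[str, str | None]] = {}
    counts: dict[str, int] = {}
    m = len(bounds)
    for i in range(m):
        f = bounds[i]
        g = bounds[(i + 1) % m]
        a = f.end
        b = g.start if i + 1 < m else g.start + n  # wrap to the first gene
        if b <= a:
            continue
        span = (a, b)
        if in_ira(span):
            continue
        base = f"{f.name}-{g.name}"
        counts[base] = counts.get(base, 0) + 1
        name = base if counts[base] == 1 else f"{base}#{counts[base]}"
        spacers[name] = (circular_slice(seq, a, b), region_tag(span))

    return coding, spacers, introns


def extract_syntenic_loci(p1: AnnotatedPlastome, p2: AnnotatedPlastome,
                          part1: RegionPartition | None = None,
                          part2: RegionPartition | None = None,
                          min_noncoding_len: int = 150) -> list[SyntenicLocus]:
    """Pair protein-coding genes, intergenic spacers and introns between two
    canonical, annotated plastomes.

    Spacers pair when their flanking gene names match in both genomes;
    non-coding loci shorter than ``min_noncoding_len`` in either genome are
    dropped. Loci resident in the IR contribute one copy (IRb).
    """
    c1, s1, i1 = _locus_entries(p1, part1, min_noncoding_len)
    c2, s2, i2 = _locus_entries(p2, part2, min_noncoding_len)
    loci: list[SyntenicLocus] = []
    for name in sorted(set(c1) & set(c2)):
        seq_a, reg, _ = c1[name]
        seq_b = c2[name][0]
        loci.append(SyntenicLocus(name, "coding", seq_a, seq_b, region=reg))
    for cls, d1, d2 in (("spacer", s1, s2), ("intron", i1, i2)):
        for name in sorted(set(d1) & set(d2)):
            seq_a, reg = d1[name]
            seq_b = d2[name][0]
            if min(len(seq_a), len(seq_b)) < min_noncoding_len:
                continue
            loci.append(SyntenicLocus(name, cls, seq_a, seq_b, region=reg))
    if not loci:
        warnings.warn("no shared loci between the two plastomes")
    loci.sort(key=lambda l: (l.locus_class, l.name))
    return loci


def _nuc_aligner(params: AlignParams) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    return aligner


def _protein_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def _codon_to_aa() -> dict[str, str]:
    from Bio.Data.CodonTable import unambiguous_dna_by_id
    table = unambiguous_dna_by_id[1]
    out = dict(table.forward_table)
    for stop in table.stop_codons:
        out[stop] = "*"
    return out


_AA = _codon_to_aa()


def _translate(seq: str) -> str:
    return "".join(_AA.get(seq[i:i + 3], "X")
                   for i in range(0, len(seq) - len(seq) % 3, 3))


def align_locus(locus: SyntenicLocus,
                params: AlignParams | None = None) -> SyntenicLocus:
    """Global pairwise alignment with affine gaps; coding loci are aligned
    codon-aware (proteins aligned, codons back-threaded), so internal gap
    lengths are multiples of 3 on codon boundaries.

    A coding locus whose length is not divisible by 3 in either genome is
    flagged and aligned as non-coding.
    """
    params = params or AlignParams()
    if not locus.seq1 or not locus.seq2:
        raise ValueError(f"{locus.name}: empty sequence")
    if (locus.locus_class == "coding"
            and len(locus.seq1) % 3 == 0 and len(locus.seq2) % 3 == 0):
        prot1, prot2 = _translate(locus.seq1), _translate(locus.seq2)
        aln = _protein_aligner().align(prot1, prot2)[0]
        row1, row2 = str(aln[0]), str(aln[1])
        out1, out2 = [], []
        i = j = 0
        for a, b in zip(row1, row2):
            if a != _GAP and b != _GAP:
                out1.append(locus.seq1[3 * i:3 * i + 3])
                out2.append(locus.seq2[3 * j:3 * j + 3])
                i, j = i + 1, j + 1
            elif a != _GAP:
                out1.append(locus.seq1[3 * i:3 * i + 3])
                out2.append(_GAP * 3)
                i += 1
            else:
                out1.append(_GAP * 3)
                out2.append(locus.seq2[3 * j:3 * j + 3])
                j += 1
        locus.aln1, locus.aln2 = "".join(out1), "".join(out2)
        return locus
    if locus.locus_class == "coding":
        warnings.warn(f"{locus.name}: coding length not divisible by 3; "
                      "aligned as non-coding")
        locus.flagged = True
    aln = _nuc_aligner(params).align(locus.seq1, locus.seq2)[0]
    locus.aln1, locus.aln2 = str(aln[0]), str(aln[1])
    return locus


def trim_terminal_gaps(locus: SyntenicLocus) -> SyntenicLocus:
    """Remove leading/trailing columns in which either row is a gap;
    internal columns are untouched. Idempotent."""
    if not locus.is_aligned():
        raise ValueError(f"{locus.name}: not aligned")
    a, b = locus.aln1, locus.aln2
    lo, hi = 0, len(a)
    while lo < hi and (a[lo] == _GAP or b[lo] == _GAP):
        lo += 1
    while hi > lo and (a[hi - 1] == _GAP or b[hi - 1] == _GAP):
        hi -= 1
    locus.aln1, locus.aln2 = a[lo:hi], b[lo:hi]
    if hi == lo:
        warnings.warn(f"{locus.name}: alignment trims to zero length")
        locus.flagged = True
    return locus


def count_events(locus: SyntenicLocus) -> tuple[int, int, int]:
    """(conserved_sites, substitutions, indel_events) of a trimmed pairwise
    alignment.

    Conserved = identical non-gap columns; substitution = differing non-gap
    columns; one InDel event = one maximal run of gap columns. Columns
    containing N are ignored for site counts and break gap runs like any
    other non-gap column.
    """
    a, b = locus.aln1, locus.aln2
    conserved = subs = events = 0
    in_gap = False
    for x, y in zip(a, b):
        assert not (x == _GAP and y == _GAP), "gap-gap column in pairwise alignment"
        if x == _GAP or y == _GAP:
            if not in_gap:
                events += 1
                in_gap = True
            continue
        in_gap = False
        if x == "N" or y == "N":
            continue
        if x == y:
            conserved += 1
        else:
            subs += 1
    return conserved, subs, events


def sv_percent(conserved: int, substitutions: int, indel_events: int) -> float:
    """Sequence variability percentage."""
    if min(conserved, substitutions, indel_events) < 0:
        raise ValueError("negative counts")
    denom = conserved + substitutions + indel_events
    if denom == 0:
        raise ValueError("SV% undefined: empty alignment")
    return 100.0 * (substitutions + indel_events) / denom


def _gc_percent(seq1: str, seq2: str) -> float:
    s = seq1 + seq2
    acgt = sum(s.count(c) for c in "ACGT")
    if acgt == 0:
        return float("nan")
    return 100.0 * (s.count("G") + s.count("C")) / acgt


def divergence_table(loci: list[SyntenicLocus],
                     params: AlignParams | None = None) -> list[DivergenceRecord]:
    """Align, trim and count every locus; zero-length alignments excluded."""
    records = []
    for locus in loci:
        if not locus.is_aligned():
            align_locus(locus, params)
            trim_terminal_gaps(locus)
        if not locus.aln1:
            continue
        conserved, subs, events = count_events(locus)
        if conserved + subs + events == 0:
            continue
        records.append(DivergenceRecord(
            name=locus.name,
            locus_class=locus.locus_class,
            conserved_sites=conserved,
            substitutions=subs,
            indel_events=events,
            sv_percent=sv_percent(conserved, subs, events),
            gc_percent=_gc_percent(locus.seq1, locus.seq2),
            region=locus.region,
        ))
    return records


def rank_hotspots(records: list[DivergenceRecord], k: int = 10) -> list[DivergenceRecord]:
    """Top-k non-coding loci by SV%, ties broken by locus name."""
    noncoding = [r for r in records if r.locus_class != "coding"]
    noncoding.sort(key=lambda r: (-r.sv_percent, r.name))
    if len(noncoding) < k:
        warnings.warn(f"only {len(noncoding)} non-coding records for top-{k}")
    return noncoding[:k]


def _spearman(x, y) -> dict:
    if len(set(x)) < 2 or len(set(y)) < 2:
        return {"r": None, "p": None, "note": "undefined (constant input)"}
    r, pval = stats.spearmanr(x, y)
    return {"r": float(r), "p": float(pval)}


def _mannwhitney(a, b) -> dict:
    if len(a) < 1 or len(b) < 1:
        return {"u": None, "p": None, "note": "empty group"}
    u, pval = stats.mannwhitneyu(a, b, alternative="two-sided")
    return {"u": float(u), "p": float(pval)}


def divergence_statistics(records: list[DivergenceRecord]) -> dict:
    """Spearman correlations (SV~GC, InDels~substitutions, InDels~GC,
    substitutions~GC) and two-sided Mann-Whitney comparisons (coding vs
    non-coding SV; single-copy vs IR SV among non-coding loci).

    Raw two-sided p-values, no multiple-testing correction.
    """
    sv = [r.sv_percent for r in records]
    gc = [r.gc_percent for r in records]
    indels = [r.indel_events for r in records]
    subs = [r.substitutions for r in records]
    out = {
        "n_loci": len(records),
        "spearman": {
            "sv_vs_gc": _spearman(sv, gc),
            "indels_vs_substitutions": _spearman(indels, subs),
            "indels_vs_gc": _spearman(indels, gc),
            "substitutions_vs_gc": _spearman(subs, gc),
        },
    }
    coding = [r.sv_percent for r in records if r.locus_class == "coding"]
    noncoding = [r.sv_percent for r in records if r.locus_class != "coding"]
    mw = {"coding_vs_noncoding_sv": _mannwhitney(coding, noncoding)}
    nc_sc = [r.sv_percent for r in records
             if r.locus_class != "coding" and r.region in ("LSC", "SSC")]
    nc_ir = [r.sv_percent for r in records
             if r.locus_class != "coding" and r.region == "IR"]
    if nc_sc and nc_ir:
        mw["sc_vs_ir_noncoding_sv"] = _mannwhitney(nc_sc, nc_ir)
    out["mann_whitney"] = mw
    if coding and noncoding and np.mean(coding) > 0:
        out["noncoding_to_coding_sv_ratio"] = float(
            np.mean(noncoding) / np.mean(coding))
    return out
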