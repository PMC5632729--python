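"""Pairwise dN/dS by Nei-Gojobori (1986) codon counting with Jukes-Cantor
correction.

Synonymous site fractions are computed per codon (changes to stop codons
count as non-synonymous), averaged over the two sequences. Codon pairs
differing at 2-3 positions are resolved by averaging synonymous and
non-synonymous step counts over all minimal mutational pathways, excluding
pathways that pass through a stop codon. Rates are corrected as
d = -(3/4) ln(1 - (4/3) p); p >= 3/4 is reported as saturated.
"""

from __future__ import annotations

import math
import warnings
from itertools import permutations

from Bio.Data.CodonTable import unambiguous_dna_by_id

from .model import DnDsRecord, SyntenicLocus

_BASES = "ACGT"


def _code(table_id: int) -> tuple[dict[str, str], set[str]]:
    table = unambiguous_dna_by_id[table_id]
    return dict(table.forward_table), set(table.stop_codons)


def syn_site_fraction(codon: str, table_id: int = 1) -> float:
    """Expected synonymous sites of one codon (0..3): at each position, the
    fraction of the three possible changes that preserve the amino acid."""
    forward, stops = _code(table_id)
    if codon in stops or any(c not in _BASES for c in codon):
        raise ValueError(f"cannot count sites of codon {codon!r}")
    aa = forward[codon]
    s = 0.0
    for pos in range(3):
        for alt in _BASES:
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1:]
            if mutant not in stops and forward[mutant] == aa:
                s += 1.0 / 3.0
    return s


def pathway_counts(c1: str, c2: str, table_id: int = 1) -> tuple[float, float]:
    """(synonymous, non-synonymous) differences between two codons, averaged
    over all minimal mutational pathways; pathways through stop codons are
    excluded (all pathways used if every one hits a stop)."""
    forward, stops = _code(table_id)
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0

    def walk(order) -> tuple[float, float] | None:
        cur = c1
        sd = nd = 0.0
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in stops:
                return None
            if forward[cur] == forward[nxt]:
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        return sd, nd

    valid = [r for r in (walk(order) for order in permutations(diff)) if r is not None]
    if not valid:
        valid = []
        for order in permutations(diff):
            cur = c1
            sd = nd = 0.0
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
                syn = (cur not in stops and nxt not in stops
                       and forward.get(cur) == forward.get(nxt))
                sd, nd = sd + syn, nd + (not syn)
                cur = nxt
            valid.append((sd, nd))
    sd = sum(v[0] for v in valid) / len(valid)
    nd = sum(v[1] for v in valid) / len(valid)
    return sd, nd


def _jc_correct(p: float) -> float | None:
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0) + 0.0  # avoid -0.0


def codonize(locus: SyntenicLocus, table_id: int = 1) -> list[tuple[str, str]]:
    """Aligned codon pairs of a trimmed, frame-preserving coding locus.

    Codons containing gaps or N are skipped; the terminal stop pair is
    removed; a codon with an internal stop in ONE sequence is skipped with a
    warning; internal stops in BOTH sequences flag the locus as a pseudogene
    (raised as ValueError).
    """
    if not locus.is_aligned():
        raise ValueError(f"{locus.name}: not aligned")
    a, b = locus.aln1, locus.aln2
    if len(a) % 3 != 0:
        raise ValueError(f"{locus.name}: alignment length {len(a)} not a multiple of 3")
    _, stops = _code(table_id)
    raw = [(a[i:i + 3], b[i:i + 3]) for i in range(0, len(a), 3)]
    # drop a terminal stop pair
    while raw and (raw[-1][0] in stops or raw[-1][1] in stops
                   or "-" in raw[-1][0] or "-" in raw[-1][1]):
        last = raw[-1]
        if last[0] in stops or last[1] in stops:
            raw = raw[:-1]
            break
        if "-" in last[0] or "-" in last[1]:
            raw = raw[:-1]
        else:  # pragma: no cover
            break
    pairs: list[tuple[str, str]] = []
    for c1, c2 in raw:
        if "-" in c1 or "-" in c2 or "N" in c1 or "N" in c2:
            continue
        stop1, stop2 = c1 in stops, c2 in stops
        if stop1 and stop2:
            raise ValueError(f"{locus.name}: internal stop in both sequences "
                             "(pseudogene), locus excluded")
        if stop1 or stop2:
            warnings.warn(f"{locus.name}: internal stop codon skipped")
            continue
        pairs.append((c1, c2))
    return pairs


def ng86_pair(pairs: list[tuple[str, str]], gene: str = "",
              table_id: int = 1) -> DnDsRecord:
    """Nei-Gojobori estimates from aligned codon pairs."""
    if not pairs:
        raise ValueError("no comparable codon pairs")
    s1 = sum(syn_site_fraction(c1, table_id) for c1, _ in pairs)
    s2 = sum(syn_site_fraction(c2, table_id) for _, c2 in pairs)
    s_sites = (s1 + s2) / 2.0
    n_sites = 3.0 * len(pairs) - s_sites
    sd = nd = 0.0
    for c1, c2 in pairs:
        ds_i, dn_i = pathway_counts(c1, c2, table_id)
        sd += ds_i
        nd += dn_i
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    ds = _jc_correct(ps)
    dn = _jc_correct(pn)
    saturated = ds is None or dn is None
    omega = None
    if dn is not None and ds is not None and ds > 0:
        omega = dn / ds
    return DnDsRecord(
        gene=gene, n_codons=len(pairs), n_sites=n_sites, s_sites=s_sites,
        nd=nd, sd=sd, pn=pn, ps=ps, dn=dn, ds=ds, omega=omega,
        saturated=saturated,
    )


def _ensure_aligned(locus: SyntenicLocus) -> SyntenicLocus:
    if not locus.is_aligned():
        from .divergence import align_locus, trim_terminal_gaps
        trim_terminal_gaps(align_locus(locus))
    return locus


def gene_dnds(locus: SyntenicLocus, table_id: int = 1) -> DnDsRecord:
    return ng86_pair(codonize(_ensure_aligned(locus), table_id),
                     gene=locus.name, table_id=table_id)


def dnds_table(loci: list[SyntenicLocus], table_id: int = 1) -> list[DnDsRecord]:
    """Per-gene records over aligned coding loci; pseudogene-flagged loci are
    excluded with a warning."""
    out = []
    for locus in loci:
        if locus.locus_class != "coding" or locus.flagged:
            continue
        try:
            out.append(gene_dnds(locus, table_id))
        except ValueError as exc:
            warnings.warn(str(exc))
    return out


def concatenate_and_rate(loci: list[SyntenicLocus], table_id: int = 1) -> DnDsRecord:
    """NG86 on the concatenation of all codonizable coding loci, in sorted
    gene-name order (counts are additive, so this equals summing per-gene
    nd/sd/site totals)."""
    usable = sorted(
        (l for l in loci if l.locus_class == "coding" and not l.flagged),
        key=lambda l: l.name,
    )
    pairs: list[tuple[str, str]] = []
    for locus in usable:
        try:
            pairs.extend(codonize(_ensure_aligned(locus), table_id))
        except ValueError as exc:
            warnings.warn(str(exc))
    if not pairs:
        raise ValueError("no shared intact coding loci to concatenate")
    return ng86_pair(pairs, gene="concatenated", table_id=table_id)
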