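"""Synthetic plastome generation with a complete ground-truth ledger.

The generator emits circular quadripartite genomes — LSC + IRb + SSC + IRa
with IRa the exact reverse complement of IRb — carrying a plastid-like gene
complement (including the 11 ndh genes in the SSC and ycf1 spanning the
IRa/SSC junction by a configurable overhang), planted SSR and dispersed-
repeat elements, ndh-loss scenarios coupled to IR boundary shifts, and a
two-descendant mutation process (substitutions + indels) for divergence
studies. Every planted fact is recorded in a :class:`SimTruth` ledger so
each analysis stage can be checked against known truth.

Determinism: every random draw flows from ``SimConfig.seed`` through
purpose-tagged ``numpy`` generators, so the same configuration yields
byte-identical genomes on any platform.

Two construction details exist purely to make recovery exact rather than
merely probable: one guard base is fixed at each junction-adjacent spacer
position so IR extension stops exactly at the planted boundary, and planted
SSR/repeat elements get mismatching flank columns so maximality trimming
lands exactly on the planted coordinates. Spacer sequence is scrubbed of
chance SSRs (a base is changed in any unplanned run that meets the census
thresholds), because random AT-rich sequence of plastome size otherwise
contains such runs with near-certainty.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .model import (
    AnnotatedPlastome,
    GeneFeature,
    NDH_GENES,
    RegionPartition,
    RepeatHit,
    SSRLocus,
    revcomp,
)
from .ssr import DEFAULT_THRESHOLDS, find_ssrs, is_primitive

_STOPS = {"TAA", "TAG", "TGA"}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


class ConfigError(ValueError):
    pass


# ---------------------------------------------------------------------------
# configuration

@dataclass(frozen=True)
class GeneSpec:
    """One gene in a region layout. ``exons`` are CDS/exon lengths in
    transcription order; ``introns`` the lengths between them."""

    name: str
    exons: tuple[int, ...]
    category: str = "protein_coding"
    strand: str = "+"
    introns: tuple[int, ...] = ()
    pseudo_retained: Optional[int] = None  # truncated remnant length

    @property
    def cds_length(self) -> int:
        return sum(self.exons)

    @property
    def span_length(self) -> int:
        if self.pseudo_retained is not None:
            return self.pseudo_retained
        return sum(self.exons) + sum(self.introns)


@dataclass(frozen=True)
class PlantedSSRSpec:
    motif: str
    unit_count: int
    region: str = "LSC"


@dataclass(frozen=True)
class PlantedRepeatSpec:
    kind: str = "forward"  # forward | palindromic | reverse
    length: int = 40
    mismatches: int = 0
    region: str = "LSC"


def default_lsc_genes() -> tuple[GeneSpec, ...]:
    g = GeneSpec
    return (
        g("psbA", (1062,), strand="-"),
        g("matK", (1530,)),
        g("rps16", (40, 227), introns=(860,), strand="-"),
        g("atpA", (1524,), strand="-"),
        g("atpF", (145, 410), introns=(700,), strand="-"),
        g("rpoC1", (432, 1614), introns=(750,), strand="-"),
        g("rpoB", (3213,), strand="-"),
        g("trnS", (88,), category="tRNA"),
        g("psbD", (1062,)),
        g("psbC", (1386,)),
        g("trnG", (71,), category="tRNA"),
        g("trnT", (72,), category="tRNA"),
        g("trnL", (35, 50), category="tRNA", introns=(500,)),
        g("trnF", (73,), category="tRNA"),
        g("rbcL", (1428,)),
        g("accD", (1467,)),
        g("ycf4", (555,)),
        g("cemA", (690,)),
        g("petA", (963,)),
        g("psbE", (252,), strand="-"),
        g("petL", (96,)),
        g("psaJ", (135,)),
        g("rpl20", (354,), strand="-"),
        g("rps18", (306,)),
        g("rpl33", (201,)),
        g("psbB", (1527,)),
        g("clpP", (69, 294, 228), introns=(650, 700), strand="-"),
        g("petB", (6, 642), introns=(700,)),
        g("petD", (8, 475), introns=(650,)),
        g("rpoA", (1014,), strand="-"),
        g("rps11", (417,), strand="-"),
        g("rpl36", (114,), strand="-"),
        g("rps8", (405,), strand="-"),
        g("rpl14", (369,), strand="-"),
        g("rpl16", (9, 399), introns=(900,), strand="-"),
        g("rps3", (657,), strand="-"),
        g("rpl22", (396,), strand="-"),
        g("rps19", (279,), strand="-"),
    )


def default_ir_genes() -> tuple[GeneSpec, ...]:
    g = GeneSpec
    return (
        g("rrn16", (1491,), category="rRNA"),
        g("trnI", (74,), category="tRNA"),
        g("trnA", (73,), category="tRNA"),
        g("rrn23", (2810,), category="rRNA"),
        g("rrn4.5", (95,), category="rRNA"),
        g("rrn5", (121,), category="rRNA"),
    )


def default_ssc_genes() -> tuple[GeneSpec, ...]:
    """SSC gene order: ndhF adjacent to J_SB; all 11 ndh genes live here."""
    g = GeneSpec
    return (
        g("ndhF", (2247,), strand="-"),
        g("rpl32", (174,)),
        g("ccsA", (966,)),
        g("ndhD", (1503,), strand="-"),
        g("psaC", (246,), strand="-"),
        g("ndhE", (306,), strand="-"),
        g("ndhG", (531,), strand="-"),
        g("ndhI", (501,), strand="-"),
        g("ndhA", (553, 539), introns=(1100,), strand="-"),
        g("ndhH", (1182,), strand="-"),
        g("rps15", (273,), strand="-"),
        g("ndhB", (1533,), strand="-"),
        g("ndhC", (363,), strand="-"),
        g("ndhJ", (477,), strand="-"),
        g("ndhK", (675,), strand="-"),
    )


def compact_ssc_genes() -> tuple[GeneSpec, ...]:
    g = GeneSpec
    return (
        g("ndhF", (450,), strand="-"),
        g("rpl32", (150,)),
        g("ndhD", (276,), strand="-"),
        g("ndhE", (126,), strand="-"),
        g("ndhG", (150,), strand="-"),
        g("ndhI", (126,), strand="-"),
        g("ndhA", (186, 189), introns=(210,), strand="-"),
        g("ndhH", (225,), strand="-"),
        g("ndhB", (300,), strand="-"),
        g("ndhC", (150,), strand="-"),
        g("ndhJ", (126,), strand="-"),
        g("ndhK", (150,), strand="-"),
    )


def compact_lsc_genes() -> tuple[GeneSpec, ...]:
    g = GeneSpec
    return (
        g("psbA", (510,), strand="-"),
        g("matK", (630,)),
        g("trnG", (71,), category="tRNA"),
        g("rbcL", (720,)),
        g("clpP", (69, 294), introns=(300,), strand="-"),
        g("psbB", (570,)),
        g("trnL", (35, 50), category="tRNA", introns=(280,)),
        g("rpoA", (480,), strand="-"),
        g("rps8", (300,)),
    )


def compact_ir_genes() -> tuple[GeneSpec, ...]:
    g = GeneSpec
    return (
        g("rrn16", (900,), category="rRNA"),
        g("trnI", (74,), category="tRNA"),
        g("rrn5", (121,), category="rRNA"),
    )


@dataclass
class SimConfig:
    """Study conditions for one synthetic plastome (pair).

    Default architecture mirrors an Apostasia-like plastome: region lengths
    83,035 / 26,452 / 20,187 bp (LSC/IR/SSC), a 991 bp ycf1 overhang into
    IRa, AT fraction 0.64. Mutation defaults are pairwise per-site
    substitution probabilities of 0.02 in non-coding and 0.01 in coding
    sequence (purifying selection slows genes) with 1.5 InDel events per
    non-coding locus pair and geometric indel lengths of mean 3: this puts
    congeneric-scale divergence on the loci — mean coding SV% below ~2.5
    and non-coding SV% severalfold higher.
    """

    seed: int = 0
    identifier: str = "synthetic"
    lsc_len: int = 83035
    ssc_len: int = 20187
    ir_len: int = 26452
    ycf1_len: int = 5313
    ycf1_overhang: int = 991
    at_fraction: float = 0.64
    lsc_genes: tuple[GeneSpec, ...] = field(default_factory=default_lsc_genes)
    ir_genes: tuple[GeneSpec, ...] = field(default_factory=default_ir_genes)
    ssc_genes: tuple[GeneSpec, ...] = field(default_factory=default_ssc_genes)
    min_spacer: int = 150
    p_sub: float = 0.02
    p_sub_coding: float = 0.01
    indel_rate: float = 1.5
    indel_mean_len: float = 3.0
    coding_indel_rate: float = 0.2
    ssr_thresholds: dict[int, int] = field(
        default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    planted_ssrs: tuple[PlantedSSRSpec, ...] = ()
    planted_repeats: tuple[PlantedRepeatSpec, ...] = ()

    @classmethod
    def compact(cls, seed: int = 0, **kw) -> "SimConfig":
        """A ~17 kb genome with the same architecture, for fast sweeps."""
        defaults = dict(
            seed=seed, identifier="synthetic-compact",
            lsc_len=6200, ssc_len=5800, ir_len=2600,
            ycf1_len=1200, ycf1_overhang=240,
            lsc_genes=compact_lsc_genes(), ir_genes=compact_ir_genes(),
            ssc_genes=compact_ssc_genes(), min_spacer=100,
        )
        defaults.update(kw)
        return cls(**defaults)

    def ndh_cds_lengths(self) -> dict[str, int]:
        return {g.name: g.cds_length for g in self.ssc_genes
                if g.name in NDH_GENES}


@dataclass(frozen=True)
class Scenario:
    """An ndh-loss scenario: genes to delete or truncate to pseudogene
    remnants, and the IR extension into the SSC (bp duplicated into both IR
    copies)."""

    label: str = "A"
    delete: tuple[str, ...] = ()
    pseudogenize: tuple[tuple[str, int], ...] = ()  # (gene, retained bp)
    ir_extension: int = 0


def scenario_b(cfg: SimConfig, expansion: int = 800) -> Scenario:
    present = tuple(g.name for g in cfg.ssc_genes if g.name in NDH_GENES)
    return Scenario("B", delete=present, ir_extension=expansion)


def scenario_c(cfg: SimConfig, retained_target: int,
               slope: float = 0.136) -> Scenario:
    """A partial ndh-loss scenario whose total retained ndh length equals
    ``retained_target`` and whose planted IR shift is slope x target
    (which must be integral — e.g. targets in multiples of 125 bp for the
    default slope 17/125 = 0.136)."""
    lengths = cfg.ndh_cds_lengths()
    order = [n for n in NDH_GENES if n in lengths]
    total = sum(lengths.values())
    if not 0 < retained_target < total:
        raise ConfigError(f"retained target {retained_target} outside (0, {total})")
    shift = slope * retained_target
    if abs(shift - round(shift)) > 1e-9:
        raise ConfigError(f"slope*target = {shift} is not an integer IR shift")
    keep: list[str] = []
    pseudo: list[tuple[str, int]] = []
    remaining = retained_target
    for name in order:
        if lengths[name] <= remaining:
            keep.append(name)
            remaining -= lengths[name]
        elif remaining > 0:
            pseudo.append((name, remaining))
            remaining = 0
    delete = tuple(n for n in order if n not in keep
                   and n not in {p[0] for p in pseudo})
    return Scenario("C", delete=delete, pseudogenize=tuple(pseudo),
                    ir_extension=int(round(shift)))


# ---------------------------------------------------------------------------
# ground truth

@dataclass
class SimTruth:
    partition: RegionPartition
    planted_ssrs: list[SSRLocus]
    planted_repeats: list[RepeatHit]
    scenario: str
    retained_ndh_length: int
    ycf1_to_jsa: int
    ir_extension: int
    config: SimConfig
    spacers: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class LocusPairTruth:
    """Mutation ledger for one locus evolved into two descendants."""

    subs1: list[tuple[int, str, str]]
    subs2: list[tuple[int, str, str]]
    indels1: list[tuple[int, int, str]]  # (ancestor pos, length, ins|del)
    indels2: list[tuple[int, int, str]]
    expected_substitution_columns: int
    expected_conserved_sites: int

    @property
    def expected_indel_events(self) -> int:
        return len(self.indels1) + len(self.indels2)

    @property
    def expected_sv_percent(self) -> float:
        num = self.expected_substitution_columns + self.expected_indel_events
        denom = num + self.expected_conserved_sites
        return 100.0 * num / denom if denom else 0.0


# ---------------------------------------------------------------------------
# random primitives

def _rng(seed: int, tag: str) -> np.random.Generator:
    return np.random.default_rng(
        [seed & 0x7FFFFFFF, zlib.crc32(tag.encode()) & 0x7FFFFFFF])


_BASE_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_seq(length: int, rng: np.random.Generator, at: float) -> str:
    if length <= 0:
        return ""
    p = [at / 2, (1 - at) / 2, (1 - at) / 2, at / 2]
    return rng.choice(_BASE_ARR, size=length, p=p).tobytes().decode()


def _random_cds(length: int, rng: np.random.Generator, at: float) -> str:
    """Random coding sequence: ATG start, TAA stop, no internal stops."""
    if length % 3 != 0 or length < 9:
        raise ConfigError(f"CDS length {length} must be a multiple of 3, >= 9")
    s = list(_random_seq(length, rng, at))
    s[0:3] = "ATG"
    s[-3:] = "TAA"
    for i in range(3, length - 3, 3):
        if "".join(s[i:i + 3]) in _STOPS:
            s[i + 2] = "C"  # TAA/TAG/TGA -> TAC/TGC, never a stop
    return "".join(s)


# ---------------------------------------------------------------------------
# assembly

@dataclass
class _Layout:
    seq: str
    features: list[GeneFeature]
    spacers: list[tuple[int, int]]  # relative intervals of random spacer DNA


def _gene_fragment(spec: GeneSpec, rng: np.random.Generator,
                   at: float) -> tuple[str, list[tuple[int, int]]]:
    """Genomic fragment and relative exon segments for one gene."""
    if spec.pseudo_retained is not None:
        full = _random_cds(spec.cds_length, rng, at)
        frag_t = full[:spec.pseudo_retained]
        segs_t = [(0, len(frag_t))]
    elif spec.category == "protein_coding":
        cds = _random_cds(spec.cds_length, rng, at)
        parts, segs_t, pos, ci = [], [], 0, 0
        for idx, elen in enumerate(spec.exons):
            parts.append(cds[ci:ci + elen])
            segs_t.append((pos, pos + elen))
            pos += elen
            ci += elen
            if idx < len(spec.exons) - 1:
                intron = _random_seq(spec.introns[idx], rng, at)
                parts.append(intron)
                pos += len(intron)
        frag_t = "".join(parts)
    else:
        parts, segs_t, pos = [], [], 0
        for idx, elen in enumerate(spec.exons):
            parts.append(_random_seq(elen, rng, at))
            segs_t.append((pos, pos + elen))
            pos += elen
            if idx < len(spec.exons) - 1:
                parts.append(_random_seq(spec.introns[idx], rng, at))
                pos += spec.introns[idx]
        frag_t = "".join(parts)
    if spec.strand == "-":
        L = len(frag_t)
        frag = revcomp(frag_t)
        segs = sorted((L - b, L - a) for a, b in segs_t)
    else:
        frag, segs = frag_t, segs_t
    return frag, segs


def _fill_gaps(target: int, span_sum: int, n_gaps: int, min_spacer: int,
               rng: np.random.Generator, region: str) -> list[int]:
    leftover = target - span_sum
    if leftover < n_gaps * min_spacer:
        raise ConfigError(
            f"genes overflow region {region}: {span_sum} bp of genes + "
            f"{n_gaps} x {min_spacer} bp spacers > {target} bp")
    base, rem = divmod(leftover, n_gaps)
    gaps = [base + (1 if i < rem else 0) for i in range(n_gaps)]
    for _ in range(2 * n_gaps):  # deterministic jitter, totals conserved
        i, j = int(rng.integers(0, n_gaps)), int(rng.integers(0, n_gaps))
        amt = int(rng.integers(0, max(1, base // 5)))
        if gaps[i] - amt >= min_spacer:
            gaps[i] -= amt
            gaps[j] += amt
    return gaps


def _build_region(region: str, genes: Sequence[GeneSpec], target: int,
                  cfg: SimConfig) -> _Layout:
    gaps = _fill_gaps(target, sum(g.span_length for g in genes),
                      len(genes) + 1, cfg.min_spacer,
                      _rng(cfg.seed, f"gaps:{region}"), region)
    parts: list[str] = []
    feats: list[GeneFeature] = []
    spacers: list[tuple[int, int]] = []
    pos = 0
    names = ["5prime"] + [g.name for g in genes]
    for i, gap in enumerate(gaps):
        tag = f"spacer:{region}:{names[i]}:{i}"
        parts.append(_random_seq(gap, _rng(cfg.seed, tag), cfg.at_fraction))
        spacers.append((pos, pos + gap))
        pos += gap
        if i < len(genes):
            spec = genes[i]
            frag, segs = _gene_fragment(
                spec, _rng(cfg.seed, f"gene:{spec.name}"), cfg.at_fraction)
            feats.append(GeneFeature(
                spec.name, spec.category, spec.strand,
                [(pos + a, pos + b) for a, b in segs],
                pseudogene=spec.pseudo_retained is not None))
            parts.append(frag)
            pos += len(frag)
    return _Layout("".join(parts), feats, spacers)


def _shift_feature(f: GeneFeature, offset: int) -> GeneFeature:
    return replace(f, segments=[(a + offset, b + offset) for a, b in f.segments])


def _mirror_ir_feature(f: GeneFeature, irb: tuple[int, int],
                       ira_start: int) -> GeneFeature:
    L0, I = irb[0], irb[1] - irb[0]
    segs = sorted((ira_start + (I - (b - L0)), ira_start + (I - (a - L0)))
                  for a, b in f.segments)
    return replace(f, segments=segs,
                   strand="-" if f.strand == "+" else "+")


def _apply_scenario_to_genes(genes: Sequence[GeneSpec],
                             scenario: Scenario) -> tuple[GeneSpec, ...]:
    present = {g.name for g in genes}
    for name in scenario.delete:
        if name not in present:
            raise ConfigError(f"scenario deletes absent gene {name}")
    pseudo = dict(scenario.pseudogenize)
    for name in pseudo:
        if name not in present:
            raise ConfigError(f"scenario pseudogenizes absent gene {name}")
    out = []
    for g in genes:
        if g.name in scenario.delete:
            continue
        if g.name in pseudo:
            out.append(replace(g, pseudo_retained=pseudo[g.name]))
        else:
            out.append(g)
    return tuple(out)


# ---------------------------------------------------------------------------
# genome assembly

def _choose_base(exclude: set[str]) -> str:
    for b in "ACGT":
        if b not in exclude:
            return b
    raise RuntimeError("no base satisfies constraints")


class _Genome:
    """Mutable assembled genome with IR mirroring and CDS stop-safety."""

    def __init__(self, seq: str, features: list[GeneFeature],
                 part: RegionPartition):
        self.arr = bytearray(seq.encode())
        self.n = len(seq)
        self.features = features
        self.part = part
        self.protected = np.zeros(self.n, dtype=bool)
        # planted repeat pairs: scrub edits inside a copy must be mirrored
        # into the partner copy to preserve the planted relationship
        self.repeat_pairs: list[tuple[str, int, int, int]] = []
        # transcription-ordered genome positions per intact CDS
        self._cds_pos: dict[int, tuple[GeneFeature, list[int], int]] = {}
        for f in features:
            if f.category != "protein_coding" or f.pseudogene:
                continue
            positions: list[int] = []
            for a, b in sorted(f.segments):
                positions.extend(range(a, b))
            if f.strand == "-":
                positions.reverse()
            for idx, q in enumerate(positions):
                self._cds_pos[q % self.n] = (f, positions, idx)

    # -- base access -------------------------------------------------------
    def base(self, p: int) -> str:
        return chr(self.arr[p % self.n])

    def sequence(self) -> str:
        return self.arr.decode()

    # -- IR mirroring ------------------------------------------------------
    def _mirror(self, p: int) -> Optional[int]:
        (bs, be), (as_, ae) = self.part.irb, self.part.ira
        if bs <= p < be:
            return as_ + (be - 1 - p)
        if as_ <= p < ae:
            return bs + (ae - 1 - p)
        return None

    def write(self, p: int, b: str) -> None:
        p %= self.n
        self.arr[p] = ord(b)
        q = self._mirror(p)
        if q is not None:
            self.arr[q] = ord(_COMP[b])

    # -- CDS stop safety ---------------------------------------------------
    def stop_safe(self, p: int, b: str) -> bool:
        hit = self._cds_pos.get(p % self.n)
        if hit is None:
            return True
        f, positions, idx = hit
        ci = idx // 3
        tri = positions[3 * ci:3 * ci + 3]
        if len(tri) < 3:
            return True
        bases = []
        for q in tri:
            base = b if q % self.n == p % self.n else self.base(q)
            bases.append(_COMP[base] if f.strand == "-" else base)
        return "".join(bases) not in _STOPS

    def protect(self, a: int, b: int) -> None:
        for p in range(a, b):
            self.protected[p % self.n] = True

    def repeat_partner(self, p: int) -> Optional[tuple[int, bool]]:
        """Partner position (and whether it carries the complement) of a
        base inside a planted repeat copy."""
        for kind, q1, q2, R in self.repeat_pairs:
            for qa, qb in ((q1, q2), (q2, q1)):
                if qa <= p < qa + R:
                    t = p - qa
                    if kind == "forward":
                        return qb + t, False
                    if kind == "palindromic":
                        return qb + (R - 1 - t), True
                    return qb + (R - 1 - t), False  # reverse
        return None


def _fix_junction_guards(g: _Genome) -> None:
    """One guard base per junction so IR extension stops exactly at the
    planted boundaries."""
    part = g.part
    pairs = [
        (0, part.lsc[1] - 1),           # J_LA wrap vs J_LB flank
        (part.ssc[0], part.ssc[1] - 1),  # J_SB flank vs J_SA flank
    ]
    for guard, partner in pairs:
        bad = {_COMP[g.base(partner)], g.base(guard - 1), g.base(guard + 1)}
        if len(bad) >= 4:
            bad = {_COMP[g.base(partner)]}
        b = _choose_base(bad)
        if not g.stop_safe(guard, b):  # guards sit in spacers; belt and braces
            b = _choose_base(bad | {b})
        g.write(guard, b)
    for guard, partner in pairs:
        g.protect(guard, guard + 1)
        g.protect(partner, partner + 1)


def _scrub_fragment(seq: str, thresholds: dict[int, int],
                    rng: np.random.Generator) -> str:
    """Break chance SSRs inside an isolated fragment (linear scan)."""
    s = list(seq)
    for _ in range(50):
        loci = find_ssrs("".join(s), thresholds, circular=False)
        if not loci:
            return "".join(s)
        for l in loci:
            u = l.unit_size
            mid = (l.span[0] + l.span[1]) // 2
            bad = {s[mid]}
            if mid - u >= 0:
                bad.add(s[mid - u])
            if mid + u < len(s):
                bad.add(s[mid + u])
            s[mid] = _choose_base(bad)
    raise RuntimeError("fragment scrub did not converge")


def _plant_elements(g: _Genome, spacers: list[tuple[int, int]],
                    cfg: SimConfig) -> tuple[list[SSRLocus], list[RepeatHit]]:
    by_region: dict[str, list[tuple[int, int]]] = {"LSC": [], "SSC": []}
    for a, b in spacers:
        reg = g.part.region_of((a + b) // 2)
        if reg in by_region:
            by_region[reg].append((a, b))
    for reg in by_region:
        by_region[reg].sort(key=lambda iv: (-(iv[1] - iv[0]), iv[0]))
    used: dict[str, int] = {"LSC": 0, "SSC": 0}

    def take_slot(region: str, need: int) -> tuple[int, int]:
        slots = by_region.get(region)
        if slots is None:
            raise ConfigError(f"cannot plant into region {region!r}")
        while used[region] < len(slots):
            a, b = slots[used[region]]
            used[region] += 1
            if b - a >= need:
                return a, b
        raise ConfigError(f"no spacer in {region} can hold {need} bp element")

    ssrs: list[SSRLocus] = []
    for spec in cfg.planted_ssrs:
        if not (1 <= len(spec.motif) <= 6) or not is_primitive(spec.motif):
            raise ConfigError(f"motif {spec.motif!r} must be primitive, 1-6 bp")
        size = len(spec.motif) * spec.unit_count
        a, b = take_slot(spec.region, size + 10)
        q = a + (b - a - size) // 2
        for i in range(size):
            g.write(q + i, spec.motif[i % len(spec.motif)])
        left = _choose_base({spec.motif[-1], g.base(q - 2)})
        g.write(q - 1, left)
        right = _choose_base({spec.motif[0], g.base(q + size + 1)})
        g.write(q + size, right)
        g.protect(q - 1, q + size + 1)
        ssrs.append(SSRLocus(spec.motif, spec.unit_count, (q, q + size)))

    rng = _rng(cfg.seed, "plant:repeats")
    repeats: list[RepeatHit] = []
    for spec in cfg.planted_repeats:
        R = spec.length
        if R < 12 or spec.mismatches > 3:
            raise ConfigError("planted repeat: length >= 12, mismatches <= 3")
        content = _scrub_fragment(
            _random_seq(R, rng, cfg.at_fraction), cfg.ssr_thresholds, rng)
        a1, b1 = take_slot(spec.region, R + 14)
        a2, b2 = take_slot(spec.region, R + 14)
        q1 = a1 + (b1 - a1 - R) // 2
        q2 = a2 + (b2 - a2 - R) // 2
        if q1 > q2:
            q1, q2 = q2, q1
        if spec.mismatches:
            # keep every clean prefix/suffix below the 30 bp census floor so
            # the planted pair is the only maximal reportable window
            lo, hi = max(4, R - 30), min(R - 5, 29)
            if hi < lo:
                raise ConfigError(
                    "mismatched planted repeats must be shorter than 60 bp")
            cols = sorted(rng.choice(np.arange(lo, hi + 1),
                                     size=spec.mismatches,
                                     replace=False).tolist())
        else:
            cols = []
        c1 = list(content)
        if spec.kind == "forward":
            c2 = list(content)
            for pos in cols:
                c2[pos] = _choose_base({c1[pos], c2[pos - 1], c2[pos + 1]})
        elif spec.kind == "palindromic":
            c2 = list(revcomp(content))
            for pos in cols:
                j = R - 1 - pos
                c2[j] = _choose_base({_COMP[c1[pos]], c2[j - 1], c2[j + 1]})
        elif spec.kind == "reverse":
            c2 = list(content[::-1])
            for pos in cols:
                j = R - 1 - pos
                c2[j] = _choose_base({c1[pos], c2[j - 1], c2[j + 1]})
        else:
            raise ConfigError(f"unknown repeat kind {spec.kind!r}")
        for i in range(R):
            g.write(q1 + i, c1[i])
            g.write(q2 + i, c2[i])
        # 4-column mismatch guards around copy2's flanks
        if spec.kind == "forward":
            for t in range(1, 5):
                g.write(q2 - t, _choose_base({g.base(q1 - t), g.base(q2 - t + 1)}))
            for t in range(0, 4):
                g.write(q2 + R + t,
                        _choose_base({g.base(q1 + R + t), g.base(q2 + R + t - 1)}))
        else:
            comp = (lambda b: _COMP[b]) if spec.kind == "palindromic" else (lambda b: b)
            for t in range(1, 5):
                g.write(q2 + R + t - 1,
                        _choose_base({comp(g.base(q1 - t)), g.base(q2 + R + t - 2)}))
                g.write(q2 - t,
                        _choose_base({comp(g.base(q1 + R + t - 1)), g.base(q2 - t + 1)}))
        # flanks and guards are immutable; copy interiors stay editable via
        # paired writes, except the planted mismatch columns
        g.protect(q1 - 5, q1)
        g.protect(q1 + R, q1 + R + 5)
        g.protect(q2 - 5, q2)
        g.protect(q2 + R, q2 + R + 5)
        for pos in cols:
            g.protect(q1 + pos, q1 + pos + 1)
            j = pos if spec.kind == "forward" else R - 1 - pos
            g.protect(q2 + j, q2 + j + 1)
        g.repeat_pairs.append((spec.kind, q1, q2, R))
        repeats.append(RepeatHit(spec.kind, (q1, q1 + R), (q2, q2 + R),
                                 R, spec.mismatches))
    return ssrs, repeats


def _scrub_genome(g: _Genome, cfg: SimConfig,
                  whitelist: set[tuple[str, tuple[int, int]]]) -> None:
    """Mutate one base inside every unplanned SSR run until the census is
    clean; planted spans and guards are never touched."""
    for _ in range(300):
        loci = find_ssrs(g.sequence(), cfg.ssr_thresholds, circular=True)
        offenders = [l for l in loci if (l.motif, l.span) not in whitelist]
        if not offenders:
            return
        progressed = False
        for l in offenders:
            u = l.unit_size
            center = (l.span[0] + l.span[1]) // 2
            candidates = sorted(range(l.span[0], l.span[1]),
                                key=lambda p: abs(p - center))
            for p0 in candidates:
                p = p0 % g.n
                if g.protected[p]:
                    continue
                q = g._mirror(p)
                if q is not None and g.protected[q]:
                    continue
                partner = g.repeat_partner(p)
                if partner is not None and g.protected[partner[0]]:
                    continue
                bad = {g.base(p), g.base(p - u), g.base(p + u)}
                choice = None
                for b in "ACGT":
                    if b in bad:
                        continue
                    if not g.stop_safe(p, b):
                        continue
                    if q is not None and not g.stop_safe(q, _COMP[b]):
                        continue
                    choice = b
                    break
                if choice is None:
                    continue
                g.write(p, choice)
                if partner is not None:  # keep the planted pairing intact
                    pp, needs_comp = partner
                    g.write(pp, _COMP[choice] if needs_comp else choice)
                progressed = True
                break
        if not progressed:
            raise RuntimeError("SSR scrub blocked by protected spans")
    raise RuntimeError("SSR scrub did not converge")


def _assemble(cfg: SimConfig, scenario: Scenario) -> tuple[AnnotatedPlastome, SimTruth]:
    o = cfg.ycf1_overhang
    if not 0 < o < cfg.ycf1_len:
        raise ConfigError("ycf1 overhang must lie inside the gene")
    delta = scenario.ir_extension
    ssc_genes = _apply_scenario_to_genes(cfg.ssc_genes, scenario)
    removed = (sum(gs.span_length for gs in cfg.ssc_genes)
               - sum(gs.span_length for gs in ssc_genes))

    ycf1_cds = _random_cds(cfg.ycf1_len, _rng(cfg.seed, "gene:ycf1"),
                           cfg.at_fraction)
    G = revcomp(ycf1_cds)  # genomic orientation, '-' strand
    ycf1_ssc_part, ycf1_ira_part = G[:cfg.ycf1_len - o], G[cfg.ycf1_len - o:]

    lsc = _build_region("LSC", cfg.lsc_genes, cfg.lsc_len, cfg)
    irb_body = _build_region("IR", cfg.ir_genes, cfg.ir_len - o, cfg)
    ssc_core_target = cfg.ssc_len - len(ycf1_ssc_part) - removed
    ssc_core = _build_region("SSC", ssc_genes, ssc_core_target, cfg)

    ssc_full = ssc_core.seq + ycf1_ssc_part
    if delta < 0 or delta >= len(ssc_full):
        raise ConfigError(f"IR extension {delta} outside [0, SSC length)")
    tail = ssc_full[len(ssc_full) - delta:] if delta else ""
    irb_seq = irb_body.seq + revcomp(ycf1_ira_part) + revcomp(tail)
    ssc_seq = ssc_full[:len(ssc_full) - delta]
    genome = lsc.seq + irb_seq + ssc_seq + revcomp(irb_seq)

    L, I, S = len(lsc.seq), len(irb_seq), len(ssc_seq)
    part = RegionPartition((0, L), (L, L + I), (L + I, L + I + S),
                           (L + I + S, L + 2 * I + S))
    j_sa = part.j_sa

    features: list[GeneFeature] = [
        *lsc.features,
        *[_shift_feature(f, L) for f in irb_body.features],
        *[_shift_feature(f, L + I) for f in ssc_core.features],
    ]
    ycf1_start = j_sa - (cfg.ycf1_len - o - delta)
    features.append(GeneFeature("ycf1", "protein_coding", "-",
                                [(ycf1_start, ycf1_start + cfg.ycf1_len)]))
    for f in irb_body.features:
        features.append(_mirror_ir_feature(_shift_feature(f, L), part.irb, j_sa))
    features.sort(key=lambda f: (f.start, f.name))

    g = _Genome(genome, features, part)
    _fix_junction_guards(g)
    spacer_abs = (lsc.spacers
                  + [(a + L + I, b + L + I) for a, b in ssc_core.spacers])
    ssrs, repeats = _plant_elements(g, spacer_abs, cfg)
    whitelist = {(s.motif, s.span) for s in ssrs}
    _scrub_genome(g, cfg, whitelist)

    ident = cfg.identifier if scenario.label == "A" else \
        f"{cfg.identifier}-{scenario.label}"
    plastome = AnnotatedPlastome(ident, g.sequence(), features, True)
    retained = sum(
        next(f.total_length for f in features if f.name == name)
        for name in NDH_GENES
        if any(f.name == name for f in features)
    )
    truth = SimTruth(
        partition=part, planted_ssrs=ssrs, planted_repeats=repeats,
        scenario=scenario.label, retained_ndh_length=retained,
        ycf1_to_jsa=o + delta, ir_extension=delta, config=cfg,
        spacers=spacer_abs,
    )
    return plastome, truth


def generate_ancestor(cfg: SimConfig) -> tuple[AnnotatedPlastome, SimTruth]:
    """A clean type-A plastome plus its ground-truth ledger."""
    return _assemble(cfg, Scenario("A"))


def apply_scenario(source: SimConfig | SimTruth,
                   scenario: Scenario) -> tuple[AnnotatedPlastome, SimTruth]:
    """Rebuild the configured genome under an ndh-loss scenario.

    Scenario A is a no-op: the result is byte-identical to the ancestor of
    the same configuration.
    """
    cfg = source.config if isinstance(source, SimTruth) else source
    return _assemble(cfg, scenario)


# ---------------------------------------------------------------------------
# mutation processes (star genealogy: two independent descendants)

def _alt_base(base: str, rng: np.random.Generator) -> str:
    alts = [b for b in "ACGT" if b != base]
    return alts[int(rng.integers(0, 3))]


def _draw_indels(n: int, lam: float, mean_len: float, coding: bool,
                 rng: np.random.Generator, margin: int,
                 occupied: list[tuple[int, int]]) -> list[tuple[int, int, str]]:
    events: list[tuple[int, int, str]] = []
    for _ in range(int(rng.poisson(lam))):
        length = int(rng.geometric(1.0 / mean_len))
        if coding:
            length = 3 * ((length + 2) // 3)
        kind = "del" if rng.random() < 0.5 else "ins"
        span_needed = length if kind == "del" else 1
        lo, hi = margin, n - margin - span_needed
        if hi <= lo:
            continue
        placed = False
        for _try in range(50):
            pos = int(rng.integers(lo, hi))
            span = (pos - 2, pos + span_needed + 2)
            if all(span[1] <= a or b <= span[0] for a, b in occupied):
                occupied.append(span)
                events.append((pos, length, kind))
                placed = True
                break
        if not placed:
            warnings.warn("indel placement rejected 50 times; event skipped")
    return events


def _apply_mutations(seq: str, subs: list[tuple[int, str, str]],
                     indels: list[tuple[int, int, str]],
                     rng: np.random.Generator, at: float) -> str:
    s = list(seq)
    for pos, old, new in subs:
        s[pos] = new
    for pos, length, kind in sorted(indels, reverse=True):
        if kind == "del":
            del s[pos:pos + length]
        else:
            s[pos:pos] = list(_random_seq(length, rng, at))
    return "".join(s)


def evolve_locus(seq: str, rng: np.random.Generator,
                 p_sub: float = 0.01, indel_rate: float = 1.0,
                 indel_mean_len: float = 3.0, coding: bool = False,
                 at: float = 0.64) -> tuple[str, str, LocusPairTruth]:
    """Evolve one locus into two descendants.

    Each descendant receives per-site Bernoulli(p_sub/2) substitutions
    (uniform alternative base) and Poisson(indel_rate/2) indel events with
    geometric lengths (mean ``indel_mean_len``; multiples of 3 when
    ``coding``). Indels never overlap each other across the two descendants,
    so every event is its own gap run in the true alignment.
    """
    n = len(seq)
    occupied: list[tuple[int, int]] = []
    out_seqs = []
    subs_all: list[list[tuple[int, str, str]]] = []
    indels_all: list[list[tuple[int, int, str]]] = []
    for _ in range(2):
        positions = np.flatnonzero(rng.random(n) < p_sub / 2.0)
        subs = [(int(p), seq[p], _alt_base(seq[p], rng)) for p in positions]
        indels = _draw_indels(n, indel_rate / 2.0, indel_mean_len, coding,
                              rng, margin=3, occupied=occupied)
        subs_all.append(subs)
        indels_all.append(indels)
        out_seqs.append(_apply_mutations(seq, subs, indels, rng, at))

    deleted: set[int] = set()
    for indels in indels_all:
        for pos, length, kind in indels:
            if kind == "del":
                deleted.update(range(pos, pos + length))
    m1 = {p: new for p, _, new in subs_all[0]}
    m2 = {p: new for p, _, new in subs_all[1]}
    differing = sum(
        1 for p in set(m1) | set(m2)
        if p not in deleted and m1.get(p, seq[p]) != m2.get(p, seq[p]))
    visible = n - len(deleted)
    truth = LocusPairTruth(
        subs1=subs_all[0], subs2=subs_all[1],
        indels1=indels_all[0], indels2=indels_all[1],
        expected_substitution_columns=differing,
        expected_conserved_sites=visible - differing,
    )
    return out_seqs[0], out_seqs[1], truth


def _lift_interval(iv: tuple[int, int], pos: int, delta: int) -> tuple[int, int]:
    s, e = iv
    if pos < s:
        return (s + delta, e + delta)
    if pos < e:
        return (s, e + delta)
    return iv


def _lift_features(features: list[GeneFeature], pos: int,
                   delta: int) -> list[GeneFeature]:
    return [replace(f, segments=[_lift_interval(seg, pos, delta)
                                 for seg in f.segments])
            for f in features]


def evolve_pair(p: AnnotatedPlastome, truth: SimTruth,
                seed: Optional[int] = None
                ) -> tuple[AnnotatedPlastome, AnnotatedPlastome,
                           dict[str, "object"]]:
    """Whole-genome two-descendant evolution of a generated plastome.

    Substitutions fall genome-wide outside planted elements and junction
    guards; a substitution in the IR is mirrored into the other copy
    (concerted evolution), keeping the two IR copies identical within each
    descendant. CDS substitutions that would create an internal stop are
    re-drawn. Indels fall in single-copy spacers (any length) and in
    single-copy CDS exons (multiples of 3, ``coding_indel_rate``); features
    and the region partition are lifted through every indel.
    """
    cfg = truth.config
    rng = _rng(cfg.seed if seed is None else seed, "evolve-pair")
    n = p.length
    part = truth.partition
    blocked = np.zeros(n, dtype=bool)
    for s in truth.planted_ssrs:
        blocked[s.span[0] - 1:s.span[1] + 1] = True
    for r in truth.planted_repeats:
        blocked[r.span1[0] - 5:r.span1[1] + 5] = True
        blocked[r.span2[0] - 5:r.span2[1] + 5] = True
    for g in (0, part.lsc[1] - 1, part.ssc[0], part.ssc[1] - 1):
        blocked[g] = True
    ira = part.ira
    blocked[ira[0]:ira[1]] = True  # IR subs drawn on the IRb copy only

    helper = _Genome(p.sequence, p.features, part)

    def mirrored(pos: int) -> Optional[int]:
        return helper._mirror(pos)

    cds_mask = np.zeros(n, dtype=bool)
    for pos in helper._cds_pos:
        cds_mask[pos] = True
    p_site = np.where(cds_mask, cfg.p_sub_coding, cfg.p_sub) / 2.0

    descendants = []
    ledgers = {}
    for d in (1, 2):
        subs: list[tuple[int, str, str]] = []
        positions = np.flatnonzero((rng.random(n) < p_site) & ~blocked)
        for pos in positions:
            pos = int(pos)
            old = p.sequence[pos]
            new = None
            for _try in range(6):
                cand = _alt_base(old, rng)
                mir = mirrored(pos)
                if helper.stop_safe(pos, cand) and (
                        mir is None or helper.stop_safe(mir, _COMP[cand])):
                    new = cand
                    break
            if new is None:
                continue
            subs.append((pos, old, new))
            mir = mirrored(pos)
            if mir is not None:
                subs.append((mir, p.sequence[mir], _COMP[new]))

        occupied: list[tuple[int, int]] = ledgers.setdefault("_occupied", [])
        indels: list[tuple[int, int, str]] = []
        for a, b in truth.spacers:
            local = _draw_indels(b - a, cfg.indel_rate / 2.0,
                                 cfg.indel_mean_len, False, rng, margin=3,
                                 occupied=[(s - a, e - a) for s, e in occupied])
            for pos, length, kind in local:
                occupied.append((a + pos - 2, a + pos + max(length, 1) + 2))
                indels.append((a + pos, length, kind))
        for f in p.features:
            if f.category != "protein_coding" or f.pseudogene:
                continue
            if part.region_of(f.start % n) not in ("LSC", "SSC"):
                continue
            a, b = max(f.segments, key=lambda seg: seg[1] - seg[0])
            if b - a < 60:
                continue
            local = _draw_indels(b - a, cfg.coding_indel_rate / 2.0,
                                 cfg.indel_mean_len, True, rng, margin=9,
                                 occupied=[(s - a, e - a) for s, e in occupied])
            for pos, length, kind in local:
                occupied.append((a + pos - 2, a + pos + max(length, 1) + 2))
                indels.append((a + pos, length, kind))

        seq_d = _apply_mutations(p.sequence, subs, indels, rng, cfg.at_fraction)
        feats = [replace(f, segments=list(f.segments)) for f in p.features]
        lifted_part = part
        for pos, length, kind in sorted(indels, reverse=True):
            delta = length if kind == "ins" else -length
            feats = _lift_features(feats, pos, delta)
            lifted_part = RegionPartition(
                _lift_interval(lifted_part.lsc, pos, delta),
                _lift_interval(lifted_part.irb, pos, delta),
                _lift_interval(lifted_part.ssc, pos, delta),
                _lift_interval(lifted_part.ira, pos, delta),
            )
        descendants.append(AnnotatedPlastome(
            f"{p.identifier}-d{d}", seq_d, feats, True))
        ledgers[f"subs{d}"] = subs
        ledgers[f"indels{d}"] = indels
        ledgers[f"partition{d}"] = lifted_part
    ledgers.pop("_occupied", None)
    return descendants[0], descendants[1], ledgers


# ---------------------------------------------------------------------------
# codon-pair simulator for dN/dS recovery

_SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _STOPS
)


def simulate_codon_pairs(n_codons: int, omega: float,
                         rng: np.random.Generator, mu: float = 0.3
                         ) -> tuple[list[tuple[str, str]], dict]:
    """Evolve two codon sequences from a common ancestor under a selection
    filter: synonymous point mutations are always accepted, non-synonymous
    ones with probability ``omega``; mutations into stop codons are
    rejected. ``mu`` is the expected pairwise attempt rate per nucleotide
    site.

    Returns the aligned codon pairs and a ledger of realized accepted
    synonymous/non-synonymous counts.
    """
    from .dnds import _code

    forward, stops = _code(1)
    anc = [
        _SENSE_CODONS[int(rng.integers(0, len(_SENSE_CODONS)))]
        for _ in range(n_codons)
    ]
    realized = {"syn": 0, "nonsyn": 0}
    seqs = []
    for _lineage in range(2):
        cur = list(anc)
        attempts = int(rng.poisson(mu / 2.0 * 3 * n_codons))
        for _ in range(attempts):
            ci = int(rng.integers(0, n_codons))
            pos = int(rng.integers(0, 3))
            codon = cur[ci]
            alt = _alt_base(codon[pos], rng)
            mutant = codon[:pos] + alt + codon[pos + 1:]
            if mutant in stops:
                continue
            if forward[codon] == forward[mutant]:
                cur[ci] = mutant
                realized["syn"] += 1
            elif rng.random() < omega:
                cur[ci] = mutant
                realized["nonsyn"] += 1
        seqs.append(cur)
    pairs = list(zip(seqs[0], seqs[1]))
    return pairs, realized
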