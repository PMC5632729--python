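"""Shared data model for comparative plastome analysis.

Coordinates are 0-based half-open throughout. Plastomes are circular; an
interval whose ``end`` exceeds the sequence length denotes an origin-spanning
feature and is interpreted modulo the genome length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: gene feature categories
CATEGORIES = ("protein_coding", "tRNA", "rRNA", "intron", "other")

#: the 11 plastid NADH-dehydrogenase-like subunit genes
NDH_GENES = (
    "ndhA", "ndhB", "ndhC", "ndhD", "ndhE", "ndhF",
    "ndhG", "ndhH", "ndhI", "ndhJ", "ndhK",
)


def revcomp(seq: str) -> str:
    """Reverse complement over the closed alphabet {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_sequence(seq: str) -> str:
    """Uppercase and map IUPAC ambiguity codes other than N to N."""
    seq = seq.upper().replace("U", "T")
    if any(c not in "ACGTN" for c in set(seq)):
        bad = sorted(set(seq) - set("ACGTN"))
        warnings.warn(
            f"ambiguity characters {bad} mapped to N", stacklevel=2
        )
        seq = "".join(c if c in "ACGTN" else "N" for c in seq)
    return seq


def circular_slice(seq: str, start: int, end: int) -> str:
    """Extract ``seq[start:end]`` on a circular sequence; ``end`` may exceed
    ``len(seq)`` (wrap-around) and ``start`` is taken modulo the length."""
    n = len(seq)
    start %= n
    span = end - start if end >= start else end + n - start
    if span <= n and start + span <= n:
        return seq[start : start + span]
    return (seq + seq)[start : start + span]


@dataclass
class GeneFeature:
    """A gene-level annotation: exon segments in transcription order."""

    name: str
    category: str
    strand: str  # '+' or '-'
    segments: list[tuple[int, int]]
    pseudogene: bool = False

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.segments:
            raise ValueError("segments must be non-empty")

    @property
    def start(self) -> int:
        return min(s for s, _ in self.segments)

    @property
    def end(self) -> int:
        return max(e for _, e in self.segments)

    @property
    def total_length(self) -> int:
        return sum(e - s for s, e in self.segments)

    def five_prime(self) -> int:
        """Coordinate of the 5' end (first transcribed base)."""
        if self.strand == "+":
            return min(s for s, _ in self.segments)
        return max(e for _, e in self.segments) - 1

    def spliced_sequence(self, genome: str) -> str:
        """Concatenated exon sequence, reverse-complemented for '-' strand."""
        parts = sorted(self.segments)
        seq = "".join(circular_slice(genome, s, e) for s, e in parts)
        return revcomp(seq) if self.strand == "-" else seq


@dataclass
class AnnotatedPlastome:
    identifier: str
    sequence: str
    features: list[GeneFeature] = field(default_factory=list)
    circular: bool = True

    def __post_init__(self) -> None:
        self.sequence = normalize_sequence(self.sequence)
        if not self.sequence:
            raise ValueError(f"{self.identifier}: empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def genes(self, category: Optional[str] = None,
              include_pseudo: bool = True) -> list[GeneFeature]:
        out = []
        for f in self.features:
            if category is not None and f.category != category:
                continue
            if not include_pseudo and f.pseudogene:
                continue
            out.append(f)
        return out

    def find_gene(self, name: str) -> Optional[GeneFeature]:
        for f in self.features:
            if f.name == name:
                return f
        return None


@dataclass
class RegionPartition:
    """Quadripartite partition in canonical coordinates.

    Canonical linearization order is LSC -> IRb -> SSC -> IRa with the LSC
    starting at coordinate 0. ``j_sb`` (IRb/SSC) and ``j_sa`` (SSC/IRa) are
    the SSC's two endpoints.
    """

    lsc: tuple[int, int]
    irb: tuple[int, int]
    ssc: tuple[int, int]
    ira: tuple[int, int]

    @property
    def lsc_length(self) -> int:
        return self.lsc[1] - self.lsc[0]

    @property
    def ssc_length(self) -> int:
        return self.ssc[1] - self.ssc[0]

    @property
    def ir_length(self) -> int:
        return self.irb[1] - self.irb[0]

    @property
    def j_sb(self) -> int:
        """Junction IRb/SSC (= SSC start)."""
        return self.ssc[0]

    @property
    def j_sa(self) -> int:
        """Junction SSC/IRa (= SSC end)."""
        return self.ssc[1]

    @property
    def genome_length(self) -> int:
        return self.lsc_length + self.ssc_length + 2 * self.ir_length

    def region_of(self, pos: int) -> str:
        n = self.genome_length
        for name, (s, e) in (("LSC", self.lsc), ("IRb", self.irb),
                             ("SSC", self.ssc), ("IRa", self.ira)):
            if (pos - s) % n < e - s:
                return name
        raise ValueError(f"position {pos} outside genome")

    def validate(self, genome_length: int) -> None:
        if self.genome_length != genome_length:
            raise ValueError(
                f"region lengths sum to {self.genome_length}, "
                f"genome is {genome_length} bp"
            )
        order = [self.lsc, self.irb, self.ssc, self.ira]
        if [s for s, _ in order] != sorted(s for s, _ in order):
            raise ValueError("regions out of canonical order")


@dataclass
class SSRLocus:
    """A perfect tandem microsatellite run (unit 1-6 bp)."""

    motif: str
    unit_count: int
    span: tuple[int, int]
    context: Optional[str] = None  # coding | non_coding | spanning

    @property
    def unit_size(self) -> int:
        return len(self.motif)

    @property
    def length(self) -> int:
        return self.span[1] - self.span[0]


@dataclass
class RepeatHit:
    """A dispersed repeat pair: forward, palindromic or reverse."""

    kind: str  # forward | palindromic | reverse
    span1: tuple[int, int]
    span2: tuple[int, int]
    length: int
    mismatches: int
    context1: Optional[str] = None
    context2: Optional[str] = None

    @property
    def identity(self) -> float:
        return 100.0 * (1.0 - self.mismatches / self.length)

    @property
    def context(self) -> Optional[str]:
        """Joint context: a class only if both copies share it, else spanning."""
        if self.context1 is None or self.context2 is None:
            return None
        if self.context1 == self.context2:
            return self.context1
        return "spanning"


@dataclass
class SyntenicLocus:
    """A locus paired between two plastomes, optionally aligned."""

    name: str
    locus_class: str  # coding | spacer | intron
    seq1: str
    seq2: str
    region: Optional[str] = None  # LSC | SSC | IR
    aln1: Optional[str] = None
    aln2: Optional[str] = None
    flagged: bool = False  # e.g. coding locus with broken frame

    def is_aligned(self) -> bool:
        return self.aln1 is not None and self.aln2 is not None


@dataclass
class DivergenceRecord:
    name: str
    locus_class: str
    conserved_sites: int
    substitutions: int
    indel_events: int
    sv_percent: float
    gc_percent: float
    region: Optional[str] = None


@dataclass
class DnDsRecord:
    """Nei-Gojobori pairwise estimates for one gene (or a concatenation)."""

    gene: str
    n_codons: int
    n_sites: float
    s_sites: float
    nd: float
    sd: float
    pn: float
    ps: float
    dn: Optional[float]
    ds: Optional[float]
    omega: Optional[float]
    saturated: bool = False


@dataclass
class JunctionProfile:
    plastome_id: str
    j_sa: int
    j_sb: int
    ycf1_to_jsa: Optional[int]
    ndh_status: dict[str, str]  # gene -> intact | pseudogene | absent
    retained_ndh_length: int
    type_label: Optional[str] = None

    @property
    def n_intact_ndh(self) -> int:
        return sum(1 for v in self.ndh_status.values() if v == "intact")


@dataclass
class OriginFit:
    """Least-squares fit of y = slope * x through the origin."""

    slope: float
    r_squared: float
    n: int
    p_value: Optional[float] = None


__all__ = [
    "AnnotatedPlastome", "GeneFeature", "RegionPartition", "SSRLocus",
    "RepeatHit", "SyntenicLocus", "DivergenceRecord", "DnDsRecord",
    "JunctionProfile", "OriginFit", "NDH_GENES", "CATEGORIES",
    "revcomp", "circular_slice", "normalize_sequence", "replace",
]
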