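"""GenBank/FASTA input, GenBank output, and tabular report writing.

Reading goes through Biopython's SeqIO; GenBank 1-based inclusive coordinates
are converted to the internal 0-based half-open convention at this boundary.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Any, Iterable, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .model import AnnotatedPlastome, GeneFeature, normalize_sequence

_CATEGORY_BY_TYPE = {"CDS": "protein_coding", "tRNA": "tRNA", "rRNA": "rRNA"}
_TYPE_BY_CATEGORY = {v: k for k, v in _CATEGORY_BY_TYPE.items()}
_STOPS = {"TAA", "TAG", "TGA"}


class PlastomeParseError(ValueError):
    pass


def _feature_name(feat) -> Optional[str]:
    for key in ("gene", "locus_tag", "product"):
        if key in feat.qualifiers:
            return feat.qualifiers[key][0]
    return None


def _category_from_name(name: str) -> str:
    low = name.lower()
    if low.startswith("trn"):
        return "tRNA"
    if low.startswith("rrn"):
        return "rRNA"
    return "protein_coding"


def _segments_from_location(loc, genome_length: int,
                            circular: bool) -> tuple[list[tuple[int, int]], str]:
    strand = "-" if loc.strand == -1 else "+"
    segs = sorted((int(p.start), int(p.end)) for p in loc.parts)
    # merge an origin-split part pair back into one modular segment
    if circular and len(segs) >= 2 and segs[0][0] == 0 and segs[-1][1] == genome_length:
        first, last = segs[0], segs[-1]
        segs = segs[1:-1] + [(last[0], genome_length + first[1])]
        segs.sort()
    return segs, strand


def _has_internal_stop(cds: str) -> bool:
    return any(cds[i:i + 3] in _STOPS for i in range(0, len(cds) - 3, 3))


def read_plastome(path: str | Path, infer_pseudogenes: bool = False) -> AnnotatedPlastome:
    """Read a single-record GenBank file into an :class:`AnnotatedPlastome`.

    gene/CDS/tRNA/rRNA features become :class:`GeneFeature` entries; IR-copy
    duplicates are preserved as distinct features. A feature is flagged as a
    pseudogene when the record carries a ``/pseudo`` qualifier, or — with
    ``infer_pseudogenes=True`` — when its CDS length is not a multiple of 3
    or contains an internal stop codon.
    """
    path = Path(path)
    try:
        record = SeqIO.read(str(path), "genbank")
    except Exception as exc:  # Biopython raises bare ValueError on bad input
        raise PlastomeParseError(f"{path}: cannot parse GenBank record: {exc}") from exc
    try:
        seq = str(record.seq)
    except Exception as exc:
        raise PlastomeParseError(f"{path}: record has no sequence") from exc
    if not seq:
        raise PlastomeParseError(f"{path}: record has an empty sequence")
    circular = record.annotations.get("topology", "circular") == "circular"
    n = len(seq)

    features: list[GeneFeature] = []
    primary_keys: set[tuple[str, int]] = set()
    for feat in record.features:
        if feat.type not in _CATEGORY_BY_TYPE:
            continue
        name = _feature_name(feat)
        if name is None:
            continue
        segs, strand = _segments_from_location(feat.location, n, circular)
        pseudo = "pseudo" in feat.qualifiers or "pseudogene" in feat.qualifiers
        category = _CATEGORY_BY_TYPE[feat.type]
        if infer_pseudogenes and category == "protein_coding" and not pseudo:
            total = sum(e - s for s, e in segs)
            cds = "".join(
                seq[s % n:e] if e <= n else (seq + seq)[s:e] for s, e in sorted(segs)
            )
            if strand == "-":
                from .model import revcomp
                cds = revcomp(cds)
            pseudo = total % 3 != 0 or _has_internal_stop(cds)
        features.append(GeneFeature(name, category, strand, segs, pseudo))
        primary_keys.add((name, min(s for s, _ in segs)))

    # gene-only features (typically pseudogenes lacking a CDS child)
    for feat in record.features:
        if feat.type != "gene":
            continue
        name = _feature_name(feat)
        if name is None:
            continue
        segs, strand = _segments_from_location(feat.location, n, circular)
        key = (name, min(s for s, _ in segs))
        if any(abs(key[1] - s) <= 5 and key[0] == nm for nm, s in primary_keys):
            continue
        pseudo = "pseudo" in feat.qualifiers or "pseudogene" in feat.qualifiers
        features.append(
            GeneFeature(name, _category_from_name(name), strand, segs, pseudo)
        )

    features.sort(key=lambda f: (f.start, f.name))
    return AnnotatedPlastome(record.id or path.stem, seq, features, circular)


def read_fasta(path: str | Path) -> AnnotatedPlastome:
    """Read a single unannotated sequence from FASTA."""
    record = SeqIO.read(str(path), "fasta")
    return AnnotatedPlastome(record.id, str(record.seq), [], True)


def write_genbank(p: AnnotatedPlastome, path: str | Path) -> None:
    """Emit an annotated plastome as a single-record GenBank flat file."""
    n = p.length
    record = SeqRecord(
        Seq(p.sequence),
        id=p.identifier[:16],
        name=p.identifier[:16].replace(" ", "_"),
        description=f"{p.identifier} plastome",
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if p.circular else "linear",
        },
    )
    for f in p.features:
        strand = -1 if f.strand == "-" else 1
        locs = []
        for s, e in sorted(f.segments):
            if e <= n:
                locs.append(SimpleLocation(s, e, strand=strand))
            else:  # origin-spanning: split back into two GenBank parts
                locs.append(SimpleLocation(s, n, strand=strand))
                locs.append(SimpleLocation(0, e - n, strand=strand))
        loc = locs[0] if len(locs) == 1 else CompoundLocation(locs)
        quals: dict[str, list[str]] = {"gene": [f.name]}
        if f.pseudogene:
            quals["pseudo"] = [""]
        record.features.append(SeqFeature(loc, type="gene", qualifiers=dict(quals)))
        ftype = _TYPE_BY_CATEGORY.get(f.category, "misc_feature")
        if not f.pseudogene or ftype != "CDS":
            record.features.append(SeqFeature(loc, type=ftype, qualifiers=dict(quals)))
    SeqIO.write(record, str(path), "genbank")


def count_unique_genes(p: AnnotatedPlastome) -> dict[str, Any]:
    """Distinct gene names per category, IR duplicates counted once.

    Pseudogenes are excluded from the functional counts and listed
    separately. Trans-spliced genes annotated in pieces (rps12) share a name
    and therefore count once.
    """
    if not p.features:
        raise ValueError(f"{p.identifier}: no features to count")
    by_cat: dict[str, set[str]] = {}
    pseudo: set[str] = set()
    for f in p.features:
        if f.pseudogene:
            pseudo.add(f.name)
        else:
            by_cat.setdefault(f.category, set()).add(f.name)
    out: dict[str, Any] = {cat: len(names) for cat, names in sorted(by_cat.items())}
    out["pseudogenes"] = sorted(pseudo)
    return out


def _to_rows(records: Iterable[Any]) -> list[dict[str, Any]]:
    rows = []
    for r in records:
        if dataclasses.is_dataclass(r) and not isinstance(r, type):
            rows.append(dataclasses.asdict(r))
        elif isinstance(r, dict):
            rows.append(dict(r))
        else:
            raise TypeError(f"cannot tabulate record of type {type(r)}")
    return rows


def write_report(records: Iterable[Any] | pd.DataFrame, path: str | Path,
                 format: str = "tsv") -> None:
    """Write a homogeneous record table as TSV or JSON, sorted by the first
    column for deterministic output."""
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        rows = _to_rows(records)
        df = pd.DataFrame(rows)
    if len(df.columns) and len(df):
        df = df.sort_values(list(df.columns)[0], kind="mergesort")
    if format == "tsv":
        df.to_csv(path, sep="\t", index=False)
    elif format == "json":
        with open(path, "w") as fh:
            json.dump(df.to_dict(orient="records"), fh, indent=1, default=str)
            fh.write("\n")
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_report(path: str | Path, format: str = "tsv") -> list[dict[str, Any]]:
    if format == "tsv":
        df = pd.read_csv(path, sep="\t")
        return df.to_dict(orient="records")
    if format == "json":
        with open(path) as fh:
            return json.load(fh)
    raise ValueError(f"unknown report format {format!r}")
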