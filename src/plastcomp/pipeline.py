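"""End-to-end orchestration: structure -> ssr -> repeats -> divergence ->
dnds -> junctions over one plastome or a pair, with a flat, validated
configuration and deterministic outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import divergence as dv
from . import dnds as dn
from . import io as pio
from . import junctions as jn
from . import repeats as rp
from . import ssr as sr
from . import structure as st

__version__ = "0.1.0"

log = logging.getLogger("plastcomp")


@dataclass
class RunConfig:
    """Flat pipeline configuration; unknown keys in a config file are
    errors, not warnings."""

    genbank1: str = ""
    genbank2: Optional[str] = None
    out_dir: str = "plastcomp-out"
    min_ir_len: int = 1000
    max_mismatch_rate: float = 0.001
    ssr_mono: int = 8
    ssr_di: int = 5
    ssr_multi: int = 3
    repeat_min_len: int = 30
    repeat_max_hamming: int = 3
    repeat_min_identity: float = 90.0
    min_noncoding_len: int = 150
    top_hotspots: int = 10
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _analyze_single(p, cfg: RunConfig):
    part = st.detect_inverted_repeat(p, cfg.min_ir_len, cfg.max_mismatch_rate)
    p, part = st.canonicalize(p, part)
    return p, part


def run_all(cfg: RunConfig) -> dict:
    """Run every stage and write one report per module plus a combined
    summary JSON. Reruns with the same config reproduce identical files."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"version": __version__, "config": cfg.to_dict()}

    genomes = []
    for path in filter(None, (cfg.genbank1, cfg.genbank2)):
        if not Path(path).exists():
            raise FileNotFoundError(f"input file not found: {path}")
        genomes.append(pio.read_plastome(path))

    thresholds = sr.expand_thresholds(cfg.ssr_mono, cfg.ssr_di, cfg.ssr_multi)
    structure_rows, ssr_rows, repeat_rows, junction_rows = [], [], [], []
    canon = []
    for p in genomes:
        log.info("structure: %s", p.identifier)
        p, part = _analyze_single(p, cfg)
        canon.append((p, part))
        structure_rows.append(st.structure_summary(p, part))

        loci = sr.classify_context(sr.find_ssrs(p, thresholds), p)
        ssum = sr.ssr_summary(loci)
        ssr_rows.append({"plastome": p.identifier, **ssum["by_class"],
                         "total": ssum["total"]})

        hits = rp.find_repeats(p, cfg.repeat_min_len, cfg.repeat_max_hamming,
                               min_identity=cfg.repeat_min_identity, part=part)
        rp.classify_hit_contexts(hits, p)
        bins = rp.bin_by_length(hits)
        repeat_rows.append({
            "plastome": p.identifier,
            "forward": sum(h.kind == "forward" for h in hits),
            "palindromic": sum(h.kind == "palindromic" for h in hits),
            "reverse": sum(h.kind == "reverse" for h in hits),
            "total": len(hits), **bins,
        })

        prof = jn.profile_junctions(p, part)
        jn.classify_type(prof)
        junction_rows.append({
            "plastome": p.identifier, "type": prof.type_label,
            "j_sb": prof.j_sb, "j_sa": prof.j_sa,
            "ycf1_to_jsa": prof.ycf1_to_jsa,
            "retained_ndh_bp": prof.retained_ndh_length,
            "n_intact_ndh": prof.n_intact_ndh,
        })

    pio.write_report(structure_rows, out / "structure.tsv")
    pio.write_report(ssr_rows, out / "ssr_summary.tsv")
    pio.write_report(repeat_rows, out / "repeats_summary.tsv")
    pio.write_report(junction_rows, out / "junctions.tsv")
    summary["structure"] = structure_rows
    summary["ssr"] = ssr_rows
    summary["repeats"] = repeat_rows
    summary["junctions"] = junction_rows

    if len(canon) == 2:
        (p1, part1), (p2, part2) = canon
        log.info("divergence: %s vs %s", p1.identifier, p2.identifier)
        loci = dv.extract_syntenic_loci(p1, p2, part1, part2,
                                        cfg.min_noncoding_len)
        records = dv.divergence_table(loci)
        pio.write_report(records, out / "divergence.tsv")
        hotspots = dv.rank_hotspots(records, cfg.top_hotspots)
        pio.write_report(hotspots, out / "hotspots.tsv")
        stats = dv.divergence_statistics(records)
        with open(out / "divergence_stats.json", "w") as fh:
            json.dump(stats, fh, indent=1)
            fh.write("\n")
        summary["divergence"] = {
            "n_loci": len(records),
            "hotspots": [h.name for h in hotspots],
            "statistics": stats,
        }

        rates = dn.dnds_table(loci)
        pio.write_report(rates, out / "dnds.tsv")
        try:
            concat = dn.concatenate_and_rate(loci)
            summary["dnds_concatenated"] = dataclasses.asdict(concat)
        except ValueError as exc:
            summary["dnds_concatenated"] = {"error": str(exc)}

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, default=str)
        fh.write("\n")
    return summary
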