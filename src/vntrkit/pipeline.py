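"""End-to-end orchestration: locus characterization, cohort genotyping, and
two-species comparison reports.

``characterize_locus`` chains the full single-locus analysis: periodicity
detection -> array location -> unit decomposition -> consensus composition ->
restriction digest -> copy-number call -> cassette census.  The report is a
plain JSON-serializable structure with a provenance block recording every
parameter, so a run can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Any

import pandas as pd

from . import __version__, arraydetect, composition, conservation, gel
from .synthetic import DEFAULT_CASSETTES

DEFAULT_CONFIG: dict[str, Any] = {
    "k": 16,
    "min_period": 500,
    "max_period": 50000,
    "min_support": None,        # None -> collision-scaled default
    "band": 200,                # alignment band for unit identity
    "enzyme": "XbaI",
    "unit_bp": gel.DEFAULT_UNIT_BP,
    "flank_bp": 0,
    "cgi_min_len": 200,
    "cgi_min_gc": 0.5,
    "cgi_min_oe": 0.6,
    "cassette_max_mm": 2,
    "island_k": 11,
    "island_xdrop": 12,
    "island_min_len": 20,
    "island_min_identity": 0.85,
}


@dataclass
class LocusReport:
    """Aggregated results of a single-locus characterization run."""

    array: dict[str, Any] | None = None
    decomposition: dict[str, Any] | None = None
    composition: dict[str, Any] | None = None
    digest: dict[str, Any] | None = None
    copy_number: dict[str, Any] | None = None
    cassettes: dict[str, Any] | None = None
    provenance: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "LocusReport":
        return cls(**json.loads(text))


def read_fasta(path) -> dict[str, str]:
    """All records of a FASTA file as an ordered name -> sequence mapping."""
    from Bio import SeqIO

    try:
        records = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}
    except (OSError, ValueError) as exc:
        raise IOError(f"cannot read FASTA {path}: {exc}") from exc
    if not records:
        raise IOError(f"no FASTA records in {path}")
    return records


def read_bed(path) -> list[tuple[int, int, str, str]]:
    """BED intervals as (start, end, name, strand); strand defaults to '+'."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise IOError(f"{path}: line {lineno}: fewer than 3 BED fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise IOError(f"{path}: line {lineno}: bad coordinates") from exc
            name = fields[3] if len(fields) > 3 else "."
            strand = fields[5] if len(fields) > 5 else "+"
            out.append((start, end, name, strand))
    return out


def characterize_locus(fasta_path, annotations_path=None,
                       config: dict[str, Any] | None = None) -> LocusReport:
    """Run the full locus characterization pipeline on a FASTA sequence.

    The first FASTA record is analysed.  When an annotation BED is supplied,
    its class coverage over the detected array span is reported as well.
    """
    cfg = dict(DEFAULT_CONFIG)
    if config:
        cfg.update(config)
    seq = next(iter(read_fasta(fasta_path).values()))
    annotations = read_bed(annotations_path) if annotations_path else None

    report = LocusReport(provenance={
        "tool": "vntrkit", "version": __version__,
        "fasta": str(fasta_path),
        "annotations": str(annotations_path) if annotations_path else None,
        "config": {k: v for k, v in cfg.items()},
        "sequence_length": len(seq),
    })

    spectrum = arraydetect.offset_spectrum(
        seq, k=cfg["k"], min_period=cfg["min_period"], max_period=cfg["max_period"])
    unit = arraydetect.estimate_unit_length(spectrum, min_support=cfg["min_support"])
    if unit is None:
        report.array = {"detected": False}
        return report
    call = arraydetect.locate_array(seq, unit, k=cfg["k"])
    if call is None:
        report.array = {"detected": False, "unit_length": unit}
        return report
    report.array = {
        "detected": True, "start": call.start, "end": call.end,
        "unit_length": call.unit_length, "phase": call.phase,
        "copy_estimate": call.copy_estimate,
    }

    dec = arraydetect.decompose_array(seq, call, band=cfg["band"])
    report.decomposition = {
        "n_units": dec.n_units,
        "unit_intervals": dec.unit_intervals,
        "mean_offdiagonal_identity": dec.mean_offdiagonal_identity(),
    }

    comp = composition.composition_report(
        dec.consensus,
        min_len=cfg["cgi_min_len"], min_gc=cfg["cgi_min_gc"],
        min_oe=cfg["cgi_min_oe"])
    report.composition = {
        "unit_gc_fraction": comp.gc_fraction,
        "unit_cpg_count": comp.cpg_count,
        "unit_cpg_obs_exp": comp.cpg_obs_exp,
        "unit_cgi_intervals": comp.cgi_intervals,
        "locus_gc_fraction": composition.gc_fraction(seq),
    }
    if annotations:
        enr = composition.class_enrichment(
            (call.start, call.end),
            [(s, e, lab) for s, e, lab, _ in annotations],
            (0, len(seq)))
        report.composition["array_class_coverage"] = enr.class_coverage

    enzyme = gel.BUILTIN_ENZYMES[cfg["enzyme"]] if isinstance(cfg["enzyme"], str) \
        else cfg["enzyme"]
    frags = gel.digest(seq, enzyme)
    sizes = sorted((e - s for s, e in frags), reverse=True)
    report.digest = {
        "enzyme": enzyme.name, "n_fragments": len(frags),
        "fragment_sizes": sizes[:10], "largest_fragment": sizes[0],
    }
    report.copy_number = {
        "fragment_bp": sizes[0],
        "unit_bp": cfg["unit_bp"], "flank_bp": cfg["flank_bp"],
        "copies": gel.call_copies(sizes[0], cfg["unit_bp"], cfg["flank_bp"]),
        "copies_at_detected_unit": gel.call_copies(sizes[0], call.unit_length, 0),
    }

    library = cfg.get("cassette_library") or DEFAULT_CASSETTES
    census = {}
    for name, cseq in library.items():
        hits = conservation.scan_motif(dec.consensus, cseq,
                                       max_mm=cfg["cassette_max_mm"])
        census[name] = len(hits)
    report.cassettes = {
        "per_unit": census,
        "cassettes_per_unit": int(sum(census.values())),
    }
    return report


def genotype_cohort(band_table_path, unit_bp: float = gel.DEFAULT_UNIT_BP,
                    flank_bp: float = 0) -> pd.DataFrame:
    """Copy-number calls for every band in a cohort table (sizes in kb).

    Returns one row per band: member_id, band_kb, fragment_bp, copies, and
    the member's allele count.
    """
    rows = []
    for member, bands in gel.read_band_table(band_table_path, size_unit="kb"):
        for b in bands:
            rows.append({
                "member_id": member,
                "band_kb": b / 1000.0,
                "fragment_bp": b,
                "copies": gel.call_copies(b, unit_bp, flank_bp),
                "n_alleles": len(bands),
            })
    return pd.DataFrame(rows, columns=["member_id", "band_kb", "fragment_bp",
                                       "copies", "n_alleles"])


def compare_species(fasta_a, fasta_b,
                    config: dict[str, Any] | None = None) -> dict[str, Any]:
    """Conserved-island report between two repeat-unit FASTA sequences."""
    cfg = dict(DEFAULT_CONFIG)
    if config:
        cfg.update(config)
    a = next(iter(read_fasta(fasta_a).values()))
    b = next(iter(read_fasta(fasta_b).values()))
    islands = conservation.find_conserved_islands(
        a, b, k=cfg["island_k"], xdrop=cfg["island_xdrop"],
        min_len=cfg["island_min_len"], min_identity=cfg["island_min_identity"])
    return {
        "n_islands": len(islands),
        "islands": [dataclasses.asdict(i) for i in islands],
        "provenance": {
            "tool": "vntrkit", "version": __version__,
            "fasta_a": str(fasta_a), "fasta_b": str(fasta_b),
            "config": {k: cfg[k] for k in
                       ("island_k", "island_xdrop", "island_min_len",
                        "island_min_identity")},
        },
    }
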