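"""Readers and writers for the standard interchange formats.

FASTA in/out goes through Biopython.  BED is the interchange format between
pipeline stages (0-based half-open, matching the internal convention):
occurrences as BED6 plus a seventh column with the matched bases, dimers as
BED6 plus the member-motif coordinates, clusters as BED12 whose blocks are
the merged member intervals.  Motif sets are 3-column TSV (name, tf,
pattern; shorthand alternatives such as TGCAA/T allowed), composite grammars
are YAML, regulation labels are 2-column TSV.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .composites import ClusterCall, DimerOccurrence, DimerPattern
from .enrichment import EnrichmentResult
from .motifs import CoreMotif, MotifOccurrence, compile_motif

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_motif_table",
    "write_motif_table",
    "read_grammar",
    "read_labels",
    "occurrences_to_bed",
    "read_occurrences_bed",
    "dimers_to_bed",
    "read_dimers_bed",
    "clusters_to_bed",
    "write_architecture_table",
    "write_enrichment_report",
]


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """(record id, sequence) pairs; duplicate ids are rejected by name."""
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        records.append((rec.id, str(rec.seq).upper()))
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    seq_records = [
        SeqRecord(Seq(seq), id=sid, description="") for sid, seq in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def read_motif_table(path: str | Path) -> list[CoreMotif]:
    """Tab-separated motif set: name, tf, pattern.  '#' lines are comments."""
    motifs: list[CoreMotif] = []
    names: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 3 tab-separated fields, got {len(fields)}"
                )
            name, tf, pattern = fields
            if name in names:
                raise ValueError(f"{path}:{lineno}: duplicate motif name {name!r}")
            names.add(name)
            motifs.append(compile_motif(name, tf, pattern))
    return motifs


def write_motif_table(motifs: Sequence[CoreMotif], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# name\ttf\tpattern\n")
        for m in motifs:
            fh.write(f"{m.name}\t{m.tf}\t{m.pattern}\n")


def read_grammar(path: str | Path) -> tuple[list[DimerPattern], dict]:
    """Composite grammar YAML: dimer patterns plus cluster parameters.

    Expected shape::

        dimers:
          - {name: Onecut_HoxCut, first: Hox, second: Cut,
             gap_min: 2, gap_max: 6, orientation: any}
        clusters:
          min_members: 2
          max_span: 150
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    patterns = []
    for i, entry in enumerate(doc.get("dimers", [])):
        try:
            patterns.append(
                DimerPattern(
                    name=entry["name"],
                    first_motif=entry["first"],
                    second_motif=entry["second"],
                    gap_min=int(entry["gap_min"]),
                    gap_max=int(entry["gap_max"]),
                    orientation_policy=entry.get("orientation", "any"),
                )
            )
        except KeyError as exc:
            raise ValueError(f"{path}: dimer entry {i}: missing key {exc}") from exc
    cluster_params = {"min_members": 2, "max_span": 150}
    cluster_params.update(doc.get("clusters", {}) or {})
    return patterns, cluster_params


def read_labels(path: str | Path) -> dict[str, str]:
    """2-column TSV (gene id, regulated|non_regulated) -> mapping."""
    labels: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 tab-separated fields, got {len(fields)}"
                )
            gene, label = fields
            if label not in ("regulated", "non_regulated"):
                raise ValueError(
                    f"{path}:{lineno}: label must be regulated|non_regulated, got {label!r}"
                )
            if gene in labels:
                raise ValueError(f"{path}:{lineno}: duplicate gene id {gene!r}")
            labels[gene] = label
    return labels


# ---------------------------------------------------------------------------
# BED interchange
# ---------------------------------------------------------------------------

def occurrences_to_bed(
    occurrences: Sequence[MotifOccurrence], path: str | Path
) -> None:
    """BED6 (+ matched bases as column 7)."""
    with open(path, "w") as fh:
        for o in occurrences:
            fh.write(
                f"{o.seq_id}\t{o.start}\t{o.end}\t{o.motif_name}\t0\t{o.strand}"
                f"\t{o.matched or '.'}\n"
            )


def read_occurrences_bed(path: str | Path) -> list[MotifOccurrence]:
    out: list[MotifOccurrence] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: need >= 6 BED columns")
            matched = fields[6] if len(fields) > 6 and fields[6] != "." else None
            out.append(
                MotifOccurrence(
                    motif_name=fields[3],
                    seq_id=fields[0],
                    start=int(fields[1]),
                    end=int(fields[2]),
                    strand=fields[5],
                    matched=matched,
                )
            )
    return out


def dimers_to_bed(dimers: Sequence[DimerOccurrence], path: str | Path) -> None:
    """BED6 over the dimer span, plus gap and both member coordinates."""
    with open(path, "w") as fh:
        for d in dimers:
            extra = "\t".join(
                str(x)
                for x in (
                    d.gap,
                    d.first.motif_name,
                    d.first.start,
                    d.first.end,
                    d.first.strand,
                    d.second.motif_name,
                    d.second.start,
                    d.second.end,
                    d.second.strand,
                )
            )
            fh.write(
                f"{d.seq_id}\t{d.start}\t{d.end}\t{d.pattern_name}\t0\t.\t{extra}\n"
            )


def read_dimers_bed(path: str | Path) -> list[DimerOccurrence]:
    out: list[DimerOccurrence] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 15:
                raise ValueError(f"{path}:{lineno}: need 15 dimer BED columns")
            first = MotifOccurrence(f[7], f[0], int(f[8]), int(f[9]), f[10])
            second = MotifOccurrence(f[11], f[0], int(f[12]), int(f[13]), f[14])
            out.append(DimerOccurrence(f[3], first, second, int(f[6])))
    return out


def _merged_blocks(cluster: ClusterCall) -> list[tuple[int, int]]:
    intervals = sorted(
        [(occ.start, occ.end) for d in cluster.members for occ in (d.first, d.second)]
    )
    merged = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def clusters_to_bed(clusters: Sequence[ClusterCall], path: str | Path) -> None:
    """BED12; blocks are the merged member-motif intervals, plus n_members."""
    with open(path, "w") as fh:
        for i, c in enumerate(clusters):
            blocks = _merged_blocks(c)
            sizes = ",".join(str(e - s) for s, e in blocks)
            starts = ",".join(str(s - c.start) for s, _ in blocks)
            name = f"cluster_{i + 1}"
            fh.write(
                f"{c.seq_id}\t{c.start}\t{c.end}\t{name}\t0\t.\t{c.start}\t{c.end}"
                f"\t0\t{len(blocks)}\t{sizes}\t{starts}\t{c.n_members}\n"
            )


def write_architecture_table(
    rows: Sequence[tuple[str, str]], path: str | Path
) -> None:
    """Tab-separated (seq_id, architecture string) table."""
    with open(path, "w") as fh:
        fh.write("seq_id\tarchitecture\n")
        for sid, arch in rows:
            fh.write(f"{sid}\t{arch}\n")


def write_enrichment_report(
    results: Sequence[EnrichmentResult], tsv_path: str | Path, json_path: str | Path
) -> None:
    """Human-readable TSV plus a machine-readable JSON of the same results."""
    rows = []
    for r in results:
        rows.append(
            {
                "pattern": r.pattern_name,
                "f_regulated": r.f_reg,
                "f_non_regulated": r.f_non,
                "fold_enrichment": r.fold,
                "present_reg": r.counts[0][0],
                "present_non": r.counts[0][1],
                "n_reg": r.n_reg,
                "n_non": r.n_non,
                "p_exact_two_sided": r.p_exact,
            }
        )
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)
    with open(json_path, "w") as fh:
        json.dump(rows, fh, indent=2, default=float)
        fh.write("\n")
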