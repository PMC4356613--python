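"""The scan -> dimers -> clusters -> architectures -> enrichment pipeline.

One call (or the ``motifarch run`` command) ties the stages together on a
multi-record FASTA of upstream regions, writing each stage's output under a
common prefix together with a manifest that echoes the resolved
configuration, so a run can be reproduced byte for byte from (inputs, config,
seed).
"""
from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from .composites import (
    DimerPattern,
    architecture_string,
    call_clusters,
    detect_overlaps,
    find_dimers,
)
from .enrichment import EnrichmentResult, enrichment_test, presence_table
from .io import (
    clusters_to_bed,
    dimers_to_bed,
    occurrences_to_bed,
    read_fasta,
    read_grammar,
    read_labels,
    read_motif_table,
    write_architecture_table,
    write_enrichment_report,
)
from .motifs import BOTH_STRANDS, default_motif_set, scan_cores

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration for one pipeline run."""

    motifs_path: str | None = None  # None -> documented default motif set
    grammar_path: str | None = None  # None -> Onecut + Pdm3 default grammar
    strands: tuple[str, ...] = BOTH_STRANDS
    min_members: int = 2
    max_span: int = 150
    labels_path: str | None = None
    seed: int = 0
    out_prefix: str = "motifarch_run"


@dataclass
class PipelineResult:
    occurrences: dict
    dimers: dict
    clusters: dict
    architectures: list[tuple[str, str]]
    enrichment: list[EnrichmentResult] = field(default_factory=list)
    manifest: dict = field(default_factory=dict)


def _default_grammar() -> list[DimerPattern]:
    return [
        DimerPattern("Onecut_HoxCut", "Hox", "Cut", 2, 6),
        DimerPattern("Pdm3_HoxPou", "PdmHox", "Pou", 2, 3),
        DimerPattern("Acj6_HoxPou", "Hox", "Pou", 0, 12),
    ]


def run_pipeline(config: RunConfig, fasta: str | Path) -> PipelineResult:
    """Run every stage on the FASTA and write the result bundle.

    Outputs (all under ``config.out_prefix``): ``.occurrences.bed``,
    ``.dimers.bed``, ``.clusters.bed``, ``.architectures.tsv``, optionally
    ``.enrichment.tsv``/``.json``, and ``.manifest.json``.  Empty stages write
    empty files rather than failing.
    """
    for label, p in (
        ("motif table", config.motifs_path),
        ("grammar", config.grammar_path),
        ("labels", config.labels_path),
    ):
        if p is not None and not Path(p).exists():
            raise FileNotFoundError(f"{label} file does not exist: {p}")

    motifs = (
        read_motif_table(config.motifs_path)
        if config.motifs_path
        else default_motif_set()
    )
    if config.grammar_path:
        patterns, cluster_params = read_grammar(config.grammar_path)
    else:
        patterns = _default_grammar()
        cluster_params = {
            "min_members": config.min_members,
            "max_span": config.max_span,
        }

    records = read_fasta(fasta)
    all_occ: dict[str, list] = {}
    all_dimers: dict[str, list] = {}
    all_clusters: dict[str, list] = {}
    arch_rows: list[tuple[str, str]] = []

    motif_names = {m.name for m in motifs}
    for sid, seq in records:
        occ = scan_cores(sid, seq, motifs, strands=config.strands)
        all_occ[sid] = occ
        dimers = []
        # absent partners are routine when scanning many grammars over many
        # regions; the per-call warning is for interactive single-region use
        with warnings.catch_warnings():
            warnings.filterwarnings(
                "ignore", message="dimer pattern", category=UserWarning
            )
            for pattern in patterns:
                if {pattern.first_motif, pattern.second_motif} <= motif_names:
                    dimers.extend(find_dimers(occ, pattern))
        dimers.sort(key=lambda d: (d.start, d.end, d.pattern_name))
        all_dimers[sid] = dimers
        clusters = call_clusters(
            dimers,
            min_members=int(cluster_params["min_members"]),
            max_span=int(cluster_params["max_span"]),
        )
        all_clusters[sid] = clusters
        for ci, cluster in enumerate(clusters, start=1):
            members = sorted(
                {occ for d in cluster.members for occ in (d.first, d.second)},
                key=lambda o: o.sort_key(),
            )
            overlaps = detect_overlaps(members)
            arch_rows.append(
                (f"{sid}:cluster_{ci}", architecture_string(members, overlaps))
            )

    prefix = Path(config.out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    occurrences_to_bed(
        [o for sid, _ in records for o in all_occ[sid]], f"{prefix}.occurrences.bed"
    )
    dimers_to_bed(
        [d for sid, _ in records for d in all_dimers[sid]], f"{prefix}.dimers.bed"
    )
    clusters_to_bed(
        [c for sid, _ in records for c in all_clusters[sid]], f"{prefix}.clusters.bed"
    )
    write_architecture_table(arch_rows, f"{prefix}.architectures.tsv")

    enrichment_results: list[EnrichmentResult] = []
    if config.labels_path:
        labels = read_labels(config.labels_path)
        genes = [sid for sid, _ in records]
        missing = [g for g in genes if g not in labels]
        if missing:
            raise ValueError(f"labels file lacks entries for: {missing[:5]}")
        regulated = {g for g in genes if labels[g] == "regulated"}
        for pattern in patterns:
            calls = {
                sid: [d for d in all_dimers[sid] if d.pattern_name == pattern.name]
                for sid, _ in records
            }
            table = presence_table(calls, genes, pattern.name)
            enrichment_results.append(enrichment_test(table, regulated))
        write_enrichment_report(
            enrichment_results,
            f"{prefix}.enrichment.tsv",
            f"{prefix}.enrichment.json",
        )

    config_dict = asdict(config)
    config_dict["strands"] = list(config.strands)
    manifest = {
        "package": "motifarch",
        "version": __version__,
        "seed": config.seed,
        "config": config_dict,
        "config_sha256": hashlib.sha256(
            json.dumps(config_dict, sort_keys=True).encode()
        ).hexdigest(),
        "input_fasta": str(fasta),
        "n_records": len(records),
        "n_occurrences": sum(len(v) for v in all_occ.values()),
        "n_dimers": sum(len(v) for v in all_dimers.values()),
        "n_clusters": sum(len(v) for v in all_clusters.values()),
        "motifs": [
            {"name": m.name, "tf": m.tf, "pattern": m.pattern} for m in motifs
        ],
        "grammar": [asdict(p) for p in patterns],
        "cluster_params": {k: int(v) for k, v in cluster_params.items()},
    }
    with open(f"{prefix}.manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return PipelineResult(
        occurrences=all_occ,
        dimers=all_dimers,
        clusters=all_clusters,
        architectures=arch_rows,
        enrichment=enrichment_results,
        manifest=manifest,
    )
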