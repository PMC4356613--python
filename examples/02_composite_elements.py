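"""Detect composite elements: spaced dimers, overlaps, clusters, architectures.

Reconstructs a compact Or59b-style cluster — a Pdm3 Hox core 2 bp upstream of
a Pou core whose 3' end is shared with an E-box — then a three-dimer
Or85a-style condensed cluster, and prints the canonical architecture string.
"""
from motifarch import (
    DimerPattern,
    architecture_string,
    call_clusters,
    compile_motif,
    detect_overlaps,
    find_dimers,
    scan_cores,
)

motifs = [
    compile_motif("PdmHox", "Pdm3", "TAAT"),
    compile_motif("Pou", "Pdm3", "TGCAW"),
    compile_motif("Ebox", "Fer1", "CANNTG"),
]

# TAAT .. 2 bp .. TGCAA sharing its last 3 bp with an E-box (CAATTG)
cluster_seq = "TAAT" + "GG" + "TGCAATTG" + "CGCG"
occurrences = scan_cores("Or59b_like", cluster_seq, motifs, strands=("+",))
print("occurrences:", [(o.motif_name, o.start, o.end) for o in occurrences])

pdm3 = DimerPattern("Pdm3_HoxPou", "PdmHox", "Pou", gap_min=2, gap_max=3)
dimers = find_dimers(occurrences, pdm3)
print(f"Pdm3 dimers: {len(dimers)} (gap={dimers[0].gap} bp)")

overlaps = detect_overlaps(occurrences)
print(f"overlaps: {[(p.a.motif_name, p.b.motif_name, p.overlap_len) for p in overlaps]}")

arch = architecture_string(occurrences, overlaps)
print("architecture:", arch)
# "PdmHox+.2.Pou+~Ebox+": the Hox core, a 2 bp gap, then the Pou core fused
# to the E-box by a 3 bp overlap — moving any motif or breaking the overlap
# yields a different string, which is how rearranged clusters are compared.

# An Or85a-style condensed cluster: three Hox/Pou dimers within 117 bp.
acj6 = [
    compile_motif("Hox", "Acj6", "AATTA"),
    compile_motif("Pou2", "Acj6", "TGCAW"),
]
spacer = "GCGCGCGCGCGCGCGCGCGCGCGCGCGCGCG"  # 31 bp of dimer-free background
unit = "AATTA" + "GGG" + "TGCAA"  # one Hox/Pou dimer, 3 bp gap
region = (spacer + unit) * 3 + spacer
occ85 = scan_cores("Or85a_like", region, acj6, strands=("+",))
acj6_dimer = DimerPattern("Acj6_HoxPou", "Hox", "Pou2", gap_min=0, gap_max=12)
dimers85 = find_dimers(occ85, acj6_dimer)
clusters = call_clusters(dimers85, min_members=2, max_span=150)
for c in clusters:
    print(
        f"cluster on {c.seq_id}: {c.n_members} dimers, span {c.span} bp "
        f"[{c.start},{c.end})"
    )
# One maximal cluster of 3 dimers should appear: the span (about 105 bp here)
# is the condensed arrangement that distinguishes a functional cluster from
# the same dimers scattered over a kilobase.
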