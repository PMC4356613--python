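"""Test enrichment of a composite pattern between two gene sets.

Simulates a cohort of 1 kb regions — 20 "regulated" genes that carry a tandem
2x Onecut Hox/Cut dimer element with probability 0.7 and 20 "non-regulated"
genes at probability 0.1 — then runs scan -> dimers -> clusters -> presence
-> Fisher exact test, exactly the comparison behind the published
"71% vs 8%, almost a tenfold enrichment" contrast.
"""
from motifarch import (
    CohortSpec,
    DimerPattern,
    call_clusters,
    compile_motif,
    enrichment_test,
    find_dimers,
    fold_from_fractions,
    generate_cohort,
    onecut_pair_template,
    presence_table,
    scan_cores,
)

spec = CohortSpec(
    n_reg=20, n_non=20, p_reg=0.7, p_non=0.1,
    element=onecut_pair_template(), seed=42,
)
cohort = generate_cohort(spec)

motifs = [
    compile_motif("Hox", "Onecut", "AATTA"),
    compile_motif("Cut", "Onecut", "ATCAA"),
]
onecut = DimerPattern("Onecut_HoxCut", "Hox", "Cut", gap_min=2, gap_max=6)

calls = {}
for seq_id, seq in cohort.records:
    occurrences = scan_cores(seq_id, seq, motifs)
    dimers = find_dimers(occurrences, onecut)
    calls[seq_id] = call_clusters(dimers, min_members=2, max_span=150)

genes = [seq_id for seq_id, _ in cohort.records]
table = presence_table(calls, genes, "Onecut_HoxCut_x2")
result = enrichment_test(table, cohort.regulated_ids)

print(f"presence fraction, regulated:     {result.f_reg:.2f} ({result.counts[0][0]}/{result.n_reg})")
print(f"presence fraction, non-regulated: {result.f_non:.2f} ({result.counts[0][1]}/{result.n_non})")
print(f"fold enrichment:                  {result.fold:.2f}")
print(f"two-sided exact p:                {result.p_exact:.4g}")
by_group = cohort.truth.groupby("group")["planted"].mean()
print(f"planted truth: reg {by_group['regulated']:.2f}, "
      f"non {by_group['non_regulated']:.2f}")

# The detected fractions track the planted ones: the tandem element is nearly
# absent from random backgrounds (a chance cluster needs two spurious dimers
# within 150 bp, ~0.5% per kb, usually via twin Hox hits on both strands of a
# TAATTA run).  For the published fractions:
print(f"published contrast 0.71 vs 0.08 -> fold {fold_from_fractions(0.71, 0.08):.3f}")
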