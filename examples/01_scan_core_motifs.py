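"""Scan a promoter-like region for degenerate TF core motifs.

Builds a small region containing a Hox core (AATTA) and a Pou core
(TGCAA/T -> TGCAW) and reports every strand-aware window match.
"""
from motifarch import compile_motif, scan_cores

hox = compile_motif("Hox", "Acj6", "AATTA")
pou = compile_motif("Pou", "Acj6", "TGCAA/T")
print(f"compiled motifs: {hox.name}={hox.pattern}, {pou.name}={pou.pattern}")

# a 40 bp toy region: Hox at 5, its reverse complement at 20, Pou at 30
region = "GCGCG" + "AATTA" + "CGCGCGCGCG" + "TAATT" + "CGCGC" + "TGCAT" + "GCGCG"
occurrences = scan_cores("toy_region", region, [hox, pou])

for o in occurrences:
    print(f"{o.motif_name:>4} {o.strand} [{o.start:2d},{o.end:2d})  matched={o.matched}")

# Each line is one binding-site candidate: coordinates are 0-based half-open
# on the forward strand; a '-' hit means the reverse complement of the shown
# substring fits the core pattern.  Expect Hox+ at [5,10), Hox- at [20,25)
# (forward TAATT), and Pou+ at [30,35) (the W position realized as T).
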