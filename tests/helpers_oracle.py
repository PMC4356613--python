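"""Independent brute-force oracles for the detection operations.

Deliberately naive and structured differently from the library code: the
scanner oracle checks each window symbol by symbol (complementing the window,
not the pattern), the dimer oracle enumerates all occurrence pairs, the
cluster oracle searches all subsets, and the exact-test oracle enumerates the
hypergeometric distribution with math.comb.
"""
from __future__ import annotations

import itertools
from math import comb

IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def window_satisfies(window: str, pattern: str) -> bool:
    return len(window) == len(pattern) and all(
        base in IUPAC_SETS[sym] for base, sym in zip(window, pattern)
    )


def naive_scan(seq_id, sequence, motifs, strands=("+", "-")):
    """Per-window membership check; '-' windows are reverse-complemented."""
    seq = sequence.upper()
    hits = []
    for motif in motifs:
        k = len(motif.pattern)
        for start in range(0, len(seq) - k + 1):
            window = seq[start : start + k]
            if "+" in strands and window_satisfies(window, motif.pattern):
                hits.append((start, start + k, motif.name, "+"))
            if "-" in strands:
                rc = "".join(COMP[b] for b in reversed(window))
                if window_satisfies(rc, motif.pattern):
                    hits.append((start, start + k, motif.name, "-"))
    return sorted(hits)


def brute_dimers(occurrences, pattern):
    """All ordered occurrence pairs satisfying the dimer constraints."""
    out = []
    for a in occurrences:
        for b in occurrences:
            if a is b:
                continue
            if a.motif_name != pattern.first_motif or b.motif_name != pattern.second_motif:
                continue
            if a.start >= b.start:
                continue
            gap = b.start - a.end
            if not pattern.gap_min <= gap <= pattern.gap_max:
                continue
            if pattern.orientation_policy == "same_strand" and a.strand != b.strand:
                continue
            out.append((a.start, a.end, a.strand, b.start, b.end, b.strand, gap))
    return sorted(out)


def exhaustive_clusters(dimers, min_members, max_span):
    """All maximal feasible dimer subsets, found by full subset search.

    A subset is feasible when it has >= min_members members and span
    <= max_span, and maximal when no single further dimer can be added
    without breaking feasibility.  Returns a set of frozensets of
    (start, end) member keys.
    """
    n = len(dimers)

    def feasible(indices) -> bool:
        members = [dimers[i] for i in indices]
        span = max(d.end for d in members) - min(d.start for d in members)
        return span <= max_span

    maximal = set()
    for r in range(min_members, n + 1):
        for combo in itertools.combinations(range(n), r):
            if not feasible(combo):
                continue
            if any(feasible(combo + (j,)) for j in range(n) if j not in combo):
                continue
            maximal.add(frozenset(combo))
    return {
        frozenset((dimers[i].start, dimers[i].end) for i in s) for s in maximal
    }


def enumerate_fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by summing hypergeometric pmfs <= the observed pmf."""
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    denom = comb(n, col1)

    def pmf(k: int) -> float:
        return comb(row1, k) * comb(n - row1, col1 - k) / denom

    k_min = max(0, col1 - (n - row1))
    k_max = min(row1, col1)
    p_obs = pmf(a)
    total = 0.0
    for k in range(k_min, k_max + 1):
        p = pmf(k)
        if p <= p_obs * (1 + 1e-12):
            total += p
    return min(1.0, total)
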