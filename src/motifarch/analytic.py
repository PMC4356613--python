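"""Closed-form expectations for motif and dimer counts in iid backgrounds.

Used to calibrate the synthetic-background false-positive rates: by linearity
of expectation, the expected both-strand count of a k-bp pattern in an L-bp
iid sequence is the per-window match probability summed over all windows and
strands; for a fully specified k-mer this is 2 (L - k + 1) 4^-k under a
uniform composition.  Dimer expectations multiply the two window
probabilities, which is exact for non-negative gaps (disjoint windows).
"""
from __future__ import annotations

from .alphabet import BASES, IUPAC, reverse_complement

__all__ = ["match_prob", "expected_motif_count", "expected_dimer_count"]

UNIFORM = (0.25, 0.25, 0.25, 0.25)


def match_prob(pattern: str, base_probs=UNIFORM) -> float:
    """Probability that one window of iid bases satisfies the IUPAC pattern."""
    p = 1.0
    for sym in pattern:
        p *= sum(base_probs[BASES.index(b)] for b in IUPAC[sym])
    return p


def expected_motif_count(
    pattern: str,
    length: int,
    base_probs=UNIFORM,
    strands: tuple[str, ...] = ("+", "-"),
) -> float:
    """Expected occurrence count over all windows of the requested strands."""
    k = len(pattern)
    n_windows = max(0, length - k + 1)
    total = 0.0
    for strand in strands:
        pat = pattern if strand == "+" else reverse_complement(pattern)
        total += n_windows * match_prob(pat, base_probs)
    return total


def expected_dimer_count(
    first_pattern: str,
    second_pattern: str,
    length: int,
    gap_min: int,
    gap_max: int,
    base_probs=UNIFORM,
    orientation_policy: str = "any",
) -> float:
    """Expected number of dimer instances (ordered pairs with gap in window).

    Sums the product of the two window probabilities over every anchor
    position, admissible gap and strand combination.  Exact for gap_min >= 0,
    where the two windows are disjoint and hence independent under an iid
    background.
    """
    if gap_min < 0:
        raise ValueError("analytic dimer expectation requires non-negative gaps")
    l1, l2 = len(first_pattern), len(second_pattern)
    combos = [("+", "+"), ("-", "-")]
    if orientation_policy == "any":
        combos += [("+", "-"), ("-", "+")]
    elif orientation_policy != "same_strand":
        raise ValueError(f"unknown orientation policy {orientation_policy!r}")
    total = 0.0
    for g in range(gap_min, gap_max + 1):
        n_anchor = max(0, length - (l1 + g + l2) + 1)
        if n_anchor == 0:
            continue
        for s1, s2 in combos:
            p1 = match_prob(
                first_pattern if s1 == "+" else reverse_complement(first_pattern),
                base_probs,
            )
            p2 = match_prob(
                second_pattern if s2 == "+" else reverse_complement(second_pattern),
                base_probs,
            )
            total += n_anchor * p1 * p2
    return total
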