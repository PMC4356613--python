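"""IUPAC nucleotide alphabet tables and strand utilities."""
from __future__ import annotations

#: Degenerate code -> set of plain bases it covers.
IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: Set of plain bases -> the single IUPAC code covering exactly that set.
CODE_FOR: dict[frozenset[str], str] = {bases: code for code, bases in IUPAC.items()}

BASES = "ACGT"
SEQUENCE_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVNacgtryswkmbdhvn",
    "TGCAYRSWMKVHDBNtgcayrswmkvhdbn",
)


def complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)


def reverse_complement(seq: str) -> str:
    """Reverse complement; degenerate codes map to their complementary codes."""
    return seq.translate(_COMPLEMENT)[::-1]


def symbol_matches(symbol: str, base: str) -> bool:
    """True if the plain base satisfies the IUPAC symbol (N in a sequence never matches)."""
    return base in IUPAC[symbol]
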