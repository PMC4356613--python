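"""Core-motif compilation and exhaustive degenerate-motif scanning.

Transcription factors that restrict odorant-receptor expression bind short
(3-6 bp) degenerate core motifs, e.g. the Acj6 Hox core ``AATTA`` and the Pou
core ``TGCAA/T`` (= ``TGCAW``).  This module compiles such shorthands into
IUPAC patterns and finds every window match on both strands of a promoter
region, in 0-based half-open forward coordinates.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

from .alphabet import BASES, CODE_FOR, IUPAC, SEQUENCE_ALPHABET, reverse_complement

__all__ = [
    "CoreMotif",
    "MotifOccurrence",
    "MotifSyntaxError",
    "compile_motif",
    "scan_cores",
    "default_motif_set",
]

_NAME_RE = re.compile(r"^[A-Za-z0-9_\-]+$")

BOTH_STRANDS = ("+", "-")


class MotifSyntaxError(ValueError):
    """A motif shorthand could not be compiled; carries the offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (position {position})")
        self.position = position


@dataclass(frozen=True)
class CoreMotif:
    """A named degenerate DNA core pattern attributed to a transcription factor."""

    name: str
    tf: str
    pattern: str

    def __post_init__(self) -> None:
        if not _NAME_RE.match(self.name):
            raise ValueError(
                f"motif name {self.name!r} must match [A-Za-z0-9_-]+ "
                "(reserved characters are used by architecture strings)"
            )
        if not 3 <= len(self.pattern) <= 12:
            raise ValueError(
                f"motif {self.name!r}: pattern length must be 3-12, got {len(self.pattern)}"
            )
        for i, sym in enumerate(self.pattern):
            if sym not in IUPAC:
                raise MotifSyntaxError(
                    f"motif {self.name!r}: {sym!r} is not an IUPAC code", i
                )

    def __len__(self) -> int:
        return len(self.pattern)


@dataclass(frozen=True)
class MotifOccurrence:
    """One strand-aware match of a core motif, in forward 0-based half-open coords.

    ``matched`` is the literal forward-strand substring [start, end); for a
    ``-`` strand occurrence its reverse complement satisfies the pattern.
    ``matched`` may be None for occurrences reconstructed from interchange
    files that do not carry sequence.
    """

    motif_name: str
    seq_id: str
    start: int
    end: int
    strand: str
    matched: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.start < 0 or self.end < self.start:
            raise ValueError(f"bad interval [{self.start}, {self.end})")
        if self.matched is not None and len(self.matched) != self.end - self.start:
            raise ValueError("matched substring length disagrees with [start, end)")

    @property
    def length(self) -> int:
        return self.end - self.start

    def sort_key(self):
        return (self.start, self.end, self.motif_name, self.strand)


def compile_motif(name: str, tf: str, shorthand: str) -> CoreMotif:
    """Compile a motif shorthand (IUPAC, optionally with ``X/Y`` alternatives).

    The literature writes terminal alternatives as e.g. ``TGCAA/T``; each
    ``X/Y`` (X, Y plain bases) is replaced by the IUPAC code covering exactly
    {X, Y}, so ``TGCAA/T`` compiles to ``TGCAW``.  Plain IUPAC strings pass
    through unchanged.

    Raises :class:`MotifSyntaxError` (with the offending position) for unknown
    symbols or alternatives that do not name plain bases.
    """
    s = shorthand.upper()
    out: list[str] = []
    i = 0
    while i < len(s):
        c = s[i]
        if c == "/":
            raise MotifSyntaxError(f"{shorthand!r}: '/' without a leading base", i)
        if i + 1 < len(s) and s[i + 1] == "/":
            if i + 2 >= len(s):
                raise MotifSyntaxError(f"{shorthand!r}: dangling '/'", i + 1)
            x, y = c, s[i + 2]
            if x not in BASES or y not in BASES:
                raise MotifSyntaxError(
                    f"{shorthand!r}: alternative {x}/{y} must use plain bases", i
                )
            code = CODE_FOR.get(frozenset({x, y}))
            if code is None:  # pragma: no cover - every base pair has a code
                raise MotifSyntaxError(f"{shorthand!r}: no IUPAC code for {x}/{y}", i)
            out.append(code)
            i += 3
            continue
        if c not in IUPAC:
            raise MotifSyntaxError(f"{shorthand!r}: {c!r} is not an IUPAC code", i)
        out.append(c)
        i += 1
    return CoreMotif(name=name, tf=tf, pattern="".join(out))


@lru_cache(maxsize=512)
def _window_regex(pattern: str) -> re.Pattern[str]:
    """Overlap-tolerant regex for an IUPAC pattern.

    Character classes list plain bases only, so an N in the *sequence* never
    matches any pattern symbol (including pattern N).
    """
    body = "".join("[%s]" % "".join(sorted(IUPAC[sym])) for sym in pattern)
    return re.compile(r"(?=(%s))" % body)


def _validate_sequence(seq_id: str, sequence: str) -> str:
    seq = sequence.upper()
    bad = set(seq) - SEQUENCE_ALPHABET
    if bad:
        raise ValueError(
            f"sequence {seq_id!r} contains invalid characters: {sorted(bad)}"
        )
    return seq


def scan_cores(
    seq_id: str,
    sequence: str,
    motifs: Iterable[CoreMotif],
    strands: Sequence[str] = BOTH_STRANDS,
) -> list[MotifOccurrence]:
    """Locate every window match of every motif, on the requested strands.

    Overlapping and nested matches are all reported (the exhaustive scan the
    per-region motif counts imply).  A window matching both strands of a
    palindromic pattern yields two occurrences, one per strand.  Output is
    sorted by (start, end, motif_name, strand).
    """
    for s in strands:
        if s not in ("+", "-"):
            raise ValueError(f"unknown strand {s!r}")
    seq = _validate_sequence(seq_id, sequence)
    hits: list[MotifOccurrence] = []
    for motif in motifs:
        k = len(motif.pattern)
        if k > len(seq):
            continue
        for strand in strands:
            pat = motif.pattern if strand == "+" else reverse_complement(motif.pattern)
            for m in _window_regex(pat).finditer(seq):
                start = m.start()
                hits.append(
                    MotifOccurrence(
                        motif_name=motif.name,
                        seq_id=seq_id,
                        start=start,
                        end=start + k,
                        strand=strand,
                        matched=seq[start : start + k],
                    )
                )
    hits.sort(key=MotifOccurrence.sort_key)
    return hits


def default_motif_set() -> list[CoreMotif]:
    """The documented default core-motif set for OR upstream-region scans.

    Hox (Acj6) ``AATTA`` and Pou ``TGCAW`` (written TGCAA/T in the
    literature) are published cores; the Pdm3 Hox core is ``TAAT``.  Two
    entries are assumptions, stated as such: the E-box uses the canonical
    bHLH consensus ``CANNTG``, and the Onecut Cut core uses the HNF6-family
    core ``ATCAA``.  Supply your own motif table to override.
    """
    return [
        compile_motif("Hox", "Acj6", "AATTA"),
        compile_motif("Pou", "Acj6", "TGCAA/T"),
        compile_motif("PdmHox", "Pdm3", "TAAT"),
        compile_motif("Ebox", "Fer1", "CANNTG"),
        compile_motif("Cut", "Onecut", "ATCAA"),
    ]
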