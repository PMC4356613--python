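"""Composite cis-regulatory elements: motif dimers, overlaps, clusters, grammars.

The regulatory logic studied here is carried not by single core motifs but by
their arrangement: ordered dimers with constrained spacing (Onecut binds
Hox/Cut cores 2-6 bp apart; Pdm3 binds a Hox core 2-3 bp upstream of a Pou
core), pairs of motifs that physically overlap (the Or59b Pou core shares
bases with an E-box), and condensed clusters of several dimers within a short
span (the 117-bp Or85a Hox/Pou cluster).  This module detects those composite
elements from motif occurrences and serializes cluster architectures into
canonical strings so arrangements can be compared across genes.

Coordinate conventions
----------------------
All coordinates are 0-based half-open on the forward strand of the supplied
region.  Regions are assumed to be oriented 5'->3' toward the gene, so the
``first`` motif of a dimer is the 5' (upstream) partner.  The gap between two
occurrences is ``second.start - first.end``, i.e. the number of intervening
bases ("spaced 2-6 bps apart" means gap in [2, 6]); negative gaps encode
required overlap.
"""
from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .motifs import MotifOccurrence

__all__ = [
    "DimerPattern",
    "DimerOccurrence",
    "OverlapPair",
    "ClusterCall",
    "Architecture",
    "find_dimers",
    "detect_overlaps",
    "call_clusters",
    "architecture_of",
    "architecture_string",
    "parse_architecture",
]


@dataclass(frozen=True)
class DimerPattern:
    """An ordered motif pair with a spacing window.

    ``orientation_policy`` is ``"any"`` (default; the source data states no
    strand requirement for dimers) or ``"same_strand"``.
    """

    name: str
    first_motif: str
    second_motif: str
    gap_min: int
    gap_max: int
    orientation_policy: str = "any"

    def __post_init__(self) -> None:
        if self.gap_min > self.gap_max:
            raise ValueError(
                f"pattern {self.name!r}: gap_min {self.gap_min} > gap_max {self.gap_max}"
            )
        if self.orientation_policy not in ("any", "same_strand"):
            raise ValueError(
                f"pattern {self.name!r}: unknown orientation policy "
                f"{self.orientation_policy!r}"
            )


@dataclass(frozen=True)
class DimerOccurrence:
    """A concrete matched dimer: two occurrences with their realized gap."""

    pattern_name: str
    first: MotifOccurrence
    second: MotifOccurrence
    gap: int

    def __post_init__(self) -> None:
        if self.first.start >= self.second.start:
            raise ValueError("dimer first motif must start 5' of the second")
        if self.gap != self.second.start - self.first.end:
            raise ValueError("gap must equal second.start - first.end")

    @property
    def seq_id(self) -> str:
        return self.first.seq_id

    @property
    def start(self) -> int:
        return self.first.start

    @property
    def end(self) -> int:
        return self.second.end

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class OverlapPair:
    """Two occurrences of different motifs sharing at least one base."""

    a: MotifOccurrence
    b: MotifOccurrence
    overlap_len: int

    def __post_init__(self) -> None:
        expect = max(0, min(self.a.end, self.b.end) - max(self.a.start, self.b.start))
        if self.overlap_len != expect or self.overlap_len <= 0:
            raise ValueError("overlap_len must be the (positive) interval overlap")
        if self.a.motif_name == self.b.motif_name:
            raise ValueError("overlap pairs must involve two different motifs")


@dataclass(frozen=True)
class ClusterCall:
    """A maximal set of dimers condensed within a span limit."""

    seq_id: str
    members: tuple[DimerOccurrence, ...]
    start: int
    end: int

    @property
    def span(self) -> int:
        return self.end - self.start

    @property
    def n_members(self) -> int:
        return len(self.members)


def find_dimers(
    occurrences: Sequence[MotifOccurrence], pattern: DimerPattern
) -> list[DimerOccurrence]:
    """Every ordered occurrence pair matching the dimer pattern.

    Pairs may share occurrences (a motif may participate in several dimers).
    If a partner motif never occurs in the supplied list a warning is issued
    and the result is empty.  Output sorted by (first.start, second.start).
    """
    seq_ids = {o.seq_id for o in occurrences}
    if len(seq_ids) > 1:
        raise ValueError(f"occurrences span multiple sequences: {sorted(seq_ids)}")
    names = {o.motif_name for o in occurrences}
    missing = {pattern.first_motif, pattern.second_motif} - names
    if occurrences and missing:
        warnings.warn(
            f"dimer pattern {pattern.name!r}: no occurrences of "
            f"{sorted(missing)} in this sequence",
            stacklevel=2,
        )
    firsts = [o for o in occurrences if o.motif_name == pattern.first_motif]
    seconds = [o for o in occurrences if o.motif_name == pattern.second_motif]
    out: list[DimerOccurrence] = []
    for a in firsts:
        for b in seconds:
            if a is b or a.start >= b.start:
                continue
            gap = b.start - a.end
            if not pattern.gap_min <= gap <= pattern.gap_max:
                continue
            if pattern.orientation_policy == "same_strand" and a.strand != b.strand:
                continue
            out.append(DimerOccurrence(pattern.name, a, b, gap))
    out.sort(key=lambda d: (d.first.start, d.second.start, d.second.motif_name))
    return out


def detect_overlaps(occurrences: Sequence[MotifOccurrence]) -> list[OverlapPair]:
    """All unordered pairs of different motifs with a positive interval overlap.

    Each pair is reported once, with ``a < b`` by (start, motif_name); half-open
    adjacency (a.end == b.start) is not an overlap.
    """
    seq_ids = {o.seq_id for o in occurrences}
    if len(seq_ids) > 1:
        raise ValueError(f"occurrences span multiple sequences: {sorted(seq_ids)}")
    ordered = sorted(occurrences, key=lambda o: (o.start, o.motif_name, o.end, o.strand))
    out: list[OverlapPair] = []
    for i, a in enumerate(ordered):
        for b in ordered[i + 1 :]:
            if b.start >= a.end:
                break  # sorted by start: nothing further can overlap a
            if a.motif_name == b.motif_name:
                continue
            ov = min(a.end, b.end) - max(a.start, b.start)
            if ov > 0:
                out.append(OverlapPair(a, b, ov))
    return out


def call_clusters(
    dimers: Sequence[DimerOccurrence],
    min_members: int = 2,
    max_span: int = 150,
) -> list[ClusterCall]:
    """Call every maximal set of >= min_members dimers with span <= max_span.

    A set's span is (max end - min start) over its members.  Because any dimer
    starting at or after a set's leftmost start and ending within
    ``leftmost start + max_span`` can be added without violating the span
    limit, each maximal feasible set is exactly the set of dimers contained in
    the window anchored at its leftmost member; the call therefore enumerates
    those anchored windows and drops duplicates and subsets.  No reported
    cluster is a subset of another (maximality).
    """
    if min_members < 2:
        raise ValueError(f"min_members must be >= 2, got {min_members}")
    if max_span <= 0:
        raise ValueError(f"max_span must be positive, got {max_span}")
    if not dimers:
        return []
    seq_ids = {d.seq_id for d in dimers}
    if len(seq_ids) > 1:
        raise ValueError(f"dimers span multiple sequences: {sorted(seq_ids)}")
    (seq_id,) = seq_ids
    ds = sorted(dimers, key=lambda d: (d.start, d.end))
    candidate_sets: list[frozenset[int]] = []
    for i, anchor in enumerate(ds):
        members = frozenset(
            j
            for j, d in enumerate(ds)
            if d.start >= anchor.start and d.end <= anchor.start + max_span
        )
        if i in members and len(members) >= min_members:
            candidate_sets.append(members)
    unique = set(candidate_sets)
    maximal = [
        s for s in unique if not any(s < other for other in unique)
    ]
    calls = []
    for s in maximal:
        members = tuple(sorted((ds[j] for j in s), key=lambda d: (d.start, d.end)))
        calls.append(
            ClusterCall(
                seq_id=seq_id,
                members=members,
                start=min(d.start for d in members),
                end=max(d.end for d in members),
            )
        )
    calls.sort(key=lambda c: (c.start, c.end))
    return calls


# ---------------------------------------------------------------------------
# Architecture strings
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Architecture:
    """Structural content of an architecture string.

    ``elements`` are (motif_name, strand) left to right; ``links[i]`` joins
    element i to i+1 and is either an integer gap in bp or None for a flagged
    overlap.
    """

    elements: tuple[tuple[str, str], ...]
    links: tuple[int | None, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.elements and len(self.links) != len(self.elements) - 1:
            raise ValueError("need exactly one link between consecutive elements")


def _canonical_order(elements: Sequence[MotifOccurrence]) -> list[MotifOccurrence]:
    return sorted(elements, key=lambda o: (o.start, o.end, o.motif_name, o.strand))


def architecture_of(
    elements: Sequence[MotifOccurrence],
    overlaps: Sequence[OverlapPair] = (),
) -> Architecture:
    """Reduce occurrences (plus flagged overlaps) to their architecture."""
    listed = list(elements)
    for pair in overlaps:
        for member in (pair.a, pair.b):
            if member not in listed:
                raise ValueError(
                    f"overlap references occurrence {member} not in the element list"
                )
    ordered = _canonical_order(listed)
    flagged = {frozenset({p.a.sort_key(), p.b.sort_key()}) for p in overlaps}
    links: list[int | None] = []
    for prev, nxt in zip(ordered, ordered[1:]):
        if frozenset({prev.sort_key(), nxt.sort_key()}) in flagged:
            links.append(None)
        else:
            links.append(nxt.start - prev.end)
    return Architecture(
        elements=tuple((o.motif_name, o.strand) for o in ordered),
        links=tuple(links),
    )


def architecture_string(
    elements: Sequence[MotifOccurrence],
    overlaps: Sequence[OverlapPair] = (),
) -> str:
    """Canonical serialization of an ordered element list.

    Elements appear left to right as ``name`` + strand; consecutive elements
    are joined by ``.gap.`` (gap in bp, may be negative for unflagged
    overlap) or by ``~`` when the adjacent pair is a flagged overlap, e.g.
    ``"Hox+.2.Pou+"`` or ``"Pou+~Ebox+"``.  Deterministic for a fixed input;
    the empty element list serializes to ``""``.
    """
    arch = architecture_of(elements, overlaps)
    return serialize_architecture(arch)


def serialize_architecture(arch: Architecture) -> str:
    if not arch.elements:
        return ""
    parts = [arch.elements[0][0] + arch.elements[0][1]]
    for (name, strand), link in zip(arch.elements[1:], arch.links):
        parts.append("~" if link is None else f".{link}.")
        parts.append(name + strand)
    return "".join(parts)


_SEP_RE = re.compile(r"~|\.(-?\d+)\.")
_ELEMENT_RE = re.compile(r"^([A-Za-z0-9_\-]+)([+-])$")


def parse_architecture(text: str) -> Architecture:
    """Parse an architecture string back to its structure (round-trips exactly)."""
    if text == "":
        return Architecture((), ())
    tokens = _SEP_RE.split(text)
    element_tokens = tokens[0::2]
    link_tokens = tokens[1::2]
    elements = []
    for tok in element_tokens:
        m = _ELEMENT_RE.match(tok)
        if not m:
            raise ValueError(f"malformed architecture element {tok!r} in {text!r}")
        elements.append((m.group(1), m.group(2)))
    links = tuple(None if t is None else int(t) for t in link_tokens)
    return Architecture(tuple(elements), links)
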