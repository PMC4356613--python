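"""Ground-truthed synthetic promoter regions with planted composite elements.

The study design this emulates: ~1 kb of sequence directly upstream of each
gene's translational start, scanned for short degenerate cores and their
composite arrangements, with a "regulated" and a "non-regulated" gene cohort
that differ in how often they carry a composite element.  No sequence set is
deposited with the original analysis, so every pipeline stage is exercised
against simulated regions whose planted elements are known base by base.

Planting overwrites background bases in place (no insertion), keeping region
length fixed.  Only pattern-covered positions are overwritten; gap bases
between dimer partners stay background.  Where two planted patterns overlap,
the shared positions must satisfy both patterns simultaneously (their IUPAC
base sets are intersected); templates whose overlap admits no base are
rejected with the conflicting positions.

Randomness: one generator drives everything, in a fixed draw order — per
sequence: background bases, Bernoulli planting flag, then (if planted)
template variant, position, and degenerate bases left to right.  All outputs
are pure functions of (spec, seed).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .alphabet import BASES, IUPAC, reverse_complement
from .motifs import CoreMotif, MotifOccurrence, compile_motif

__all__ = [
    "BackgroundModel",
    "PlacedPattern",
    "ElementTemplate",
    "PlantedElement",
    "CohortSpec",
    "Cohort",
    "OverlapConflictError",
    "at_rich_model",
    "generate_background",
    "plant_architecture",
    "generate_cohort",
    "motif_template",
    "dimer_template",
    "overlap_template",
    "compound_template",
    "pdm3_dimer_template",
    "pou_ebox_overlap_template",
    "onecut_dimer_template",
    "onecut_pair_template",
    "or59b_cluster_template",
]

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


class OverlapConflictError(ValueError):
    """No base assignment satisfies all patterns at the listed positions."""

    def __init__(self, positions: Sequence[int]):
        super().__init__(
            "planted patterns conflict at template position(s) "
            f"{sorted(positions)}: no base satisfies all overlapping patterns"
        )
        self.positions = tuple(sorted(positions))


@dataclass(frozen=True)
class BackgroundModel:
    """Uninformative promoter background: iid bases of a fixed composition."""

    length: int = 1000
    base_probs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.base_probs) != 4 or any(p < 0 for p in self.base_probs):
            raise ValueError("base_probs must be four non-negative numbers (A,C,G,T)")
        if abs(sum(self.base_probs) - 1.0) > 1e-9:
            raise ValueError(f"base_probs sum to {sum(self.base_probs)}, not 1")


def at_rich_model(length: int = 1000, seed: int = 0) -> BackgroundModel:
    """60% AT preset (Drosophila intergenic DNA is AT-rich); never applied silently."""
    return BackgroundModel(length=length, base_probs=(0.3, 0.2, 0.2, 0.3), seed=seed)


def generate_background(
    model: BackgroundModel, rng: np.random.Generator | None = None
) -> str:
    """An iid random sequence of the model's length; reproducible from model.seed."""
    if model.length <= 0:
        raise ValueError(f"background length must be positive, got {model.length}")
    if rng is None:
        rng = np.random.default_rng(model.seed)
    idx = rng.choice(4, size=model.length, p=model.base_probs)
    return bytes(_BASE_BYTES[idx]).decode("ascii")


# ---------------------------------------------------------------------------
# Element templates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlacedPattern:
    """One motif pattern at a fixed offset (and strand) inside a template."""

    motif_name: str
    pattern: str
    offset: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.offset < 0:
            raise ValueError("pattern offset must be non-negative")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def end(self) -> int:
        return self.offset + len(self.pattern)


@dataclass(frozen=True)
class ElementTemplate:
    """A plantable element: one or more alternative motif arrangements.

    ``variants`` are concrete placements; a spacing window such as the 2-3 bp
    Pdm3 Hox-Pou gap becomes one variant per admissible gap, sampled uniformly
    at planting time.
    """

    name: str
    kind: str  # motif | dimer | overlap_pair | cluster
    variants: tuple[tuple[PlacedPattern, ...], ...]

    def __post_init__(self) -> None:
        if not self.variants or any(not v for v in self.variants):
            raise ValueError("template needs at least one non-empty variant")

    @property
    def max_length(self) -> int:
        return max(max(p.end for p in v) for v in self.variants)


def _pat(motif: CoreMotif | tuple[str, str]) -> tuple[str, str]:
    if isinstance(motif, CoreMotif):
        return motif.name, motif.pattern
    return motif


def motif_template(motif: CoreMotif | tuple[str, str], strand: str = "+") -> ElementTemplate:
    name, pattern = _pat(motif)
    return ElementTemplate(
        name=name,
        kind="motif",
        variants=((PlacedPattern(name, pattern, 0, strand),),),
    )


def dimer_template(
    name: str,
    first: CoreMotif | tuple[str, str],
    second: CoreMotif | tuple[str, str],
    gap: int | tuple[int, int],
    strand: str = "+",
) -> ElementTemplate:
    """An ordered pair with a fixed gap or a (gap_min, gap_max) window."""
    fname, fpat = _pat(first)
    sname, spat = _pat(second)
    gaps = range(gap, gap + 1) if isinstance(gap, int) else range(gap[0], gap[1] + 1)
    variants = tuple(
        (
            PlacedPattern(fname, fpat, 0, strand),
            PlacedPattern(sname, spat, len(fpat) + g, strand),
        )
        for g in gaps
    )
    return ElementTemplate(name=name, kind="dimer", variants=variants)


def overlap_template(
    name: str,
    a: CoreMotif | tuple[str, str],
    b: CoreMotif | tuple[str, str],
    shift: int,
    strand: str = "+",
) -> ElementTemplate:
    """Motif ``b`` starting ``shift`` bases after ``a`` with a positive overlap."""
    aname, apat = _pat(a)
    bname, bpat = _pat(b)
    if not 0 < shift < len(apat):
        raise ValueError(
            f"shift {shift} gives no overlap between {aname} (len {len(apat)}) and {bname}"
        )
    return ElementTemplate(
        name=name,
        kind="overlap_pair",
        variants=(
            (
                PlacedPattern(aname, apat, 0, strand),
                PlacedPattern(bname, bpat, shift, strand),
            ),
        ),
    )


def compound_template(
    name: str,
    parts: Sequence[tuple[ElementTemplate, int]],
    kind: str = "cluster",
) -> ElementTemplate:
    """Compose templates at fixed offsets; variant sets combine cross-product."""
    variant_lists: list[tuple[tuple[PlacedPattern, ...], ...]] = []
    offsets = []
    for tmpl, offset in parts:
        variant_lists.append(tmpl.variants)
        offsets.append(offset)
    combos: list[tuple[PlacedPattern, ...]] = [()]
    for variants, offset in zip(variant_lists, offsets):
        combos = [
            prefix
            + tuple(
                PlacedPattern(p.motif_name, p.pattern, p.offset + offset, p.strand)
                for p in variant
            )
            for prefix in combos
            for variant in variants
        ]
    return ElementTemplate(name=name, kind=kind, variants=tuple(combos))


# -- presets mirroring the composite elements described for the OR regions ----

def pdm3_dimer_template(gap: int | tuple[int, int] = (2, 3)) -> ElementTemplate:
    """Pdm3 site: Hox core TAAT 2-3 bp upstream of a Pou core TGCAW."""
    return dimer_template(
        "Pdm3_HoxPou", ("PdmHox", "TAAT"), ("Pou", "TGCAW"), gap=gap
    )


def pou_ebox_overlap_template() -> ElementTemplate:
    """Or59b-style Pou/E-box overlap: TGCAW and CANNTG sharing 3 bp (TGCAWNTG)."""
    return overlap_template("Pou_Ebox", ("Pou", "TGCAW"), ("Ebox", "CANNTG"), shift=2)


def onecut_dimer_template(gap: int | tuple[int, int] = (2, 6)) -> ElementTemplate:
    """Onecut site: Hox core AATTA and Cut core ATCAA spaced 2-6 bp apart."""
    return dimer_template("Onecut_HoxCut", ("Hox", "AATTA"), ("Cut", "ATCAA"), gap=gap)


def onecut_pair_template(spacing: int = 8) -> ElementTemplate:
    """Two Onecut Hox/Cut dimers in tandem (the synthetic 2x dimer construct)."""
    one = onecut_dimer_template()
    # worst-case single-dimer length: 5 + 6 + 5
    second_offset = 5 + 6 + 5 + spacing
    return compound_template(
        "Onecut_HoxCut_x2", [(one, 0), (one, second_offset)], kind="cluster"
    )


def or59b_cluster_template() -> ElementTemplate:
    """The compact Or59b-style cluster: Acj6 Hox, then Pdm3 Hox-gap-Pou~E-box.

    The E-box starts 2 bp into the Pou core so the two share 3 bp (TGCAWNTG);
    the Pdm3 gap is sampled from its 2-3 bp window, and the E-box tracks it.
    """
    variants = []
    for g in (2, 3):
        pou_off = 8 + 4 + g
        variants.append(
            (
                PlacedPattern("Hox", "AATTA", 0),
                PlacedPattern("PdmHox", "TAAT", 8),
                PlacedPattern("Pou", "TGCAW", pou_off),
                PlacedPattern("Ebox", "CANNTG", pou_off + 2),
            )
        )
    return ElementTemplate(name="Or59b_cluster", kind="cluster", variants=tuple(variants))


# ---------------------------------------------------------------------------
# Planting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedElement:
    """Exact truth for one planted element."""

    kind: str
    name: str
    position: int
    realized_sequence: str
    truth: tuple[MotifOccurrence, ...]


def _realize(parts: Sequence[PlacedPattern], rng: np.random.Generator) -> dict[int, str]:
    """Sample concrete bases for every pattern-covered template position.

    Shared positions intersect the allowed base sets of all covering patterns;
    an empty intersection raises :class:`OverlapConflictError`.
    """
    allowed: dict[int, set[str]] = {}
    for p in parts:
        pat = p.pattern if p.strand == "+" else reverse_complement(p.pattern)
        for i, sym in enumerate(pat):
            pos = p.offset + i
            bases = set(IUPAC[sym])
            allowed[pos] = allowed.get(pos, set(BASES)) & bases
    conflicts = [pos for pos, s in allowed.items() if not s]
    if conflicts:
        raise OverlapConflictError(conflicts)
    realized: dict[int, str] = {}
    for pos in sorted(allowed):
        choices = sorted(allowed[pos])
        realized[pos] = (
            choices[0] if len(choices) == 1 else choices[rng.integers(len(choices))]
        )
    return realized


def plant_architecture(
    background: str,
    template: ElementTemplate,
    position: int | str = "random",
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    seq_id: str = "planted",
) -> tuple[str, PlantedElement]:
    """Overwrite background bases with a realization of the template.

    Returns the edited sequence and the exact truth (motif coordinates,
    strands, realized bases).  Degenerate positions are sampled uniformly from
    their allowed bases; the planted bases satisfy every pattern of the chosen
    variant, overlaps included.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    variant = template.variants[
        0 if len(template.variants) == 1 else int(rng.integers(len(template.variants)))
    ]
    length = max(p.end for p in variant)
    if length > len(background):
        raise ValueError(
            f"template {template.name!r} (length {length}) does not fit in a "
            f"{len(background)} bp background"
        )
    if position == "random":
        pos = int(rng.integers(0, len(background) - length + 1))
    else:
        pos = int(position)
        if pos < 0 or pos + length > len(background):
            raise ValueError(
                f"template {template.name!r} does not fit at position {pos}"
            )
    realized = _realize(variant, rng)
    seq = list(background)
    for offset, base in realized.items():
        seq[pos + offset] = base
    new_seq = "".join(seq)
    truth = tuple(
        MotifOccurrence(
            motif_name=p.motif_name,
            seq_id=seq_id,
            start=pos + p.offset,
            end=pos + p.end,
            strand=p.strand,
            matched=new_seq[pos + p.offset : pos + p.end],
        )
        for p in sorted(variant, key=lambda p: (p.offset, p.end))
    )
    element = PlantedElement(
        kind=template.kind,
        name=template.name,
        position=pos,
        realized_sequence=new_seq[pos : pos + length],
        truth=truth,
    )
    return new_seq, element


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Two labelled groups of regions with different element-planting rates."""

    n_reg: int
    n_non: int
    p_reg: float
    p_non: float
    element: ElementTemplate
    background: BackgroundModel = field(default_factory=BackgroundModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reg < 1 or self.n_non < 1:
            raise ValueError("both group sizes must be >= 1")
        for label, p in (("p_reg", self.p_reg), ("p_non", self.p_non)):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{label} must lie in [0, 1], got {p}")


@dataclass
class Cohort:
    """FASTA-ready records plus per-sequence truth and group labels."""

    records: list[tuple[str, str]]
    truth: pd.DataFrame  # seq_id, group, planted, position, element
    labels: pd.DataFrame  # gene, label
    planted: dict[str, PlantedElement]

    @property
    def regulated_ids(self) -> set[str]:
        return set(self.labels.loc[self.labels["label"] == "regulated", "gene"])


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Simulate a regulated / non-regulated cohort from a :class:`CohortSpec`."""
    if spec.element.max_length > spec.background.length:
        raise ValueError(
            f"element {spec.element.name!r} (length {spec.element.max_length}) "
            f"exceeds the {spec.background.length} bp background"
        )
    rng = np.random.default_rng(spec.seed)
    records: list[tuple[str, str]] = []
    rows = []
    label_rows = []
    planted: dict[str, PlantedElement] = {}
    groups = (
        ("regulated", "reg", spec.n_reg, spec.p_reg),
        ("non_regulated", "non", spec.n_non, spec.p_non),
    )
    for group, prefix, n, p in groups:
        for i in range(1, n + 1):
            sid = f"{prefix}_{i:03d}"
            seq = generate_background(spec.background, rng=rng)
            carries = bool(rng.random() < p)
            position: int | None = None
            if carries:
                seq, element = plant_architecture(
                    seq, spec.element, rng=rng, seq_id=sid
                )
                planted[sid] = element
                position = element.position
            records.append((sid, seq))
            rows.append(
                {
                    "seq_id": sid,
                    "group": group,
                    "planted": carries,
                    "position": position,
                    "element": spec.element.name,
                }
            )
            label_rows.append({"gene": sid, "label": group})
    truth = pd.DataFrame(rows).astype({"position": "Int64"})
    labels = pd.DataFrame(label_rows)
    return Cohort(records=records, truth=truth, labels=labels, planted=planted)
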