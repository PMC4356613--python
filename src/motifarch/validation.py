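"""Simulation-based validation experiments for the detection pipeline.

These functions regenerate the study conditions end to end — plant composite
elements into 1 kb synthetic regions, run the scanner and composite detectors,
and measure sensitivity, background calibration and cohort fraction recovery.
They are what the test suite and the reproduction script call; all results are
pure functions of the seed.
"""
from __future__ import annotations

import math
import warnings
from contextlib import contextmanager
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .analytic import expected_dimer_count
from .composites import DimerPattern, call_clusters, detect_overlaps, find_dimers
from .enrichment import enrichment_test, presence_table
from .motifs import compile_motif, scan_cores
from .simulate import (
    BackgroundModel,
    CohortSpec,
    generate_background,
    generate_cohort,
    onecut_pair_template,
    pdm3_dimer_template,
    plant_architecture,
    pou_ebox_overlap_template,
)

__all__ = [
    "planted_recovery",
    "background_dimer_calibration",
    "cohort_recovery",
]

@contextmanager
def _absent_partner_ok():
    """In bulk background scans a partner motif is often absent by chance;
    the per-sequence warning is informative interactively but noise here."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="dimer pattern", category=UserWarning)
        yield


PDM3_PATTERN = DimerPattern("Pdm3_HoxPou", "PdmHox", "Pou", gap_min=2, gap_max=3)
ONECUT_PATTERN = DimerPattern("Onecut_HoxCut", "Hox", "Cut", gap_min=2, gap_max=6)

_PDM3_MOTIFS = (
    compile_motif("PdmHox", "Pdm3", "TAAT"),
    compile_motif("Pou", "Pdm3", "TGCAW"),
)
_OVERLAP_MOTIFS = (
    compile_motif("Pou", "Acj6", "TGCAW"),
    compile_motif("Ebox", "Fer1", "CANNTG"),
)
_ONECUT_MOTIFS = (
    compile_motif("Hox", "Onecut", "AATTA"),
    compile_motif("Cut", "Onecut", "ATCAA"),
)


@dataclass(frozen=True)
class RecoveryResult:
    dimer_sensitivity: float
    overlap_sensitivity: float
    n_sequences: int


def planted_recovery(
    n_sequences: int = 500,
    seed: int = 0,
    background: BackgroundModel | None = None,
) -> RecoveryResult:
    """Detector sensitivity on planted Pdm3 dimers and Pou~E-box overlaps.

    Each region receives one planted element at a random position; detection
    uses the element's own grammar (2-3 bp Hox-Pou gap; positive Pou/E-box
    interval overlap).  A plant counts as recovered when a detected composite
    matches the planted coordinates exactly.
    """
    background = background or BackgroundModel()
    rng = np.random.default_rng(seed)
    dimer_tmpl = pdm3_dimer_template()
    overlap_tmpl = pou_ebox_overlap_template()
    dimer_hits = 0
    overlap_hits = 0
    for i in range(n_sequences):
        sid = f"sim_{i:04d}"
        bg = generate_background(background, rng=rng)
        seq, planted = plant_architecture(bg, dimer_tmpl, rng=rng, seq_id=sid)
        occ = scan_cores(sid, seq, _PDM3_MOTIFS)
        dimers = find_dimers(occ, PDM3_PATTERN)
        t_first, t_second = planted.truth
        if any(
            d.first.start == t_first.start and d.second.start == t_second.start
            for d in dimers
        ):
            dimer_hits += 1

        bg2 = generate_background(background, rng=rng)
        seq2, planted2 = plant_architecture(bg2, overlap_tmpl, rng=rng, seq_id=sid)
        occ2 = scan_cores(sid, seq2, _OVERLAP_MOTIFS)
        pairs = detect_overlaps(occ2)
        t_a, t_b = planted2.truth
        if any(
            {(p.a.motif_name, p.a.start), (p.b.motif_name, p.b.start)}
            == {(t_a.motif_name, t_a.start), (t_b.motif_name, t_b.start)}
            for p in pairs
        ):
            overlap_hits += 1
    return RecoveryResult(
        dimer_sensitivity=dimer_hits / n_sequences,
        overlap_sensitivity=overlap_hits / n_sequences,
        n_sequences=n_sequences,
    )


@dataclass(frozen=True)
class CalibrationResult:
    observed_mean: float
    expected_mean: float
    standard_error: float
    z: float
    n_sequences: int


def background_dimer_calibration(
    n_sequences: int = 500,
    seed: int = 0,
    background: BackgroundModel | None = None,
    pattern: DimerPattern = PDM3_PATTERN,
) -> CalibrationResult:
    """Chance dimer rate on unplanted backgrounds vs the analytic expectation.

    The observed per-sequence mean dimer count is compared with the
    product-of-window expectation for the same background model; ``z`` is the
    discrepancy in units of the observed standard error.
    """
    background = background or BackgroundModel()
    rng = np.random.default_rng(seed)
    motifs = {
        "Pdm3_HoxPou": _PDM3_MOTIFS,
        "Onecut_HoxCut": _ONECUT_MOTIFS,
    }[pattern.name]
    by_name = {m.name: m for m in motifs}
    counts = np.empty(n_sequences)
    for i in range(n_sequences):
        sid = f"bg_{i:04d}"
        seq = generate_background(background, rng=rng)
        occ = scan_cores(sid, seq, motifs)
        with _absent_partner_ok():
            counts[i] = len(find_dimers(occ, pattern))
    expected = expected_dimer_count(
        by_name[pattern.first_motif].pattern,
        by_name[pattern.second_motif].pattern,
        background.length,
        pattern.gap_min,
        pattern.gap_max,
        background.base_probs,
        pattern.orientation_policy,
    )
    se = float(counts.std(ddof=1) / math.sqrt(n_sequences))
    observed = float(counts.mean())
    z = (observed - expected) / se if se > 0 else math.inf * (observed != expected)
    return CalibrationResult(
        observed_mean=observed,
        expected_mean=expected,
        standard_error=se,
        z=float(z),
        n_sequences=n_sequences,
    )


def _binomial_interval(n: int, p: float, level: float = 0.95) -> tuple[int, int]:
    """Equal-tail central interval of Binomial(n, p), in counts."""
    alpha = 1.0 - level
    lo = int(stats.binom.ppf(alpha / 2, n, p))
    hi = int(stats.binom.ppf(1 - alpha / 2, n, p))
    return lo, hi


def cohort_recovery(
    n_replicates: int = 500,
    n_reg: int = 200,
    n_non: int = 200,
    p_reg: float = 0.7,
    p_non: float = 0.1,
    seed: int = 0,
    min_members: int = 2,
    max_span: int = 150,
) -> pd.DataFrame:
    """Replicate cohort simulations run through scan -> dimers -> clusters ->
    presence -> enrichment; returns one row per replicate.

    The planted element is the tandem 2x Onecut Hox/Cut dimer construct, whose
    chance rate in a 1 kb uniform background is negligible, so the detected
    presence fraction estimates the planting probability.  Columns include
    each group's estimated fraction and whether it falls inside the central
    95% binomial interval of the true planting probability.
    """
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=n_replicates)
    element = onecut_pair_template()
    lo_reg, hi_reg = _binomial_interval(n_reg, p_reg)
    lo_non, hi_non = _binomial_interval(n_non, p_non)
    rows = []
    for r in range(n_replicates):
        spec = CohortSpec(
            n_reg=n_reg,
            n_non=n_non,
            p_reg=p_reg,
            p_non=p_non,
            element=element,
            seed=int(rep_seeds[r]),
        )
        cohort = generate_cohort(spec)
        calls = {}
        with _absent_partner_ok():
            for sid, seq in cohort.records:
                occ = scan_cores(sid, seq, _ONECUT_MOTIFS)
                dimers = find_dimers(occ, ONECUT_PATTERN)
                calls[sid] = call_clusters(
                    dimers, min_members=min_members, max_span=max_span
                )
        genes = [sid for sid, _ in cohort.records]
        table = presence_table(calls, genes, ONECUT_PATTERN.name)
        result = enrichment_test(table, cohort.regulated_ids)
        k_reg = result.counts[0][0]
        k_non = result.counts[0][1]
        rows.append(
            {
                "replicate": r,
                "f_reg": result.f_reg,
                "f_non": result.f_non,
                "fold": result.fold,
                "p_exact": result.p_exact,
                "reg_in_interval": lo_reg <= k_reg <= hi_reg,
                "non_in_interval": lo_non <= k_non <= hi_non,
            }
        )
    return pd.DataFrame(rows)
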