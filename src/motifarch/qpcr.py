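"""Relative expression quantification by the comparative threshold-cycle method.

Fold change between an experimental and a control condition is 2^(-ddCt) with

    ddCt = (Ct_target,exp - Ct_ref,exp) - (Ct_target,ctrl - Ct_ref,ctrl)

where the reference gene (tubulin in the OR panels) normalizes input amounts.
Replicate Ct lists are summarized by their arithmetic mean, and the standard
error of ddCt is propagated as the root sum of squared per-condition SEMs.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from statistics import mean, stdev
from typing import Sequence

import pandas as pd

__all__ = ["DdctMeasurement", "DdctResult", "ddct_fold_change", "fold_change_table"]

_CONDITIONS = ("ct_target_exp", "ct_ref_exp", "ct_target_ctrl", "ct_ref_ctrl")


@dataclass(frozen=True)
class DdctMeasurement:
    """Threshold cycles for target and reference genes in two conditions.

    Each field is a single Ct or a list of replicate Cts (PCR cycles, finite
    and positive).
    """

    ct_target_exp: float | Sequence[float]
    ct_ref_exp: float | Sequence[float]
    ct_target_ctrl: float | Sequence[float]
    ct_ref_ctrl: float | Sequence[float]


@dataclass(frozen=True)
class DdctResult:
    delta_delta_ct: float
    fold: float
    se_delta_delta_ct: float | None  # None without replicate information

    @property
    def fold_interval(self) -> tuple[float, float] | None:
        """Fold range at ddCt +/- 1 SE (None without replicates)."""
        if self.se_delta_delta_ct is None:
            return None
        lo = 2.0 ** -(self.delta_delta_ct + self.se_delta_delta_ct)
        hi = 2.0 ** -(self.delta_delta_ct - self.se_delta_delta_ct)
        return (lo, hi)


def _summarize(name: str, value) -> tuple[float, float | None]:
    """(mean Ct, SEM or None) for one condition; validates the Ct values."""
    if value is None:
        raise ValueError(f"missing threshold cycles for condition {name!r}")
    if isinstance(value, (int, float)):
        values = [float(value)]
    else:
        values = [float(v) for v in value]
        if not values:
            raise ValueError(f"missing threshold cycles for condition {name!r}")
    for v in values:
        if not math.isfinite(v) or v <= 0:
            raise ValueError(f"condition {name!r}: Ct values must be finite and > 0")
    if len(values) < 2:
        return values[0], None
    return mean(values), stdev(values) / math.sqrt(len(values))


def ddct_fold_change(m: DdctMeasurement) -> DdctResult:
    """Fold change 2^(-ddCt) of the experimental condition relative to control."""
    means: dict[str, float] = {}
    sems: list[float | None] = []
    for name in _CONDITIONS:
        mu, sem = _summarize(name, getattr(m, name))
        means[name] = mu
        sems.append(sem)
    ddct = (means["ct_target_exp"] - means["ct_ref_exp"]) - (
        means["ct_target_ctrl"] - means["ct_ref_ctrl"]
    )
    if any(s is not None for s in sems):
        se = math.sqrt(sum((s or 0.0) ** 2 for s in sems))
    else:
        se = None
    return DdctResult(delta_delta_ct=ddct, fold=2.0 ** (-ddct), se_delta_delta_ct=se)


def fold_change_table(
    ct: pd.DataFrame,
    target: str,
    reference: str = "tubulin",
    experimental: str = "experimental",
    control: str = "control",
) -> DdctResult:
    """Run the comparative-Ct method from a long-format Ct table.

    ``ct`` needs columns ``gene``, ``condition`` and ``ct``; replicate rows
    per (gene, condition) are summarized by the mean with SEM propagation.
    """
    for col in ("gene", "condition", "ct"):
        if col not in ct.columns:
            raise ValueError(f"Ct table lacks required column {col!r}")

    def _pull(gene: str, condition: str, label: str) -> list[float]:
        rows = ct[(ct["gene"] == gene) & (ct["condition"] == condition)]
        if rows.empty:
            raise ValueError(
                f"missing threshold cycles for condition {label!r} "
                f"(gene {gene!r}, condition {condition!r})"
            )
        return rows["ct"].astype(float).tolist()

    m = DdctMeasurement(
        ct_target_exp=_pull(target, experimental, "ct_target_exp"),
        ct_ref_exp=_pull(reference, experimental, "ct_ref_exp"),
        ct_target_ctrl=_pull(target, control, "ct_target_ctrl"),
        ct_ref_ctrl=_pull(reference, control, "ct_ref_ctrl"),
    )
    return ddct_fold_change(m)
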