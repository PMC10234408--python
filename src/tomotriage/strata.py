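"""Stratified cancer-characteristic breakdowns.

For each tumour-characteristic stratum (invasiveness, density, histological
type and grade, nuclear grade, size, node status, radiographic appearance)
this module tallies, under one or more triage strategies: cancers detected,
cancers detected beyond DM-only screening ("extra"), and cancers missed
relative to giving every woman both examinations — each with an exact
binomial confidence interval on the proportion of the stratum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import CHARACTERISTIC_AXES, Cohort
from .metrics import ProportionCI, clopper_pearson
from .workflows import TriageConfig, Workflow, triage_masks

__all__ = ["StratumSummary", "StrategyStratumCounts", "characteristics_table", "strata_frame"]

#: Sentinel level meaning "recorded as missing" (kept as an explicit level,
#: distinct from an empty field, which means the axis does not apply).
MISSING_LEVEL = "missing"


@dataclass(frozen=True)
class StrategyStratumCounts:
    n_detected: int
    ci_detected: ProportionCI
    n_extra: int
    ci_extra: ProportionCI
    n_missed: int
    ci_missed: ProportionCI


@dataclass(frozen=True)
class StratumSummary:
    """One (axis, level) row: totals, DM baseline, and per-strategy counts."""

    axis: str
    level: str
    n_total: int
    n_dm_detected: int
    ci_dm_detected: ProportionCI
    strategies: dict[str, StrategyStratumCounts] = field(default_factory=dict)


def characteristics_table(
    cohort: Cohort,
    strategies: Sequence[TriageConfig],
    level: float = 0.95,
) -> list[StratumSummary]:
    """Stratified detection tallies for every populated (axis, level).

    Strata are formed over cancers only; an axis contributes the cancers for
    which it is applicable (non-empty), with explicitly-missing values kept
    as a ``missing`` level.  Proportions use the stratum size as denominator.
    Returns an empty list (with a warning) if no cancer carries any
    characteristic.
    """
    ca = cohort.cancers()
    axes = [
        a
        for a in CHARACTERISTIC_AXES
        if a in ca.columns and ca[a].fillna("").astype(str).str.len().gt(0).any()
    ]
    if not axes:
        warnings.warn("cohort carries no cancer characteristics; empty table")
        return []

    dm_recalled = ca["dm_recall"].to_numpy(bool)
    full_recalled = dm_recalled | ca["dbt_recall"].to_numpy(bool)
    per_strategy: dict[str, np.ndarray] = {}
    for cfg in strategies:
        recalled, _, _ = triage_masks(ca, cfg)
        per_strategy[cfg.label] = recalled

    out: list[StratumSummary] = []
    for axis in axes:
        values = ca[axis].fillna("").astype(str)
        applicable = values.str.len() > 0
        levels = list(dict.fromkeys(values[applicable]))  # first-seen order
        for lev in levels:
            in_stratum = (values == lev).to_numpy()
            n = int(in_stratum.sum())
            x_dm = int((in_stratum & dm_recalled).sum())
            strat_counts: dict[str, StrategyStratumCounts] = {}
            for label, recalled in per_strategy.items():
                x_det = int((in_stratum & recalled).sum())
                x_extra = int((in_stratum & recalled & ~dm_recalled).sum())
                x_miss = int((in_stratum & full_recalled & ~recalled).sum())
                strat_counts[label] = StrategyStratumCounts(
                    n_detected=x_det,
                    ci_detected=clopper_pearson(x_det, n, level),
                    n_extra=x_extra,
                    ci_extra=clopper_pearson(x_extra, n, level),
                    n_missed=x_miss,
                    ci_missed=clopper_pearson(x_miss, n, level),
                )
            out.append(
                StratumSummary(
                    axis=axis,
                    level=lev,
                    n_total=n,
                    n_dm_detected=x_dm,
                    ci_dm_detected=clopper_pearson(x_dm, n, level),
                    strategies=strat_counts,
                )
            )
    return out


def strata_frame(summaries: Sequence[StratumSummary]) -> pd.DataFrame:
    """Long-format table: one row per (axis, level, strategy, metric)."""
    rows = []
    for s in summaries:
        rows.append(
            {
                "axis": s.axis,
                "level": s.level,
                "strategy": "dm_only",
                "metric": "detected",
                "count": s.n_dm_detected,
                "n_total": s.n_total,
                "proportion": s.ci_dm_detected.point,
                "ci_lower": s.ci_dm_detected.lower,
                "ci_upper": s.ci_dm_detected.upper,
            }
        )
        for label, c in s.strategies.items():
            for metric, count, ci in (
                ("detected", c.n_detected, c.ci_detected),
                ("extra", c.n_extra, c.ci_extra),
                ("missed", c.n_missed, c.ci_missed),
            ):
                rows.append(
                    {
                        "axis": s.axis,
                        "level": s.level,
                        "strategy": label,
                        "metric": metric,
                        "count": count,
                        "n_total": s.n_total,
                        "proportion": ci.point,
                        "ci_lower": ci.lower,
                        "ci_upper": ci.upper,
                    }
                )
    return pd.DataFrame(rows)
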