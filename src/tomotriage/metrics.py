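"""Outcome statistics: strategy summaries, threshold sweeps, exact intervals.

All internal values are kept at full precision; rounding (per-1000 rates to
one decimal, percent increases half-away-from-zero to integer percent, PPV
to three decimals) happens only in the display helpers, which take a
precision argument.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .workflows import THRESHOLDED, TriageConfig, Workflow, evaluate_cohort

__all__ = [
    "OutcomeSummary",
    "ProportionCI",
    "SweepCurve",
    "clopper_pearson",
    "operating_points",
    "round_half_away",
    "strategy_table",
    "summarize",
    "summarize_strategies",
    "sweep_thresholds",
]


@dataclass
class OutcomeSummary:
    """Aggregate consequences of one strategy on one cohort.

    ``None`` marks a field that is undefined for the given denominators
    (e.g. the added-DBT detection rate when no DBT exam is performed) or not
    yet computed (baseline comparisons before :func:`summarize`); undefined
    values are never silently reported as 0.
    """

    workflow: str
    threshold: float | None
    n_total: int
    n_cancer: int
    detected: int
    fp_total: int
    fn: int
    tn: int
    n_dbt_exams: int
    n_dm_read: int
    ppv: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    rate_total_per1000: float | None = None
    extra_vs_dm: int | None = None
    pct_increase_vs_dm: float | None = None
    missed_vs_full: int | None = None
    fp_extra_vs_dm: int | None = None
    pct_fp_increase: float | None = None
    rate_added_per1000: float | None = None
    empty: bool = False

    @property
    def n_noncancer(self) -> int:
        return self.n_total - self.n_cancer

    @property
    def label(self) -> str:
        if self.threshold is not None:
            return f"{self.workflow}@{self.threshold:g}"
        return self.workflow

    def to_dict(self) -> dict:
        out = {k: v for k, v in self.__dict__.items()}
        return out


@dataclass(frozen=True)
class ProportionCI:
    """x/n with an exact (Clopper–Pearson) binomial confidence interval."""

    numerator: int
    denominator: int
    point: float
    lower: float
    upper: float
    level: float = 0.95
    method: str = "clopper_pearson"

    def __post_init__(self) -> None:
        if not (0.0 <= self.lower <= self.point <= self.upper <= 1.0):
            raise ValueError("CI ordering violated: need 0 <= lower <= point <= upper <= 1")


def clopper_pearson(x: int, n: int, level: float = 0.95) -> ProportionCI:
    """Exact binomial interval by inverting the binomial tails.

    Endpoints are the standard beta quantiles: ``lower = B(α/2; x, n−x+1)``
    and ``upper = B(1−α/2; x+1, n−x)``, with ``lower = 0`` at ``x = 0`` and
    ``upper = 1`` at ``x = n``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0 <= x <= n):
        raise ValueError("x must lie in [0, n]")
    alpha = 1.0 - level
    lower = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2, x, n - x + 1))
    upper = 1.0 if x == n else float(stats.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return ProportionCI(
        numerator=x, denominator=n, point=x / n, lower=lower, upper=upper, level=level
    )


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (the convention used for printed percents)."""
    q = Decimal(1).scaleb(-ndigits)
    d = Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP)
    return float(d)


def _pct(delta: float, base: int) -> float | None:
    return None if base == 0 else 100.0 * delta / base


def summarize(
    cohort,
    config: TriageConfig,
    baselines: Mapping[str, OutcomeSummary] | None = None,
) -> OutcomeSummary:
    """Full outcome summary for one strategy, compared against baselines.

    ``baselines`` maps ``"dm_only"`` and ``"full_both"`` to summaries
    computed on the *same* cohort; they are computed here if omitted.
    Extra detections/false positives are relative to DM-only screening;
    missed cancers are relative to giving every woman both examinations.
    """
    if baselines is None:
        baselines = {
            "dm_only": evaluate_cohort(cohort, TriageConfig(Workflow.DM_ONLY)),
            "full_both": evaluate_cohort(cohort, TriageConfig(Workflow.FULL_BOTH)),
        }
    s = evaluate_cohort(cohort, config)
    dm = baselines["dm_only"]
    full = baselines["full_both"]
    if dm.n_total != s.n_total or full.n_total != s.n_total:
        raise ValueError("baselines were not computed on the same cohort")
    s.extra_vs_dm = s.detected - dm.detected
    s.pct_increase_vs_dm = _pct(s.extra_vs_dm, dm.detected)
    s.missed_vs_full = full.detected - s.detected
    s.fp_extra_vs_dm = s.fp_total - dm.fp_total
    s.pct_fp_increase = _pct(s.fp_extra_vs_dm, dm.fp_total)
    s.rate_added_per1000 = (
        1000.0 * s.extra_vs_dm / s.n_dbt_exams if s.n_dbt_exams > 0 else None
    )
    return s


def summarize_strategies(
    cohort, configs: Sequence[TriageConfig]
) -> list[OutcomeSummary]:
    """Summaries for several strategies sharing one pair of baselines."""
    baselines = {
        "dm_only": evaluate_cohort(cohort, TriageConfig(Workflow.DM_ONLY)),
        "full_both": evaluate_cohort(cohort, TriageConfig(Workflow.FULL_BOTH)),
    }
    return [summarize(cohort, c, baselines) for c in configs]


def default_strategies(
    thresholds: Sequence[float] = (9.0, 7.5),
) -> list[TriageConfig]:
    """DM-only, then combination/precedence at each threshold, then the
    full-both and DBT-only references — the standard comparison set."""
    configs = [TriageConfig(Workflow.DM_ONLY)]
    for t in thresholds:
        configs.append(TriageConfig(Workflow.COMBINATION, t))
        configs.append(TriageConfig(Workflow.PRECEDENCE, t))
    configs.append(TriageConfig(Workflow.FULL_BOTH))
    configs.append(TriageConfig(Workflow.DBT_ONLY))
    return configs


@dataclass
class SweepCurve:
    """Outcome summaries along an increasing threshold grid."""

    workflow: str
    thresholds: list[float]
    summaries: list[OutcomeSummary]

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.thresholds, self.thresholds[1:])):
            raise ValueError("thresholds must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t, s in zip(self.thresholds, self.summaries):
            rows.append(
                {
                    "threshold": t,
                    "detected": s.detected,
                    "extra_vs_dm": s.extra_vs_dm,
                    "missed_vs_full": s.missed_vs_full,
                    "fp_total": s.fp_total,
                    "fp_extra_vs_dm": s.fp_extra_vs_dm,
                    "n_dbt_exams": s.n_dbt_exams,
                    "prop_dbt_added": s.n_dbt_exams / s.n_total if s.n_total else None,
                    "rate_added_per1000": s.rate_added_per1000,
                    "rate_total_per1000": s.rate_total_per1000,
                    "sensitivity": s.sensitivity,
                    "specificity": s.specificity,
                    "ppv": s.ppv,
                }
            )
        return pd.DataFrame(rows)


def sweep_thresholds(
    cohort, workflow: Workflow | str, grid: Iterable[float]
) -> SweepCurve:
    """Evaluate a thresholded workflow over a sorted threshold grid."""
    wf = Workflow(workflow)
    if wf not in THRESHOLDED:
        raise ValueError(f"sweep requires a thresholded workflow, got {wf.value}")
    grid = [float(t) for t in grid]
    if not grid:
        raise ValueError("threshold grid is empty")
    baselines = {
        "dm_only": evaluate_cohort(cohort, TriageConfig(Workflow.DM_ONLY)),
        "full_both": evaluate_cohort(cohort, TriageConfig(Workflow.FULL_BOTH)),
    }
    summaries = [
        summarize(cohort, TriageConfig(wf, t), baselines) for t in grid
    ]
    return SweepCurve(workflow=wf.value, thresholds=grid, summaries=summaries)


def operating_points(cohort) -> dict[str, tuple[float, float]]:
    """(sensitivity, specificity) of the three reference reading strategies."""
    if cohort.n_cancer == 0 or cohort.n_noncancer == 0:
        raise ValueError("operating points need >= 1 cancer and >= 1 non-cancer")
    points = {}
    for wf in (Workflow.DM_ONLY, Workflow.DBT_ONLY, Workflow.FULL_BOTH):
        s = evaluate_cohort(cohort, TriageConfig(wf))
        points[wf.value] = (s.sensitivity, s.specificity)
    return points


# ---------------------------------------------------------------------------
# Display
# ---------------------------------------------------------------------------


def strategy_table(
    summaries: Sequence[OutcomeSummary],
    rate_precision: int = 1,
    ppv_precision: int = 3,
) -> pd.DataFrame:
    """Flat table of the headline columns, rounded for presentation.

    Percent increases are rounded half away from zero to integer percent;
    counts are exact; internal full-precision values are untouched.
    """

    def pct(v):
        return None if v is None else int(round_half_away(v))

    rows = []
    for s in summaries:
        rows.append(
            {
                "strategy": s.label,
                "detected": s.detected,
                "extra_vs_dm": s.extra_vs_dm,
                "pct_increase": pct(s.pct_increase_vs_dm),
                "missed_vs_full": s.missed_vs_full,
                "fp_total": s.fp_total,
                "fp_extra_vs_dm": s.fp_extra_vs_dm,
                "pct_fp_increase": pct(s.pct_fp_increase),
                "ppv": None if s.ppv is None else round(s.ppv, ppv_precision),
                "n_dbt_exams": s.n_dbt_exams,
                "n_dm_read": s.n_dm_read,
                "rate_added_per1000": None
                if s.rate_added_per1000 is None
                else round_half_away(s.rate_added_per1000, rate_precision),
                "rate_total_per1000": None
                if s.rate_total_per1000 is None
                else round_half_away(s.rate_total_per1000, rate_precision),
            }
        )
    return pd.DataFrame(rows)
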