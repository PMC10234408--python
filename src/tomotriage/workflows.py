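"""Triage workflows: per-woman and cohort-level recall logic.

Five strategies are evaluated:

* ``dm_only`` — DM double reading for everyone (the baseline programme).
* ``dbt_only`` — DBT double reading for everyone; no DM exam performed.
* ``full_both`` — both arms for everyone; recall if either arm recalls.
* ``combination`` — DBT is added when the AI score strictly exceeds the
  threshold; for those women recall is the union of the two arms' decisions.
* ``precedence`` — DBT is added above the threshold and its double-reading
  result *replaces* the DM reading (the DM exam is still acquired, so its
  dose accrues, but it is not read).

Ties at the threshold go to no-DBT (strict ``score > t`` comparison).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .cohort import Cohort, ScreeningRecord
    from .metrics import OutcomeSummary

__all__ = [
    "TriageConfig",
    "WomanOutcome",
    "Workflow",
    "evaluate_cohort",
    "evaluate_woman",
    "triage_masks",
    "woman_outcomes",
]


class Workflow(str, Enum):
    DM_ONLY = "dm_only"
    DBT_ONLY = "dbt_only"
    FULL_BOTH = "full_both"
    COMBINATION = "combination"
    PRECEDENCE = "precedence"


#: Workflows whose behaviour depends on the AI-score threshold.
THRESHOLDED = (Workflow.COMBINATION, Workflow.PRECEDENCE)


@dataclass(frozen=True)
class TriageConfig:
    """Strategy selector: workflow, and — for triage workflows — threshold.

    ``comparison`` is ``strict_greater`` (DBT added iff ``score > threshold``);
    the field exists so other tie rules could be added without changing the
    config surface.
    """

    workflow: Workflow
    threshold: float | None = None
    comparison: str = "strict_greater"

    def __post_init__(self) -> None:
        wf = Workflow(self.workflow)
        object.__setattr__(self, "workflow", wf)
        if wf in THRESHOLDED:
            if self.threshold is None:
                raise ValueError(f"{wf.value} requires a threshold")
            if not (0.0 <= self.threshold <= 10.0):
                raise ValueError("threshold must lie in [0, 10]")
        elif self.threshold is not None:
            raise ValueError(f"{wf.value} does not take a threshold")
        if self.comparison != "strict_greater":
            raise ValueError(f"unknown comparison {self.comparison!r}")

    @property
    def label(self) -> str:
        if self.workflow in THRESHOLDED:
            return f"{self.workflow.value}@{self.threshold:g}"
        return self.workflow.value


@dataclass(frozen=True)
class WomanOutcome:
    """Per-woman consequence of a strategy (audit granularity)."""

    woman_id: str
    dbt_performed: bool
    dm_read: bool
    recalled: bool
    outcome_class: str  # TP | FP | FN | TN


def triage_masks(
    df: pd.DataFrame, config: TriageConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(recalled, dbt_performed, dm_read) boolean arrays for a cohort table."""
    dm = df["dm_recall"].to_numpy(bool)
    dbt = df["dbt_recall"].to_numpy(bool)
    n = len(df)
    wf = config.workflow
    if wf is Workflow.DM_ONLY:
        return dm, np.zeros(n, bool), np.ones(n, bool)
    if wf is Workflow.DBT_ONLY:
        return dbt, np.ones(n, bool), np.zeros(n, bool)
    if wf is Workflow.FULL_BOTH:
        return dm | dbt, np.ones(n, bool), np.ones(n, bool)
    above = df["ai_score"].to_numpy(float) > config.threshold
    if wf is Workflow.COMBINATION:
        return np.where(above, dm | dbt, dm), above, np.ones(n, bool)
    # precedence: DBT result replaces the (unread) DM reading above threshold
    return np.where(above, dbt, dm), above, ~above


def evaluate_woman(record: "ScreeningRecord", config: TriageConfig) -> WomanOutcome:
    """Apply the strategy's recall logic to a single screening record."""
    df = pd.DataFrame(
        {
            "dm_recall": [record.dm_recall],
            "dbt_recall": [record.dbt_recall],
            "ai_score": [record.ai_score],
        }
    )
    recalled, dbt_performed, dm_read = (m[0] for m in triage_masks(df, config))
    if record.has_cancer:
        outcome = "TP" if recalled else "FN"
    else:
        outcome = "FP" if recalled else "TN"
    return WomanOutcome(
        woman_id=record.woman_id,
        dbt_performed=bool(dbt_performed),
        dm_read=bool(dm_read),
        recalled=bool(recalled),
        outcome_class=outcome,
    )


def woman_outcomes(cohort: "Cohort", config: TriageConfig) -> pd.DataFrame:
    """Per-woman outcome table (columns mirror :class:`WomanOutcome`)."""
    df = cohort.df
    recalled, dbt_performed, dm_read = triage_masks(df, config)
    ca = df["has_cancer"].to_numpy(bool)
    outcome = np.where(
        ca, np.where(recalled, "TP", "FN"), np.where(recalled, "FP", "TN")
    )
    return pd.DataFrame(
        {
            "woman_id": df["woman_id"].to_numpy(),
            "dbt_performed": dbt_performed,
            "dm_read": dm_read,
            "recalled": recalled,
            "outcome_class": outcome,
        }
    )


def evaluate_cohort(cohort: "Cohort", config: TriageConfig) -> "OutcomeSummary":
    """Aggregate a strategy over a cohort.

    Fills the baseline-free fields of :class:`~tomotriage.metrics.OutcomeSummary`
    (detected, false positives, exam counts, PPV, sensitivity, specificity,
    total detection rate); comparisons against the DM-only and full-both
    baselines are added by :func:`tomotriage.metrics.summarize`.
    """
    from .metrics import OutcomeSummary

    df = cohort.df
    n = len(df)
    if n == 0:
        return OutcomeSummary(
            workflow=config.workflow.value,
            threshold=config.threshold,
            n_total=0,
            n_cancer=0,
            detected=0,
            fp_total=0,
            fn=0,
            tn=0,
            n_dbt_exams=0,
            n_dm_read=0,
            empty=True,
        )
    recalled, dbt_performed, dm_read = triage_masks(df, config)
    ca = df["has_cancer"].to_numpy(bool)
    tp = int((recalled & ca).sum())
    fp = int((recalled & ~ca).sum())
    n_ca = int(ca.sum())
    n_no = n - n_ca
    return OutcomeSummary(
        workflow=config.workflow.value,
        threshold=config.threshold,
        n_total=n,
        n_cancer=n_ca,
        detected=tp,
        fp_total=fp,
        fn=n_ca - tp,
        tn=n_no - fp,
        n_dbt_exams=int(dbt_performed.sum()),
        n_dm_read=int(dm_read.sum()),
        ppv=tp / (tp + fp) if tp + fp > 0 else None,
        sensitivity=tp / n_ca if n_ca > 0 else None,
        specificity=1.0 - fp / n_no if n_no > 0 else None,
        rate_total_per1000=1000.0 * tp / n,
    )
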