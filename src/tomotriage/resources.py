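"""Resource models: population organ dose and relative reading time.

Adding tomosynthesis for above-threshold women costs radiation dose and
radiologist reading time.  This module aggregates per-woman organ dose under
a triage strategy and applies a simple multiplier model for the relative
change in total screen-reading time versus an all-DM programme.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
from scipy import stats

if TYPE_CHECKING:  # pragma: no cover
    from .cohort import Cohort
    from .workflows import TriageConfig

__all__ = [
    "DoseParams",
    "DoseSummary",
    "ReadingTimeParams",
    "draw_doses",
    "population_mean_dose",
    "reading_time_change",
]


@dataclass(frozen=True)
class DoseParams:
    """Per-modality organ-dose distributions (mGy), truncated normal at 0.

    Defaults are the per-examination means/SDs of the MBTST material:
    2.69 (0.778) mGy for the two-view DM exam, 2.24 (0.672) mGy for the
    one-view DBT exam; women examined with both averaged 4.91 (1.347) mGy.
    ``both_mean_mGy``/``both_sd`` are reference constants, not sampled.
    """

    dm_mean_mGy: float = 2.69
    dm_sd: float = 0.778
    dbt_mean_mGy: float = 2.24
    dbt_sd: float = 0.672
    both_mean_mGy: float = 4.91
    both_sd: float = 1.347
    family: str = "truncnorm"

    def __post_init__(self) -> None:
        if self.dm_mean_mGy <= 0 or self.dbt_mean_mGy <= 0:
            raise ValueError("dose means must be positive")
        if self.dm_sd < 0 or self.dbt_sd < 0:
            raise ValueError("dose SDs must be nonnegative")
        if self.family != "truncnorm":
            raise ValueError(f"unknown dose distribution family {self.family!r}")


def draw_doses(
    params: DoseParams, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Sample per-woman (DM, DBT) organ doses, independent of everything else."""

    def trunc(mean: float, sd: float) -> np.ndarray:
        if sd == 0:
            return np.full(n, mean)
        a = (0.0 - mean) / sd
        return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n, random_state=rng)

    return trunc(params.dm_mean_mGy, params.dm_sd), trunc(
        params.dbt_mean_mGy, params.dbt_sd
    )


@dataclass(frozen=True)
class ReadingTimeParams:
    """Relative reading-time multipliers versus reading a DM exam alone.

    ``rel_dbt_alone`` — reading DBT instead of DM (≈ +75%);
    ``rel_dm_plus_dbt`` — reading DM and DBT together (≈ +125%).
    """

    rel_dbt_alone: float = 1.75
    rel_dm_plus_dbt: float = 2.25

    def __post_init__(self) -> None:
        if self.rel_dbt_alone < 1 or self.rel_dm_plus_dbt < 1:
            raise ValueError("relative reading times must be >= 1")


@dataclass(frozen=True)
class DoseSummary:
    mean_mGy: float
    sd_mGy: float
    n: int


def population_mean_dose(cohort: "Cohort", config: "TriageConfig") -> DoseSummary:
    """Mean (and SD) organ dose per woman under a triage strategy.

    A woman's dose is the DM dose if a DM exam is performed plus the DBT dose
    if DBT is performed.  DM is performed for every woman in every workflow
    except DBT-only screening — in the precedence workflow the DM exam is
    acquired even when it is not read, so its dose still accrues.
    """
    from .workflows import Workflow, triage_masks

    df = cohort.df
    for col in ("dose_dm_mGy", "dose_dbt_mGy"):
        bad = df.loc[df[col].isna(), "woman_id"]
        if len(bad):
            raise ValueError(
                f"missing {col} on records: {list(bad[:10])}"
                + ("..." if len(bad) > 10 else "")
            )
    _, dbt_performed, _ = triage_masks(df, config)
    dm_performed = config.workflow != Workflow.DBT_ONLY
    total = df["dose_dbt_mGy"].to_numpy() * dbt_performed
    if dm_performed:
        total = total + df["dose_dm_mGy"].to_numpy()
    return DoseSummary(
        mean_mGy=float(np.mean(total)), sd_mGy=float(np.std(total, ddof=1)), n=len(df)
    )


def reading_time_change(
    fraction_converted: float,
    workflow: "Workflow | str",
    params: ReadingTimeParams | None = None,
) -> float:
    """Percent change in total reading time versus reading DM for everyone.

    ``fraction_converted`` is the fraction of women whose screen is upgraded
    (DBT added).  Combination reads DM+DBT together for those women
    (multiplier ``rel_dm_plus_dbt``); precedence reads DBT instead of DM
    (``rel_dbt_alone``).  Full precision is returned; rounding is left to
    the display layer.
    """
    from .workflows import Workflow

    params = params if params is not None else ReadingTimeParams()
    if not (0.0 <= fraction_converted <= 1.0):
        raise ValueError("fraction_converted must lie in [0, 1]")
    wf = Workflow(workflow)
    if wf in (Workflow.COMBINATION, Workflow.FULL_BOTH):
        return fraction_converted * (params.rel_dm_plus_dbt - 1.0) * 100.0
    if wf in (Workflow.PRECEDENCE, Workflow.DBT_ONLY):
        return fraction_converted * (params.rel_dbt_alone - 1.0) * 100.0
    return 0.0
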