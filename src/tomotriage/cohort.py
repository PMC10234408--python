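"""Cohort data model, deterministic reference-cohort construction, and simulation.

A screening cohort is one row per woman: cancer status, the recall decision of
each double-reading arm (two-view digital mammography, DM, and one-view
tomosynthesis, DBT), a decimal AI risk score in (0, 10], per-modality organ
doses, and — for cancers — optional tumour-characteristic categories.

Two ways of obtaining a cohort are provided:

* :func:`build_fixture_cohort` constructs a deterministic cohort that exactly
  reproduces a set of printed joint counts (arm detection/false-positive
  marginals, overlaps, and above-threshold decompositions).  The default
  constraints, :func:`mbtst_constraints`, encode the Malmö Breast
  Tomosynthesis Screening Trial (MBTST) study population of 14,768 women.
* :func:`simulate_cohort` draws stochastic cohorts from a parametric model
  with correlated per-arm recall decisions and decile-calibrated AI scores.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, fields
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .resources import DoseParams, draw_doses

__all__ = [
    "CHARACTERISTIC_AXES",
    "COHORT_COLUMNS",
    "Cohort",
    "FixtureConstraints",
    "FixtureError",
    "ScreeningRecord",
    "SimulationParams",
    "ThresholdBlock",
    "ValidationReport",
    "build_fixture_cohort",
    "build_mbtst_cohort",
    "mbtst_constraints",
    "read_cohort",
    "simulate_cohort",
    "tally_constraints",
    "validate_cohort",
    "write_cohort",
]

#: Core columns of the cohort table, in serialization order.
COHORT_COLUMNS = [
    "woman_id",
    "has_cancer",
    "dm_recall",
    "dbt_recall",
    "ai_score",
    "dose_dm_mGy",
    "dose_dbt_mGy",
]

#: Cancer-characteristic axes (optional columns; empty when not applicable).
CHARACTERISTIC_AXES = [
    "invasiveness",
    "density",
    "histology",
    "histological_grade",
    "nuclear_grade",
    "size_cat",
    "node_status",
    "appearance",
]


@dataclass
class ScreeningRecord:
    """One woman's screen: truth, per-arm recall decisions, score, doses."""

    woman_id: str
    has_cancer: bool
    dm_recall: bool
    dbt_recall: bool
    ai_score: float
    dose_dm_mGy: float = 0.0
    dose_dbt_mGy: float = 0.0
    characteristics: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.ai_score <= 10.0):
            raise ValueError(
                f"ai_score must lie in (0, 10], got {self.ai_score!r}"
            )
        if self.dose_dm_mGy < 0 or self.dose_dbt_mGy < 0:
            raise ValueError("organ doses must be nonnegative")
        if self.characteristics and not self.has_cancer:
            raise ValueError("characteristics are only valid for cancers")

    @property
    def score_bin(self) -> int:
        """Integer score bin 1..10 (decimal score rounded up)."""
        return int(math.ceil(self.ai_score))


@dataclass
class Cohort:
    """An ordered collection of screening records backed by a DataFrame.

    ``df`` holds one row per woman with :data:`COHORT_COLUMNS` plus any
    characteristic columns.  ``provenance`` records how the cohort came to
    be (``fixture``, ``simulated`` or ``loaded``) together with the seed and
    a digest of the generating parameters, so a run can be reproduced
    exactly.
    """

    df: pd.DataFrame
    provenance: str = "loaded"
    seed: int | None = None
    params_digest: str | None = None

    def __post_init__(self) -> None:
        missing = [c for c in COHORT_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"cohort table lacks columns: {missing}")
        if self.df["woman_id"].duplicated().any():
            dupes = self.df.loc[self.df["woman_id"].duplicated(), "woman_id"]
            raise ValueError(f"duplicate woman_id values: {list(dupes[:5])}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_cancer(self) -> int:
        return int(self.df["has_cancer"].sum())

    @property
    def n_noncancer(self) -> int:
        return len(self.df) - self.n_cancer

    def cancers(self) -> pd.DataFrame:
        return self.df[self.df["has_cancer"]]

    def records(self) -> Iterator[ScreeningRecord]:
        axes = [a for a in CHARACTERISTIC_AXES if a in self.df.columns]
        for row in self.df.itertuples(index=False):
            chars = None
            if getattr(row, "has_cancer") and axes:
                chars = {
                    a: getattr(row, a)
                    for a in axes
                    if isinstance(getattr(row, a), str) and getattr(row, a)
                }
                chars = chars or None
            yield ScreeningRecord(
                woman_id=str(row.woman_id),
                has_cancer=bool(row.has_cancer),
                dm_recall=bool(row.dm_recall),
                dbt_recall=bool(row.dbt_recall),
                ai_score=float(row.ai_score),
                dose_dm_mGy=float(row.dose_dm_mGy),
                dose_dbt_mGy=float(row.dose_dbt_mGy),
                characteristics=chars,
            )


# ---------------------------------------------------------------------------
# Fixture constraints
# ---------------------------------------------------------------------------


class FixtureError(ValueError):
    """A set of fixture constraints is internally inconsistent.

    ``constraint`` names the violated rule.
    """

    def __init__(self, constraint: str, message: str):
        self.constraint = constraint
        super().__init__(f"[{constraint}] {message}")


@dataclass(frozen=True)
class ThresholdBlock:
    """Above-threshold decomposition printed for one AI-score threshold.

    Counts are of women with ``ai_score`` strictly greater than the
    threshold: all women, DBT-only-detected cancers, DM-only-detected
    cancers, DBT-only false positives and DM-only false positives.
    """

    n_above: int
    n_dbtonly_cancer_above: int
    n_dmonly_cancer_above: int
    n_dbtonly_fp_above: int
    n_dmonly_fp_above: int


@dataclass(frozen=True)
class FixtureConstraints:
    """Joint counts a deterministic cohort must reproduce exactly.

    Marginals cover cancer detection by each reading arm (with overlap) and
    arm false positives (with union); ``blocks`` adds, per AI-score
    threshold, the above-threshold decomposition.  ``band_scores`` optionally
    pins the representative decimal score of each inter-threshold band
    (highest band first, then down to the sub-threshold band); if omitted,
    band midpoints are used.
    """

    n_total: int = 14768
    n_cancer: int = 136
    n_dm_detected: int = 95
    n_dbt_detected: int = 128
    n_both_detected: int = 87
    n_dm_fp: int = 271
    n_dbt_fp: int = 404
    n_union_fp: int = 521
    blocks: Mapping[float, ThresholdBlock] = field(default_factory=dict)
    band_scores: tuple[float, ...] | None = None

    # -- derived marginals -------------------------------------------------
    @property
    def n_dmonly_cancer(self) -> int:
        return self.n_dm_detected - self.n_both_detected

    @property
    def n_dbtonly_cancer(self) -> int:
        return self.n_dbt_detected - self.n_both_detected

    @property
    def n_neither_cancer(self) -> int:
        return self.n_cancer - (
            self.n_dm_detected + self.n_dbt_detected - self.n_both_detected
        )

    @property
    def n_both_fp(self) -> int:
        return self.n_dm_fp + self.n_dbt_fp - self.n_union_fp

    @property
    def n_dmonly_fp(self) -> int:
        return self.n_dm_fp - self.n_both_fp

    @property
    def n_dbtonly_fp(self) -> int:
        return self.n_dbt_fp - self.n_both_fp

    @property
    def n_tn(self) -> int:
        return self.n_total - self.n_cancer - self.n_union_fp

    @property
    def thresholds(self) -> list[float]:
        """Block thresholds sorted descending."""
        return sorted(self.blocks, reverse=True)

    # -- consistency -------------------------------------------------------
    def validate(self) -> None:
        """Raise :class:`FixtureError` naming the first violated constraint."""
        for f in fields(self):
            if f.name in ("blocks", "band_scores"):
                continue
            if getattr(self, f.name) < 0:
                raise FixtureError(f.name, "count must be nonnegative")
        if self.n_cancer > self.n_total:
            raise FixtureError("n_cancer", "more cancers than women")
        if self.n_both_detected > min(self.n_dm_detected, self.n_dbt_detected):
            raise FixtureError(
                "n_both_detected", "overlap exceeds an arm marginal"
            )
        if self.n_neither_cancer < 0:
            raise FixtureError(
                "detection_union",
                "n_dm_detected + n_dbt_detected - n_both_detected exceeds n_cancer",
            )
        if self.n_union_fp > max(0, self.n_total - self.n_cancer):
            raise FixtureError("n_union_fp", "more false positives than non-cancers")
        if self.n_union_fp < max(self.n_dm_fp, self.n_dbt_fp):
            raise FixtureError("n_union_fp", "union smaller than an arm marginal")
        if self.n_both_fp < 0:
            raise FixtureError("n_union_fp", "union exceeds sum of arm marginals")

        marg = {
            "n_dbtonly_cancer_above": self.n_dbtonly_cancer,
            "n_dmonly_cancer_above": self.n_dmonly_cancer,
            "n_dbtonly_fp_above": self.n_dbtonly_fp,
            "n_dmonly_fp_above": self.n_dmonly_fp,
        }
        prev: ThresholdBlock | None = None
        for t in self.thresholds:
            blk = self.blocks[t]
            if blk.n_above > self.n_total:
                raise FixtureError(f"block[{t}].n_above", "exceeds n_total")
            for name, m in marg.items():
                v = getattr(blk, name)
                if v < 0:
                    raise FixtureError(f"block[{t}].{name}", "negative count")
                if v > m:
                    raise FixtureError(
                        f"block[{t}].{name}", f"exceeds marginal {m}"
                    )
            if prev is not None:
                # higher threshold ⇒ componentwise ≤ lower threshold
                for name in ("n_above", *marg):
                    if getattr(prev, name) > getattr(blk, name):
                        raise FixtureError(
                            f"block[{t}].{name}",
                            "block at higher threshold exceeds lower-threshold block",
                        )
            prev = blk
        self._band_table()  # raises on infeasible band fills

    def _band_table(self) -> pd.DataFrame:
        """Per-band category counts implied by the constraints.

        Bands are indexed top-down: band 0 is scores above the highest
        threshold, band k is the sub-threshold remainder.  The four
        threshold-constrained categories are decomposed by differencing
        consecutive blocks; both-arm cancers/FPs and women recalled by
        neither arm sit in the bottom band; true negatives fill each
        band up to its exact ``n_above`` difference.
        """
        ts = self.thresholds
        cats = [
            ("dbt_only_cancer", "n_dbtonly_cancer_above", self.n_dbtonly_cancer),
            ("dm_only_cancer", "n_dmonly_cancer_above", self.n_dmonly_cancer),
            ("dbt_only_fp", "n_dbtonly_fp_above", self.n_dbtonly_fp),
            ("dm_only_fp", "n_dmonly_fp_above", self.n_dmonly_fp),
        ]
        nbands = len(ts) + 1
        table = pd.DataFrame(
            0,
            index=range(nbands),
            columns=[c for c, _, _ in cats]
            + ["both_cancer", "neither_cancer", "both_fp", "tn"],
        )
        cum_prev = {c: 0 for c, _, _ in cats}
        n_above_prev = 0
        for i, t in enumerate(ts):
            blk = self.blocks[t]
            band_constrained = 0
            for cat, attr, _ in cats:
                d = getattr(blk, attr) - cum_prev[cat]
                if d < 0:  # guarded already by monotonicity check
                    raise FixtureError(f"block[{t}].{attr}", "non-monotone")
                table.loc[i, cat] = d
                cum_prev[cat] = getattr(blk, attr)
                band_constrained += d
            band_n = blk.n_above - n_above_prev
            if band_n < 0:
                raise FixtureError(f"block[{t}].n_above", "non-monotone")
            fill = band_n - band_constrained
            if fill < 0:
                raise FixtureError(
                    f"block[{t}]",
                    f"constrained categories ({band_constrained}) exceed the "
                    f"band's n_above difference ({band_n})",
                )
            table.loc[i, "tn"] = fill
            n_above_prev = blk.n_above
        # bottom band: marginal remainders + all unconstrained categories
        for cat, _, m in cats:
            table.loc[nbands - 1, cat] = m - cum_prev[cat]
        table.loc[nbands - 1, "both_cancer"] = self.n_both_detected
        table.loc[nbands - 1, "neither_cancer"] = self.n_neither_cancer
        table.loc[nbands - 1, "both_fp"] = self.n_both_fp
        tn_bottom = self.n_tn - int(table["tn"].sum())
        if tn_bottom < 0:
            raise FixtureError(
                "n_total",
                "true negatives insufficient to fill the above-threshold bands",
            )
        table.loc[nbands - 1, "tn"] = tn_bottom
        if int(table.to_numpy().sum()) != self.n_total:
            raise FixtureError("n_total", "band table does not sum to n_total")
        return table

    def band_score(self, band: int) -> float:
        """Representative decimal score of band (0 = top)."""
        ts = self.thresholds
        if self.band_scores is not None:
            return float(self.band_scores[band])
        hi = 10.0 if band == 0 else ts[band - 1]
        lo = ts[band] if band < len(ts) else 0.0
        return (lo + hi) / 2.0


def mbtst_constraints() -> FixtureConstraints:
    """Joint counts of the MBTST study population (n = 14,768).

    136 cancers (95 DM-detected, 128 DBT-detected, 87 by both; 8 DM-only,
    41 DBT-only); 271 DM false positives, 404 DBT, union 521.  Blocks give
    the above-threshold decompositions at AI-score thresholds 9.0 and 7.5.
    Representative scores 9.5 / 8.25 / 4.0 for the three bands.
    """
    return FixtureConstraints(
        blocks={
            9.0: ThresholdBlock(
                n_above=1493,
                n_dbtonly_cancer_above=24,
                n_dmonly_cancer_above=7,
                n_dbtonly_fp_above=60,
                n_dmonly_fp_above=30,
            ),
            7.5: ThresholdBlock(
                n_above=3251,
                n_dbtonly_cancer_above=31,
                n_dmonly_cancer_above=8,
                n_dbtonly_fp_above=103,
                n_dmonly_fp_above=52,
            ),
        },
        band_scores=(9.5, 8.25, 4.0),
    )


# category -> (has_cancer, dm_recall, dbt_recall)
_CATEGORY_FLAGS = {
    "both_cancer": (True, True, True),
    "dm_only_cancer": (True, True, False),
    "dbt_only_cancer": (True, False, True),
    "neither_cancer": (True, False, False),
    "both_fp": (False, True, True),
    "dm_only_fp": (False, True, False),
    "dbt_only_fp": (False, False, True),
    "tn": (False, False, False),
}


def build_fixture_cohort(
    constraints: FixtureConstraints | None = None,
    seed: int = 0,
    dose_params: DoseParams | None = None,
) -> Cohort:
    """Build a deterministic cohort that re-tallies to ``constraints`` exactly.

    Women are laid out band by band (highest scores first); within a band,
    recall categories in a fixed order.  Every woman in a band receives that
    band's representative decimal score, so each threshold block is satisfied
    by construction.  Organ doses are drawn from ``dose_params`` (truncated
    normals, independent of score) with the given ``seed``; all structural
    columns are seed-independent.
    """
    constraints = constraints if constraints is not None else mbtst_constraints()
    constraints.validate()
    table = constraints._band_table()
    dose_params = dose_params if dose_params is not None else DoseParams()

    has_cancer: list[bool] = []
    dm: list[bool] = []
    dbt: list[bool] = []
    score: list[float] = []
    for band in table.index:
        s = constraints.band_score(band)
        for cat in table.columns:
            c, d, b = _CATEGORY_FLAGS[cat]
            k = int(table.loc[band, cat])
            has_cancer += [c] * k
            dm += [d] * k
            dbt += [b] * k
            score += [s] * k

    n = len(score)
    rng = np.random.default_rng(seed)
    dose_dm, dose_dbt = draw_doses(dose_params, n, rng)
    width = max(5, len(str(n)))
    df = pd.DataFrame(
        {
            "woman_id": [f"W{i:0{width}d}" for i in range(1, n + 1)],
            "has_cancer": has_cancer,
            "dm_recall": dm,
            "dbt_recall": dbt,
            "ai_score": score,
            "dose_dm_mGy": dose_dm,
            "dose_dbt_mGy": dose_dbt,
        }
    )
    return Cohort(
        df,
        provenance="fixture",
        seed=seed,
        params_digest=_digest(constraints),
    )


def tally_constraints(
    cohort: Cohort, thresholds: Iterable[float]
) -> FixtureConstraints:
    """Re-tally a cohort into the :class:`FixtureConstraints` form.

    Inverse of :func:`build_fixture_cohort`: counting detection marginals,
    false-positive marginals and the above-threshold decomposition at each
    threshold directly from the records.
    """
    df = cohort.df
    ca = df["has_cancer"].to_numpy(bool)
    dm = df["dm_recall"].to_numpy(bool)
    dbt = df["dbt_recall"].to_numpy(bool)
    s = df["ai_score"].to_numpy(float)
    blocks = {}
    for t in thresholds:
        above = s > t
        blocks[float(t)] = ThresholdBlock(
            n_above=int(above.sum()),
            n_dbtonly_cancer_above=int((above & ca & dbt & ~dm).sum()),
            n_dmonly_cancer_above=int((above & ca & dm & ~dbt).sum()),
            n_dbtonly_fp_above=int((above & ~ca & dbt & ~dm).sum()),
            n_dmonly_fp_above=int((above & ~ca & dm & ~dbt).sum()),
        )
    return FixtureConstraints(
        n_total=len(df),
        n_cancer=int(ca.sum()),
        n_dm_detected=int((ca & dm).sum()),
        n_dbt_detected=int((ca & dbt).sum()),
        n_both_detected=int((ca & dm & dbt).sum()),
        n_dm_fp=int((~ca & dm).sum()),
        n_dbt_fp=int((~ca & dbt).sum()),
        n_union_fp=int((~ca & (dm | dbt)).sum()),
        blocks=blocks,
    )


# ---------------------------------------------------------------------------
# Characteristic assignment for the MBTST fixture
# ---------------------------------------------------------------------------

# Invasive counts per (recall category, band index): aligned with the printed
# per-strategy characteristic breakdowns, which pin the invasive/in-situ split
# of the extra-detected (DBT-only above threshold) and missed (DBT-only below)
# cancers at both thresholds, and of the DM-detected cancers overall.
_MBTST_INVASIVE = {
    ("dbt_only_cancer", 0): (24, 23),  # (cell size, invasive)
    ("dbt_only_cancer", 1): (7, 5),
    ("dbt_only_cancer", 2): (10, 9),
    ("dm_only_cancer", 0): (7, 7),
    ("dm_only_cancer", 1): (1, 1),
    ("both_cancer", 2): (87, 71),
}

# Per-axis level blocks (level, count), assigned deterministically over
# cancers ordered invasive-first.  Marginals match the printed table exactly.
_MBTST_AXIS_BLOCKS: dict[str, list[tuple[str, int]]] = {
    "density": [("1", 10), ("2", 43), ("3", 63), ("4", 20)],
    "size_cat": [
        ("<=10", 49),
        ("11-15", 44),
        ("16-19", 14),
        (">=20", 27),
        ("missing", 2),
    ],
    "node_status": [("positive", 29), ("negative", 94), ("missing", 13)],
    "appearance": [
        ("spiculated_mass", 91),
        ("circumscribed_mass", 18),
        ("microcalcifications", 22),
        ("distortion", 4),
        ("lymph_node", 1),
    ],
}
_MBTST_HISTOLOGY_INVASIVE = [
    ("invasive_ductal", 74),
    ("invasive_lobular", 24),
    ("tubular", 17),
    ("other_invasive", 1),
]
_MBTST_HISTGRADE_INVASIVE = [("1", 45), ("2", 52), ("3", 17), ("missing", 2)]
_MBTST_NUCLEARGRADE_INSITU = [("1", 2), ("2", 7), ("3", 11)]


def _expand(blocks: Sequence[tuple[str, int]]) -> list[str]:
    out: list[str] = []
    for level, k in blocks:
        out += [level] * k
    return out


def assign_mbtst_characteristics(cohort: Cohort) -> Cohort:
    """Attach tumour characteristics to the cancers of the MBTST fixture.

    Invasiveness is assigned per recall-category × score-band cell so the
    per-strategy invasive/in-situ breakdowns are exact at thresholds 9.0 and
    7.5.  The remaining axes receive their printed marginal counts blockwise
    over a deterministic ordering (invasive cancers first); their joint
    distribution with recall category is not pinned by any printed number.
    Grade axes apply only to their subset: histological grade to invasive
    cancers, nuclear grade to in-situ; the sentinel level ``missing`` marks
    cancers whose value was not recorded, while an empty field means the
    axis does not apply.
    """
    df = cohort.df.copy()
    ca = df["has_cancer"]
    dm = df["dm_recall"]
    dbt = df["dbt_recall"]
    s = df["ai_score"]
    band = np.where(s > 9.0, 0, np.where(s > 7.5, 1, 2))
    category = np.select(
        [ca & dm & dbt, ca & dm & ~dbt, ca & ~dm & dbt],
        ["both_cancer", "dm_only_cancer", "dbt_only_cancer"],
        default="",
    )

    for axis in CHARACTERISTIC_AXES:
        df[axis] = ""

    # invasiveness per constrained cell
    for (cat, b), (size, n_inv) in _MBTST_INVASIVE.items():
        idx = df.index[(category == cat) & (band == b)]
        if len(idx) != size:
            raise FixtureError(
                "characteristics",
                f"cell {cat}/band{b} has {len(idx)} cancers, expected {size}",
            )
        df.loc[idx[:n_inv], "invasiveness"] = "invasive"
        df.loc[idx[n_inv:], "invasiveness"] = "in_situ"

    inv_idx = df.index[df["invasiveness"] == "invasive"]
    ins_idx = df.index[df["invasiveness"] == "in_situ"]
    df.loc[inv_idx, "histology"] = _expand(_MBTST_HISTOLOGY_INVASIVE)
    df.loc[ins_idx, "histology"] = "dcis"
    df.loc[inv_idx, "histological_grade"] = _expand(_MBTST_HISTGRADE_INVASIVE)
    df.loc[ins_idx, "nuclear_grade"] = _expand(_MBTST_NUCLEARGRADE_INSITU)

    all_ca_idx = inv_idx.append(ins_idx)
    for axis, blocks in _MBTST_AXIS_BLOCKS.items():
        df.loc[all_ca_idx, axis] = _expand(blocks)

    return Cohort(
        df,
        provenance=cohort.provenance,
        seed=cohort.seed,
        params_digest=cohort.params_digest,
    )


def build_mbtst_cohort(seed: int = 0, characteristics: bool = True) -> Cohort:
    """The deterministic MBTST reference cohort (14,768 women).

    Convenience wrapper: default constraints, representative band scores
    9.5 / 8.25 / 4.0, doses at the study's per-modality means/SDs, and — by
    default — tumour characteristics attached to the 136 cancers.
    """
    cohort = build_fixture_cohort(mbtst_constraints(), seed=seed)
    if characteristics:
        cohort = assign_mbtst_characteristics(cohort)
    return cohort


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


def _default_cancer_weights() -> tuple[float, ...]:
    # decile-calibrated detector: >85% of cancers score in bin 10
    return tuple([0.13 / 9] * 9 + [0.87])


def _default_normal_weights() -> tuple[float, ...]:
    return tuple([0.1] * 10)


@dataclass(frozen=True)
class SimulationParams:
    """Generative model for stochastic synthetic cohorts.

    Per woman, independently: cancer status ~ Bernoulli(``prevalence``); the
    (DM recall, DBT recall) pair is drawn from the 2×2 distribution implied
    by the marginal sensitivities and their joint (for cancers) or by the
    false-positive rates and their joint (for non-cancers); the AI score is
    drawn class-conditionally — an integer bin from the weight vector, then
    uniform within the bin ``(k-1, k]``; doses are truncated normals
    independent of everything else.

    ``score_recall_association`` in [0, 1] optionally couples cancer scores
    to DBT detection: that fraction of cancers has its recall pairs matched
    to scores in descending order (DBT-recalled first), 0 = independence.

    Defaults are calibrated to the MBTST marginals.
    """

    n_total: int = 14768
    prevalence: float = 136 / 14768
    sens_dm: float = 95 / 136
    sens_dbt: float = 128 / 136
    sens_both: float = 87 / 136
    fp_rate_dm: float = 271 / 14632
    fp_rate_dbt: float = 404 / 14632
    fp_rate_both: float = 154 / 14632
    cancer_score_weights: tuple[float, ...] = field(
        default_factory=_default_cancer_weights
    )
    normal_score_weights: tuple[float, ...] = field(
        default_factory=_default_normal_weights
    )
    score_recall_association: float = 0.0
    dose_params: DoseParams = field(default_factory=DoseParams)
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "prevalence",
            "sens_dm",
            "sens_dbt",
            "sens_both",
            "fp_rate_dm",
            "fp_rate_dbt",
            "fp_rate_both",
            "score_recall_association",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for pair, joint, label in (
            ((self.sens_dm, self.sens_dbt), self.sens_both, "sens"),
            ((self.fp_rate_dm, self.fp_rate_dbt), self.fp_rate_both, "fp_rate"),
        ):
            if joint > min(pair) + 1e-12:
                raise ValueError(f"{label}_both exceeds a marginal")
            if 1.0 - pair[0] - pair[1] + joint < -1e-12:
                raise ValueError(
                    f"{label} marginals and joint imply a negative 2x2 cell"
                )
        for name in ("cancer_score_weights", "normal_score_weights"):
            w = np.asarray(getattr(self, name), dtype=float)
            if len(w) != 10 or (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} must be 10 nonnegative weights summing to 1")


def _joint_cells(p1: float, p2: float, p12: float) -> np.ndarray:
    """Cell probabilities [neither, arm1-only, arm2-only, both] of the 2×2."""
    cells = np.array([1 - p1 - p2 + p12, p1 - p12, p2 - p12, p12])
    return np.clip(cells, 0.0, None) / np.clip(cells, 0.0, None).sum()


def _draw_scores(rng: np.random.Generator, weights, n: int) -> np.ndarray:
    bins = rng.choice(10, size=n, p=np.asarray(weights, dtype=float)) + 1
    return bins - rng.random(n)  # uniform within (k-1, k]


def simulate_cohort(params: SimulationParams | None = None) -> Cohort:
    """Draw a stochastic synthetic cohort; reproducible under ``params.seed``."""
    params = params if params is not None else SimulationParams()
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_total
    has_cancer = rng.random(n) < params.prevalence
    n_ca = int(has_cancer.sum())
    n_no = n - n_ca

    dm = np.zeros(n, dtype=bool)
    dbt = np.zeros(n, dtype=bool)
    cells_ca = _joint_cells(params.sens_dm, params.sens_dbt, params.sens_both)
    cells_no = _joint_cells(
        params.fp_rate_dm, params.fp_rate_dbt, params.fp_rate_both
    )
    draw_ca = rng.choice(4, size=n_ca, p=cells_ca)
    draw_no = rng.choice(4, size=n_no, p=cells_no)
    dm[has_cancer] = np.isin(draw_ca, (1, 3))
    dbt[has_cancer] = np.isin(draw_ca, (2, 3))
    dm[~has_cancer] = np.isin(draw_no, (1, 3))
    dbt[~has_cancer] = np.isin(draw_no, (2, 3))

    score = np.empty(n)
    score[has_cancer] = _draw_scores(rng, params.cancer_score_weights, n_ca)
    score[~has_cancer] = _draw_scores(rng, params.normal_score_weights, n_no)

    a = params.score_recall_association
    if a > 0 and n_ca > 1:
        # rank-couple a fraction of cancers: highest scores to DBT-recalled
        k = int(round(a * n_ca))
        pick = rng.choice(n_ca, size=k, replace=False)
        ca_idx = np.flatnonzero(has_cancer)[pick]
        order_scores = np.sort(score[ca_idx])[::-1]
        pair_rank = np.lexsort((dm[ca_idx], dbt[ca_idx]))[::-1]
        reordered = ca_idx[pair_rank]
        score[reordered] = order_scores

    dose_dm, dose_dbt = draw_doses(params.dose_params, n, rng)
    width = max(5, len(str(n)))
    df = pd.DataFrame(
        {
            "woman_id": [f"S{i:0{width}d}" for i in range(1, n + 1)],
            "has_cancer": has_cancer,
            "dm_recall": dm,
            "dbt_recall": dbt,
            "ai_score": score,
            "dose_dm_mGy": dose_dm,
            "dose_dbt_mGy": dose_dbt,
        }
    )
    return Cohort(
        df, provenance="simulated", seed=params.seed, params_digest=_digest(params)
    )


def _digest(obj) -> str:
    return hashlib.sha256(repr(obj).encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Validation and I/O
# ---------------------------------------------------------------------------


@dataclass
class ValidationReport:
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_cohort(cohort: Cohort) -> ValidationReport:
    """Report every record-level invariant violation; empty report iff valid."""
    df = cohort.df
    report = ValidationReport()
    bad = df[~((df["ai_score"] > 0) & (df["ai_score"] <= 10))]
    for wid in bad["woman_id"]:
        report.violations.append(f"{wid}: ai_score outside (0, 10]")
    bad = df[(df["dose_dm_mGy"] < 0) | (df["dose_dbt_mGy"] < 0)]
    for wid in bad["woman_id"]:
        report.violations.append(f"{wid}: negative organ dose")
    axes = [a for a in CHARACTERISTIC_AXES if a in df.columns]
    if axes:
        has_chars = (
            df[axes].apply(lambda c: c.fillna("").astype(str).str.len() > 0).any(axis=1)
        )
        for wid in df.loc[has_chars & ~df["has_cancer"], "woman_id"]:
            report.violations.append(
                f"{wid}: characteristics present on a non-cancer record"
            )
    for wid in df.loc[df["woman_id"].duplicated(), "woman_id"].unique():
        report.violations.append(f"{wid}: duplicate woman_id")
    return report


def write_cohort(cohort: Cohort, path) -> None:
    """Write the cohort table as delimited text (CSV; booleans as 0/1)."""
    df = cohort.df.copy()
    for col in ("has_cancer", "dm_recall", "dbt_recall"):
        df[col] = df[col].astype(int)
    df.to_csv(path, index=False)


def read_cohort(path) -> Cohort:
    """Read a cohort table written by :func:`write_cohort`."""
    df = pd.read_csv(
        path, keep_default_na=False, na_values=[], float_precision="round_trip"
    )
    for col in ("has_cancer", "dm_recall", "dbt_recall"):
        df[col] = df[col].astype(int).astype(bool)
    for col in ("ai_score", "dose_dm_mGy", "dose_dbt_mGy"):
        df[col] = df[col].astype(float)
    df["woman_id"] = df["woman_id"].astype(str)
    for axis in CHARACTERISTIC_AXES:
        if axis in df.columns:
            df[axis] = df[axis].astype(str)
    return Cohort(df, provenance="loaded")
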