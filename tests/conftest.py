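import pandas as pd
import pytest

from tomotriage import (
    Cohort,
    FixtureConstraints,
    ThresholdBlock,
    build_mbtst_cohort,
)


@pytest.fixture(scope="session")
def mbtst() -> Cohort:
    """The deterministic 14,768-woman reference cohort with characteristics."""
    return build_mbtst_cohort(seed=0)


@pytest.fixture()
def toy_constraints() -> FixtureConstraints:
    """20 women: 4 cancers (2 both / 1 DM-only / 1 DBT-only), FP 2/2 union 3,
    one threshold block at 5.0 holding 6 women (1/1/1/1 constrained)."""
    return FixtureConstraints(
        n_total=20,
        n_cancer=4,
        n_dm_detected=3,
        n_dbt_detected=3,
        n_both_detected=2,
        n_dm_fp=2,
        n_dbt_fp=2,
        n_union_fp=3,
        blocks={
            5.0: ThresholdBlock(
                n_above=6,
                n_dbtonly_cancer_above=1,
                n_dmonly_cancer_above=1,
                n_dbtonly_fp_above=1,
                n_dmonly_fp_above=1,
            )
        },
    )


@pytest.fixture()
def toy_cohort() -> Cohort:
    """Ten hand-written records covering every recall category."""
    rows = [
        # id, cancer, dm, dbt, score
        ("T01", 1, 1, 1, 9.5),
        ("T02", 1, 1, 0, 6.0),
        ("T03", 1, 0, 1, 8.0),
        ("T04", 1, 0, 1, 2.0),
        ("T05", 1, 0, 0, 1.5),
        ("T06", 0, 1, 1, 7.0),
        ("T07", 0, 1, 0, 9.0),
        ("T08", 0, 0, 1, 3.0),
        ("T09", 0, 0, 0, 5.0),
        ("T10", 0, 0, 0, 10.0),
    ]
    df = pd.DataFrame(
        rows, columns=["woman_id", "has_cancer", "dm_recall", "dbt_recall", "ai_score"]
    )
    for c in ("has_cancer", "dm_recall", "dbt_recall"):
        df[c] = df[c].astype(bool)
    df["dose_dm_mGy"] = 2.5
    df["dose_dbt_mGy"] = 2.0
    return Cohort(df, provenance="loaded")


def brute_force_tally(cohort: Cohort, thresholds) -> dict:
    """Independent record-by-record tally used as the oracle for fixture
    construction (plain Python loops, no package counting code)."""
    out = {
        "n_total": 0,
        "n_cancer": 0,
        "n_dm_detected": 0,
        "n_dbt_detected": 0,
        "n_both_detected": 0,
        "n_dm_fp": 0,
        "n_dbt_fp": 0,
        "n_union_fp": 0,
        "blocks": {
            t: {
                "n_above": 0,
                "n_dbtonly_cancer_above": 0,
                "n_dmonly_cancer_above": 0,
                "n_dbtonly_fp_above": 0,
                "n_dmonly_fp_above": 0,
            }
            for t in thresholds
        },
    }
    for rec in cohort.records():
        out["n_total"] += 1
        if rec.has_cancer:
            out["n_cancer"] += 1
            if rec.dm_recall:
                out["n_dm_detected"] += 1
            if rec.dbt_recall:
                out["n_dbt_detected"] += 1
            if rec.dm_recall and rec.dbt_recall:
                out["n_both_detected"] += 1
        else:
            if rec.dm_recall:
                out["n_dm_fp"] += 1
            if rec.dbt_recall:
                out["n_dbt_fp"] += 1
            if rec.dm_recall or rec.dbt_recall:
                out["n_union_fp"] += 1
        for t in thresholds:
            if rec.ai_score > t:
                blk = out["blocks"][t]
                blk["n_above"] += 1
                if rec.has_cancer and rec.dbt_recall and not rec.dm_recall:
                    blk["n_dbtonly_cancer_above"] += 1
                if rec.has_cancer and rec.dm_recall and not rec.dbt_recall:
                    blk["n_dmonly_cancer_above"] += 1
                if not rec.has_cancer and rec.dbt_recall and not rec.dm_recall:
                    blk["n_dbtonly_fp_above"] += 1
                if not rec.has_cancer and rec.dm_recall and not rec.dbt_recall:
                    blk["n_dmonly_fp_above"] += 1
    return out


def assert_matches_constraints(cohort: Cohort, constraints: FixtureConstraints):
    got = brute_force_tally(cohort, list(constraints.thresholds))
    for name in (
        "n_total",
        "n_cancer",
        "n_dm_detected",
        "n_dbt_detected",
        "n_both_detected",
        "n_dm_fp",
        "n_dbt_fp",
        "n_union_fp",
    ):
        assert got[name] == getattr(constraints, name), name
    for t, blk in constraints.blocks.items():
        for f in (
            "n_above",
            "n_dbtonly_cancer_above",
            "n_dmonly_cancer_above",
            "n_dbtonly_fp_above",
            "n_dmonly_fp_above",
        ):
            assert got["blocks"][t][f] == getattr(blk, f), f"block[{t}].{f}"
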