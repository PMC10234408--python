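"""Fixture construction, validation, serialization and their invariants."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st

from tomotriage import (
    Cohort,
    FixtureConstraints,
    FixtureError,
    ScreeningRecord,
    ThresholdBlock,
    TriageConfig,
    Workflow,
    build_fixture_cohort,
    evaluate_cohort,
    mbtst_constraints,
    read_cohort,
    validate_cohort,
    write_cohort,
)

from conftest import assert_matches_constraints


class TestFixtureConstruction:
    def test_mbtst_fixture_retallies_exactly(self, mbtst):
        """Brute-force per-record tally reproduces every printed count."""
        assert_matches_constraints(mbtst, mbtst_constraints())

    def test_toy_constraints_exact(self, toy_constraints):
        cohort = build_fixture_cohort(toy_constraints, seed=3)
        assert len(cohort) == 20
        assert_matches_constraints(cohort, toy_constraints)

    def test_all_normal_cohort_yields_zero_everywhere(self):
        """Empty-signal case: no cancers, no FPs, every workflow finds nothing."""
        spec = FixtureConstraints(
            n_total=50,
            n_cancer=0,
            n_dm_detected=0,
            n_dbt_detected=0,
            n_both_detected=0,
            n_dm_fp=0,
            n_dbt_fp=0,
            n_union_fp=0,
            blocks={
                5.0: ThresholdBlock(10, 0, 0, 0, 0),
            },
        )
        cohort = build_fixture_cohort(spec, seed=0)
        for cfg in (
            TriageConfig(Workflow.DM_ONLY),
            TriageConfig(Workflow.COMBINATION, 5.0),
            TriageConfig(Workflow.PRECEDENCE, 5.0),
            TriageConfig(Workflow.FULL_BOTH),
            TriageConfig(Workflow.DBT_ONLY),
        ):
            s = evaluate_cohort(cohort, cfg)
            assert s.detected == 0 and s.fp_total == 0

    @pytest.mark.parametrize(
        "patch, constraint_part",
        [
            ({"n_both_detected": 200}, "n_both_detected"),
            ({"n_union_fp": 900}, "n_union_fp"),
            ({"n_cancer": 20000}, "n_cancer"),
            ({"n_dm_fp": -1}, "n_dm_fp"),
        ],
    )
    def test_inconsistent_constraints_raise_named_error(self, patch, constraint_part):
        base = mbtst_constraints().__dict__ | patch
        with pytest.raises(FixtureError) as exc:
            build_fixture_cohort(FixtureConstraints(**base), seed=0)
        assert constraint_part in exc.value.constraint

    def test_block_exceeding_marginal_raises(self, toy_constraints):
        blocks = {5.0: ThresholdBlock(6, 3, 1, 1, 1)}  # only 1 DBT-only cancer exists
        bad = FixtureConstraints(**(toy_constraints.__dict__ | {"blocks": blocks}))
        with pytest.raises(FixtureError) as exc:
            build_fixture_cohort(bad, seed=0)
        assert "n_dbtonly_cancer_above" in exc.value.constraint

    def test_overfull_band_raises(self, toy_constraints):
        # constrained categories exceed the band's n_above
        blocks = {5.0: ThresholdBlock(3, 1, 1, 1, 1)}
        bad = FixtureConstraints(**(toy_constraints.__dict__ | {"blocks": blocks}))
        with pytest.raises(FixtureError):
            build_fixture_cohort(bad, seed=0)

    def test_band_scores_default_to_midpoints(self, toy_constraints):
        cohort = build_fixture_cohort(toy_constraints, seed=0)
        assert set(np.unique(cohort.df["ai_score"])) == {7.5, 2.5}

    def test_seed_changes_doses_only(self, toy_constraints):
        a = build_fixture_cohort(toy_constraints, seed=1).df
        b = build_fixture_cohort(toy_constraints, seed=2).df
        structural = ["woman_id", "has_cancer", "dm_recall", "dbt_recall", "ai_score"]
        pd.testing.assert_frame_equal(a[structural], b[structural])
        assert not np.allclose(a["dose_dm_mGy"], b["dose_dm_mGy"])


@st.composite
def consistent_constraints(draw):
    """Randomized small constraint sets that are consistent by construction:
    per-band counts for every category are drawn first, then marginals and
    cumulative threshold blocks are derived from them."""
    k = draw(st.integers(1, 3))
    thresholds = sorted(
        draw(
            st.lists(
                st.sampled_from([1.0, 2.5, 4.0, 5.5, 7.0, 8.5, 9.5]),
                min_size=k,
                max_size=k,
                unique=True,
            )
        ),
        reverse=True,
    )
    nbands = k + 1
    per_band = {
        cat: [draw(st.integers(0, 4)) for _ in range(nbands)]
        for cat in ("dbt_c", "dm_c", "dbt_fp", "dm_fp")
    }
    fills = [draw(st.integers(0, 4)) for _ in range(k)]  # TNs in upper bands
    tn_bottom = draw(st.integers(0, 8))
    both_c = draw(st.integers(0, 4))
    neither_c = draw(st.integers(0, 3))
    both_fp = draw(st.integers(0, 4))

    n_dbt_c, n_dm_c = sum(per_band["dbt_c"]), sum(per_band["dm_c"])
    n_dbt_fp_only, n_dm_fp_only = sum(per_band["dbt_fp"]), sum(per_band["dm_fp"])
    n_cancer = n_dbt_c + n_dm_c + both_c + neither_c
    n_union_fp = n_dbt_fp_only + n_dm_fp_only + both_fp
    n_total = n_cancer + n_union_fp + sum(fills) + tn_bottom

    blocks = {}
    cum = {cat: 0 for cat in per_band}
    n_above = 0
    for i, t in enumerate(thresholds):
        for cat in per_band:
            cum[cat] += per_band[cat][i]
        n_above += sum(per_band[cat][i] for cat in per_band) + fills[i]
        blocks[t] = ThresholdBlock(
            n_above=n_above,
            n_dbtonly_cancer_above=cum["dbt_c"],
            n_dmonly_cancer_above=cum["dm_c"],
            n_dbtonly_fp_above=cum["dbt_fp"],
            n_dmonly_fp_above=cum["dm_fp"],
        )
    return FixtureConstraints(
        n_total=n_total,
        n_cancer=n_cancer,
        n_dm_detected=n_dm_c + both_c,
        n_dbt_detected=n_dbt_c + both_c,
        n_both_detected=both_c,
        n_dm_fp=n_dm_fp_only + both_fp,
        n_dbt_fp=n_dbt_fp_only + both_fp,
        n_union_fp=n_union_fp,
        blocks=blocks,
    )


@settings(max_examples=60, deadline=None, derandomize=True,
          suppress_health_check=[HealthCheck.too_slow])
@given(spec=consistent_constraints(), seed=st.integers(0, 2**16))
def test_fixture_retally_idempotence(spec, seed):
    """Any consistent constraint set round-trips: build, re-tally, compare."""
    cohort = build_fixture_cohort(spec, seed=seed)
    assert_matches_constraints(cohort, spec)


class TestRecordAndValidation:
    @pytest.mark.parametrize("score", [0.0, -1.0, 10.5])
    def test_record_rejects_out_of_range_score(self, score):
        with pytest.raises(ValueError):
            ScreeningRecord("X", False, False, False, ai_score=score)

    def test_record_rejects_characteristics_without_cancer(self):
        with pytest.raises(ValueError):
            ScreeningRecord(
                "X", False, False, False, 5.0, characteristics={"density": "2"}
            )

    def test_valid_fixture_gives_empty_report(self, mbtst):
        assert validate_cohort(mbtst).ok

    def test_violations_name_record_and_rule(self, toy_cohort):
        df = toy_cohort.df.copy()
        df.loc[df.index[0], "ai_score"] = 0.0
        df["density"] = ""
        df.loc[df.index[-1], "density"] = "3"  # T10 is not a cancer
        report = validate_cohort(Cohort(df))
        assert any("T01" in v and "ai_score" in v for v in report.violations)
        assert any("T10" in v and "characteristics" in v for v in report.violations)

    def test_duplicate_ids_rejected(self, toy_cohort):
        df = toy_cohort.df.copy()
        df.loc[df.index[1], "woman_id"] = "T01"
        with pytest.raises(ValueError, match="duplicate"):
            Cohort(df)


class TestSerialization:
    def test_write_read_write_is_byte_identical(self, mbtst, tmp_path):
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_cohort(mbtst, p1)
        write_cohort(read_cohort(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_same_seed_same_bytes(self, toy_constraints, tmp_path):
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_cohort(build_fixture_cohort(toy_constraints, seed=7), p1)
        write_cohort(build_fixture_cohort(toy_constraints, seed=7), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_roundtrip_preserves_values(self, mbtst, tmp_path):
        p = tmp_path / "c.csv"
        write_cohort(mbtst, p)
        back = read_cohort(p)
        pd.testing.assert_frame_equal(
            back.df, mbtst.df.reset_index(drop=True), check_dtype=False
        )
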