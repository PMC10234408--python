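# Methods

## Setting

A paired-design screening cohort: every woman underwent two-view digital
mammography (DM) and one-view wide-angle digital breast tomosynthesis (DBT),
each double read in a separate arm with its own consensus recall decision.
An AI cancer-detection system scored the DM examination with a decimal risk
score in (0, 10]; the score's integer ceiling is calibrated by the vendor so
that each integer bin holds roughly 10% of a screening population and more
than 85% of cancers fall in bin 10. The question evaluated is retrospective:
what would have happened had DBT been performed, and read, only for women
whose score strictly exceeds a threshold *t*.

Ground truth is detection by either reading arm; interval cancers and
next-round detections are out of scope. "False positive" means a woman
recalled by an examination that is performed *and read* in the simulated
workflow, without a cancer diagnosis.

## Triage workflows

For the thresholded workflows, DBT is performed iff `score > t` — a strict
comparison, so ties at the threshold stay DM-only.

* **Combination**: above-threshold women are recalled if either arm recalls
  (union of the two independent double readings). Recall decisions for joint
  reading of both modalities by the same readers are unknowable from a
  two-arm design, so the union of the separately-made decisions is used as
  is; no reader behaviour is re-modelled.
* **Precedence**: above the threshold only the DBT reading is used; the DM
  examination is still acquired (its dose accrues) but is not read, so a
  DM-only detection above the threshold becomes a miss and a DM-only false
  positive above the threshold is avoided.

DM-only, DBT-only (no DM exam at all) and full-both act as references.
Aggregation is exact counting — every derived quantity (extra and missed
cancers, PPV, rates per 1000, sensitivity/specificity) is a pure function of
the per-woman outcome table. Undefined ratios (e.g. the added-DBT detection
rate when no DBT exam is performed) are reported as missing, never as 0.

## The deterministic reference cohort

The published joint counts fully determine a cohort up to relabelling:
marginal detection counts per arm with their overlap, false-positive counts
with their union, and — per threshold — the number of women above it and the
above-threshold counts of DBT-only cancers, DM-only cancers, DBT-only false
positives and DM-only false positives. `build_fixture_cohort` lays women out
in score bands delimited by the block thresholds: the threshold-constrained
categories are decomposed into bands by differencing consecutive blocks;
true negatives fill each band to its exact size; both-arm cancers, both-arm
false positives and never-recalled cancers — whose score band no printed
count constrains — are placed in the bottom band. Every woman in a band gets
the band's representative score (any in-band value yields identical
tallies); the reference cohort uses 9.5, 8.25 and 4.0 for the bands above
9.0, (7.5, 9.0] and ≤ 7.5, while scaled-down constraint sets default to band
midpoints. Construction is validated by re-tallying: a property test builds
randomized consistent constraint sets and checks the round trip exactly.

Two published figures are intentionally *not* matched: the abstract-level
variants of the threshold-9.0 results (25 extra cancers / 1797 women / 14
per 1000 / 58 false positives) conflict with the detailed results table (24
/ 1493 / 16.1 / 60), which is internally consistent and is the source
followed here. The origin of the discrepancy is not determinable from the
published material.

### Tumour characteristics

Only per-axis marginal counts of the cancer characteristics are published
(invasiveness 116/20; density 10/43/63/20; histological type 74/24/17/20/1;
histological grade 45/52/17/+2 missing over invasive cancers; nuclear grade
2/7/11 over in-situ; size; node status; radiographic appearance), plus
per-strategy detected/extra/missed breakdowns. For **invasiveness** the
breakdowns at both thresholds are mutually consistent and pin the
invasive/in-situ split of every recall-category × score-band cell that
matters (DBT-only cancers split 23/1, 5/2, 9/1 across the three bands;
DM-detected cancers split 79/16); the fixture reproduces these exactly. For
the other axes the joint distribution with recall category is
under-determined; levels are assigned blockwise in a fixed deterministic
order (invasive cancers first), so per-axis totals are exact but
per-strategy breakdowns of those axes are not guaranteed to match. Grade
axes apply only to their subset; a cancer whose value was not recorded
carries the explicit level `missing`, distinct from "axis not applicable"
(empty), and stratified totals are conserved within the applicable subset.

## Stochastic simulator

`simulate_cohort` draws, independently per woman: cancer status
(Bernoulli, default prevalence 136/14768 ≈ 0.92%); a recall pair from the
2×2 distribution implied by the arm marginals and their joint (defaults
95/136, 128/136, joint 87/136 for cancers; 271/14632, 404/14632, joint
154/14632 for non-cancers — infeasible combinations are rejected); and an AI
score: an integer bin from class-conditional weights (non-cancers uniform
at 0.1 per bin; cancers 0.87 in bin 10, the remainder spread evenly),
then uniform within the bin `(k−1, k]`. `score_recall_association ∈ [0, 1]`
optionally rank-couples scores to DBT detection: that fraction of cancers
has its recall pairs re-matched to scores in descending order,
DBT-recalled first, leaving all marginals untouched; the default 0 keeps
score and recall independent given class. All randomness flows from one
`numpy` generator seeded by `seed`, and cohorts are byte-reproducible.

The simulator emulates marginal calibration, arm correlation and decile
scoring. It does **not** emulate real-data features such as score–dose or
score–density correlation, per-lesion multiplicity, reader drift, or the
empirical dependence between tumour type and AI score; tests passing on
simulated cohorts therefore validate the accounting machinery, not the
clinical transportability of any threshold.

## Statistics

Confidence intervals for proportions are exact Clopper–Pearson intervals at
the 95% level, computed from beta quantiles
(`lower = B(α/2; x, n−x+1)`, `upper = B(1−α/2; x+1, n−x)`, with 0 and 1 at
the boundaries); tests verify equivalence with direct binomial tail-sum
inversion for all x at n ≤ 12 (1e−9) and conservative coverage by
simulation. Percent increases are computed on unrounded counts and rounded
half-away-from-zero to integer percent only for display; per-1000 rates are
kept at full precision internally with a display precision argument
(1 decimal by default). One published PPV (0.251 for combination at 7.5)
differs from the computed 126/500 = 0.252; the computed value is reported.

## Resource models

**Organ dose.** Per-modality doses default to truncated normals (at 0)
matched to the published per-exam means/SDs — DM 2.69 (0.778) mGy, DBT
2.24 (0.672) mGy — drawn independently of score. Population mean dose under
a strategy sums the DM dose (performed in every workflow except DBT-only;
the precedence workflow still acquires DM) and the DBT dose where DBT is
performed. Under this independence the closed form is
`E[dose] = μ_DM + f·μ_DBT` with *f* the DBT fraction, giving 2.92 mGy at
t = 9.0 and 3.18 at 7.5; the published population values (2.89, 3.14) are
slightly lower, implying a score–dose correlation in the real data that is
not quantified in the published material, so those two values are
documented as not reproducible from the stated inputs and are not asserted.

**Reading time.** A converted screen costs a multiplier relative to reading
DM alone: 2.25 when DM and DBT are read together (combination), 1.75 when
DBT replaces DM (precedence). The relative change in total reading time is
`f·(multiplier − 1)·100%`, giving 27.5% / 16.5% at t = 7.5 (published as
27% / 16%). At t = 9.0 the same arithmetic gives 12.6% / 7.6% where the
publication prints 11% / 6%; the stated multipliers and the 1493-woman
fraction cannot produce those figures (possibly a different above-threshold
fraction was used), so the arithmetic values are returned and the mismatch
is noted here rather than hidden.

## Numerical and design choices

* Strict threshold comparison throughout; the config carries a `comparison`
  field so another tie rule could be added without interface change.
* The decimal score's support is taken as (0, 10], consistent with ceiling
  binning to integers 1–10; whether the true lower bound is 0 or 1 is not
  stated and does not affect any tally.
* Cohort tables are plain CSV with booleans as 0/1 and empty fields for
  not-applicable characteristics; floats round-trip exactly
  (`float_precision="round_trip"` on read), so write → read → write is
  byte-identical.
* Problem sizes in the test suite: calibration checks use one simulated
  cohort of 10⁵ women (3-standard-error tolerances) and 200 replicate
  cohorts at the reference size for the replication check; interval coverage
  uses 2000 binomial draws. These sizes make Monte-Carlo error negligible
  relative to the tolerances while keeping the default suite quick.

## Limitations

Per-woman (not per-lesion) modelling; no consensus-meeting or arbitration
dynamics; no modelling of how radiologists would behave if they knew the AI
had flagged a case; no interval-cancer follow-up, so "missed" means missed
relative to two-modality screen detection only; single-vendor,
single-centre counts behind the reference cohort limit generalizability of
any specific threshold.
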