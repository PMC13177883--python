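# Methods

This note records the modelling assumptions, default parameters and numerical
choices behind `cpcea`, and what the synthetic-data experiments do and do not
demonstrate about real data.

## Synthetic cohort generator

The generator emulates a prospective observational cohort of children with
CP (ages 3–18) followed for 12 months. Defaults reproduce the study
conditions the package replicates:

- 148 children; 92 receive Intensive and Emerging Rehabilitation Therapies
  (IERT) on top of standard care, 56 standard care alone.
- GMFCS level counts 24/35/29/21/39 (I–V) overall, split 7/16/20/18/31 vs
  17/19/9/3/8 between the treated and control arms — the treated arm is
  systematically severer, as observed in practice.
- Exactly-one-therapy-per-subgroup assignment: intensive therapies
  speech/physio/occupational 42/39/11 (covering all 92 treated children) and
  emerging therapies hippotherapy/Therasuit/Petö/homeopathy 15/32/34/6
  (87 children, so most treated children combine one therapy from each
  subgroup). Therapy labels are randomly matched to treated children, so
  therapy is independent of severity *within* the arm.
- Outcome construction. Per child a bivariate Gaussian disturbance
  (e_cost, e_effect) is drawn with SDs €2,650 / 0.20 QALY and correlation
  0.3 (configurable). The utility plateau is
  `baseline (0.517) + GMFCS offset + e_effect`; the therapy effect ramps
  linearly (half at 6 months, full at 12), so the AUC QALY gain equals the
  configured per-therapy QALY increment exactly, before truncation of
  utilities at 1. Annual cost is `max(5,156.48 + e_cost, 0)` public baseline
  plus the configured per-therapy cost increments.
- Default increments are calibrated to the study's published 12-month
  regression coefficient layer (e.g. physiotherapy +€6,863.01 / +0.216 QALY;
  Therasuit +€4,193.84 / +0.222). With the overlapping-subgroup design these
  cannot simultaneously reproduce the published *group-mean* cost table; the
  coefficient layer was preferred because it is what the estimators consume.
  The standard-care baseline (€5,156.48/year) is preserved. The residual SDs
  were back-calculated from the published coefficient standard errors
  (SE ≈ σ·√(1/n_t + 1/n_ST)).
- Dropout: 5 children, missing-at-random within the emerging-therapy
  subgroup, flagged (never deleted); estimators apply complete-case
  filtering downstream. Ages and sexes are cosmetic covariates drawn to the
  per-arm census bins; the default estimation uses therapy dummies only.

**What the defaults deliberately include.** Two structural features make the
default cohort *observationally realistic* and therefore make the raw
dummies-only coefficients diverge from the configured increments: (i)
severity confounding — the treated arm's lower baseline utility depresses
every therapy's effect coefficient; (ii) cross-subgroup spillover — a
treated child's cost and QALY carry both subgroups' increments while each
regression system includes only its own subgroup's dummies. Both are
features of the study design being emulated, not estimator defects.

**Estimator-correctness experiments** therefore use a separate, well-posed
configuration fixed once up front: GMFCS utility offsets zero, baseline
utility 0.40 (clear of the utility ceiling at 1, whose censoring would
otherwise bias means), and increments only on the probed therapy
(physiotherapy: +€1,700 / +0.20 QALY). Under that configuration the
configured increments are exactly the estimand, and parameter recovery,
calibration and interval-coverage checks are meaningful. Passing them shows
the generator and estimator are mutually consistent; it does not show that
dummies-only SUR deconfounds real observational data — it cannot.

## QALYs and discounting

QALYs are the trapezoidal area under the utility trajectory (assessments at
0, 0.5, 1 years by default): `0.25·u0 + 0.5·u6 + 0.25·u12`. Negative
utilities (worse-than-dead EQ-5D-Y states) are allowed and never clamped;
utilities are capped at 1. The 12-month QALY is undiscounted. Long-term
discounting is end-of-cycle at 3%/year with no half-cycle correction: cycle
t contributes with factor (1.03)^−t. The 30-year full-health annuity is
(1 − 1.03⁻³⁰)/0.03 = 19.6004, used as an exact identity test of the
microsimulation. EQ-5D-Y dimension scoring and national tariffs are out of
scope; utilities are consumed directly (a profile→utility lookup can be
applied upstream).

## SUR estimation

One-step feasible GLS: per-equation OLS, residual cross-covariance with
small-sample divisor n (not n−k; the simplest member of the FGLS family),
then the stacked GLS solve with the Kronecker weight. An iterated-FGLS
toggle exists but changes nothing when both equations share a regressor
matrix — the point estimates then equal OLS exactly, which every fit can be
checked against. Coefficient covariance comes from the GLS normal equations
(S ⊗ (X′X)⁻¹); p-values are asymptotic normal. Consequences: standard errors
are mildly optimistic in small samples (divisor n and z rather than t), so
95% intervals cover ~94% in the n=148 replicates — within the ±2% band the
acceptance suite enforces. ICERs divide the therapy's cost coefficient by
its effect coefficient; |Δeffect| < 1e-6 QALY raises an undefined-ratio
error rather than emitting an exploding ratio. Both-negative pairs report
the ratio with a southwest-quadrant flag. No pooled group-level ICER is ever
emitted (aggregating heterogeneous overlapping therapies would bias it).

## Microsimulation

States H/S1/S2/D with D absorbing; per-edge annual rates converted via
p = 1 − exp(−rate·multiplier), stay-probability as the row residual
(negative residual → named parameter error). Direct probability entry is
supported. Backward transitions (S1→H, S2→S1) are representable, default 0.
Horizon fixed at 30 annual cycles; no age-dependent mortality (fixed annual
probabilities). Accrual timing: during cycle t an individual occupies the
state entered at t−1, accrues that state's cost/utility discounted by
(1.03)^−t, then transitions. The trace records occupancy at cycle
boundaries (row 0 = baseline mix).

Common random numbers are implemented as an identical per-individual,
per-cycle uniform array regenerated from the configuration seed for every
strategy; this gives bit-identical results for identical parameters and
strategy-order invariance, and vectorises so 100,000 individuals × 30 cycles
× 4 strategies run in under a second.

The shipped transition rates, per-state costs and utilities are
**illustrative**: the study's calibrated severity-specific inputs are not
publicly available, so defaults were chosen once as plausible magnitudes for
a slowly progressing pediatric motor disorder (e.g. H→S1 0.030/yr, S2→D
0.030/yr, standard-care utilities 0.75/0.55/0.35). No validated quantity in
the package depends on them; the acceptance checks use closed-form
identities (annuity, matrix-power Markov limit) that hold for any parameter
set.

## Uncertainty analysis

Short-term PSA is parametric from the SUR coefficient covariance: CEACs use
the normal closed form for P(λΔe − Δc > 0); ellipses use the exact symmetric
square root of the 2×2 block, boundary at the χ²(2) quantile (5.9915 at
95%). The bootstrap is stratified by treatment arm (preserving the 92/56
design); failed resamples are skipped and counted, >10% aborts. The
long-term bootstrap statistic re-derives microsimulation inputs from each
cohort resample (baseline severity mix, per-state utilities from observed
12-month utilities, cost levels from arm means) and re-runs a reduced
simulation (default 10,000 individuals/iteration) under common random
numbers; it propagates cohort sampling uncertainty, not literature-based
rate uncertainty. Quadrant ties on the CE plane count toward the positive
side (≥ 0).

## Reproducibility and problem sizes

A pipeline master seed fans out to named substreams (cohort, microsim,
bootstrap) via `SeedSequence.spawn`, so enlarging one stage never perturbs
another; re-runs are byte-identical. Test problem sizes were chosen so the
whole suite runs in well under a minute on one core: recovery at n = 2,960
(×20 scale), coverage over 1,000 replicates of n = 148, Markov-oracle
agreement at n = 100,000, CEAC sampling oracle at 10⁶ draws, bootstrap
calibration at n = 500 / B = 1,000.

## Known limitations

- The generator's Gaussian disturbances and linear utility ramp are minimal
  structure, not a fitted model of real EQ-5D-Y trajectories; ceiling
  censoring at utility 1 is real but the default effect sizes press against
  it for mildly affected children.
- Dominance classification covers simple dominance only (no extended
  dominance across more than two alternatives).
- The microsimulation has a single per-state cost (no category breakdown)
  and healthcare-payer perspective only; monetary outputs are 2023 euros
  with no CPI machinery.
- No imputation: the design assumes near-complete follow-up and
  complete-case analysis.
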