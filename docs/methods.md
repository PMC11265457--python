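# Methods

## The analysis model

`riskhte` operationalizes risk-stratified heterogeneity-of-treatment-effect
(HTE) analysis for a two-arm randomized trial with a right-censored
time-to-event outcome. The workflow has four stages.

**1. Cohort preparation.** Complete-case filtering on a declared covariate
list (no imputation), then an outcome-stratified 50/50 split into a
training/validation half and an untouched test half. Because the event is
rare (~10% cumulative incidence), the training half is rebalanced by random
oversampling of event rows with replacement until the classes match; the
test half is never altered. Per-stratum split counts use
round-half-to-even on `stratum size × test_fraction` — a deterministic,
documented rule; any similar rounding convention would be defensible.
Oversampled duplicates keep their original id plus a `replicate` counter so
resampling bookkeeping stays auditable, and the pipeline (not the
operation) guarantees oversampling is applied only to the training half.

**2. Subgroup generation.** Three strategies, all reducing to a
`SubgroupAssignment` of group indices 1..G ordered by risk:

- *Extant linear PH score.* Predicted 5-year risk
  `1 − S₀(5)^exp(Σ β(x−x̄))` within the participant's stratum, consumed
  from a coefficient table and never re-estimated. Scored on the **full**
  filtered cohort (an external score needs no held-out set); an option
  restricts it to the test half for apples-to-apples comparison with the
  learned models.
- *Tree committee.* Classification trees (Gini impurity, `max_leaf_nodes`
  cap standing in for cost-complexity pruning to ≤ 6 leaves) on B = 30
  bootstrap resamples of the augmented training half, each tuned by 5-fold
  cross-validated accuracy over depth and minimum leaf size. The committee's
  representative is the tree with **lower-median** test-set accuracy
  (deterministic for even B). Its leaves, numbered by ascending
  leaf-predicted event probability, are the subgroups; sizes are
  data-driven and unequal.
- *Weighted forest.* A random forest (100 trees, ≤ 10 leaves each,
  per-split feature subsetting and minimum leaf size tuned by 10-fold CV
  accuracy). The risk score is the mean over trees of each tree's
  positive-class leaf frequency — a probability-weighted vote. Scores are
  cut into quintiles.

The classifiers model only the binary "event observed" label; censoring is
deliberately ignored at this stage (a stated simplification of the
approach, revisited under Limitations).

Quintile cuts are **rank-based**: sort by `(score, id)` and slice into G
contiguous blocks whose sizes differ by at most one, larger blocks at the
high-risk end. Rank cuts (not value thresholds) are what make 1,150
participants fall into five groups of exactly 230, and make the partition
invariant under any strictly monotone rescaling of the scores.

**3. Predictive-ability assessment** (always on the test half):
accuracy/sensitivity/specificity/PPV at a 50% risk threshold with
normal-approximation CIs on each metric's own denominator (Wilson optional;
PPV is flagged undefined, not zero, when nothing is predicted positive);
the cumulative/dynamic time-dependent AUC at 5 years; and per-subgroup
calibration of mean predicted risk against the Kaplan–Meier observed rate.

The time-dependent AUC uses the nearest-neighbour bivariate-survival
estimator: conditional survival `S(5 | marker ≈ mᵢ)` is a weighted
Kaplan–Meier over the symmetric rank window `|F̂(mⱼ) − F̂(mᵢ)| ≤ λ`, with
span λ = 0.25·n^(−0.20) by default (a common convention; results should be
span-checked), and sensitivity/specificity at each cutpoint are read off
the smoothed conditional survival, with monotonicity enforced before the
trapezoidal area. The estimator handles censoring before the horizon; with
none, it agrees with the Mann–Whitney concordance to within smoothing error
(~0.02), which is how it is tested. The smoothing also means perfectly
separating scores score slightly below 1.

**4. Heterogeneity testing.** Absolute scale: per-subgroup 5-year ARR from
arm-specific Kaplan–Meier estimates, `se = sqrt(Var_G[Ŝ_c] + Var_G[Ŝ_t])`
with Greenwood variances, CI `arr ± z·se` (a normal-approximation
difference; symmetric, consistent with how such intervals are typically
reported — a complementary log-log construction would differ slightly in
small groups). Cochran's Q with fixed-effect inverse-variance weights
against χ²_{G−1}. NNT = 1/ARR with order-swapped reciprocal CI bounds,
reported only when the ARR CI excludes zero (an interval through ±∞ is
suppressed rather than misstated). Relative scale: Cox PH regression on
arm, subgroup indicators and their interactions (Efron tie handling, via
lifelines), joint Wald χ² on the G−1 interaction coefficients; per-subgroup
hazard ratios from within-subgroup Cox fits. A subgroup lacking an arm or
an event fails loudly by default (`on_sparse="merge"` collapses it into its
lower neighbour instead), and a minimum per-arm subgroup size (default 10)
guards the KM contrasts — small leaves produce uninformatively wide
intervals.

No cross-model multiplicity correction is applied; the report notes this.

## The synthetic-trial generator

`trialgen` emulates the structure the analysis assumes: by default 2,291
participants, 1:1 allocation, ten covariates (six standard-normal
continuous, four binary with prevalences 5–70%) with log hazard ratios
spanning 0–0.5, a Weibull proportional-hazards event model (shape 1 by
default, i.e. exponential — the simplest model consistent with a
semi-parametric analysis), administrative censoring at a 7-year horizon,
optional independent exponential dropout, and a target observed-event
fraction of 10.5%.

The Weibull scale is not a free dial: it is calibrated by monotone root
search (Brent) so the expected observed-event fraction matches the target
to 0.005, using the closed form `1 − exp(−e^lp (H/s)^k)` without dropout
and numerical integration of `f_T·S_dropout` with it. Treatment effects:
`null` (HR 1), `constant_hr`, or `risk_graded` with treatment log-HR
`θ₀ + θ₁·(risk percentile)` (defaults θ₀ = 0, θ₁ = −0.9, i.e. HR 1 at the
lowest risk falling to ≈ 0.41 at the highest; a step map concentrating
benefit above a percentile threshold is available and recorded in config).
The generator returns the latent truth — linear predictor, risk
percentile, per-arm true 5-year risks — aligned row-for-row with the
observable table, so recovery tests compare estimates to known values.

What the generator does **not** emulate: the real cohort's covariate
distributions and correlations (covariates are independent here),
competing risks, informative censoring, non-proportional hazards, and
calendar-time accrual. Passing tests therefore demonstrate the machinery's
correctness and its operating characteristics under a clean
proportional-hazards world, not performance on any particular real trial.

## Numerical and design choices

- Kaplan–Meier and Greenwood variance are computed in-package (lifelines
  does not expose the plain Greenwood variance the ARR standard error
  needs) and cross-checked against lifelines and a brute-force
  product-limit enumeration in the tests. When Ŝ(t) reaches 0 its variance
  is reported as 0 by convention.
- Quintile ties break by `(score, id)`; remainder participants go to the
  higher-risk groups. Lower-median committee selection uses the
  (B−1)/2-th order statistic with a stable sort.
- All randomness flows through `numpy.random.default_rng` seeds carried in
  the configs; identical config ⇒ byte-identical output tables. Fitted
  committees/forests persist a JSON reproducibility record (seed, grids,
  chosen hyperparameters, per-tree accuracies, selected index) rather than
  pickled estimators, keeping all outputs plain text.
- Replication experiments subgroup by the **latent true risk** rather than
  a refitted model per replicate: this isolates the tests' operating
  characteristics from model-fitting noise and keeps 500-replicate runs
  under a minute. Reported problem sizes: 500 replicates for the null
  calibration of Q, 150 for risk-graded power, 120 for the interaction
  test's level under constant HR, each at n = 2,300 and ~10% events.

## Known limitations

- The classifiers ignore censoring in their labels; participants censored
  early are diluted into the event-free class. Survival trees/forests would
  address this and are deliberately out of scope.
- The ARR confidence interval is a plain normal approximation; near rate 0
  or 1, or in subgroups of a few dozen per arm, its coverage degrades.
- Under a constant hazard ratio the absolute-scale Q test is *expected* to
  exceed its nominal level — ARR genuinely varies with baseline risk — so
  "constant HR" is a null only for the relative-scale test; the no-effect
  scenario is the null for both.
- The NNE AUC is O(n²) and intended for cohorts of a few thousand, not
  hundreds of thousands.
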