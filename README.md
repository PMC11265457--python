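# riskhte

Risk-model-based subgroup analysis of treatment-effect heterogeneity (HTE)
in randomized trials.

A randomized trial reports one average treatment effect, but the effect may
concentrate in identifiable subgroups. A principled alternative to
one-variable-at-a-time subgroup testing is to rank participants by their
predicted *baseline risk of the outcome*, cut the cohort into risk groups,
and ask whether the treatment effect varies across them. `riskhte`
implements that workflow for time-to-event outcomes, for biostatisticians
and trial analysts, with three interchangeable subgroup-generating
strategies:

- **extant linear PH score** — an externally published, stratified (e.g.
  sex-specific) proportional-hazards risk score consumed from a coefficient
  table: predicted 5-year risk `1 − S₀(5)^exp(lp)` with
  `lp = Σ βₖ(xₖ − x̄ₖ)`, cut into rank quintiles;
- **decision-tree committee** — classification trees fitted to 30
  bootstraps of a class-rebalanced training half; the tree with median
  held-out accuracy is selected and its ≤ 6 terminal leaves are the
  subgroups;
- **weighted random forest** — 100 trees of ≤ 10 leaves whose mean
  positive-class probability is the risk score, again cut into quintiles.

Heterogeneity is then quantified on two scales:

- **absolute**: per subgroup *g*, the 5-year absolute risk reduction
  `ARR_g = (1 − Ŝ_control(5)) − (1 − Ŝ_treated(5))` from Kaplan–Meier
  estimates with Greenwood variances, pooled by fixed-effect inverse-variance
  weights and tested with Cochran's Q (`Q = Σ w_g (ARR_g − ARR̄)²`,
  χ²_{G−1});
- **relative**: the joint Wald χ² on the treatment-by-subgroup interaction
  terms of a Cox proportional-hazards model (Efron ties), with per-subgroup
  hazard ratios.

Because absolute benefit under even a *constant* hazard ratio grows with
baseline risk, these two scales can disagree — detecting that dissociation
is the point of running both. A synthetic-trial generator
(`riskhte.trialgen`) with known latent truth (per-participant linear
predictor and true per-arm 5-year risks) supports calibration and
power/type-I-error experiments.

## Worked example

`examples/extant_risk_score.py` writes a sex-stratified coefficient table,
reads it back, scores a simulated 1,150-participant cohort with a
risk-graded benefit, and contrasts the arms within risk quintiles:

```
group sizes: [230, 230, 230, 230, 230]
group 1: 5-year ARR =   3.0% ( -3.0 to   9.0)
group 2: 5-year ARR =  -1.2% ( -8.8 to   6.4)
group 3: 5-year ARR =   6.3% ( -0.5 to  13.1)
group 4: 5-year ARR =   5.8% ( -0.7 to  12.2)
group 5: 5-year ARR =  12.2% (  3.6 to  20.8)
Cochran's Q = 5.84 on 4 df, p = 0.211
top-quintile NNT = 8.2 (4.8 to 27.5)
```

Each row is the control-minus-treated Kaplan–Meier 5-year event rate in one
predicted-risk quintile with its 95% CI. The benefit gradient is visible in
the point estimates (12.2% absolute reduction in the riskiest fifth, i.e.
about 8 participants treated per event prevented) even though Q does not
reach significance at this sample size — subgroup contrasts in mid-size
trials are noisy.

`examples/simulated_hte_analysis.py` runs all three strategies end to end
on a 2,411-participant simulated cohort:

```
analyzed 2411 participants (1205 train / 1206 test)

linear_ph   groups=5  top-group ARR=11.0% (4.5 to 17.5)  Q p=0.019  interaction p=0.553
tree        groups=6  top-group ARR=7.0% (-0.9 to 15.0)  Q p=0.329  interaction p=0.900
forest      groups=5  top-group ARR=5.5% (-3.1 to 14.1)  Q p=0.112  interaction p=0.253
```

Here the absolute-scale test flags heterogeneity for the extant-score
quintiles while no model shows relative-scale heterogeneity — the expected
signature when benefit tracks baseline risk.

A thin CLI wraps the same pipeline: `hte run --config analysis.yaml`,
`hte simulate --scenario scenario.yaml --out sim`, and
`hte replicate --scenario scenario.yaml --reps 200`.

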