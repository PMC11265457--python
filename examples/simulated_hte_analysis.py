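"""Full heterogeneity analysis on a simulated trial.

Simulates a mid-size prevention trial whose treatment benefit grows with
baseline outcome risk, then runs all three subgroup strategies (extant
linear-PH score, decision-tree committee, probability-weighted random
forest) and prints the absolute- and relative-scale heterogeneity tests.
"""

import numpy as np

from riskhte import AnalysisConfig, ScenarioConfig, generate_trial, run_hte_analysis
from riskhte.risk_models import LinearPHRiskModel, StratumModel
from riskhte.trialgen import CovariateSpec

# a cohort of 2,411 with ~10% cumulative incidence and a risk-graded benefit
scenario = ScenarioConfig(
    n_participants=2411,
    covariates=ScenarioConfig().covariates
    + [CovariateSpec("sex", "categorical", {"levels": ["F", "M"], "probs": [0.66, 0.34]})],
    effect_mode="risk_graded",
    seed=42,
)

# the "extant published score": same coefficients the generator used,
# with the matching 5-year baseline survival, stratified by sex
trial = generate_trial(scenario)
scale = float(trial.truth["baseline_scale"].iloc[0])
s0 = float(np.exp(-(5.0 / scale)))
coef = dict(scenario.risk_coefficients)
linear_model = LinearPHRiskModel(
    stratum_column="sex",
    strata={s: StratumModel(coef, {k: 0.0 for k in coef}, s0) for s in ("F", "M")},
)

config = AnalysisConfig(
    models=["linear_ph", "tree", "forest"],
    scenario=scenario,
    linear_model=linear_model,
    seed=9,
)
bundle = run_hte_analysis(config)

print(f"analyzed {bundle.flow['n_analyzed']} participants "
      f"({bundle.flow['n_train']} train / {bundle.flow['n_test']} test)\n")
for name, m in bundle.models.items():
    top = m.subgroup_table.iloc[-1]
    print(f"{name:10s}  groups={m.subgroups.n_groups}  "
          f"top-group ARR={100 * top['arr']:.1f}% "
          f"({100 * top['arr_lo']:.1f} to {100 * top['arr_hi']:.1f})  "
          f"Q p={m.q_test.p_value:.3f}  interaction p={m.interaction_test.p_value:.3f}")

# A positive top-group ARR with a small Cochran's Q p-value says the absolute
# benefit differs across risk subgroups; an unremarkable interaction p says
# the hazard ratio does not — benefit concentrates where baseline risk is high.
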