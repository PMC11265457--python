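"""Applying a published stratified risk score from a coefficient table.

Shows the file-based workflow: write a sex-stratified linear PH score to a
coefficient CSV, read it back, predict 5-year risks for a cohort, cut the
scores into quintiles, and estimate the subgroup absolute risk reductions.
"""

import tempfile
from pathlib import Path

from riskhte import ScenarioConfig, generate_trial, quintile_partition
from riskhte.risk_models import LinearPHRiskModel, StratumModel, predict_linear_ph_risk
from riskhte.survival import arr_with_ci, cochran_q, km_estimate, nnt_from_arr
from riskhte.trialgen import CovariateSpec

# a published-style score: one model per sex, centered covariates
model = LinearPHRiskModel(
    stratum_column="sex",
    strata={
        "F": StratumModel({"age": 0.055, "frail": 0.6}, {"age": 74.0, "frail": 0.0}, 0.93),
        "M": StratumModel({"age": 0.065, "frail": 0.7}, {"age": 74.0, "frail": 0.0}, 0.90),
    },
)
table_path = Path(tempfile.mkdtemp()) / "coefficients.csv"
model.write_table(table_path)
model = LinearPHRiskModel.read_table(table_path, stratum_column="sex")

scenario = ScenarioConfig(
    n_participants=1150,
    covariates=[
        CovariateSpec("age", "continuous", {"mean": 74.0, "sd": 5.4}),
        CovariateSpec("frail", "binary", {"p": 0.05}),
        CovariateSpec("sex", "categorical", {"levels": ["F", "M"], "probs": [0.66, 0.34]}),
    ],
    risk_coefficients={"age": 0.06, "frail": 0.65},
    effect_mode="risk_graded",
    seed=6,
)
cohort = generate_trial(scenario).participants

risks = predict_linear_ph_risk(model, cohort)
groups = quintile_partition(risks, ids=cohort["id"].to_numpy())
print("group sizes:", [int(s) for s in groups.sizes()])

arrs = []
for g in range(1, 6):
    sub = cohort[groups.groups == g]
    control = sub[sub["arm"] == "control"]
    treated = sub[sub["arm"] == "treated"]
    est = arr_with_ci(
        km_estimate(control["time"], control["event"]),
        km_estimate(treated["time"], treated["event"]),
        t=5.0,
        subgroup=g,
    )
    arrs.append(est)
    print(f"group {g}: 5-year ARR = {100 * est.arr:5.1f}% "
          f"({100 * est.lo:5.1f} to {100 * est.hi:5.1f})")

q = cochran_q(arrs)
print(f"Cochran's Q = {q.statistic:.2f} on {q.df} df, p = {q.p_value:.3f}")
top = arrs[-1]
if top.lo > 0:
    nnt = nnt_from_arr(top)
    print(f"top-quintile NNT = {nnt.nnt:.1f} ({nnt.lo:.1f} to {nnt.hi:.1f})")

# Each row is the control-minus-treated 5-year Kaplan–Meier event rate in one
# risk quintile; Q tests whether these absolute differences share one value.
# At ~230 participants per quintile the benefit gradient is visible in the
# point estimates well before Q reaches significance — subgroup contrasts in
# mid-size trials are noisy, which is the method's central caveat.
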