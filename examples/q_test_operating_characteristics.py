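"""Operating characteristics of the subgroup heterogeneity tests.

Replicates three simulated scenarios — no effect, constant hazard ratio,
and risk-graded benefit — and reports how often Cochran's Q (absolute
scale) and the Cox interaction Wald test (relative scale) reject at 0.05.
Replication counts are kept small here so the script runs in ~30 s.
"""

import numpy as np

from riskhte import ScenarioConfig
from riskhte.experiments import replicate_q_experiment

REPS = 100

null = replicate_q_experiment(
    ScenarioConfig(n_participants=2300, effect_mode="null"), reps=REPS, seed=1
)
print(f"null effect:      Q rejects {100 * null['q_reject_rate']:.0f}% "
      f"(nominal 5%)")

constant = replicate_q_experiment(
    ScenarioConfig(
        n_participants=2300, effect_mode="constant_hr",
        effect_params={"log_hr": float(np.log(0.7))},
    ),
    reps=REPS // 2,
    seed=2,
    interaction=True,
)
print(f"constant HR 0.7:  Q rejects {100 * constant['q_reject_rate']:.0f}%, "
      f"interaction rejects {100 * constant['interaction_reject_rate']:.0f}%")

graded = replicate_q_experiment(
    ScenarioConfig(n_participants=2300, effect_mode="risk_graded"), reps=REPS, seed=3
)
print(f"risk-graded:      Q rejects {100 * graded['q_reject_rate']:.0f}%, "
      f"mean top-quintile ARR {100 * graded['mean_top_arr']:.1f}%")

# The dissociation to notice: a constant hazard ratio already spreads the
# absolute benefit across risk groups (Q above nominal) while the relative-
# scale interaction stays at its nominal level — absolute and relative
# heterogeneity are different questions about the same trial.
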