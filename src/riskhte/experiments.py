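"""Replication experiments on simulated trials.

These drive the operating-characteristic checks of the heterogeneity tests:
repeat a scenario over seeds, partition each replicate into risk-quintile
subgroups by the latent true risk, and record the absolute-scale Cochran's Q
and (optionally) the relative-scale Cox interaction test.  Subgrouping by
the latent risk isolates the behaviour of the tests themselves from the
variability of any fitted risk model.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from riskhte.risk_models import quintile_partition
from riskhte.survival import arr_with_ci, cochran_q, cox_interaction_test, km_estimate
from riskhte.trialgen import ScenarioConfig, generate_trial

__all__ = ["replicate_q_experiment"]


def _replicate_seeds(seed: int, reps: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(2**31, size=reps)


def replicate_q_experiment(
    config: ScenarioConfig,
    reps: int = 100,
    seed: int = 0,
    n_groups: int = 5,
    horizon: float = 5.0,
    alpha: float = 0.05,
    interaction: bool = False,
) -> dict:
    """Repeat ``config`` over ``reps`` seeds; test heterogeneity across
    true-risk quintiles in each replicate.

    Returns rejection rates at ``alpha`` for Cochran's Q (and, when
    ``interaction`` is set, the Cox interaction Wald test), the mean
    top-group ARR estimate, and the per-replicate records.
    """
    records = []
    for rep_seed in _replicate_seeds(seed, reps):
        cfg = dataclasses.replace(config, seed=int(rep_seed))
        trial = generate_trial(cfg)
        table = trial.participants
        assignment = quintile_partition(
            trial.truth["risk_control"].to_numpy(),
            ids=table["id"].to_numpy(),
            n_groups=n_groups,
        )
        arrs = []
        for g in range(1, n_groups + 1):
            sub = table[assignment.groups == g]
            treated = sub[sub["arm"] == "treated"]
            control = sub[sub["arm"] == "control"]
            arrs.append(
                arr_with_ci(
                    km_estimate(control["time"], control["event"]),
                    km_estimate(treated["time"], treated["event"]),
                    horizon,
                    alpha=alpha,
                    subgroup=g,
                )
            )
        q = cochran_q(arrs)
        rec = {
            "seed": int(rep_seed),
            "q_statistic": q.statistic,
            "q_p": q.p_value,
            "top_arr": arrs[-1].arr,
        }
        if interaction:
            test, _ = cox_interaction_test(table, assignment, alpha=alpha, subgroup_hrs=False)
            rec["interaction_p"] = test.p_value
        records.append(rec)

    out = {
        "q_reject_rate": float(np.mean([r["q_p"] < alpha for r in records])),
        "mean_top_arr": float(np.mean([r["top_arr"] for r in records])),
        "per_replicate": records,
    }
    if interaction:
        out["interaction_reject_rate"] = float(
            np.mean([r["interaction_p"] < alpha for r in records])
        )
    return out
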