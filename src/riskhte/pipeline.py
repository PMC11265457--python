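"""End-to-end analysis pipeline.

Runs the four stages — cohort preparation, subgroup-model fitting,
predictive-ability assessment, and treatment-heterogeneity testing — for any
subset of the three subgroup strategies, bundling results with provenance
(config hash, seeds, library versions) into a machine-readable report.

The extant linear-PH score is applied to the full filtered cohort (it was
developed elsewhere, so no held-out set is needed), while the tree and
forest train on the augmented training half and are assessed and subgrouped
on the untouched test half.  Predictive metrics are always computed on the
test half so models are compared on the same rows.  An option restricts the
linear-PH heterogeneity analysis to the test half for an apples-to-apples
comparison.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from riskhte import __version__
from riskhte.cohort import (
    binary_outcome_label,
    complete_case_filter,
    oversample_minority,
    read_participant_table,
    stratified_split,
)
from riskhte.evaluation import calibration_by_subgroup, threshold_metrics, time_dependent_auc
from riskhte.risk_models import (
    LinearPHRiskModel,
    SubgroupAssignment,
    fit_tree_committee,
    fit_weighted_forest,
    forest_risk_scores,
    predict_linear_ph_risk,
    quintile_partition,
    tree_risk_scores,
    tree_subgroups,
)
from riskhte.survival import (
    arr_with_ci,
    cochran_q,
    cox_interaction_test,
    km_estimate,
    nnt_from_arr,
    subgroup_results_table,
)

logger = logging.getLogger("riskhte")

__all__ = [
    "AnalysisConfig",
    "ModelReport",
    "ReportBundle",
    "run_hte_analysis",
    "flow_accounting",
    "merge_small_subgroups",
]

VALID_MODELS = ("linear_ph", "tree", "forest")


@dataclass
class AnalysisConfig:
    """Configuration for one full analysis run.

    Provide either ``participants_path`` (CSV participant table) or a
    ``scenario`` (simulation config from :mod:`riskhte.trialgen`).  The
    ``linear_ph`` model additionally needs ``coefficient_table_path`` plus
    ``stratum_column``, or a prefitted model object.
    """

    models: list[str] = field(default_factory=lambda: list(VALID_MODELS))
    participants_path: str | None = None
    scenario: "object | None" = None  # riskhte.trialgen.ScenarioConfig
    coefficient_table_path: str | None = None
    linear_model: LinearPHRiskModel | None = None
    stratum_column: str = "sex"
    covariates: list[str] | None = None  # None -> every non-core column
    required_covariates: list[str] | None = None  # None -> same as covariates
    horizon: float = 5.0
    n_groups: int = 5
    alpha: float = 0.05
    test_fraction: float = 0.5
    seed: int = 0
    min_subgroup_per_arm: int = 10
    restrict_linear_to_test: bool = False
    on_sparse: str = "fail"
    tree_params: dict = field(default_factory=dict)  # forwarded to fit_tree_committee
    forest_params: dict = field(default_factory=dict)  # forwarded to fit_weighted_forest
    output_dir: str | None = None

    def __post_init__(self):
        if not self.models:
            raise ValueError("at least one model must be requested")
        unknown = set(self.models) - set(VALID_MODELS)
        if unknown:
            raise ValueError(f"unknown models requested: {sorted(unknown)}")
        if self.horizon <= 0:
            raise ValueError("horizon must be > 0")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        scenario = d.pop("scenario", None)
        cfg = cls(**d)
        if scenario is not None:
            from riskhte.trialgen import CovariateSpec, ScenarioConfig

            scenario["covariates"] = [CovariateSpec(**c) for c in scenario.get("covariates", [])]
            cfg.scenario = ScenarioConfig(**scenario)
        return cfg

    def content_hash(self) -> str:
        d = dataclasses.asdict(self)
        d.pop("linear_model", None)
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class ModelReport:
    model: str
    subgroups: SubgroupAssignment
    subgroup_table: pd.DataFrame  # rates, ARR, HR per subgroup
    metrics: "object"  # ClassificationMetrics
    auc: float
    calibration: list
    q_test: "object"  # HeterogeneityTest, absolute scale
    interaction_test: "object"  # HeterogeneityTest, relative scale
    nnt_top_group: "object | None"  # NNTEstimate


@dataclass
class ReportBundle:
    flow: dict
    models: dict[str, ModelReport]
    provenance: dict

    @staticmethod
    def _jsonable(obj):
        """Recursively map non-finite floats to None so the JSON form
        round-trips losslessly (NaN is not valid JSON and never compares equal)."""
        if isinstance(obj, dict):
            return {k: ReportBundle._jsonable(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [ReportBundle._jsonable(v) for v in obj]
        if isinstance(obj, (float, np.floating)):
            return float(obj) if np.isfinite(obj) else None
        if isinstance(obj, np.integer):
            return int(obj)
        return obj

    def to_dict(self) -> dict:
        out = {"flow": self.flow, "provenance": self.provenance, "models": {}}
        for name, m in self.models.items():
            out["models"][name] = {
                "n_groups": m.subgroups.n_groups,
                "group_sizes": [int(s) for s in m.subgroups.sizes()],
                "subgroup_table": m.subgroup_table.to_dict(orient="records"),
                "metrics": {
                    "threshold": m.metrics.threshold,
                    "confusion": {"tp": m.metrics.tp, "fp": m.metrics.fp,
                                  "tn": m.metrics.tn, "fn": m.metrics.fn},
                    "accuracy": dataclasses.asdict(m.metrics.accuracy),
                    "sensitivity": dataclasses.asdict(m.metrics.sensitivity),
                    "specificity": dataclasses.asdict(m.metrics.specificity),
                    "ppv": dataclasses.asdict(m.metrics.ppv) if m.metrics.ppv else None,
                    "auc": m.auc,
                },
                "calibration": [dataclasses.asdict(r) for r in m.calibration],
                "q_test": dataclasses.asdict(m.q_test),
                "interaction_test": dataclasses.asdict(m.interaction_test),
                "nnt_top_group": dataclasses.asdict(m.nnt_top_group) if m.nnt_top_group else None,
            }
        return self._jsonable(out)

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    def write_tables(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, m in self.models.items():
            m.subgroup_table.to_csv(outdir / f"subgroups_{name}.csv", index=False)
            pd.DataFrame([dataclasses.asdict(r) for r in m.calibration]).to_csv(
                outdir / f"calibration_{name}.csv", index=False
            )
        flow_accounting(self).to_csv(outdir / "flow.csv", index=False)
        (outdir / "report.json").write_text(self.to_json())


def merge_small_subgroups(table, assignment, min_per_arm: int) -> SubgroupAssignment:
    """Collapse subgroups with fewer than ``min_per_arm`` participants in an
    arm into their lower neighbour (upper for group 1), renumbering 1..G'."""
    groups = assignment.groups.copy()
    arm = table["arm"].to_numpy()
    while True:
        labels = np.unique(groups)
        bad = None
        for g in labels:
            mask = groups == g
            if min((arm[mask] == "treated").sum(), (arm[mask] == "control").sum()) < min_per_arm:
                bad = g
                break
        if bad is None:
            break
        if len(labels) < 2:
            raise ValueError("cannot merge further: a single undersized subgroup remains")
        i = int(np.where(labels == bad)[0][0])
        target = labels[i - 1] if i > 0 else labels[1]
        groups[groups == bad] = target
    labels = np.unique(groups)
    relabel = {old: new for new, old in enumerate(labels, start=1)}
    groups = np.array([relabel[g] for g in groups])
    return SubgroupAssignment(
        groups=groups, n_groups=len(labels), provenance=assignment.provenance
    )


def _subgroup_arrs(table, assignment, horizon, alpha, min_per_arm):
    """KM/ARR per subgroup, guarding against subgroups too small to estimate."""
    groups = assignment.groups
    arrs = []
    for g in range(1, assignment.n_groups + 1):
        sub = table[groups == g]
        n_t = int((sub["arm"] == "treated").sum())
        n_c = int((sub["arm"] == "control").sum())
        if min(n_t, n_c) < min_per_arm:
            raise ValueError(
                f"subgroup {g} has fewer than {min_per_arm} participants in an arm "
                f"({n_t} treated / {n_c} control); Kaplan–Meier contrast unreliable"
            )
        treated = sub[sub["arm"] == "treated"]
        control = sub[sub["arm"] == "control"]
        curve_t = km_estimate(treated["time"], treated["event"])
        curve_c = km_estimate(control["time"], control["event"])
        arrs.append(arr_with_ci(curve_c, curve_t, horizon, alpha=alpha, subgroup=g))
    return arrs


def run_hte_analysis(config: AnalysisConfig) -> ReportBundle:
    """Execute the full four-stage analysis and return the report bundle."""
    scenario_used = None
    if config.participants_path is not None:
        raw = read_participant_table(config.participants_path)
    elif config.scenario is not None:
        from riskhte.trialgen import generate_trial

        scenario_used = config.scenario
        raw = generate_trial(config.scenario).participants
    else:
        raise ValueError("config must provide participants_path or scenario")

    covariates = config.covariates
    if covariates is None:
        covariates = [c for c in raw.columns if c not in ("id", "arm", "event", "time")]
    required = config.required_covariates or covariates

    filtered, n_excluded = complete_case_filter(raw, required)
    split = stratified_split(filtered, config.test_fraction, seed=config.seed)
    split.n_excluded = n_excluded
    train_aug = oversample_minority(split.train, seed=config.seed + 1)
    logger.info(
        "cohort: %d input, %d excluded, %d train (%d augmented), %d test",
        len(raw), n_excluded, len(split.train), len(train_aug), len(split.test),
    )

    test = split.test
    test_labels = binary_outcome_label(test)
    ml_covariates = [c for c in covariates if c != config.stratum_column] or covariates

    models: dict[str, ModelReport] = {}
    for name in config.models:
        if name == "linear_ph":
            model = config.linear_model
            if model is None:
                if config.coefficient_table_path is None:
                    raise ValueError(
                        "linear_ph requested but no coefficient table or model provided"
                    )
                model = LinearPHRiskModel.read_table(
                    config.coefficient_table_path, stratum_column=config.stratum_column
                )
            hte_table = test if config.restrict_linear_to_test else filtered
            hte_scores = predict_linear_ph_risk(model, hte_table)
            assignment = quintile_partition(
                hte_scores, ids=hte_table["id"].to_numpy(), n_groups=config.n_groups
            )
            test_scores = predict_linear_ph_risk(model, test)
            test_assignment = quintile_partition(
                test_scores, ids=test["id"].to_numpy(), n_groups=config.n_groups
            )
        elif name == "tree":
            committee = fit_tree_committee(
                train_aug, test, ml_covariates, seed=config.seed + 2, **config.tree_params
            )
            hte_table = test
            assignment = tree_subgroups(committee, test, ml_covariates)
            hte_scores = test_scores = tree_risk_scores(committee, test, ml_covariates)
            test_assignment = assignment
        elif name == "forest":
            forest = fit_weighted_forest(
                train_aug, ml_covariates, seed=config.seed + 3, **config.forest_params
            )
            hte_table = test
            hte_scores = test_scores = forest_risk_scores(forest, test, ml_covariates)
            assignment = quintile_partition(
                test_scores, ids=test["id"].to_numpy(), n_groups=config.n_groups
            )
            test_assignment = assignment

        if config.on_sparse == "merge":
            merged = merge_small_subgroups(hte_table, assignment, config.min_subgroup_per_arm)
            if merged.n_groups < assignment.n_groups:
                logger.info(
                    "%s: merged %d undersized subgroup(s)",
                    name, assignment.n_groups - merged.n_groups,
                )
            if hte_table is test:
                test_assignment = merged
            assignment = merged

        metrics = threshold_metrics(test_labels, test_scores, alpha=config.alpha)
        auc = time_dependent_auc(
            test["time"].to_numpy(), test_labels, test_scores, horizon=config.horizon
        )
        calibration = calibration_by_subgroup(
            test_assignment, test_scores, test, horizon=config.horizon
        )
        arrs = _subgroup_arrs(
            hte_table, assignment, config.horizon, config.alpha, config.min_subgroup_per_arm
        )
        q = cochran_q(arrs)
        interaction, hrs = cox_interaction_test(
            hte_table, assignment, alpha=config.alpha, on_sparse=config.on_sparse
        )
        top = arrs[-1]
        nnt = nnt_from_arr(top) if top.arr != 0 else None
        models[name] = ModelReport(
            model=name,
            subgroups=assignment,
            subgroup_table=subgroup_results_table(arrs, hrs),
            metrics=metrics,
            auc=auc,
            calibration=calibration,
            q_test=q,
            interaction_test=interaction,
            nnt_top_group=nnt,
        )
        logger.info(
            "%s: Q=%.3f (p=%.4f), interaction p=%.4f, top-group ARR=%.3f",
            name, q.statistic, q.p_value, interaction.p_value, top.arr,
        )

    flow = {
        "n_input": int(len(raw)),
        "n_excluded": int(n_excluded),
        "n_analyzed": int(len(filtered)),
        "n_train": int(len(split.train)),
        "n_train_augmented": int(len(train_aug)),
        "n_test": int(len(test)),
        "subgroup_sizes": {name: [int(s) for s in m.subgroups.sizes()] for name, m in models.items()},
    }
    provenance = {
        "riskhte_version": __version__,
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "scenario_seed": scenario_used.seed if scenario_used is not None else None,
        "train_ids": split.train["id"].tolist(),
        "test_ids": test["id"].tolist(),
        "versions": _library_versions(),
        "note": "no cross-model multiplicity correction applied",
    }
    bundle = ReportBundle(flow=flow, models=models, provenance=provenance)
    if config.output_dir:
        bundle.write_tables(config.output_dir)
    return bundle


def _library_versions() -> dict:
    import lifelines
    import sklearn

    return {
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
        "lifelines": lifelines.__version__,
    }


def flow_accounting(report: ReportBundle) -> pd.DataFrame:
    """Participant-flow table; stage counts are internally consistent
    (train + test = input − excluded; subgroup sizes sum to the scored set)."""
    flow = report.flow
    rows = [
        {"stage": "input", "n": flow["n_input"]},
        {"stage": "excluded_missing", "n": flow["n_excluded"]},
        {"stage": "analyzed", "n": flow["n_analyzed"]},
        {"stage": "train", "n": flow["n_train"]},
        {"stage": "train_augmented", "n": flow["n_train_augmented"]},
        {"stage": "test", "n": flow["n_test"]},
    ]
    for model, sizes in flow["subgroup_sizes"].items():
        for g, size in enumerate(sizes, start=1):
            rows.append({"stage": f"{model}_group_{g}", "n": size})
    return pd.DataFrame(rows)
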