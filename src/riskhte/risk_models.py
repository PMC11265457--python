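"""Subgroup-generating risk models.

Three interchangeable strategies for partitioning trial participants by
predicted outcome risk:

1. An extant stratified linear proportional-hazards risk score (per-stratum
   coefficients with a 5-year baseline survival), consumed from a published
   coefficient table — never re-estimated here.
2. A bootstrap committee of classification trees; the tree with median test
   accuracy is selected and its terminal leaves become the subgroups.
3. A probability-weighted random forest whose aggregated positive-class
   probabilities serve as risk scores.

Scores from strategies 1 and 3 are cut into rank quintiles (equal-size
blocks) — the partition used throughout the treatment-heterogeneity
analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "StratumModel",
    "LinearPHRiskModel",
    "SubgroupAssignment",
    "TreeCommittee",
    "WeightedForest",
    "predict_linear_ph_risk",
    "quintile_partition",
    "encode_features",
    "fit_tree_committee",
    "tree_subgroups",
    "tree_risk_scores",
    "fit_weighted_forest",
    "forest_risk_scores",
]

_BASELINE_ROW = "_baseline_survival_5y"


@dataclass
class StratumModel:
    coefficients: dict[str, float]
    centers: dict[str, float]
    baseline_survival_5y: float

    def __post_init__(self):
        if not 0 < self.baseline_survival_5y < 1:
            raise ValueError("5-year baseline survival must lie in (0, 1)")
        for name, c in self.coefficients.items():
            if not np.isfinite(c):
                raise ValueError(f"non-finite coefficient for {name!r}")


@dataclass
class LinearPHRiskModel:
    """Stratified linear PH risk score, e.g. separate models per sex.

    Predicted 5-year event risk for a participant in stratum s:
    ``1 - S0_s(5) ** exp(lp)`` with
    ``lp = sum_k beta_sk * (x_k - center_sk)``.
    """

    stratum_column: str
    strata: dict[str, StratumModel]

    @classmethod
    def read_table(cls, path, stratum_column: str) -> "LinearPHRiskModel":
        """Read a delimited coefficient table with columns
        stratum, covariate, coefficient, center; the baseline survival for
        each stratum sits on a row whose covariate is ``_baseline_survival_5y``
        (center empty)."""
        df = pd.read_csv(path, dtype={"stratum": str, "covariate": str})
        strata: dict[str, StratumModel] = {}
        for label, sub in df.groupby("stratum", sort=False):
            base = sub[sub["covariate"] == _BASELINE_ROW]
            if len(base) != 1:
                raise ValueError(f"stratum {label!r} needs exactly one baseline-survival row")
            coef_rows = sub[sub["covariate"] != _BASELINE_ROW]
            strata[label] = StratumModel(
                coefficients=dict(zip(coef_rows["covariate"], coef_rows["coefficient"].astype(float))),
                centers=dict(zip(coef_rows["covariate"], coef_rows["center"].astype(float))),
                baseline_survival_5y=float(base["coefficient"].iloc[0]),
            )
        return cls(stratum_column=stratum_column, strata=strata)

    def write_table(self, path) -> None:
        rows = []
        for label, m in self.strata.items():
            for cov, coef in m.coefficients.items():
                rows.append({"stratum": label, "covariate": cov,
                             "coefficient": repr(coef), "center": repr(m.centers.get(cov, 0.0))})
            rows.append({"stratum": label, "covariate": _BASELINE_ROW,
                         "coefficient": repr(m.baseline_survival_5y), "center": ""})
        pd.DataFrame(rows).to_csv(path, index=False)


def predict_linear_ph_risk(model: LinearPHRiskModel, table: pd.DataFrame) -> np.ndarray:
    """Predicted 5-year event probability per participant from the extant score."""
    if model.stratum_column not in table.columns:
        raise KeyError(f"table lacks stratum column {model.stratum_column!r}")
    risks = np.empty(len(table))
    strata_values = table[model.stratum_column].astype(str)
    for label, sub_idx in strata_values.groupby(strata_values).groups.items():
        if label not in model.strata:
            raise KeyError(f"stratum {label!r} absent from the risk model")
        m = model.strata[label]
        lp = np.zeros(len(sub_idx))
        for cov, coef in m.coefficients.items():
            if cov not in table.columns:
                raise KeyError(f"model covariate {cov!r} missing from table")
            x = table.loc[sub_idx, cov].to_numpy(dtype=float)
            if np.isnan(x).any():
                raise ValueError(f"missing values in covariate {cov!r}")
            lp += coef * (x - m.centers.get(cov, 0.0))
        risks[table.index.get_indexer(sub_idx)] = 1.0 - m.baseline_survival_5y ** np.exp(lp)
    return risks


@dataclass
class SubgroupAssignment:
    """Per-participant risk-group index in 1..n_groups (1 = lowest risk)."""

    groups: np.ndarray
    n_groups: int
    provenance: str  # "quintile" | "tree_leaf"

    def sizes(self) -> np.ndarray:
        return np.bincount(self.groups, minlength=self.n_groups + 1)[1:]


def quintile_partition(scores, ids=None, n_groups: int = 5) -> SubgroupAssignment:
    """Cut scores into ``n_groups`` contiguous rank blocks of near-equal size.

    Participants are sorted by (score, id) ascending and split into blocks
    whose sizes differ by at most one, the larger blocks at the higher
    (riskier) groups.  Rank-based cuts are what force the equal group sizes
    seen when a cohort of 1,150 yields five groups of exactly 230; any
    strictly monotone transform of the scores yields the same partition.
    """
    scores = np.asarray(scores, dtype=float)
    n = scores.size
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    if n < n_groups:
        raise ValueError("need at least one participant per group")
    if ids is None:
        ids = np.arange(n)
    order = np.lexsort((np.asarray(ids), scores))
    sizes = np.full(n_groups, n // n_groups)
    r = n % n_groups
    if r:
        sizes[-r:] += 1
    groups = np.empty(n, dtype=int)
    start = 0
    for g, size in enumerate(sizes, start=1):
        groups[order[start : start + size]] = g
        start += size
    return SubgroupAssignment(groups=groups, n_groups=n_groups, provenance="quintile")


def encode_features(
    table: pd.DataFrame, covariates: list[str], columns: list[str] | None = None
) -> pd.DataFrame:
    """Numeric design matrix: categorical covariates one-hot encoded.

    Passing ``columns`` (from a fitted model) aligns a new table to the
    training encoding, filling absent indicator columns with 0.
    """
    X = pd.get_dummies(table[covariates], dtype=float)
    if columns is not None:
        X = X.reindex(columns=columns, fill_value=0.0)
    return X


@dataclass
class TreeCommittee:
    """B classification trees fitted to bootstrap resamples; the tree whose
    held-out accuracy is the (lower) median is the committee's representative."""

    trees: list[DecisionTreeClassifier]
    accuracies: np.ndarray
    selected_index: int
    tuning: list[dict]
    feature_names: list[str]
    max_leaves: int
    seed: int

    @property
    def selected_tree(self) -> DecisionTreeClassifier:
        return self.trees[self.selected_index]

    def record(self) -> dict:
        """JSON-serializable reproducibility record (seed + tuning + selection)."""
        return {
            "seed": self.seed,
            "max_leaves": self.max_leaves,
            "feature_names": self.feature_names,
            "accuracies": [float(a) for a in self.accuracies],
            "selected_index": int(self.selected_index),
            "tuning": self.tuning,
        }

    def write_record(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.record(), fh, indent=2)


def _lower_median_index(values: np.ndarray) -> int:
    """Index of the lower-median order statistic (stable under ties)."""
    order = np.argsort(values, kind="stable")
    return int(order[(len(values) - 1) // 2])


def fit_tree_committee(
    train_augmented: pd.DataFrame,
    test: pd.DataFrame,
    covariates: list[str],
    B: int = 30,
    max_leaves: int = 6,
    seed: int = 0,
    cv_folds: int = 5,
    depth_grid: tuple = (2, 3, 4, 6),
    min_leaf_grid: tuple = (5, 10, 20),
) -> TreeCommittee:
    """Bootstrap committee of pruned classification trees.

    For each of ``B`` bootstrap resamples (with replacement, size = train
    size) of the class-balanced training set, a tree capped at ``max_leaves``
    terminal nodes is tuned by ``cv_folds``-fold cross-validation over depth
    and minimum leaf size (accuracy objective) and refitted on the full
    resample.  Each tree's accuracy is computed on the untouched test set;
    the tree at the lower-median accuracy is marked selected.  A resample
    containing a single class is redrawn (the retry is logged in the tuning
    record).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    from riskhte.cohort import binary_outcome_label

    X_train = encode_features(train_augmented, covariates)
    feature_names = list(X_train.columns)
    y_train = binary_outcome_label(train_augmented)
    X_test = encode_features(test, covariates, columns=feature_names).to_numpy()
    y_test = binary_outcome_label(test)
    Xtr = X_train.to_numpy()
    n = len(y_train)

    rng = np.random.default_rng(seed)
    trees, accuracies, tuning = [], [], []
    for b in range(B):
        retries = 0
        while True:
            idx = rng.integers(0, n, size=n)
            yb = y_train[idx]
            if yb.min() != yb.max():
                break
            retries += 1
        Xb = Xtr[idx]
        tree_seed = int(rng.integers(2**31))
        grid = GridSearchCV(
            DecisionTreeClassifier(max_leaf_nodes=max_leaves, random_state=tree_seed),
            {"max_depth": list(depth_grid), "min_samples_leaf": list(min_leaf_grid)},
            scoring="accuracy",
            cv=KFold(cv_folds, shuffle=False),
        )
        grid.fit(Xb, yb)
        tree = grid.best_estimator_
        acc = float(np.mean(tree.predict(X_test) == y_test))
        trees.append(tree)
        accuracies.append(acc)
        tuning.append(
            {
                "bootstrap": b,
                "retries": retries,
                "tree_seed": tree_seed,
                "best_params": {k: int(v) for k, v in grid.best_params_.items()},
                "cv_accuracy": float(grid.best_score_),
                "test_accuracy": acc,
            }
        )
    accuracies = np.asarray(accuracies)
    return TreeCommittee(
        trees=trees,
        accuracies=accuracies,
        selected_index=_lower_median_index(accuracies),
        tuning=tuning,
        feature_names=feature_names,
        max_leaves=max_leaves,
        seed=seed,
    )


def _leaf_order(tree: DecisionTreeClassifier) -> dict[int, int]:
    """Map sklearn leaf node id -> group index 1..G by ascending predicted
    event probability (leaf id breaks ties)."""
    t = tree.tree_
    leaves = np.where(t.children_left == -1)[0]
    probs = []
    for leaf in leaves:
        counts = t.value[leaf].ravel()
        probs.append(counts[-1] / counts.sum() if counts.sum() else 0.0)
    order = np.lexsort((leaves, np.asarray(probs)))
    return {int(leaves[j]): rank + 1 for rank, j in enumerate(order)}


def tree_subgroups(
    committee: TreeCommittee, table: pd.DataFrame, covariates: list[str]
) -> SubgroupAssignment:
    """Partition a table by the selected tree's terminal leaves.

    Group indices are the leaves numbered by ascending leaf-predicted event
    probability, so the highest group index is always the highest-risk leaf.
    Group sizes are data-driven and generally unequal.
    """
    tree = committee.selected_tree
    X = encode_features(table, covariates, columns=committee.feature_names).to_numpy()
    leaf_ids = tree.apply(X)
    mapping = _leaf_order(tree)
    groups = np.array([mapping[int(l)] for l in leaf_ids])
    return SubgroupAssignment(groups=groups, n_groups=len(mapping), provenance="tree_leaf")


def tree_risk_scores(
    committee: TreeCommittee, table: pd.DataFrame, covariates: list[str]
) -> np.ndarray:
    """Selected tree's leaf event probabilities, used as this model's scores."""
    X = encode_features(table, covariates, columns=committee.feature_names).to_numpy()
    return committee.selected_tree.predict_proba(X)[:, 1]


@dataclass
class WeightedForest:
    """Bagged classification trees with per-split feature subsetting; the
    forest's risk score is the mean over trees of each tree's positive-class
    leaf probability (a probability-weighted vote)."""

    model: RandomForestClassifier
    tuning: dict
    feature_names: list[str]
    seed: int

    def record(self) -> dict:
        return {"seed": self.seed, "feature_names": self.feature_names, "tuning": self.tuning}

    def write_record(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.record(), fh, indent=2)


def fit_weighted_forest(
    train_augmented: pd.DataFrame,
    covariates: list[str],
    n_trees: int = 100,
    max_leaves: int = 10,
    cv_folds: int = 10,
    seed: int = 0,
) -> WeightedForest:
    """Random forest of ``n_trees`` trees, each capped at ``max_leaves``
    terminal nodes, on the class-balanced training set.

    The per-split feature-subset size and minimum leaf size are chosen by
    ``cv_folds``-fold cross-validation maximizing classification accuracy.
    """
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    from riskhte.cohort import binary_outcome_label

    X = encode_features(train_augmented, covariates)
    feature_names = list(X.columns)
    y = binary_outcome_label(train_augmented)
    rf_seed = int(np.random.default_rng(seed).integers(2**31))
    grid = GridSearchCV(
        RandomForestClassifier(
            n_estimators=n_trees, max_leaf_nodes=max_leaves, random_state=rf_seed
        ),
        {"max_features": ["sqrt", None], "min_samples_leaf": [1, 10]},
        scoring="accuracy",
        cv=KFold(cv_folds, shuffle=False),
    )
    grid.fit(X.to_numpy(), y)
    tuning = {
        "best_params": {k: (v if v is None else (v if isinstance(v, str) else int(v)))
                        for k, v in grid.best_params_.items()},
        "cv_accuracy": float(grid.best_score_),
        "rf_seed": rf_seed,
        "grid": {"max_features": ["sqrt", None], "min_samples_leaf": [1, 10]},
    }
    return WeightedForest(
        model=grid.best_estimator_, tuning=tuning, feature_names=feature_names, seed=seed
    )


def forest_risk_scores(forest: WeightedForest, table: pd.DataFrame, covariates: list[str]) -> np.ndarray:
    """Aggregated positive-class probability per participant (mean over trees)."""
    X = encode_features(table, covariates, columns=forest.feature_names).to_numpy()
    return forest.model.predict_proba(X)[:, 1]
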