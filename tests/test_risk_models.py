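"""Risk models: extant linear-PH score, quintile cut, tree committee, forest."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import spearmanr

from riskhte import ScenarioConfig, generate_trial
from riskhte.cohort import binary_outcome_label, oversample_minority, stratified_split
from riskhte.risk_models import (
    LinearPHRiskModel,
    StratumModel,
    fit_tree_committee,
    fit_weighted_forest,
    forest_risk_scores,
    predict_linear_ph_risk,
    quintile_partition,
    tree_risk_scores,
    tree_subgroups,
)


def _single_stratum_model(coefficients, centers=None, s0=0.9, stratum="F"):
    return LinearPHRiskModel(
        stratum_column="sex",
        strata={
            stratum: StratumModel(
                coefficients=coefficients,
                centers=centers or {k: 0.0 for k in coefficients},
                baseline_survival_5y=s0,
            )
        },
    )


class TestLinearPHScore:
    def test_null_linear_predictor_gives_baseline_risk(self):
        model = _single_stratum_model({"age": 0.0})
        table = pd.DataFrame({"sex": ["F"] * 4, "age": [60, 70, 80, 90]})
        assert np.allclose(predict_linear_ph_risk(model, table), 0.1)

    def test_binary_covariate_closed_form(self):
        # coefficient ln 2 doubles the hazard: risk = 1 - 0.9^2 = 0.19
        model = _single_stratum_model({"flag": np.log(2)})
        table = pd.DataFrame({"sex": ["F", "F"], "flag": [1, 0]})
        risks = predict_linear_ph_risk(model, table)
        assert risks[0] == pytest.approx(0.19)
        assert risks[1] == pytest.approx(0.10)

    def test_risk_increases_with_positive_coefficient_covariate(self):
        model = _single_stratum_model({"age": 0.05}, centers={"age": 75.0})
        table = pd.DataFrame({"sex": ["F"] * 5, "age": [65, 70, 75, 80, 85]})
        risks = predict_linear_ph_risk(model, table)
        assert np.all(np.diff(risks) > 0)
        assert risks[2] == pytest.approx(0.1)  # at the centering value

    def test_stratification_uses_the_right_stratum(self):
        model = LinearPHRiskModel(
            stratum_column="sex",
            strata={
                "F": StratumModel({"age": 0.0}, {"age": 0.0}, 0.9),
                "M": StratumModel({"age": 0.0}, {"age": 0.0}, 0.8),
            },
        )
        table = pd.DataFrame({"sex": ["F", "M", "F"], "age": [70, 70, 70]})
        assert np.allclose(predict_linear_ph_risk(model, table), [0.1, 0.2, 0.1])

    def test_unknown_stratum_and_missing_covariate_raise(self):
        model = _single_stratum_model({"age": 0.1})
        with pytest.raises(KeyError, match="stratum"):
            predict_linear_ph_risk(model, pd.DataFrame({"sex": ["X"], "age": [70]}))
        with pytest.raises(KeyError, match="covariate"):
            predict_linear_ph_risk(model, pd.DataFrame({"sex": ["F"]}))

    def test_coefficient_table_round_trip(self, tmp_path):
        model = LinearPHRiskModel(
            stratum_column="sex",
            strata={
                "F": StratumModel({"age": 0.0527, "sbp": -0.013}, {"age": 75.0, "sbp": 135.0}, 0.912),
                "M": StratumModel({"age": 0.061}, {"age": 74.0}, 0.881),
            },
        )
        path = tmp_path / "coefficients.csv"
        model.write_table(path)
        loaded = LinearPHRiskModel.read_table(path, stratum_column="sex")
        assert loaded == model


class TestQuintilePartition:
    def test_1150_scores_give_five_groups_of_230(self):
        rng = np.random.default_rng(0)
        assignment = quintile_partition(rng.random(1150))
        assert list(assignment.sizes()) == [230] * 5

    def test_each_participant_its_own_group_at_n_equals_g(self):
        assignment = quintile_partition([0.3, 0.1, 0.5, 0.2, 0.4], n_groups=5)
        assert list(assignment.sizes()) == [1] * 5
        assert assignment.groups[np.argsort([0.3, 0.1, 0.5, 0.2, 0.4])].tolist() == [1, 2, 3, 4, 5]

    def test_ties_broken_by_id_order(self):
        assignment = quintile_partition(np.zeros(10), ids=np.arange(10), n_groups=5)
        assert list(assignment.sizes()) == [2] * 5
        assert assignment.groups.tolist() == [1, 1, 2, 2, 3, 3, 4, 4, 5, 5]

    def test_remainder_goes_to_higher_risk_groups(self):
        assignment = quintile_partition(np.arange(12), n_groups=5)
        assert list(assignment.sizes()) == [2, 2, 2, 3, 3]

    @given(st.lists(st.floats(-50, 50), min_size=5, max_size=200))
    def test_invariant_under_monotone_transform(self, scores):
        # round so the exp transform stays strictly monotone in float arithmetic
        scores = np.round(np.asarray(scores), 6)
        a = quintile_partition(scores)
        b = quintile_partition(3.0 * scores + 7.0)
        c = quintile_partition(np.exp(scores / 50.0))
        assert np.array_equal(a.groups, b.groups)
        assert np.array_equal(a.groups, c.groups)
        assert a.sizes().sum() == len(scores)

    def test_degenerate_arguments_raise(self):
        with pytest.raises(ValueError):
            quintile_partition([1.0, 2.0], n_groups=0)
        with pytest.raises(ValueError):
            quintile_partition([1.0, 2.0], n_groups=3)


@pytest.fixture(scope="module")
def split_and_augmented():
    trial = generate_trial(ScenarioConfig(n_participants=900, effect_mode="null", seed=40))
    split = stratified_split(trial.participants, 0.5, seed=1)
    train_aug = oversample_minority(split.train, seed=2)
    covariates = [c for c in trial.participants.columns if c.startswith("x")] + [
        "diabetes", "hypertension", "frail", "smoker",
    ]
    return trial, split, train_aug, covariates


class TestTreeCommittee:
    def test_single_bootstrap_tree_is_selected(self, split_and_augmented):
        _, split, train_aug, covariates = split_and_augmented
        committee = fit_tree_committee(train_aug, split.test, covariates, B=1, seed=5)
        assert committee.selected_index == 0
        assert len(committee.trees) == 1

    def test_selected_accuracy_is_lower_median(self, split_and_augmented):
        _, split, train_aug, covariates = split_and_augmented
        committee = fit_tree_committee(train_aug, split.test, covariates, B=6, seed=5)
        acc = np.sort(committee.accuracies)
        assert committee.accuracies[committee.selected_index] == acc[(6 - 1) // 2]

    def test_deterministic_given_seed(self, split_and_augmented):
        _, split, train_aug, covariates = split_and_augmented
        a = fit_tree_committee(train_aug, split.test, covariates, B=3, seed=8)
        b = fit_tree_committee(train_aug, split.test, covariates, B=3, seed=8)
        assert np.array_equal(a.accuracies, b.accuracies)
        assert a.selected_index == b.selected_index
        assert a.record() == b.record()

    def test_recovers_a_separable_boundary(self):
        """One covariate separates the classes at 0: the selected tree's
        first split lands near 0 and test accuracy is near perfect."""
        rng = np.random.default_rng(9)
        n = 600
        x = rng.uniform(-1, 1, n)
        table = pd.DataFrame(
            {
                "id": np.arange(n),
                "arm": "control",
                "event": (x > 0).astype(int),
                "time": 1.0,
                "x": x,
                "noise": rng.normal(size=n),
            }
        )
        split = stratified_split(table, 0.5, seed=0)
        committee = fit_tree_committee(split.train, split.test, ["x", "noise"], B=5, seed=3)
        tree = committee.selected_tree
        assert committee.accuracies[committee.selected_index] >= 0.95
        root_feature = tree.tree_.feature[0]
        assert committee.feature_names[root_feature] == "x"
        assert abs(tree.tree_.threshold[0]) < 0.15

    def test_leaf_subgroups_partition_and_order_by_risk(self, split_and_augmented):
        _, split, train_aug, covariates = split_and_augmented
        committee = fit_tree_committee(train_aug, split.test, covariates, B=5, seed=5)
        assignment = tree_subgroups(committee, split.test, covariates)
        assert assignment.sizes().sum() == len(split.test)
        assert assignment.n_groups <= 6
        # leaf-predicted probabilities must increase with the group index
        scores = tree_risk_scores(committee, split.test, covariates)
        means = [scores[assignment.groups == g].mean() for g in range(1, assignment.n_groups + 1)]
        assert np.all(np.diff(means) > 0)

    def test_constant_features_yield_single_leaf(self):
        table = pd.DataFrame(
            {
                "id": np.arange(40),
                "arm": "control",
                "event": np.r_[np.ones(20, int), np.zeros(20, int)],
                "time": 1.0,
                "x": 1.0,
            }
        )
        committee = fit_tree_committee(table, table, ["x"], B=1, seed=0)
        assignment = tree_subgroups(committee, table, ["x"])
        assert assignment.n_groups == 1
        assert np.all(assignment.groups == 1)


class TestWeightedForest:
    def test_single_tree_forest_equals_its_tree(self, split_and_augmented):
        _, split, train_aug, covariates = split_and_augmented
        forest = fit_weighted_forest(train_aug, covariates, n_trees=1, cv_folds=3, seed=6)
        probs = forest_risk_scores(forest, split.test, covariates)
        single = forest.model.estimators_[0].predict_proba(
            np.asarray(split.test[covariates], dtype=float)
        )[:, 1]
        assert np.allclose(probs, single)
        assert np.all((probs >= 0) & (probs <= 1))

    def test_pure_noise_labels_have_chance_auc(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(12)
        n = 2000
        table = pd.DataFrame({f"x{i}": rng.normal(size=n) for i in range(1, 6)})
        table["id"] = np.arange(n)
        table["arm"] = "control"
        table["time"] = 1.0
        table["event"] = rng.binomial(1, 0.5, n)
        half = n // 2
        forest = fit_weighted_forest(
            table.iloc[:half], [f"x{i}" for i in range(1, 6)], n_trees=50, cv_folds=5, seed=7
        )
        scores = forest_risk_scores(forest, table.iloc[half:], [f"x{i}" for i in range(1, 6)])
        auc = roc_auc_score(table["event"].iloc[half:], scores)
        assert 0.45 <= auc <= 0.55

    def test_scores_track_simulated_truth(self, graded_trial):
        table = graded_trial.participants
        covariates = [c for c in table.columns if c not in ("id", "arm", "event", "time")]
        split = stratified_split(table, 0.5, seed=3)
        train_aug = oversample_minority(split.train, seed=4)
        forest = fit_weighted_forest(train_aug, covariates, cv_folds=5, seed=5)
        scores = forest_risk_scores(forest, split.test, covariates)
        truth = graded_trial.truth.set_index("id").loc[split.test["id"], "risk_control"]
        rho = spearmanr(scores, truth).statistic
        assert rho > 0.3
        # identical participants receive identical scores
        dup = pd.concat([split.test.iloc[[0]], split.test.iloc[[0]]])
        s = forest_risk_scores(forest, dup, covariates)
        assert s[0] == s[1]

    def test_mean_true_risk_rises_across_score_quintiles(self, graded_trial):
        """For both the latent linear predictor and forest scores, quintiles
        order the true risk."""
        table = graded_trial.participants
        covariates = [c for c in table.columns if c not in ("id", "arm", "event", "time")]
        truth = graded_trial.truth["risk_control"].to_numpy()
        lp_groups = quintile_partition(graded_trial.truth["lp"].to_numpy(), ids=table["id"].to_numpy())
        means = [truth[lp_groups.groups == g].mean() for g in range(1, 6)]
        assert np.all(np.diff(means) > 0)

        split = stratified_split(table, 0.5, seed=6)
        train_aug = oversample_minority(split.train, seed=7)
        forest = fit_weighted_forest(train_aug, covariates, cv_folds=5, seed=8)
        scores = forest_risk_scores(forest, split.test, covariates)
        test_truth = graded_trial.truth.set_index("id").loc[split.test["id"], "risk_control"].to_numpy()
        fr_groups = quintile_partition(scores, ids=split.test["id"].to_numpy())
        fr_means = [test_truth[fr_groups.groups == g].mean() for g in range(1, 6)]
        assert np.all(np.diff(fr_means) >= 0)

    def test_forest_quintiles_on_1150_rows_give_230_per_group(self, graded_trial):
        table = graded_trial.participants.iloc[:1150]
        covariates = [c for c in table.columns if c not in ("id", "arm", "event", "time")]
        forest = fit_weighted_forest(table, covariates, n_trees=20, cv_folds=3, seed=9)
        scores = forest_risk_scores(forest, table, covariates)
        assignment = quintile_partition(scores, ids=table["id"].to_numpy())
        assert list(assignment.sizes()) == [230] * 5

    def test_invalid_n_trees_raises(self, split_and_augmented):
        _, _, train_aug, covariates = split_and_augmented
        with pytest.raises(ValueError):
            fit_weighted_forest(train_aug, covariates, n_trees=0)
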