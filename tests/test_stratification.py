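"""Oversampling, splitting, random forest, and feature ranking."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from lbx.cohort import CohortSpec, generate_cohort
from lbx.stratification import (
    FEATURE_COLUMNS,
    ModelConfig,
    fit_evaluate,
    make_split,
    oversample,
    rank_features,
    run_stratification,
)


@pytest.fixture(scope="module")
def cohort():
    return generate_cohort(CohortSpec(seed=0))


class TestOversample:
    def test_default_sizes_rebalance_to_296(self, cohort):
        reb = oversample(cohort, seed=0)
        assert len(reb.data) == 296
        sizes = reb.sizes_after
        assert sizes == {"early": 74, "late": 74, "normal": 148}

    def test_already_balanced_input_unchanged(self):
        spec = CohortSpec(n_per_group={"early": 20, "late": 20, "normal": 40}, seed=3)
        balanced = generate_cohort(spec)
        reb = oversample(balanced, seed=0)
        assert len(reb.data) == len(balanced)
        assert reb.duplicate_of == {}

    def test_duplicates_are_exact_copies_of_originals(self, cohort):
        reb = oversample(cohort, seed=5)
        for new_pos, orig_pos in reb.duplicate_of.items():
            dup = reb.data.iloc[new_pos]
            orig = reb.data.iloc[orig_pos]
            assert dup["group"] == orig["group"]
            assert (dup[list(FEATURE_COLUMNS)] == orig[list(FEATURE_COLUMNS)]).all()

    def test_missing_group_rejected(self, cohort):
        with pytest.raises(ValueError, match="late"):
            oversample(cohort[cohort["group"] != "late"], seed=0)


class TestMakeSplit:
    def test_cancer_vs_normal_partition_sizes(self, cohort):
        reb = oversample(cohort, seed=0)
        plan = make_split(reb, "cancer-vs-normal", seed=0)
        train_labels = plan.labels.loc[plan.train_index]
        test_labels = plan.labels.loc[plan.test_index]
        assert train_labels.value_counts().to_dict() == {"cancer": 111, "normal": 111}
        assert test_labels.value_counts().to_dict() == {"cancer": 37, "normal": 37}

    def test_early_vs_late_partition_sizes(self, cohort):
        reb = oversample(cohort, seed=0)
        plan = make_split(reb, "early-vs-late", seed=0)
        train_labels = plan.labels.loc[plan.train_index]
        test_labels = plan.labels.loc[plan.test_index]
        assert train_labels.value_counts().to_dict() == {"early": 56, "late": 55}
        assert test_labels.value_counts().to_dict() == {"early": 18, "late": 19}

    def test_train_test_partition_is_exact(self, cohort):
        reb = oversample(cohort, seed=1)
        plan = make_split(reb, "cancer-vs-normal", seed=1)
        train, test = set(plan.train_index), set(plan.test_index)
        assert train.isdisjoint(test)
        assert train | test == set(reb.data.index)

    def test_ten_folds_assigned_on_train(self, cohort):
        reb = oversample(cohort, seed=0)
        plan = make_split(reb, "early-vs-late", seed=0)
        assert set(plan.folds) == set(range(10))

    def test_too_small_class_rejected(self):
        spec = CohortSpec(n_per_group={"early": 8, "late": 8, "normal": 16}, seed=0)
        reb = oversample(generate_cohort(spec), seed=0)
        with pytest.raises(ValueError, match="folds"):
            make_split(reb, "early-vs-late", seed=0)


def _separable_cohort(n=60):
    rng = np.random.default_rng(0)
    rows = []
    for group, lo, hi in (("early", 0.0, 1.0), ("late", 10.0, 20.0), ("normal", 0.0, 1.0)):
        for i in range(n):
            row = {"sample_id": f"{group}{i}", "group": group}
            for col in FEATURE_COLUMNS:
                row[col] = rng.uniform(lo, hi)
            rows.append(row)
    return pd.DataFrame(rows)


class TestFitEvaluate:
    def test_perfectly_separable_features_reach_auc_one(self):
        report = run_stratification(_separable_cohort(), "early-vs-late", seed=0)
        assert report.cv_auc == 1.0
        assert report.test_f1 == 1.0
        assert report.test_auc == 1.0

    def test_confusion_matrix_sums_to_test_size(self, cohort):
        report = run_stratification(cohort, "cancer-vs-normal", seed=2)
        assert report.confusion.to_numpy().sum() == 74

    def test_merged_fold_auc_is_trapezoid_of_stored_curve(self, cohort):
        report = run_stratification(cohort, "early-vs-late", seed=3)
        recomputed = np.trapezoid(report.cv_roc["tpr"], report.cv_roc["fpr"])
        assert report.cv_auc == pytest.approx(float(recomputed))

    def test_permuted_labels_give_chance_auc(self, cohort):
        # permute the task labels of the rebalanced rows: any association
        # between features and outcome is destroyed (permuting before
        # oversampling would leave label-consistent duplicates across the
        # split, which a forest can memorize)
        rng = np.random.default_rng(0)
        aucs = []
        for seed in range(50):
            reb = oversample(cohort, seed=seed)
            plan = make_split(reb, "cancer-vs-normal", seed=seed)
            plan.labels = pd.Series(
                rng.permutation(plan.labels.to_numpy()), index=plan.labels.index
            )
            report = fit_evaluate(reb, plan, ModelConfig(seed=seed))
            aucs.append(report.cv_auc)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.1)

    def test_missing_feature_column_named(self, cohort):
        broken = cohort.drop(columns=["rate_LEV"])
        with pytest.raises(KeyError, match="rate_LEV"):
            run_stratification(broken, "cancer-vs-normal", seed=0)


class TestRankFeatures:
    def test_label_copy_feature_ranks_first_and_constant_ranks_zero(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({c: rng.random(100) for c in FEATURE_COLUMNS})
        df["task_label"] = np.where(rng.random(100) < 0.5, "a", "b")
        df[FEATURE_COLUMNS[0]] = (df["task_label"] == "a").astype(float)
        df[FEATURE_COLUMNS[1]] = 3.14
        ranking = rank_features(df)
        assert ranking["feature"].iloc[0] == FEATURE_COLUMNS[0]
        row = ranking[ranking["feature"] == FEATURE_COLUMNS[1]]
        assert row["information_gain"].iloc[0] == 0.0

    def test_constant_label_rejected(self):
        df = pd.DataFrame({c: np.arange(20.0) for c in FEATURE_COLUMNS})
        df["task_label"] = "a"
        with pytest.raises(ValueError, match="constant"):
            rank_features(df)

    def test_lev_rate_is_the_leading_predictor(self):
        firsts = 0
        for seed in range(40):
            cohort = generate_cohort(CohortSpec(seed=100 + seed))
            report = run_stratification(cohort, "cancer-vs-normal", seed=seed)
            firsts += report.feature_ranking["feature"].iloc[0] == "rate_LEV"
        assert firsts >= 0.8 * 40
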