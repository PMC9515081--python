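"""Cohort stratification: oversampling, stratified split, random forest.

Protocol: (1) rebalance by random oversampling with replacement — the
late-stage group up to the early-stage size, then the normal group up to
the combined cancer size; (2) stratified 75/25 train/test split with a
fixed per-class rounding rule; (3) a 10-tree random forest assessed by
10-fold cross-validation on the training partition, with the ROC built
from the merged out-of-fold predictions; (4) refit on the full training
partition and score the held-out test set (confusion matrix, F1);
(5) rank features by information gain on the training partition.

Oversampling precedes the split, so duplicates of one original sample
can land on both sides of it; this leakage is inherent to the protocol
being modelled and is flagged in every report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import auc, confusion_matrix, f1_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from .labels import ENUMERATED_CLASSES

TASKS = ("cancer-vs-normal", "early-vs-late")

#: Feature set: per-ml rates of every enumerated event class.
FEATURE_COLUMNS: tuple[str, ...] = tuple(f"rate_{c}" for c in ENUMERATED_CLASSES)

#: Positive class per task (the clinically "alarming" side).
POSITIVE_CLASS = {"cancer-vs-normal": "cancer", "early-vs-late": "late"}


@dataclass
class RebalancedCohort:
    """Oversampled cohort plus provenance of the duplicated rows."""

    data: pd.DataFrame
    duplicate_of: dict[int, int]  # new row position -> original row position
    sizes_before: dict[str, int]
    sizes_after: dict[str, int]


@dataclass
class SplitPlan:
    """Train/test partition with a 10-fold assignment on the train side."""

    task: str
    train_index: np.ndarray
    test_index: np.ndarray
    folds: np.ndarray  # fold id per train row
    labels: pd.Series  # binary task label per row of the rebalanced cohort


@dataclass
class ModelConfig:
    trees: int = 10
    folds: int = 10
    train_fraction: float = 0.75
    seed: int = 0


@dataclass
class ModelReport:
    """Stratification experiment output.

    Carries both the merged-fold cross-validation view and the held-out
    test view, since published figures mix the two. ``rf_params`` records
    the full forest configuration for reproducibility.
    """

    task: str
    cv_roc: pd.DataFrame  # fpr, tpr, threshold of the merged-fold ROC
    cv_auc: float
    fold_aucs: list[float]
    test_auc: float
    test_f1: float
    confusion: pd.DataFrame
    feature_ranking: pd.DataFrame  # feature, information_gain (descending)
    rf_params: dict = field(default_factory=dict)
    oversample_leakage_note: str = (
        "oversampling precedes the train/test split; duplicated samples may "
        "appear in both partitions"
    )

    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "cv_auc": self.cv_auc,
            "fold_aucs": self.fold_aucs,
            "test_auc": self.test_auc,
            "test_f1": self.test_f1,
            "confusion": self.confusion.to_dict(),
            "feature_ranking": self.feature_ranking.to_dict(orient="records"),
            "rf_params": self.rf_params,
            "note": self.oversample_leakage_note,
        }


def oversample(cohort: pd.DataFrame, seed: int = 0) -> RebalancedCohort:
    """Rebalance groups by random duplication of original rows.

    Stage 1 brings the late-stage group to the early-stage size; stage 2
    brings the normal group to the combined cancer size. Groups already
    at/above target are left untouched. With the default study sizes
    (74/26/30) this yields 74 early + 74 late + 148 normal = 296 rows.
    """
    rng = np.random.default_rng(seed)
    counts = cohort["group"].value_counts().to_dict()
    for g in ("early", "late", "normal"):
        if counts.get(g, 0) == 0:
            raise ValueError(f"missing group {g!r}")

    df = cohort.reset_index(drop=True)
    duplicate_of: dict[int, int] = {}

    def top_up(frame: pd.DataFrame, group: str, target: int) -> pd.DataFrame:
        members = frame.index[frame["group"] == group].to_numpy()
        deficit = target - len(members)
        if deficit <= 0:
            return frame
        picks = rng.choice(members, size=deficit, replace=True)
        extra = frame.loc[picks].copy()
        start = len(frame)
        extra.index = range(start, start + deficit)
        for new_pos, orig_pos in zip(extra.index, picks):
            duplicate_of[int(new_pos)] = int(orig_pos)
        return pd.concat([frame, extra])

    df = top_up(df, "late", counts["early"])
    cancer_total = counts["early"] + max(counts["early"], counts["late"])
    df = top_up(df, "normal", cancer_total)
    after = df["group"].value_counts().to_dict()
    return RebalancedCohort(
        df.reset_index(drop=True), duplicate_of, counts, after
    )


def _task_labels(data: pd.DataFrame, task: str) -> pd.Series:
    if task == "cancer-vs-normal":
        return data["group"].map(
            lambda g: "cancer" if g in ("early", "late") else "normal"
        )
    if task == "early-vs-late":
        labels = data["group"].where(data["group"].isin(["early", "late"]))
        return labels
    raise ValueError(f"unknown task {task!r}; expected one of {TASKS}")


def make_split(
    rebalanced: RebalancedCohort,
    task: str,
    seed: int = 0,
    config: ModelConfig | None = None,
) -> SplitPlan:
    """Stratified 75/25 split with 10-fold assignment on the train side.

    Per-class training sizes use a fixed rounding rule — ceil for the
    alphabetically first class, floor for the second — which reproduces
    the canonical partition sizes for the default cohort: 111/111 train
    and 37/37 test for cancer-vs-normal, 56/55 and 18/19 for
    early-vs-late.
    """
    config = config or ModelConfig(seed=seed)
    rng = np.random.default_rng(seed)
    labels = _task_labels(rebalanced.data, task)
    mask = labels.notna()
    classes = sorted(labels.dropna().unique())

    train_parts, test_parts = [], []
    for i, cls in enumerate(classes):
        members = rebalanced.data.index[mask & (labels == cls)].to_numpy()
        rng.shuffle(members)
        exact = config.train_fraction * len(members)
        n_train = math.ceil(exact) if i == 0 else math.floor(exact)
        train_parts.append(members[:n_train])
        test_parts.append(members[n_train:])
    train_index = np.concatenate(train_parts)
    test_index = np.concatenate(test_parts)

    train_labels = labels.loc[train_index]
    smallest = train_labels.value_counts().min()
    if smallest < config.folds:
        raise ValueError(
            f"cannot form {config.folds} folds: a class has only {smallest} training members"
        )
    skf = StratifiedKFold(n_splits=config.folds, shuffle=True, random_state=seed % 2**31)
    folds = np.empty(len(train_index), dtype=int)
    for fold_id, (_, val_pos) in enumerate(
        skf.split(np.zeros(len(train_index)), train_labels.to_numpy())
    ):
        folds[val_pos] = fold_id
    return SplitPlan(task, train_index, test_index, folds, labels)


def rank_features(
    train: pd.DataFrame,
    label_col: str = "task_label",
    features: tuple[str, ...] = FEATURE_COLUMNS,
    bins: int = 10,
) -> pd.DataFrame:
    """Information-gain ranking on equal-frequency-discretized features.

    Gain = H(label) - sum_b p(b) H(label | bin b), with features cut into
    at most ``bins`` equal-frequency bins. Descending by gain, ties
    broken alphabetically. A constant label column is an error.
    """
    y = train[label_col]
    if y.nunique() < 2:
        raise ValueError("label column is constant; information gain undefined")

    def entropy(s: pd.Series) -> float:
        p = s.value_counts(normalize=True).to_numpy()
        return float(-(p * np.log2(p)).sum())

    h_y = entropy(y)
    rows = []
    for feat in features:
        if feat not in train.columns:
            raise KeyError(f"missing feature column {feat!r}")
        values = train[feat]
        if values.nunique() <= 1:
            gain = 0.0
        else:
            # bin on the values themselves so ties share a bin (zero-inflated
            # rates are heavily tied and must not leak row order); features
            # with few distinct values are grouped by value directly
            if values.nunique() <= bins:
                binned = values
            else:
                binned = pd.qcut(values, q=bins, duplicates="drop")
            cond = 0.0
            for _, idx in y.groupby(binned, observed=True).groups.items():
                frac = len(idx) / len(y)
                cond += frac * entropy(y.loc[idx])
            gain = h_y - cond
        rows.append({"feature": feat, "information_gain": gain})
    out = pd.DataFrame(rows).sort_values(
        ["information_gain", "feature"], ascending=[False, True]
    )
    return out.reset_index(drop=True)


def fit_evaluate(
    rebalanced: RebalancedCohort,
    plan: SplitPlan,
    config: ModelConfig | None = None,
) -> ModelReport:
    """Train and assess the random forest under the split plan."""
    config = config or ModelConfig()
    data = rebalanced.data
    for col in FEATURE_COLUMNS:
        if col not in data.columns:
            raise KeyError(f"missing feature column {col!r}")

    pos = POSITIVE_CLASS[plan.task]
    x_train = data.loc[plan.train_index, list(FEATURE_COLUMNS)].to_numpy()
    y_train = (plan.labels.loc[plan.train_index] == pos).to_numpy()
    x_test = data.loc[plan.test_index, list(FEATURE_COLUMNS)].to_numpy()
    y_test = (plan.labels.loc[plan.test_index] == pos).to_numpy()

    rf_seed = config.seed % 2**31

    # merged-fold CV predictions on the training partition
    oof = np.empty(len(x_train))
    fold_aucs = []
    for fold_id in range(config.folds):
        val = plan.folds == fold_id
        model = RandomForestClassifier(
            n_estimators=config.trees, random_state=rf_seed
        )
        model.fit(x_train[~val], y_train[~val])
        oof[val] = model.predict_proba(x_train[val])[:, 1]
        if len(np.unique(y_train[val])) == 2:
            fpr_f, tpr_f, _ = roc_curve(y_train[val], oof[val])
            fold_aucs.append(float(auc(fpr_f, tpr_f)))
    fpr, tpr, thresholds = roc_curve(y_train, oof)
    cv_auc = float(auc(fpr, tpr))

    # refit on the full training partition, score the held-out test set
    final = RandomForestClassifier(n_estimators=config.trees, random_state=rf_seed)
    final.fit(x_train, y_train)
    test_scores = final.predict_proba(x_test)[:, 1]
    fpr_t, tpr_t, _ = roc_curve(y_test, test_scores)
    test_auc = float(auc(fpr_t, tpr_t))
    y_pred = final.predict(x_test)
    f1 = float(f1_score(y_test, y_pred))
    cm = confusion_matrix(y_test, y_pred, labels=[True, False])
    confusion = pd.DataFrame(
        cm,
        index=[f"true_{pos}", "true_other"],
        columns=[f"pred_{pos}", "pred_other"],
    )

    train_df = data.loc[plan.train_index, list(FEATURE_COLUMNS)].copy()
    train_df["task_label"] = plan.labels.loc[plan.train_index].to_numpy()
    ranking = rank_features(train_df)

    return ModelReport(
        task=plan.task,
        cv_roc=pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds}),
        cv_auc=cv_auc,
        fold_aucs=fold_aucs,
        test_auc=test_auc,
        test_f1=f1,
        confusion=confusion,
        feature_ranking=ranking,
        rf_params=final.get_params(),
    )


def run_stratification(
    cohort: pd.DataFrame, task: str, seed: int = 0, config: ModelConfig | None = None
) -> ModelReport:
    """Full protocol: oversample, split, fit, evaluate."""
    config = config or ModelConfig(seed=seed)
    rebalanced = oversample(cohort, seed=seed)
    plan = make_split(rebalanced, task, seed=seed, config=config)
    return fit_evaluate(rebalanced, plan, config)
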