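"""Random-forest classification of subjects from tract FA + structure volumes.

Feature matrices join per-subject TFAS tract means (TOI features) with
ICV-standardized structure volumes (SOI features). Classification is
pairwise (patients vs controls, variant vs variant) with a stratified
fivefold cross-validation — each fold trains on 80% and validates on the
held-out 20% — using a forest of 100 trees, Gini splitting criterion,
maximum depth 4, minimum samples to split 2, minimum samples per leaf 1,
sqrt feature subsampling, and bootstrap resampling, under a fixed random
state. Feature selection removes the feature with the lowest fold-averaged
Gini importance as long as the cross-validated accuracy does not degrade.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

RF_HYPERPARAMS = dict(
    n_estimators=100,
    criterion="gini",
    max_depth=4,
    min_samples_split=2,
    min_samples_leaf=1,
    max_features="sqrt",
    bootstrap=True,
)

N_FOLDS = 5


@dataclass
class FeatureMatrix:
    X: pd.DataFrame                 # rows: subjects; columns: TOI then SOI features
    y: pd.Series                    # diagnostic group per subject
    excluded: list[tuple[str, str]] = field(default_factory=list)  # (id, reason)

    def subset(self, groups: tuple[str, str]) -> "FeatureMatrix":
        keep = self.y.isin(groups)
        return FeatureMatrix(self.X.loc[keep], self.y.loc[keep], list(self.excluded))


@dataclass
class CVReport:
    task: tuple[str, str]
    fold_accuracy: np.ndarray
    fold_sensitivity: np.ndarray
    fold_specificity: np.ndarray
    importances: pd.DataFrame       # folds x features, Gini importance
    features: list[str]
    seed: int

    @property
    def accuracy(self) -> float:
        return float(self.fold_accuracy.mean())

    @property
    def accuracy_sd(self) -> float:
        return float(self.fold_accuracy.std(ddof=1))

    @property
    def sensitivity(self) -> float:
        return float(self.fold_sensitivity.mean())

    @property
    def specificity(self) -> float:
        return float(self.fold_specificity.mean())

    def mean_importance(self) -> pd.Series:
        return self.importances.mean(axis=0).sort_values(ascending=False)

    def summary(self) -> dict:
        return {
            "task": list(self.task),
            "accuracy": self.accuracy, "accuracy_sd": self.accuracy_sd,
            "sensitivity": self.sensitivity,
            "sensitivity_sd": float(self.fold_sensitivity.std(ddof=1)),
            "specificity": self.specificity,
            "specificity_sd": float(self.fold_specificity.std(ddof=1)),
            "n_features": len(self.features),
            "top_feature": self.mean_importance().index[0],
        }


def assemble_features(tfas_records: pd.DataFrame, soi_table: pd.DataFrame,
                      cohort: pd.DataFrame,
                      toi_order: list[str] | None = None,
                      soi_order: list[str] | None = None) -> FeatureMatrix:
    """Inner-join TOI mean-FA and SOI volume features on subject id.

    Subjects missing any feature are excluded with a logged reason; a
    duplicated subject id in either table is an error. Column order is
    deterministic: TOIs in catalogue order, then SOIs.
    """
    toi_wide = tfas_records.pivot_table(index="subject_id", columns="toi",
                                        values="mean_fa", aggfunc="count")
    if (toi_wide > 1).any().any():
        raise ValueError("duplicated subject id in TFAS records")
    toi_feat = tfas_records.pivot(index="subject_id", columns="toi", values="mean_fa")
    soi_dups = soi_table.duplicated(subset=["subject_id", "soi"])
    if soi_dups.any():
        raise ValueError("duplicated subject id in SOI table")
    soi_feat = soi_table.pivot(index="subject_id", columns="soi",
                               values="standardized_volume_ml")
    toi_cols = toi_order or sorted(toi_feat.columns)
    soi_cols = soi_order or sorted(soi_feat.columns)
    toi_feat = toi_feat.reindex(columns=toi_cols).add_prefix("toi_")
    soi_feat = soi_feat.reindex(columns=soi_cols).add_prefix("soi_")
    X = toi_feat.join(soi_feat, how="outer")

    excluded = []
    complete = X.notna().all(axis=1)
    for sid in X.index[~complete]:
        missing = X.columns[X.loc[sid].isna()].tolist()
        excluded.append((sid, f"missing features: {', '.join(missing)}"))
    X = X.loc[complete]

    base = cohort[cohort["timepoint"] == "baseline"] if "timepoint" in cohort else cohort
    labels = base.set_index("subject_id")["group"]
    in_cohort = X.index.isin(labels.index)
    for sid in X.index[~in_cohort]:
        excluded.append((sid, "not in cohort table"))
    X = X.loc[in_cohort]
    y = labels.loc[X.index]
    return FeatureMatrix(X, y, excluded)


def cv_train(features: FeatureMatrix, task: tuple[str, str],
             hyperparams: dict | None = None, seed: int = 0,
             n_folds: int = N_FOLDS) -> CVReport:
    """Stratified k-fold cross-validation of the forest on one pairwise task.

    ``task = (positive_class, negative_class)``: sensitivity is recall on
    the positive (patient) class, specificity recall on the other. The same
    seed drives fold shuffling and every forest, so reports are repeatable.
    """
    hp = dict(RF_HYPERPARAMS)
    hp.update(hyperparams or {})
    fm = features.subset(task)
    counts = fm.y.value_counts()
    for cls in task:
        if counts.get(cls, 0) < n_folds:
            raise ValueError(f"class {cls!r} has {counts.get(cls, 0)} subjects; "
                             f"need >= {n_folds} for {n_folds}-fold CV")
    X = fm.X.to_numpy()
    y = (fm.y == task[0]).to_numpy().astype(int)   # 1 = positive/patient class

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    acc, sens, spec, imps = [], [], [], []
    for train_idx, val_idx in skf.split(X, y):
        clf = RandomForestClassifier(random_state=seed, **hp)
        clf.fit(X[train_idx], y[train_idx])
        pred = clf.predict(X[val_idx])
        truth = y[val_idx]
        acc.append(np.mean(pred == truth))
        pos, neg = truth == 1, truth == 0
        sens.append(np.mean(pred[pos] == 1) if pos.any() else np.nan)
        spec.append(np.mean(pred[neg] == 0) if neg.any() else np.nan)
        imps.append(clf.feature_importances_)
    importances = pd.DataFrame(imps, columns=list(fm.X.columns))
    return CVReport(task, np.array(acc), np.array(sens), np.array(spec),
                    importances, list(fm.X.columns), seed)


def gini_feature_elimination(features: FeatureMatrix, task: tuple[str, str],
                             hyperparams: dict | None = None, seed: int = 0,
                             tolerance: float = 0.0,
                             min_features: int = 2
                             ) -> tuple[list[str], list[CVReport]]:
    """Iterative backward elimination by fold-averaged Gini importance.

    Each round drops the least important feature; the reduced set is kept
    only if mean accuracy stays within ``tolerance`` of the best so far.
    Stops when a drop degrades accuracy beyond tolerance or the set reaches
    ``min_features``. Returns the final feature list and the full report
    trajectory (the rejected candidate round included, flagged by being
    last when accuracy dropped).
    """
    current = features
    report = cv_train(current, task, hyperparams, seed)
    trajectory = [report]
    best_acc = report.accuracy
    while len(report.features) > min_features:
        drop = report.mean_importance().index[-1]
        reduced = FeatureMatrix(current.X.drop(columns=[drop]), current.y,
                                current.excluded)
        cand = cv_train(reduced, task, hyperparams, seed)
        trajectory.append(cand)
        if cand.accuracy + tolerance < best_acc:
            break
        current, report = reduced, cand
        best_acc = max(best_acc, cand.accuracy)
    return report.features, trajectory
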