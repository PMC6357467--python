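"""Boosted-stump classification of disease phenotype from DMR methylation.

The classifier is discrete AdaBoost (SAMME) over depth-1 decision trees,
the standard weak learner for small-n/large-p methylation panels. Training
is two-stage: a full-feature fit ranks regions by boosting feature
importance, the regions with importance > 0 form the biomarker panel, and
the final model is refit on that panel alone. Evaluation on an
independent cohort reports micro-averaged precision (= accuracy for
single-label binary prediction) and the ROC AUC of the ensemble margins.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import AdaBoostClassifier
from sklearn.metrics import roc_auc_score
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted


class BoostedStumpClassifier(BaseEstimator, ClassifierMixin):
    """AdaBoost over decision stumps with training-mean imputation.

    Parameters
    ----------
    n_rounds : int
        Boosting rounds (ensemble size).
    learning_rate : float
        Shrinkage applied to each stump's vote.
    random_state : int
        Seed; fits are reproducible given the same data and seed.

    Attributes (after ``fit``)
    --------------------------
    classes_ : ndarray of the two class labels (sorted).
    feature_importances_ : per-feature importance, >= 0, summing to 1.
    imputation_means_ : training feature means used to fill missing values.
    """

    def __init__(self, n_rounds: int = 100, learning_rate: float = 1.0, random_state: int = 0):
        self.n_rounds = n_rounds
        self.learning_rate = learning_rate
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) != 2:
            raise ValueError(f"need exactly 2 classes, got {list(classes)}")
        if counts.min() < 2:
            raise ValueError("each class needs >= 2 training samples")
        self.imputation_means_ = np.nanmean(X, axis=0)
        self.imputation_means_ = np.where(
            np.isnan(self.imputation_means_), 0.0, self.imputation_means_
        )
        X = self._impute(X)
        self.ensemble_ = AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=1, random_state=self.random_state),
            n_estimators=self.n_rounds,
            learning_rate=self.learning_rate,
            random_state=self.random_state,
        ).fit(X, y)
        self.classes_ = self.ensemble_.classes_
        imp = self.ensemble_.feature_importances_
        total = imp.sum()
        self.feature_importances_ = imp / total if total > 0 else imp
        self.n_features_in_ = X.shape[1]
        return self

    def _impute(self, X: np.ndarray) -> np.ndarray:
        X = np.array(X, dtype=float, copy=True)
        mask = np.isnan(X)
        if mask.any():
            X[mask] = np.broadcast_to(self.imputation_means_, X.shape)[mask]
        return X

    def decision_function(self, X):
        """Signed margin in favour of ``classes_[1]``, in [-1, 1]."""
        check_is_fitted(self, "ensemble_")
        return self.ensemble_.decision_function(self._impute(np.asarray(X, float)))

    def predict(self, X):
        check_is_fitted(self, "ensemble_")
        return self.classes_[(self.decision_function(X) > 0).astype(int)]

    def stumps(self) -> list[dict]:
        """Flat description of each weighted stump (for serialization)."""
        check_is_fitted(self, "ensemble_")
        out = []
        for tree, weight in zip(self.ensemble_.estimators_, self.ensemble_.estimator_weights_):
            if weight == 0:
                continue
            t = tree.tree_
            if t.node_count == 1:  # degenerate stump: single leaf
                cls = self.classes_[int(np.argmax(t.value[0]))]
                out.append({"feature": -1, "threshold": 0.0, "left": str(cls),
                            "right": str(cls), "weight": float(weight)})
                continue
            left_cls = self.classes_[int(np.argmax(t.value[t.children_left[0]]))]
            right_cls = self.classes_[int(np.argmax(t.value[t.children_right[0]]))]
            out.append(
                {
                    "feature": int(t.feature[0]),
                    "threshold": float(t.threshold[0]),
                    "left": str(left_cls),
                    "right": str(right_cls),
                    "weight": float(weight),
                }
            )
        return out


@dataclass
class PhenotypeModel:
    """Trained two-stage boosted-stump model over named DMR features."""

    classifier: BoostedStumpClassifier
    feature_ids: list[str]
    selected_ids: list[str]
    importances: pd.Series
    positive_class: str
    metadata: dict = field(default_factory=dict)

    def feature_frame(self, table: pd.DataFrame) -> np.ndarray:
        """Align a region x sample table to the model's selected features."""
        missing = [f for f in self.selected_ids if f not in table.index]
        if missing:
            raise KeyError(f"test table lacks model features: {missing[:5]}...")
        return table.loc[self.selected_ids].to_numpy(float).T

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        return self.classifier.predict(self.feature_frame(table))

    def decision_scores(self, table: pd.DataFrame) -> np.ndarray:
        """Margins oriented so positive favours ``positive_class``."""
        raw = self.classifier.decision_function(self.feature_frame(table))
        sign = 1.0 if str(self.classifier.classes_[1]) == self.positive_class else -1.0
        return sign * raw

    def to_json(self, path: str | Path) -> None:
        payload = {
            "feature_ids": self.feature_ids,
            "selected_ids": self.selected_ids,
            "importances": {k: float(v) for k, v in self.importances.items()},
            "positive_class": self.positive_class,
            "classes": [str(c) for c in self.classifier.classes_],
            "imputation_means": [float(v) for v in self.classifier.imputation_means_],
            "stumps": self.classifier.stumps(),
            "metadata": self.metadata,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @staticmethod
    def score_from_json(path: str | Path, table: pd.DataFrame) -> np.ndarray:
        """Recompute decision scores from a serialized model (pure Python).

        Reproduces the SAMME decision function: the weight-normalised sum
        of each stump's vote for ``classes[1]``, re-signed toward the
        positive class.
        """
        payload = json.loads(Path(path).read_text())
        X = table.loc[payload["selected_ids"]].to_numpy(float).T
        means = np.asarray(payload["imputation_means"])
        mask = np.isnan(X)
        if mask.any():
            X[mask] = np.broadcast_to(means, X.shape)[mask]
        classes = payload["classes"]
        total_w = sum(s["weight"] for s in payload["stumps"])
        score = np.zeros(len(X))
        for s in payload["stumps"]:
            if s["feature"] < 0:
                pred_right = np.full(len(X), s["right"] == classes[1])
            else:
                go_right = X[:, s["feature"]] > s["threshold"]
                pred = np.where(go_right, s["right"], s["left"])
                pred_right = pred == classes[1]
            # SAMME codes the non-predicted class as -1, so each stump
            # contributes +/- 2w before weight normalisation
            score += 2.0 * s["weight"] * np.where(pred_right, 1.0, -1.0)
        score /= total_w
        sign = 1.0 if classes[1] == payload["positive_class"] else -1.0
        return sign * score


def train_boosted_stumps(
    region_table: pd.DataFrame,
    labels: pd.Series,
    rounds: int = 100,
    learning_rate: float = 1.0,
    seed: int = 0,
) -> tuple[BoostedStumpClassifier, pd.Series]:
    """Single-stage fit on a region x sample percent-methylation table.

    Returns the fitted classifier and the per-region importances indexed
    by region id.
    """
    X = region_table.to_numpy(float).T
    y = labels.loc[list(region_table.columns)].to_numpy()
    clf = BoostedStumpClassifier(
        n_rounds=rounds, learning_rate=learning_rate, random_state=seed
    ).fit(X, y)
    return clf, pd.Series(clf.feature_importances_, index=region_table.index)


def select_features(importances: pd.Series, threshold: float = 0.0) -> list[str]:
    """Feature ids with importance strictly above ``threshold``, ordered by
    descending importance then id. Raises if nothing clears the bar."""
    selected = importances[importances > threshold]
    if selected.empty:
        raise ValueError("no feature has importance above the threshold; cannot refit")
    order = sorted(selected.items(), key=lambda kv: (-kv[1], str(kv[0])))
    return [str(k) for k, _ in order]


def train_phenotype_classifier(
    region_table: pd.DataFrame,
    labels: pd.Series,
    rounds: int = 100,
    learning_rate: float = 1.0,
    seed: int = 0,
    positive_class: str = "WDH",
    importance_threshold: float = 0.0,
) -> PhenotypeModel:
    """Two-stage fit: rank all regions, keep importance > threshold, refit."""
    _, importances = train_boosted_stumps(region_table, labels, rounds, learning_rate, seed)
    selected = select_features(importances, importance_threshold)
    refit, _ = train_boosted_stumps(
        region_table.loc[selected], labels, rounds, learning_rate, seed
    )
    return PhenotypeModel(
        classifier=refit,
        feature_ids=[str(i) for i in region_table.index],
        selected_ids=selected,
        importances=importances,
        positive_class=positive_class,
        metadata={"rounds": rounds, "learning_rate": learning_rate, "seed": seed},
    )


@dataclass
class EvaluationReport:
    confusion: dict
    precision_micro: float
    roc_auc: float
    predictions: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion,
            "precision_micro": self.precision_micro,
            "roc_auc": self.roc_auc,
        }


def predict_and_evaluate(
    model: PhenotypeModel, test_table: pd.DataFrame, test_labels: pd.Series
) -> EvaluationReport:
    """Score an independent cohort.

    Labels come from the ensemble margin sign, micro precision is total
    correct over total predicted, and the AUC treats the model's positive
    class as the positive label of the margin scores.
    """
    samples = list(test_table.columns)
    y_true = test_labels.loc[samples].to_numpy()
    y_pred = model.predict(test_table)
    scores = model.decision_scores(test_table)
    correct = int((y_pred == y_true).sum())
    classes = sorted(set(map(str, y_true)) | set(map(str, y_pred)))
    confusion = {
        t: {p: int(((y_true == t) & (y_pred == p)).sum()) for p in classes} for t in classes
    }
    if len(set(y_true)) == 2:
        auc = float(roc_auc_score((y_true == model.positive_class).astype(int), scores))
    else:
        auc = np.nan
    predictions = pd.DataFrame(
        {"sample": samples, "true": y_true, "predicted": y_pred, "score": scores}
    )
    return EvaluationReport(
        confusion=confusion,
        precision_micro=correct / len(y_true),
        roc_auc=auc,
        predictions=predictions,
    )
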