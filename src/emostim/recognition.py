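"""Classifier comparison and accuracy aggregation for DE features.

The evaluation protocol is deliberately simple: a stratified 80/20
train/test split of 1-second-epoch DE features, eleven classical
classifiers trained on the training split, top-1 accuracy on the test
split, and an unweighted per-source mean over participant groups.
Scale-sensitive classifiers are wrapped in a train-set standardiser;
tree ensembles see raw features.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import (
    AdaBoostClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GroupShuffleSplit, train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .ratings import round2


def default_roster(seed: int = 0) -> dict[str, BaseEstimator]:
    """The default roster of 11 classical classifiers.

    Scale-sensitive members are pipelined behind a standardiser fitted on
    the training data only; the tree ensembles receive raw features.
    """
    scaled = lambda est: make_pipeline(StandardScaler(), est)  # noqa: E731
    return {
        "Random Forest": RandomForestClassifier(n_estimators=200, random_state=seed),
        "k-NN": scaled(KNeighborsClassifier()),
        "Linear SVM": scaled(SVC(kernel="linear", random_state=seed)),
        "RBF SVM": scaled(SVC(kernel="rbf", random_state=seed)),
        "Logistic Regression": scaled(LogisticRegression(max_iter=2000, random_state=seed)),
        "Naive Bayes": scaled(GaussianNB()),
        "Decision Tree": DecisionTreeClassifier(random_state=seed),
        "Gradient Boosting": GradientBoostingClassifier(random_state=seed),
        "AdaBoost": AdaBoostClassifier(random_state=seed),
        "LDA": scaled(LinearDiscriminantAnalysis()),
        "MLP": scaled(
            MLPClassifier(hidden_layer_sizes=(64,), max_iter=500, random_state=seed)
        ),
    }


def split_train_test(
    X: np.ndarray,
    y: np.ndarray,
    ratio: float = 0.8,
    seed: int = 0,
    groups: Optional[np.ndarray] = None,
):
    """Stratified (or group-wise) train/test split at the given train ratio.

    The default stratifies at the epoch level, preserving class
    proportions within rounding; passing ``groups`` (e.g. trial ids)
    switches to a grouped split so that epochs of one trial never span
    both sides. Requires at least 5 epochs per class and ``0 < ratio < 1``.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    if not 0 < ratio < 1:
        raise ValueError("ratio must lie strictly between 0 and 1")
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < 5:
        raise ValueError(
            f"class {classes[counts.argmin()]!r} has only {counts.min()} epochs; need >= 5"
        )
    if groups is not None:
        gss = GroupShuffleSplit(n_splits=1, train_size=ratio, random_state=seed)
        tr, te = next(gss.split(X, y, groups=np.asarray(groups)))
        return X[tr], X[te], y[tr], y[te]
    return train_test_split(X, y, train_size=ratio, stratify=y, random_state=seed)


class ClassifierBenchmark(BaseEstimator):
    """Fit a roster of classifiers and compare their test accuracies.

    Parameters
    ----------
    roster : dict of name -> estimator, optional
        Defaults to :func:`default_roster`.
    seed : int
        Seed injected into the default roster's stochastic members.

    Attributes (after :meth:`fit`)
    ------------------------------
    estimators_ : dict of fitted estimators
    classes_ : label alphabet seen at fit time
    """

    def __init__(self, roster: Optional[dict] = None, seed: int = 0):
        self.roster = roster
        self.seed = seed

    def fit(self, X, y):
        X = np.asarray(X)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("training set contains a single class")
        roster = self.roster if self.roster is not None else default_roster(self.seed)
        self.estimators_ = {name: clone(est).fit(X, y) for name, est in roster.items()}
        return self

    def evaluate(self, X, y) -> pd.DataFrame:
        """Top-1 test accuracy (%) per roster member, best first."""
        X = np.asarray(X)
        y = np.asarray(y)
        rows = [
            {"classifier": name, "accuracy_pct": 100.0 * float(np.mean(est.predict(X) == y))}
            for name, est in self.estimators_.items()
        ]
        out = pd.DataFrame(rows).sort_values(
            ["accuracy_pct", "classifier"], ascending=[False, True], kind="mergesort"
        )
        return out.reset_index(drop=True)

    def predict(self, X, classifier: str = "Random Forest"):
        return self.estimators_[classifier].predict(np.asarray(X))

    @property
    def best_(self) -> str:
        """Name of the best classifier from the most recent evaluation."""
        if not hasattr(self, "_last_eval"):
            raise AttributeError("call evaluate() first")
        return self._last_eval

    def evaluate_and_rank(self, X, y) -> pd.DataFrame:
        table = self.evaluate(X, y)
        self._last_eval = str(table.iloc[0]["classifier"])
        return table


def train_evaluate_classifiers(
    X_train, y_train, X_test, y_test, roster: Optional[dict] = None, seed: int = 0
) -> pd.DataFrame:
    """One-shot roster comparison; returns per-classifier accuracy (%)."""
    if np.asarray(X_train).shape[1] != np.asarray(X_test).shape[1]:
        raise ValueError("train and test feature dimensionality differ")
    bench = ClassifierBenchmark(roster=roster, seed=seed).fit(X_train, y_train)
    return bench.evaluate_and_rank(X_test, y_test)


def aggregate_accuracy_table(
    reports: pd.DataFrame,
    group_col: str = "participants",
    source_cols: Sequence[str] = ("specific", "comparison", "film"),
) -> pd.DataFrame:
    """Append the unweighted per-source mean row, all cells rounded to 2 dp.

    ``reports`` has one row per participant group and one accuracy column
    per stimulus source; a missing cell is an error. Aggregation is
    invariant to the ordering of groups.
    """
    source_cols = list(source_cols)
    missing = [c for c in source_cols if c not in reports.columns]
    if missing:
        raise ValueError(f"missing source columns: {missing}")
    if reports[source_cols].isna().any().any():
        raise ValueError("missing accuracy cell")
    body = reports.copy()
    body[source_cols] = body[source_cols].map(round2)
    mean_row = {group_col: "Average accuracy"}
    for c in source_cols:
        mean_row[c] = round2(float(np.mean(reports[c].to_numpy(float))))
    for c in body.columns:
        mean_row.setdefault(c, "")
    return pd.concat([body, pd.DataFrame([mean_row])], ignore_index=True)
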