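"""Hybrid diagnosis models and the 15x7 decision matrix.

A hybrid model is one (feature-selection technique, classifier) pair
trained on the FWZIC-weighted feature subset.  Three filters (ReliefF,
information gain, chi-square) crossed with five classifiers (decision
tree, SVM, naive Bayes, KNN, AdaBoost) give the 15 alternatives A1..A15.
Each is evaluated on a stratified 66/34 split over seven criteria:

    C1 train time (s, cost)    C5 F1 score (benefit)
    C2 test time (s, cost)     C6 precision (benefit)
    C3 AUC (benefit)           C7 recall (benefit)
    C4 classification accuracy (benefit)

C4-C7 are micro-averaged over the three severity classes; for
single-label multiclass prediction micro precision = recall = F1 =
accuracy, which is why those columns repeat within a row.  AUC is
macro-averaged one-vs-rest.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostClassifier
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .fwzic import FeatureWeightSet
from .prep import CLASS_COLUMN

__all__ = [
    "CRITERIA",
    "CRITERION_LABELS",
    "DIRECTIONS",
    "CLASSIFIERS",
    "FS_ORDER",
    "HybridModelSpec",
    "HYBRID_MODELS",
    "DecisionMatrix",
    "apply_feature_weights",
    "split_train_test",
    "evaluate_model",
    "build_decision_matrix",
]

CRITERIA = ("C1", "C2", "C3", "C4", "C5", "C6", "C7")
CRITERION_LABELS = {
    "C1": "train time",
    "C2": "test time",
    "C3": "AUC",
    "C4": "classification accuracy",
    "C5": "F1 score",
    "C6": "precision",
    "C7": "recall",
}
DIRECTIONS = {
    "C1": "cost",
    "C2": "cost",
    "C3": "benefit",
    "C4": "benefit",
    "C5": "benefit",
    "C6": "benefit",
    "C7": "benefit",
}

#: classifier display-name order within each FS block (A1..A5 pattern)
CLASSIFIERS = ("decision tree", "SVM", "naive Bayes", "KNN", "AdaBoost")
#: FS block order of the alternatives
FS_ORDER = ("relieff", "infogain", "chi2")
_FS_LABEL = {"relieff": "ReF", "infogain": "IG", "chi2": "Chi2"}


@dataclass(frozen=True)
class HybridModelSpec:
    """One (FS technique, classifier) alternative."""

    alt_id: str
    fs_technique: str
    classifier: str

    @property
    def name(self) -> str:
        return f"{_FS_LABEL[self.fs_technique]}-{self.classifier}"


#: the 15 alternatives in canonical row order
HYBRID_MODELS: tuple[HybridModelSpec, ...] = tuple(
    HybridModelSpec(f"A{5 * i + j + 1}", fs, clf)
    for i, fs in enumerate(FS_ORDER)
    for j, clf in enumerate(CLASSIFIERS)
)


def make_classifier(name: str, seed: int = 0):
    """Instantiate a classifier by display name with library defaults.

    Hyperparameters are the toolkit defaults; SVC is fit with probability
    estimates enabled because multiclass AUC needs class probabilities.
    """
    if name == "decision tree":
        return DecisionTreeClassifier(random_state=seed)
    if name == "naive Bayes":
        return GaussianNB()
    if name == "KNN":
        return KNeighborsClassifier()
    if name == "SVM":
        return SVC(probability=True, random_state=seed)
    if name == "AdaBoost":
        return AdaBoostClassifier(random_state=seed)
    raise ValueError(f"unknown classifier {name!r}")


def apply_feature_weights(
    df: pd.DataFrame, weights: FeatureWeightSet, class_column: str = CLASS_COLUMN
) -> pd.DataFrame:
    """Multiply each selected feature column by its FWZIC weight.

    Unselected feature columns are dropped; the class column is untouched.
    """
    missing = [f for f in weights.features if f not in df.columns]
    if missing:
        raise KeyError(f"weighted features absent from table: {missing}")
    out = df[list(weights.features)].copy()
    for feat, w in zip(weights.features, weights.weights):
        out[feat] = out[feat] * w
    out[class_column] = df[class_column].to_numpy()
    return out


def split_train_test(
    df: pd.DataFrame,
    seed: int = 0,
    train_fraction: float = 0.66,
    class_column: str = CLASS_COLUMN,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified train/test partition (66/34 by default)."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train fraction must be in (0, 1), got {train_fraction}")
    train, test = train_test_split(
        df,
        train_size=train_fraction,
        stratify=df[class_column],
        random_state=seed,
        shuffle=True,
    )
    return train.reset_index(drop=True), test.reset_index(drop=True)


def evaluate_model(
    spec: HybridModelSpec,
    train: pd.DataFrame,
    test: pd.DataFrame,
    seed: int = 0,
    class_column: str = CLASS_COLUMN,
) -> dict[str, float]:
    """Fit one hybrid model and score it over the seven criteria.

    Returns ``{"C1": train_time, ..., "C7": recall}``.  Micro averaging is
    used for accuracy/F1/precision/recall and macro one-vs-rest for AUC.
    """
    feats = [c for c in train.columns if c != class_column]
    X_tr, y_tr = train[feats].to_numpy(), train[class_column].to_numpy()
    X_te, y_te = test[feats].to_numpy(), test[class_column].to_numpy()
    if len(X_tr) == 0 or len(X_te) == 0:
        raise ValueError("train and test sets must be non-empty")
    if len(np.unique(y_tr)) < 2:
        raise ValueError("training set is single-class; cannot fit a classifier")

    clf = make_classifier(spec.classifier, seed=seed)
    with warnings.catch_warnings():
        # SVC(probability=True) is the standard way to get multiclass
        # probabilities; silence its pending-deprecation chatter
        warnings.simplefilter("ignore", FutureWarning)
        t0 = time.perf_counter()
        clf.fit(X_tr, y_tr)
        train_time = time.perf_counter() - t0

    t0 = time.perf_counter()
    y_pred = clf.predict(X_te)
    test_time = time.perf_counter() - t0
    proba = clf.predict_proba(X_te)

    acc = accuracy_score(y_te, y_pred)
    prec = precision_score(y_te, y_pred, average="micro", zero_division=0)
    rec = recall_score(y_te, y_pred, average="micro", zero_division=0)
    f1 = f1_score(y_te, y_pred, average="micro", zero_division=0)
    auc = roc_auc_score(y_te, proba, multi_class="ovr", average="macro")

    # structural identity of micro averaging for single-label prediction
    assert abs(acc - prec) < 1e-12 and abs(acc - rec) < 1e-12 and abs(acc - f1) < 1e-12

    return {
        "C1": train_time,
        "C2": test_time,
        "C3": float(auc),
        "C4": float(acc),
        "C5": float(f1),
        "C6": float(prec),
        "C7": float(rec),
    }


@dataclass(frozen=True)
class DecisionMatrix:
    """15 alternatives x 7 criteria with cost/benefit directions."""

    data: pd.DataFrame  # index alt ids, columns CRITERIA
    directions: dict[str, str] = field(default_factory=lambda: dict(DIRECTIONS))
    model_names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if list(self.data.columns) != list(CRITERIA):
            raise ValueError(f"criteria must be {CRITERIA} in order")
        if self.data.isna().any().any():
            raise ValueError("decision matrix has missing cells")
        if self.data.index.duplicated().any():
            raise ValueError("duplicate alternative ids")
        bounded = self.data[["C3", "C4", "C5", "C6", "C7"]]
        if ((bounded < 0) | (bounded > 1)).any().any():
            raise ValueError("benefit metrics C3-C7 must lie in [0, 1]")
        if (self.data[["C1", "C2"]] < 0).any().any():
            raise ValueError("times must be non-negative")

    @property
    def alternatives(self) -> list[str]:
        return list(self.data.index)

    def restrict(self, criteria: list[str]) -> "CriteriaView":
        """A criterion-subset view (e.g. quality criteria only) for ranking."""
        missing = [c for c in criteria if c not in self.data.columns]
        if missing:
            raise KeyError(f"unknown criteria: {missing}")
        return CriteriaView(
            self.data[criteria], {c: self.directions[c] for c in criteria}
        )

    def write_csv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.insert(0, "model", [self.model_names.get(a, "") for a in out.index])
        out.rename_axis("alternative").to_csv(path)

    @classmethod
    def read_csv(cls, path: str | Path) -> "DecisionMatrix":
        df = pd.read_csv(path, index_col=0)
        names = {}
        if "model" in df.columns:
            names = df["model"].to_dict()
            df = df.drop(columns=["model"])
        return cls(df[list(CRITERIA)].astype(float), dict(DIRECTIONS), names)


@dataclass(frozen=True)
class CriteriaView:
    """A read-only subset of a decision matrix's criteria."""

    data: pd.DataFrame
    directions: dict[str, str]


def build_decision_matrix(
    rows: dict[str, dict[str, float]],
    specs: tuple[HybridModelSpec, ...] = HYBRID_MODELS,
) -> DecisionMatrix:
    """Assemble evaluated rows into the canonical-order decision matrix."""
    missing = [s.alt_id for s in specs if s.alt_id not in rows]
    if missing:
        raise ValueError(f"missing evaluations for alternatives: {missing}")
    if len(rows) != len(specs):
        extra = set(rows) - {s.alt_id for s in specs}
        raise ValueError(f"unexpected alternatives: {sorted(extra)}")
    data = pd.DataFrame(
        [[rows[s.alt_id][c] for c in CRITERIA] for s in specs],
        index=[s.alt_id for s in specs],
        columns=list(CRITERIA),
    )
    return DecisionMatrix(
        data, dict(DIRECTIONS), {s.alt_id: s.name for s in specs}
    )
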