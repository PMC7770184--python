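"""Support-vector verification of connectivity biomarkers.

Selected edges (typically those the taxonomy labelled cured or activated)
are extracted as Fisher-z features; an RBF-kernel SVM is trained on one
cohort and evaluated on a held-out cohort, reporting accuracy and the ROC
curve of the decision scores.  Features are standardised with the
training cohort's mean/SD only, so no held-out information leaks into the
fitted model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .network import WeightedConnectome

__all__ = [
    "SvmConfig",
    "ClassificationReport",
    "extract_features",
    "fit_classifier",
    "train_validate",
    "roc_points",
]


@dataclass
class SvmConfig:
    """RBF-SVM hyperparameters; a deliberately untuned baseline."""

    C: float = 1.0
    gamma: float | str = "scale"  # 1 / (n_features * feature variance)
    seed: int = 0


@dataclass
class ClassificationReport:
    comparison: str
    accuracy: float
    roc: pd.DataFrame  # columns threshold, fpr, tpr
    auc: float
    per_class_counts: dict[str, int]
    config: SvmConfig
    predictions: list[str] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        return {
            "comparison": self.comparison,
            "accuracy": self.accuracy,
            "auc": self.auc,
            "per_class_counts": self.per_class_counts,
            "hyperparameters": {"C": self.config.C, "gamma": self.config.gamma,
                                "seed": self.config.seed},
        }


def extract_features(connectomes: Sequence[WeightedConnectome],
                     edges: Sequence[tuple[str, str]],
                     labels: Sequence[str]) -> pd.DataFrame:
    """Feature table: one row per connectome, one column per selected edge.

    Columns are ordered lexicographically by their (sorted) ROI-label
    pair, so train and test tables built from the same edge list always
    align.  The class label is carried in a ``label`` column.
    """
    if len(connectomes) != len(labels):
        raise ValueError("one class label per connectome required")
    canon = sorted({tuple(sorted(e)) for e in edges})
    for net in connectomes:
        roi_set = set(net.roi_labels)
        for a, b in canon:
            if a not in roi_set or b not in roi_set:
                raise KeyError(f"edge ({a}, {b}) absent from connectome "
                               f"{net.subject_id or '<unnamed>'}")
    cols = {f"{a}--{b}": [net.edge_weight(a, b) for net in connectomes]
            for a, b in canon}
    frame = pd.DataFrame(cols)
    frame["label"] = list(labels)
    return frame


def _split_xy(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    y = table["label"].to_numpy()
    x = table.drop(columns="label").to_numpy(float)
    if not np.all(np.isfinite(x)):
        raise ValueError("feature table contains non-finite entries")
    return x, y


def fit_classifier(train: pd.DataFrame, config: SvmConfig | None = None) -> Pipeline:
    """Fit scaler + RBF-SVM on the training cohort only."""
    config = config or SvmConfig()
    x, y = _split_xy(train)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes in training cohort, got {list(classes)}")
    model = Pipeline([
        ("scale", StandardScaler()),
        ("svm", SVC(kernel="rbf", C=config.C, gamma=config.gamma,
                    random_state=config.seed)),
    ])
    model.fit(x, y)
    return model


def train_validate(train: pd.DataFrame, test: pd.DataFrame,
                   config: SvmConfig | None = None,
                   comparison: str = "") -> ClassificationReport:
    """Train on one cohort, score the held-out cohort.

    Accuracy is the proportion correct at the SVM's default decision
    threshold; the ROC sweeps the decision scores.  Deterministic given
    the config.
    """
    config = config or SvmConfig()
    if list(train.columns) != list(test.columns):
        raise ValueError("train and test feature columns must match")
    model = fit_classifier(train, config)
    x_test, y_test = _split_xy(test)
    if len(x_test) == 0:
        raise ValueError("empty test cohort")
    pred = model.predict(x_test)
    accuracy = float(np.mean(pred == y_test))
    scores = model.decision_function(x_test)
    positive = model.classes_[1]  # decision_function > 0 favours classes_[1]
    roc, auc = roc_points(scores, y_test == positive)
    counts = {str(c): int(np.sum(y_test == c)) for c in np.unique(y_test)}
    return ClassificationReport(comparison=comparison, accuracy=accuracy,
                                roc=roc, auc=auc, per_class_counts=counts,
                                config=config, predictions=[str(p) for p in pred])


def roc_points(scores: Sequence[float], is_positive: Sequence[bool],
               ) -> tuple[pd.DataFrame, float]:
    """ROC curve by threshold sweep over the scores; AUC by trapezoid.

    Tied scores collapse into a single operating point.  Returns a frame
    with columns threshold, fpr, tpr (thresholds descending, beginning at
    the (0, 0) corner) and the area under the curve.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(is_positive, dtype=bool)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(~y_sorted)
    distinct = np.flatnonzero(np.diff(s_sorted, append=-np.inf))
    tpr = np.concatenate([[0.0], tp[distinct] / n_pos])
    fpr = np.concatenate([[0.0], fp[distinct] / n_neg])
    thresholds = np.concatenate([[np.inf], s_sorted[distinct]])
    auc = float(np.trapezoid(tpr, fpr))
    frame = pd.DataFrame({"threshold": thresholds, "fpr": fpr, "tpr": tpr})
    return frame, auc
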