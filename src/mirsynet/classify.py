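"""RBF-SVM evaluation of miRNA feature sets under stratified 5-fold CV.

Every sample is scored exactly once by a support-vector machine whose
training fold excluded it; features are standardised with training-fold
statistics only.  The pooled out-of-fold decision scores feed a single ROC
curve whose area equals the Mann-Whitney probability that a random case
outscores a random control (ties counted half).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .containers import CASE, ExpressionMatrix

__all__ = ["CVConfig", "ROCResult", "cross_validated_scores", "roc_auc", "evaluate_feature_sets"]


@dataclass
class CVConfig:
    """Cross-validation and SVM settings.

    kernel_width of "auto" uses 1 / (n_features * feature variance), the
    scale heuristic; regularization is the SVM C parameter.
    """

    n_folds: int = 5
    seed: int = 0
    kernel_width: float | str = "auto"
    regularization: float = 1.0

    def validate(self, class_counts: Sequence[int]) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        smallest = min(class_counts)
        if self.n_folds > smallest:
            raise ValueError(
                f"n_folds={self.n_folds} exceeds the smallest class size {smallest}; "
                "choose a smaller n_folds"
            )
        if self.regularization <= 0:
            raise ValueError("regularization must be > 0")
        if self.kernel_width != "auto" and not (
            isinstance(self.kernel_width, (int, float)) and self.kernel_width > 0
        ):
            raise ValueError("kernel_width must be positive or 'auto'")


@dataclass
class ROCResult:
    """ROC curve points and their area."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold": self.thresholds, "fpr": self.fpr, "tpr": self.tpr})


def _binary_labels(matrix: ExpressionMatrix) -> np.ndarray:
    if matrix.groups is None:
        raise ValueError("classifier evaluation requires group labels")
    y = (matrix.groups.to_numpy() == CASE).astype(int)
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("both classes must be present")
    return y


def cross_validated_scores(
    matrix: ExpressionMatrix, feature_ids: Iterable[str], cv: CVConfig | None = None
) -> pd.Series:
    """Out-of-fold RBF-SVM decision scores, one per sample.

    Folds are stratified by class and shuffled with ``cv.seed``, so scores
    are deterministic for a given seed.
    """
    cv = cv or CVConfig()
    ids = list(feature_ids)
    sub = matrix.subset(ids)
    X = sub.values.to_numpy().T  # samples x features
    if np.isnan(X).any():
        raise ValueError("matrix contains missing values; run preprocess first")
    y = _binary_labels(sub)
    cv.validate((int(y.sum()), int(y.size - y.sum())))

    gamma = "scale" if cv.kernel_width == "auto" else float(cv.kernel_width)
    scores = np.empty(y.size)
    folds = StratifiedKFold(n_splits=cv.n_folds, shuffle=True, random_state=cv.seed)
    for train, test in folds.split(X, y):
        scaler = StandardScaler().fit(X[train])
        model = SVC(kernel="rbf", C=cv.regularization, gamma=gamma)
        model.fit(scaler.transform(X[train]), y[train])
        scores[test] = model.decision_function(scaler.transform(X[test]))
    return pd.Series(scores, index=sub.sample_ids, name="score")


def roc_auc(scores: Sequence[float] | pd.Series, labels: Sequence[int]) -> ROCResult:
    """ROC curve and AUC from decision scores.

    ``labels`` are 1 for case, 0 for control.  The AUC equals
    (#concordant + 0.5 * #tied) / (n_case * n_control) over all
    case-control pairs; the curve is the threshold sweep over the unique
    scores, starting at (0, 0) and ending at (1, 1).
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("both classes must be present")
    fpr, tpr, thresholds = roc_curve(y, s)
    return ROCResult(thresholds=thresholds, tpr=tpr, fpr=fpr, auc=float(roc_auc_score(y, s)))


def evaluate_feature_sets(
    matrix: ExpressionMatrix,
    feature_sets: Mapping[str, Sequence[str]],
    cv: CVConfig | None = None,
) -> pd.DataFrame:
    """Cross-validated AUC per named feature set.

    Supports singletons, pairs, CE strata and combined panels alike;
    returns a DataFrame (set_name, n_features, auc) sorted by descending
    AUC.
    """
    cv = cv or CVConfig()
    y = _binary_labels(matrix)
    rows = []
    for name, features in feature_sets.items():
        ids = list(dict.fromkeys(features))
        if not ids:
            raise ValueError(f"feature set {name!r} is empty")
        scores = cross_validated_scores(matrix, ids, cv)
        rows.append(
            {"set_name": name, "n_features": len(ids), "auc": roc_auc(scores, y).auc}
        )
    return (
        pd.DataFrame(rows, columns=["set_name", "n_features", "auc"])
        .sort_values("auc", ascending=False, kind="mergesort")
        .reset_index(drop=True)
    )


def stratum_feature_sets(strata: Mapping[str, list]) -> dict[str, list[str]]:
    """Union of miRNAs in each nonempty CE stratum, as named feature sets."""
    out: dict[str, list[str]] = {}
    for label, pairs in strata.items():
        members = sorted({m for p in pairs for m in (p.mirna_a, p.mirna_b)})
        if members:
            out[label] = members
    return out
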