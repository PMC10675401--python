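"""Binary-relevance classification, centralized voting, and cross-validation.

Each sub-classifier is a binary-relevance (BR) bank of four one-vs-rest
RBF-kernel support-vector heads with Platt-calibrated probabilities; a
sub-classifier's confidence matrix holds, per sample, the four per-location
confidences (rows need not sum to 1, the heads are independent).  At the
decision layer every sub-classifier votes for its most-confident location;
the plurality location wins.  Ties are broken by the largest confidence sum
over the tied locations across all voters, then by fixed class-order
priority, and the event is flagged.

The harness runs stratified 5-fold or leave-one-out cross-validation with
selector and classifier fitting strictly inside each training fold.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Optional, Sequence

import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.model_selection import GridSearchCV, LeaveOneOut, StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .io import CLASS_ORDER
from .feature_selection import SelectionResult, lasso_select, sda_select

_CLASS_INDEX = {c: i for i, c in enumerate(CLASS_ORDER)}

DEFAULT_PARAM_GRID = {"C": [1.0, 10.0, 100.0], "gamma": ["scale", 0.01]}


@dataclasses.dataclass(frozen=True)
class SubClassifierSpec:
    """Which feature blocks feed one voter and which selector reduces them."""

    name: str
    operators: tuple[str, ...]
    selector: str = "none"  # lasso | sda | none

    def __post_init__(self) -> None:
        if self.selector not in {"lasso", "sda", "none"}:
            raise ValueError(f"unknown selector {self.selector!r}")


#: The five canonical voters: one sequence-signal classifier and four
#: image-signal classifiers over the deep-layer readouts and shallow textures.
PRESET_FIVE_VOTERS = (
    SubClassifierSpec("seq:DP-PSSM+PC", ("dp_pssm", "pc"), "lasso"),
    SubClassifierSpec("img:C3", ("C3",), "none"),
    SubClassifierSpec("img:GAP", ("GAP",), "none"),
    SubClassifierSpec("img:C3+Haralick+LBP", ("C3", "wavelet_haralick", "lbp"), "sda"),
    SubClassifierSpec("img:GAP+Haralick+LBP", ("GAP", "wavelet_haralick", "lbp"), "sda"),
)


@dataclasses.dataclass
class SubClassifier:
    """A fitted BR bank: 4 calibrated binary RBF heads plus its preprocessing."""

    name: str
    scaler: StandardScaler
    heads: dict[str, object]
    selection: Optional[SelectionResult]
    n_features: int
    chosen_params: dict


class _SigmoidHead:
    """Plain RBF-SVM head with a fixed logistic squashing of the margin.

    Fallback for folds where a location has a single positive training
    sample, too few for cross-validated Platt calibration.
    """

    def __init__(self, svc: SVC):
        self._svc = svc

    def fit(self, X, y):
        self._svc.fit(X, y)
        return self

    def predict_proba(self, X):
        p = 1.0 / (1.0 + np.exp(-self._svc.decision_function(X)))
        return np.column_stack([1.0 - p, p])


@dataclasses.dataclass(frozen=True)
class ConfidenceMatrix:
    """samples x 4 calibrated confidences, columns in CLASS_ORDER."""

    classifier_name: str
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[1] != len(CLASS_ORDER):
            raise ValueError(f"confidence matrix must be n x 4, got {v.shape}")
        if not np.all(np.isfinite(v)) or v.min() < 0 or v.max() > 1:
            raise ValueError("confidences must be finite and within [0, 1]")
        object.__setattr__(self, "values", v)

    def argmax_labels(self) -> np.ndarray:
        return np.array([CLASS_ORDER[i] for i in self.values.argmax(axis=1)])

    def row_normalized(self) -> np.ndarray:
        s = self.values.sum(axis=1, keepdims=True)
        return np.where(s > 0, self.values / np.where(s > 0, s, 1), 0.25)


@dataclasses.dataclass(frozen=True)
class VoteResult:
    predicted_label: str
    vote_counts: tuple[int, int, int, int]
    tie_broken: bool
    tie_rule_used: str  # plurality | summed-confidence | class-priority


@dataclasses.dataclass
class CvReport:
    """Cross-validation outcome: per-fold metrics, averages, confusion matrix."""

    scheme: str
    fold_metrics: list[dict]
    accuracy: float
    precision: float
    recall: float
    confusion: np.ndarray  # 4 x 4 counts, true class as rows (CLASS_ORDER)
    per_class_fold_accuracy: dict[str, list[float]]
    per_voter_fold_accuracy: dict[str, list[float]]
    fold_assignment: np.ndarray
    n_fit_rounds: int
    y_true: np.ndarray
    y_pred: np.ndarray

    @property
    def confusion_row_normalized(self) -> np.ndarray:
        rows = self.confusion.sum(axis=1, keepdims=True)
        return self.confusion / np.where(rows > 0, rows, 1)


def train_br(
    X: np.ndarray,
    y: np.ndarray,
    kernel_params: Optional[dict] = None,
    seed: int = 0,
    name: str = "br",
    cv_folds: int = 3,
    min_class_count: int = 2,
) -> SubClassifier:
    """Fit a binary-relevance bank of 4 calibrated RBF-SVM heads.

    Features are standardized; a shared (C, gamma) is chosen by internal grid
    search (stratified CV on the training rows), then one binary head per
    location is fitted with cross-validated Platt probability calibration.
    Deterministic under *seed*.  Every location must have at least
    ``min_class_count`` training samples (2 by default; the leave-one-out
    harness relaxes this to 1 for folds that orphan a small class, falling
    back to a fixed sigmoid squashing of the margin for that head).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    counts = {c: int((y == c).sum()) for c in CLASS_ORDER}
    lacking = [c for c, k in counts.items() if k < min_class_count]
    if lacking:
        raise ValueError(
            f"need >= {min_class_count} training samples per class; "
            f"lacking: {lacking}"
        )
    scaler = StandardScaler().fit(X)
    Z = scaler.transform(X)
    if kernel_params is None:
        folds = max(min(cv_folds, min(counts.values())), 2)
        with warnings.catch_warnings():
            # LOO folds may orphan a class below the grid-search fold count
            warnings.filterwarnings(
                "ignore", message="The least populated class", category=UserWarning
            )
            search = GridSearchCV(
                SVC(kernel="rbf", random_state=seed),
                DEFAULT_PARAM_GRID,
                cv=StratifiedKFold(folds, shuffle=True, random_state=seed),
                n_jobs=1,
            ).fit(Z, y)
        kernel_params = search.best_params_
    heads = {}
    for cls in CLASS_ORDER:
        yb = (y == cls).astype(int)
        svc = SVC(kernel="rbf", random_state=seed, **kernel_params)
        k = min(3, int(yb.sum()), int((1 - yb).sum()))
        if k >= 2:
            head = CalibratedClassifierCV(
                svc,
                method="sigmoid",
                cv=StratifiedKFold(k, shuffle=True, random_state=seed),
            )
        else:
            head = _SigmoidHead(svc)
        heads[cls] = head.fit(Z, yb)
    return SubClassifier(name, scaler, heads, None, X.shape[1], dict(kernel_params))


def predict_confidence(model: SubClassifier, X: np.ndarray) -> ConfidenceMatrix:
    """Per-class calibrated confidences of a fitted BR bank."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"{model.name}: expected {model.n_features} feature columns, "
            f"got {X.shape[1]}"
        )
    Z = model.scaler.transform(X)
    conf = np.column_stack(
        [model.heads[cls].predict_proba(Z)[:, 1] for cls in CLASS_ORDER]
    )
    return ConfidenceMatrix(model.name, np.clip(conf, 0.0, 1.0))


def centralized_vote(confidences: Sequence[ConfidenceMatrix]) -> list[VoteResult]:
    """Fuse sub-classifier confidences by plurality voting.

    Each sub-classifier votes for its row-argmax location.  Vote ties are
    broken by the largest sum of confidences over the tied locations across
    all voters, residual ties by fixed class-order priority.
    """
    if not confidences:
        raise ValueError("centralized_vote needs at least one sub-classifier")
    n = confidences[0].values.shape[0]
    for cm in confidences:
        if cm.values.shape[0] != n:
            raise ValueError("confidence matrices disagree on sample count")
    stacked = np.stack([cm.values for cm in confidences])  # (voters, n, 4)
    votes = stacked.argmax(axis=2)  # (voters, n)
    results = []
    for s in range(n):
        counts = np.bincount(votes[:, s], minlength=4)
        top = counts.max()
        tied = np.flatnonzero(counts == top)
        if tied.size == 1:
            winner, tie_broken, rule = int(tied[0]), False, "plurality"
        else:
            sums = stacked[:, s, tied].sum(axis=0)
            best = np.flatnonzero(sums == sums.max())
            tie_broken = True
            rule = "summed-confidence" if best.size == 1 else "class-priority"
            winner = int(tied[best[0]])
        results.append(
            VoteResult(CLASS_ORDER[winner], tuple(int(c) for c in counts),
                       tie_broken, rule)
        )
    return results


def compute_metrics(
    y_true: np.ndarray, y_pred: np.ndarray
) -> tuple[float, float, float, np.ndarray]:
    """Accuracy, macro precision, macro recall, and the 4x4 confusion matrix.

    Per-class precision/recall with an empty denominator are defined as 0;
    confusion rows are true classes in CLASS_ORDER.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    bad = (set(y_true) | set(y_pred)) - set(CLASS_ORDER)
    if bad:
        raise ValueError(f"labels outside the class set: {sorted(bad)}")
    ti = np.array([_CLASS_INDEX[c] for c in y_true])
    pi = np.array([_CLASS_INDEX[c] for c in y_pred])
    confusion = np.zeros((4, 4), dtype=int)
    np.add.at(confusion, (ti, pi), 1)
    accuracy = float(np.trace(confusion) / max(len(y_true), 1))
    col = confusion.sum(axis=0)
    row = confusion.sum(axis=1)
    diag = np.diag(confusion)
    precision = float(np.mean(np.where(col > 0, diag / np.maximum(col, 1), 0.0)))
    recall = float(np.mean(np.where(row > 0, diag / np.maximum(row, 1), 0.0)))
    return accuracy, precision, recall, confusion


def _fit_voter(
    spec: SubClassifierSpec,
    features: dict[str, np.ndarray],
    train: np.ndarray,
    y_train: np.ndarray,
    seed: int,
    min_class_count: int = 2,
) -> tuple[SubClassifier, Optional[SelectionResult]]:
    X_train = np.column_stack([features[op][train] for op in spec.operators])
    selection: Optional[SelectionResult] = None
    if spec.selector == "lasso":
        selection = lasso_select(X_train, y_train, seed=seed)
    elif spec.selector == "sda":
        selection = sda_select(X_train, y_train)
    if selection is not None and selection.selected_indices:
        X_train = selection.transform(X_train)
    model = train_br(
        X_train, y_train, seed=seed, name=spec.name, min_class_count=min_class_count
    )
    model.selection = selection
    return model, selection


def _voter_confidence(
    spec: SubClassifierSpec,
    model: SubClassifier,
    features: dict[str, np.ndarray],
    rows: np.ndarray,
) -> ConfidenceMatrix:
    X = np.column_stack([features[op][rows] for op in spec.operators])
    if model.selection is not None and model.selection.selected_indices:
        X = model.selection.transform(X)
    return predict_confidence(model, X)


def run_cv(
    features: dict[str, np.ndarray],
    y: np.ndarray,
    specs: Sequence[SubClassifierSpec] = PRESET_FIVE_VOTERS,
    scheme: str = "kfold",
    n_folds: int = 5,
    seed: int = 0,
) -> CvReport:
    """Cross-validate the voting ensemble.

    *features* maps operator names to aligned (n x d) arrays; each spec's
    design matrix is the column concatenation of its operator blocks.  Within
    every fold, selection and classifier fitting see training rows only.
    ``scheme`` is ``"kfold"`` (stratified, shuffled under *seed*) or
    ``"loo"``.
    """
    y = np.asarray(y)
    n = y.shape[0]
    for op, block in features.items():
        if block.shape[0] != n:
            raise ValueError(f"feature block {op!r} has {block.shape[0]} rows, not {n}")
    if scheme == "kfold":
        counts = np.unique(y, return_counts=True)[1]
        if counts.min() < n_folds:
            raise ValueError(
                f"smallest class has {counts.min()} samples < {n_folds} folds; "
                "consider scheme='loo'"
            )
        splitter = StratifiedKFold(n_folds, shuffle=True, random_state=seed)
        splits = list(splitter.split(np.zeros(n), y))
    elif scheme == "loo":
        splits = list(LeaveOneOut().split(np.zeros(n)))
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    fold_assignment = np.empty(n, dtype=int)
    y_pred = np.empty(n, dtype=object)
    fold_metrics: list[dict] = []
    per_class_fold_acc: dict[str, list[float]] = {c: [] for c in CLASS_ORDER}
    per_voter_fold_acc: dict[str, list[float]] = {s.name: [] for s in specs}
    n_fit_rounds = 0

    # LOO folds can orphan a 2-sample class down to one training sample;
    # the dataset-level contract (>= 2 per class) still holds above.
    fold_min_count = 1 if scheme == "loo" else 2
    for fold, (train, test) in enumerate(splits):
        fold_assignment[test] = fold
        confidences = []
        for spec in specs:
            model, _sel = _fit_voter(
                spec, features, train, y[train], seed, fold_min_count
            )
            cm = _voter_confidence(spec, model, features, test)
            confidences.append(cm)
            per_voter_fold_acc[spec.name].append(
                float((cm.argmax_labels() == y[test]).mean())
            )
        n_fit_rounds += 1
        fused = centralized_vote(confidences)
        preds = np.array([r.predicted_label for r in fused])
        y_pred[test] = preds
        acc, prec, rec, _ = compute_metrics(y[test], preds)
        fold_metrics.append({"accuracy": acc, "precision": prec, "recall": rec})
        for cls in CLASS_ORDER:
            mask = y[test] == cls
            if mask.any():
                per_class_fold_acc[cls].append(float((preds[mask] == cls).mean()))

    y_pred = y_pred.astype(str)
    _, _, _, confusion = compute_metrics(y, y_pred)
    return CvReport(
        scheme=scheme,
        fold_metrics=fold_metrics,
        accuracy=float(np.mean([m["accuracy"] for m in fold_metrics])),
        precision=float(np.mean([m["precision"] for m in fold_metrics])),
        recall=float(np.mean([m["recall"] for m in fold_metrics])),
        confusion=confusion,
        per_class_fold_accuracy=per_class_fold_acc,
        per_voter_fold_accuracy=per_voter_fold_acc,
        fold_assignment=fold_assignment,
        n_fit_rounds=n_fit_rounds,
        y_true=y.copy(),
        y_pred=y_pred,
    )
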