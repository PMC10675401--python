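"""Feature-space reduction for the two signals.

The sequence feature space is reduced by LASSO: one-vs-rest L1-penalized
logistic regressions over a penalty path, the penalty chosen by internal
cross-validated deviance, and the selected set taken as the union of
nonzero-coefficient features across the four class heads.

The image feature space is reduced by stepwise discriminant analysis (SDA):
forward-backward selection minimizing Wilks' lambda with the classic
F-to-enter 3.84 / F-to-remove 2.71 thresholds.

Both selectors are fitted on training rows only; applying a
:class:`SelectionResult` to test rows uses nothing but the stored column
indices, so no test-row information can leak into the transform.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.metrics import log_loss

F_ENTER_DEFAULT = 3.84
F_REMOVE_DEFAULT = 2.71
_SCHUR_TOL = 1e-10


@dataclasses.dataclass(frozen=True)
class SelectionResult:
    """Outcome of a selection run: ordered unique column indices + diagnostics."""

    selected_indices: tuple[int, ...]
    method: str
    path_diagnostics: dict

    def __post_init__(self) -> None:
        if len(set(self.selected_indices)) != len(self.selected_indices):
            raise ValueError("selected indices must be unique")

    def transform(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X)[:, list(self.selected_indices)]


def _drop_constant(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    keep = X.std(axis=0) > 0
    return X[:, keep], np.flatnonzero(keep)


def lasso_select(
    X: np.ndarray,
    y: np.ndarray,
    folds: int = 3,
    seed: int = 0,
    n_penalties: int = 8,
) -> SelectionResult:
    """LASSO selection over a one-vs-rest L1 logistic penalty path.

    Features are standardized on the given rows; constant columns are dropped
    before fitting.  For each class a binary L1 logistic regression is fitted
    at ``n_penalties`` log-spaced inverse penalties, the penalty minimizing the
    internally cross-validated deviance is chosen, and the selected set is the
    union of nonzero-coefficient features across classes.  If the union is
    empty, the weakest penalty producing at least one nonzero coefficient is
    used instead (fallback contract).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("lasso_select needs at least 2 classes")
    Xw, kept = _drop_constant(X)
    mu, sd = Xw.mean(axis=0), Xw.std(axis=0)
    Z = (Xw - mu) / sd
    Cs = np.logspace(-2.5, 1.5, n_penalties)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(cv.split(Z, y))

    def _fit(C: float, rows_X: np.ndarray, rows_y: np.ndarray) -> LogisticRegression:
        return LogisticRegression(
            l1_ratio=1.0, C=C, solver="liblinear", max_iter=2000, random_state=seed
        ).fit(rows_X, rows_y)

    selected: set[int] = set()
    chosen_Cs, nonzero_counts = [], []
    for cls in classes:
        yb = (y == cls).astype(int)
        deviances = np.zeros(Cs.size)
        for tr, te in splits:
            if yb[tr].min() == yb[tr].max():  # fold lost the positive class
                continue
            for ci, C in enumerate(Cs):
                proba = _fit(C, Z[tr], yb[tr]).predict_proba(Z[te])[:, 1]
                deviances[ci] += log_loss(yb[te], proba, labels=[0, 1])
        best = int(np.argmin(deviances))
        coef = _fit(Cs[best], Z, yb).coef_.ravel()
        nz = np.flatnonzero(coef)
        chosen_Cs.append(float(Cs[best]))
        nonzero_counts.append(int(nz.size))
        selected.update(kept[nz].tolist())

    if not selected:  # all-noise fallback: weakest penalty with >= 1 coefficient
        for C in Cs[::-1]:
            for cls in classes:
                nz = np.flatnonzero(_fit(C, Z, (y == cls).astype(int)).coef_.ravel())
                selected.update(kept[nz].tolist())
            if selected:
                break
    diagnostics = {
        "penalty_path": Cs.tolist(),
        "chosen_C_per_class": chosen_Cs,
        "nonzero_per_class": nonzero_counts,
        "n_constant_dropped": int(X.shape[1] - kept.size),
    }
    return SelectionResult(tuple(sorted(selected)), "lasso", diagnostics)


def _schur_complements(
    G: np.ndarray, S: list[int], candidates: np.ndarray
) -> np.ndarray:
    """diag residual of candidate columns after regressing on columns S, from Gram G."""
    diag = G[candidates, candidates]
    if not S:
        return diag
    GSS = G[np.ix_(S, S)]
    GSj = G[np.ix_(S, candidates)]
    try:
        sol = np.linalg.solve(GSS, GSj)
    except np.linalg.LinAlgError:
        sol = np.linalg.lstsq(GSS, GSj, rcond=None)[0]
    return diag - (GSj * sol).sum(axis=0)


def sda_select(
    X: np.ndarray,
    y: np.ndarray,
    f_enter: float = F_ENTER_DEFAULT,
    f_remove: float = F_REMOVE_DEFAULT,
    max_steps: int = 40,
) -> SelectionResult:
    """Forward-backward stepwise discriminant analysis on Wilks' lambda.

    At each forward step the candidate with the largest partial F joins the
    set if its F >= *f_enter*; after each addition, any included feature whose
    F-to-remove < *f_remove* leaves again.  Candidates whose within-class or
    total residual variance is (numerically) degenerate -- constant or
    collinear columns -- are skipped.  The lambda value after every accepted
    step is recorded; over forward steps it is non-increasing by
    construction.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, y_idx = np.unique(y, return_inverse=True)
    n, p = X.shape
    g = classes.size
    if n <= g:
        raise ValueError("sda_select needs more samples than classes")

    grand = X.mean(axis=0)
    Xt = X - grand
    Xw = X.copy()
    for c in range(g):
        rows = y_idx == c
        Xw[rows] -= X[rows].mean(axis=0)
    # Gram matrices of the centered designs give W and T scatter entries
    W = Xw.T @ Xw
    T = Xt.T @ Xt

    scale = np.maximum(T.diagonal(), 1.0)
    selected: list[int] = []
    lambdas: list[float] = []
    f_values: list[float] = []
    skipped: list[int] = []
    current_lambda = 1.0

    for _step in range(max_steps):
        changed = False
        candidates = np.array([j for j in range(p) if j not in selected], dtype=int)
        if candidates.size:
            sw = _schur_complements(W, selected, candidates)
            st = _schur_complements(T, selected, candidates)
            ok = (st > _SCHUR_TOL * scale[candidates]) & (
                sw > _SCHUR_TOL * scale[candidates]
            )
            skipped.extend(candidates[~ok].tolist())
            ratio = np.where(ok, sw / np.where(ok, st, 1.0), 1.0)  # lambda ratio <= 1
            df2 = n - g - len(selected)
            if df2 > 0:
                with np.errstate(divide="ignore"):
                    F = (df2 / (g - 1)) * (1.0 / ratio - 1.0)
                F = np.where(ok, F, -np.inf)
                best = int(np.argmax(F))
                if F[best] >= f_enter:
                    j = int(candidates[best])
                    selected.append(j)
                    current_lambda *= float(ratio[best])
                    lambdas.append(current_lambda)
                    f_values.append(float(F[best]))
                    changed = True
        # backward pass: drop anything whose F-to-remove fell below threshold
        removed = True
        while removed and len(selected) > 1:
            removed = False
            pS = len(selected)
            df2 = n - g - pS + 1
            worst_j, worst_F, worst_ratio = None, np.inf, 1.0
            for j in selected:
                rest = [k for k in selected if k != j]
                sw = _schur_complements(W, rest, np.array([j]))[0]
                st = _schur_complements(T, rest, np.array([j]))[0]
                if st <= _SCHUR_TOL * scale[j]:
                    continue
                ratio = sw / st
                if ratio <= _SCHUR_TOL:  # feature absorbs all residual scatter
                    continue  # infinite F-to-remove: never drop it
                F = (df2 / (g - 1)) * (1.0 / ratio - 1.0)
                if F < worst_F:
                    worst_j, worst_F, worst_ratio = j, F, ratio
            if worst_j is not None and worst_F < f_remove:
                selected.remove(worst_j)
                current_lambda /= worst_ratio
                lambdas.append(current_lambda)
                changed = True
                removed = True
        if not changed:
            break

    diagnostics = {
        "wilks_lambda": lambdas,
        "partial_f": f_values,
        "n_skipped_degenerate": len(set(skipped)),
        "f_enter": f_enter,
        "f_remove": f_remove,
    }
    return SelectionResult(tuple(selected), "sda", diagnostics)
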