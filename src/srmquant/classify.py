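"""Biomarker-panel classification under leave-one-out cross-validation.

Proteins are ranked by one-way ANOVA p-value across the clinical
conditions, and nested panels of the top 1..N proteins are evaluated with
four multiclass algorithms — linear discriminant analysis (LDA), quadratic
discriminant analysis (QDA), multinomial logistic regression, and random
forests — all with fixed sensible defaults and no hyperparameter tuning
(model-complexity control through panel size, rather than regularization).
Out-of-sample error comes from leave-one-out cross-validation (LOOCV):
with the default leakage-free protocol the ANOVA ranking is recomputed
inside each training fold; ``rank_once=True`` ranks on the full data
instead (the simpler protocol).

The final model report pools the LOOCV held-out class probabilities into a
confusion matrix, an out-of-sample accuracy, and per-class one-vs-rest ROC
curves with trapezoidal AUC.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats as st
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve

from .srm_data import ClassificationReport, ProteinAbundanceMatrix, ValidationError

__all__ = [
    "ALGORITHMS",
    "rank_proteins_anova",
    "evaluate_panels",
    "final_model_report",
]

ALGORITHMS = ["LDA", "QDA", "multinomial", "random_forest"]

CONDITION_ORDER = ["control", "cirrhosis", "HCC"]

_FOREST_SIZE = 100  # fixed; no tuning


def _as_frame(matrix) -> pd.DataFrame:
    if isinstance(matrix, ProteinAbundanceMatrix):
        return matrix.values
    return matrix


def _make_estimator(name: str, seed: int):
    if name == "LDA":
        return LinearDiscriminantAnalysis()
    if name == "QDA":
        return QuadraticDiscriminantAnalysis()
    if name == "multinomial":
        return LogisticRegression(C=np.inf, max_iter=2000)
    if name == "random_forest":
        return RandomForestClassifier(n_estimators=_FOREST_SIZE,
                                      random_state=seed % (2 ** 31))
    raise ValidationError(f"unknown algorithm {name!r}")


def rank_proteins_anova(matrix, labels) -> pd.DataFrame:
    """Rank proteins by one-way ANOVA p-value across conditions.

    Ties (and zero-variance proteins, which get p = 1) break on the
    protein name, giving a deterministic total order.

    Returns a DataFrame with columns protein, F_statistic, p_value in rank
    order.
    """
    values = _as_frame(matrix)
    labels = pd.Series(np.asarray(labels), index=values.index)
    classes = [c for c in labels.unique()]
    if len(classes) < 2 or labels.value_counts().min() < 2:
        raise ValidationError("need >= 2 classes with >= 2 samples each")
    rows = []
    for prot in values.columns:
        groups = [values.loc[labels == c, prot].dropna().values for c in classes]
        if any(len(g) < 2 for g in groups) or all(np.var(g) == 0 for g in groups):
            # degenerate: untestable or no within-group variance
            flat = np.concatenate(groups)
            if np.all(flat == flat[0]):
                rows.append(dict(protein=prot, F_statistic=np.nan, p_value=1.0))
                continue
        f, p = st.f_oneway(*groups)
        if not np.isfinite(p):
            f, p = np.nan, 1.0
        rows.append(dict(protein=prot, F_statistic=float(f) if np.isfinite(f)
                         else np.nan, p_value=float(p)))
    out = pd.DataFrame(rows).sort_values(["p_value", "protein"],
                                         kind="stable").reset_index(drop=True)
    return out


def _loocv_folds(n: int):
    idx = np.arange(n)
    for i in range(n):
        yield idx[idx != i], i


def evaluate_panels(
    matrix,
    labels,
    algorithms: list[str] | None = None,
    max_panel: int | None = None,
    seed: int = 0,
    rank_once: bool = False,
) -> tuple[pd.DataFrame, list[str]]:
    """LOOCV accuracy grid over nested panel sizes and algorithms.

    For each fold, proteins are ranked on the training samples only
    (unless ``rank_once``), and for every panel size k the top-k proteins
    feed each algorithm; the held-out sample's prediction is scored.  QDA
    is skipped (with a recorded warning) in any fold where some class has
    fewer training samples than k + 1, which would make its class
    covariance singular.

    Returns (grid, warnings): grid is panel size x algorithm, LOOCV
    accuracy in percent.
    """
    algorithms = list(algorithms) if algorithms is not None else list(ALGORITHMS)
    for a in algorithms:
        _make_estimator(a, 0)  # validates the name
    values = _as_frame(matrix)
    if values.isna().any().any():
        raise ValidationError("matrix must be complete (impute upstream)")
    y = np.asarray(labels)
    n, n_prot = values.shape
    max_panel = min(max_panel or n_prot, n_prot)

    global_rank = rank_proteins_anova(values, y)["protein"].tolist()
    X = values.values
    cols = list(values.columns)
    col_ix = {p: i for i, p in enumerate(cols)}

    correct = {(k, a): [] for k in range(1, max_panel + 1) for a in algorithms}
    warnings: list[str] = []
    for train, test in _loocv_folds(n):
        if rank_once:
            ranking = global_rank
        else:
            ranking = rank_proteins_anova(values.iloc[train],
                                          y[train])["protein"].tolist()
        y_tr = y[train]
        class_sizes = pd.Series(y_tr).value_counts()
        for k in range(1, max_panel + 1):
            feats = [col_ix[p] for p in ranking[:k]]
            X_tr, X_te = X[np.ix_(train, feats)], X[test, feats].reshape(1, -1)
            for a in algorithms:
                if a == "QDA" and class_sizes.min() < k + 1:
                    warnings.append(
                        f"fold {test}, panel {k}: QDA skipped "
                        f"(class with < {k + 1} samples)")
                    continue
                est = _make_estimator(a, seed)
                try:
                    est.fit(X_tr, y_tr)
                except np.linalg.LinAlgError as exc:
                    warnings.append(
                        f"fold {test}, panel {k}: {a} skipped ({exc})")
                    continue
                correct[(k, a)].append(est.predict(X_te)[0] == y[test])
    grid = pd.DataFrame(index=range(1, max_panel + 1), columns=algorithms,
                        dtype=float)
    grid.index.name = "panel_size"
    for (k, a), hits in correct.items():
        grid.loc[k, a] = 100.0 * np.mean(hits) if hits else np.nan
    return grid, warnings


def final_model_report(
    matrix,
    labels,
    panel: list[str],
    algorithm: str,
    seed: int = 0,
    accuracy_grid: pd.DataFrame | None = None,
) -> ClassificationReport:
    """Characterize one panel + algorithm choice in full.

    In-sample accuracy from a fit on all samples; LOOCV held-out class
    probabilities pooled into the out-of-sample accuracy, the true x
    predicted confusion matrix, and per-class one-vs-rest ROC curves with
    trapezoidal AUC.
    """
    values = _as_frame(matrix)
    y = np.asarray(labels)
    classes = [c for c in CONDITION_ORDER if c in set(y)]
    if len(classes) < 2:
        raise ValidationError("need at least 2 classes present in labels")
    missing = [p for p in panel if p not in values.columns]
    if missing:
        raise ValidationError(f"panel proteins not in matrix: {missing}")
    X = values[list(panel)].values
    n = len(y)

    est = _make_estimator(algorithm, seed)
    est.fit(X, y)
    in_sample = 100.0 * float(np.mean(est.predict(X) == y))

    proba = np.zeros((n, len(classes)))
    pred = np.empty(n, dtype=object)
    for train, test in _loocv_folds(n):
        fold_est = _make_estimator(algorithm, seed)
        fold_est.fit(X[train], y[train])
        p = fold_est.predict_proba(X[test].reshape(1, -1))[0]
        order = [list(fold_est.classes_).index(c) for c in classes]
        proba[test] = p[order]
        pred[test] = classes[int(np.argmax(p[order]))]

    confusion = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for yt, yp in zip(y, pred):
        confusion.loc[yt, yp] += 1
    out_sample = 100.0 * float(np.trace(confusion.values)) / n

    auc = {}
    roc_curves = {}
    for j, c in enumerate(classes):
        fpr, tpr, _ = roc_curve((y == c).astype(int), proba[:, j])
        auc[c] = float(np.trapezoid(tpr, fpr))
        roc_curves[c] = pd.DataFrame({"fpr": fpr, "tpr": tpr})

    return ClassificationReport(
        selected_panel=list(panel),
        algorithm=algorithm,
        in_sample_accuracy=round(in_sample, 2),
        out_of_sample_accuracy=round(out_sample, 2),
        confusion=confusion,
        auc=auc,
        accuracy_grid=accuracy_grid,
        roc_curves=roc_curves,
    )
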