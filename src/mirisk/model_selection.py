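"""Cross-validated (T, m) grid search and final-model fitting.

The hyperparameters are T, the per-miRNA |z| selection threshold, and m,
the number of leading PC scores in the risk model.  Both are chosen by
10-fold stratified cross-validation on the discovery cohort: within each
fold, z-values, feature selection, PCA and the PC-logistic fit all use
only the 9/10 training portion, and the mean held-out AUC over folds
scores each (T, m) cell.  The default grid is T in 0.1..5.0 step 0.1
(50 values) by m in 1..10 — 500 cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from . import association, evaluation, spca_model
from .spca_model import RiskModel

__all__ = [
    "default_t_grid",
    "default_m_grid",
    "FoldAssignment",
    "GridResult",
    "make_folds",
    "cv_grid_search",
    "select_optimum",
    "fit_final_model",
]


def default_t_grid() -> np.ndarray:
    """T = 0.1, 0.2, ..., 5.0 (50 values)."""
    return np.round(np.arange(1, 51) * 0.1, 1)


def default_m_grid() -> np.ndarray:
    """m = 1, ..., 10."""
    return np.arange(1, 11)


@dataclass(frozen=True)
class FoldAssignment:
    """Stratified k-fold partition of the discovery cohort."""

    fold: pd.Series  # fold index 0..k-1 per sample
    k: int
    seed: int


@dataclass
class GridResult:
    """Per-cell cross-validation summary.

    ``table`` has one row per (T, m) cell with columns ``T``, ``m``,
    ``mean_auc``, ``sd_auc``, ``mean_n_mirnas`` and ``n_valid_folds``;
    ``fold_aucs`` maps (T, m) to the per-fold AUC vector (NaN where the
    fold had no valid model).
    """

    table: pd.DataFrame
    fold_aucs: dict[tuple[float, int], np.ndarray]
    scoring: str = "per-fold"


def make_folds(
    labels: pd.Series, k: int = 10, seed: int = 0
) -> FoldAssignment:
    """Seeded stratified k-fold assignment (fold sizes within each class
    differ by at most one)."""
    y = np.asarray(labels)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValueError(
            f"smallest class has {counts.min()} samples; cannot build {k} folds"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold = np.empty(len(y), dtype=int)
    for i, (_, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        fold[test_idx] = i
    return FoldAssignment(fold=pd.Series(fold, index=labels.index), k=k, seed=seed)


def cv_grid_search(
    expression: pd.DataFrame,
    labels: pd.Series,
    covariates: pd.DataFrame,
    folds: FoldAssignment,
    t_grid: Sequence[float] | None = None,
    m_grid: Sequence[int] | None = None,
    scoring: str = "per-fold",
) -> GridResult:
    """Evaluate every (T, m) cell by cross-validation.

    Feature selection happens strictly inside each fold: per-miRNA
    z-values are recomputed on the fold's training portion, never on the
    full cohort.  A fold contributes to a cell only if at least one
    miRNA passes T and the PC-logistic fit converges; a cell's mean AUC
    averages its valid folds (``n_valid_folds`` records how many).
    Cells valid in no fold are carried as NaN.

    ``scoring='pooled'`` instead scores the pooled out-of-fold
    prognostic indices once per cell (mean_auc is then that single AUC).
    """
    t_grid = np.asarray(default_t_grid() if t_grid is None else t_grid, dtype=float)
    m_grid = np.asarray(default_m_grid() if m_grid is None else m_grid, dtype=int)
    if t_grid.size == 0 or m_grid.size == 0:
        raise ValueError("T and m grids must be non-empty")
    if scoring not in ("per-fold", "pooled"):
        raise ValueError(f"unknown scoring {scoring!r}")

    k = folds.k
    fold_idx = folds.fold.to_numpy()
    n_cells = len(t_grid) * len(m_grid)
    fold_aucs = {
        (float(T), int(m)): np.full(k, np.nan) for T in t_grid for m in m_grid
    }
    n_sel = {float(T): np.full(k, np.nan) for T in t_grid}
    pooled_pi: dict[tuple[float, int], np.ndarray] = {
        key: np.full(len(labels), np.nan) for key in fold_aucs
    }

    for f in range(k):
        train = fold_idx != f
        test = fold_idx == f
        expr_tr = expression.loc[train]
        y_tr = labels.loc[train]
        assoc = association.compute_z_values(expr_tr, y_tr, covariates.loc[train])
        expr_te = expression.loc[test]
        y_te = labels.loc[test].to_numpy()

        cache: dict[tuple[str, ...], tuple] = {}
        for T in t_grid:
            selected = tuple(association.select_mirnas(assoc, float(T)))
            n_sel[float(T)][f] = len(selected)
            if not selected:
                continue
            if selected in cache:
                pca, scores_tr, scores_te = cache[selected]
            else:
                pca = spca_model.fit_pca(expr_tr[list(selected)])
                scores_tr = spca_model.project(pca, expr_tr)
                scores_te = spca_model.project(pca, expr_te)
                cache[selected] = (pca, scores_tr, scores_te)
            for m in m_grid:
                m_eff = min(int(m), pca.n_components)
                betas, converged = spca_model.fit_pc_logistic(scores_tr, y_tr, m_eff)
                if not converged:
                    continue
                pi_te = scores_te[:, :m_eff] @ betas
                curve = evaluation.roc_and_auc(pi_te, y_te)
                fold_aucs[(float(T), int(m))][f] = curve.auc
                pooled_pi[(float(T), int(m))][test.nonzero()[0]] = pi_te

    rows = np.empty((n_cells, 6))
    y_all = labels.to_numpy()
    for i, (T, m) in enumerate(
        (float(T), int(m)) for T in t_grid for m in m_grid
    ):
        aucs = fold_aucs[(T, m)]
        valid = ~np.isnan(aucs)
        n_valid = int(valid.sum())
        if scoring == "pooled":
            pis = pooled_pi[(T, m)]
            scored = ~np.isnan(pis)
            if n_valid > 0 and len(np.unique(y_all[scored])) == 2:
                mean_auc = evaluation.roc_and_auc(pis[scored], y_all[scored]).auc
            else:
                mean_auc = np.nan
            sd_auc = np.nan
        else:
            mean_auc = aucs[valid].mean() if n_valid else np.nan
            sd_auc = aucs[valid].std(ddof=1) if n_valid > 1 else np.nan
        rows[i] = (T, m, mean_auc, sd_auc, np.nanmean(n_sel[T]), n_valid)

    table = pd.DataFrame(
        rows,
        columns=["T", "m", "mean_auc", "sd_auc", "mean_n_mirnas", "n_valid_folds"],
    )
    table["m"] = table["m"].astype(int)
    table["n_valid_folds"] = table["n_valid_folds"].astype(int)
    return GridResult(table=table, fold_aucs=fold_aucs, scoring=scoring)


def select_optimum(grid: GridResult) -> tuple[float, int]:
    """(T*, m*) of the cell with maximal mean AUC.

    Ties prefer the larger T (fewer miRNAs), then the smaller m.
    """
    t = grid.table
    valid = t[(t["n_valid_folds"] > 0) & t["mean_auc"].notna()]
    if valid.empty:
        raise ValueError("no (T, m) cell produced a valid model in any fold")
    best = valid.sort_values(
        ["mean_auc", "T", "m"], ascending=[False, False, True]
    ).iloc[0]
    return float(best["T"]), int(best["m"])


def fit_final_model(
    expression: pd.DataFrame,
    labels: pd.Series,
    covariates: pd.DataFrame,
    T: float,
    m: int,
    disease: str = "case",
    provenance: dict | None = None,
) -> RiskModel:
    """Fit the final risk model on the full discovery cohort.

    Recomputes z-values and the selection at T, fits PCA and the
    PC-logistic model (m capped at the available components), and sets
    the prognostic-index cutoff at the discovery-cohort ROC point with
    maximal mean sensitivity/specificity.
    """
    assoc = association.compute_z_values(expression, labels, covariates)
    selected = association.select_mirnas(assoc, T)
    if not selected:
        raise ValueError(f"no miRNA reaches |z| >= {T}; cannot fit a model")
    pca = spca_model.fit_pca(expression[selected])
    m_eff = min(int(m), pca.n_components)
    scores = spca_model.project(pca, expression)
    betas, converged = spca_model.fit_pc_logistic(scores, labels, m_eff)
    if not converged:
        raise ValueError("PC-score logistic regression did not converge")
    model = RiskModel(
        disease=disease,
        T=float(T),
        m=m_eff,
        pca=pca,
        betas=betas,
        provenance=dict(provenance or {}),
    )
    pi = spca_model.prognostic_index(model, expression)
    curve = evaluation.roc_and_auc(pi, labels)
    model.pi_cutoff = evaluation.optimal_cutoff(curve)
    return model
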