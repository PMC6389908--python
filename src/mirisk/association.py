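"""Per-miRNA covariate-adjusted logistic regression and z-value selection.

For each miRNA a logistic model

    logit P(case) = a0 + a1*sex + a2*age + a3*apoe + a4*x

is fit by maximum likelihood; the Wald z-value is ``a4 / SE(a4)``.
miRNAs are pre-selected by ``|z| >= T``.  The z-values are used only for
ranked pre-selection, so no multiple-testing correction is applied.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "COVARIATE_COLUMNS",
    "validate_covariates",
    "fit_single_mirna_logistic",
    "compute_z_values",
    "select_mirnas",
]

COVARIATE_COLUMNS = ("sex", "age", "apoe")

_MAXITER = 50


def validate_covariates(covariates: pd.DataFrame) -> pd.DataFrame:
    """Check clinical covariates (sex in {0,1}, age > 0, APOE count in
    {0,1,2}) and return them in canonical column order."""
    missing = [c for c in COVARIATE_COLUMNS if c not in covariates.columns]
    if missing:
        raise ValueError(f"covariate column(s) missing: {missing}")
    cov = covariates[list(COVARIATE_COLUMNS)]
    if cov.isna().any().any():
        raise ValueError("covariates contain missing values")
    if not cov["sex"].isin([0, 1]).all():
        raise ValueError("sex must be coded 0/1")
    if (cov["age"] <= 0).any():
        raise ValueError("age must be positive")
    if not cov["apoe"].isin([0, 1, 2]).all():
        raise ValueError("apoe must be the epsilon-4 allele count 0/1/2")
    return cov


def _check_labels(labels: pd.Series | np.ndarray) -> np.ndarray:
    y = np.asarray(labels, dtype=float)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError(f"labels must contain exactly two classes, got {classes}")
    if counts.min() < 2:
        raise ValueError("each class needs at least two samples")
    if not set(classes) <= {0.0, 1.0}:
        raise ValueError("labels must be coded 0/1")
    return y


def _fit_wald_z(y: np.ndarray, design: np.ndarray) -> tuple[float, float, float, bool]:
    """MLE logistic fit; returns (coef, se, z) of the LAST design column
    plus a convergence flag.  Separation and singular fits are flagged,
    not raised."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, design).fit(method="newton", maxiter=_MAXITER, disp=0)
        except (PerfectSeparationError, np.linalg.LinAlgError, ValueError):
            return np.nan, np.nan, np.nan, False
    coef = float(res.params[-1])
    se = float(res.bse[-1])
    converged = bool(res.mle_retvals.get("converged", False))
    if not (np.isfinite(coef) and np.isfinite(se) and se > 0):
        return coef, se, np.nan, False
    return coef, se, coef / se, converged


def _design_base(y: np.ndarray, covariates: pd.DataFrame) -> np.ndarray:
    """Intercept + non-constant covariate columns."""
    cov = validate_covariates(covariates)
    cols = [np.ones(len(cov))]
    for name in COVARIATE_COLUMNS:
        col = cov[name].to_numpy(dtype=float)
        if np.ptp(col) == 0:
            warnings.warn(
                f"covariate {name!r} is constant and was dropped from the model",
                stacklevel=3,
            )
            continue
        cols.append(col)
    return np.column_stack(cols)


def fit_single_mirna_logistic(
    labels: pd.Series | np.ndarray,
    covariates: pd.DataFrame,
    x: pd.Series | np.ndarray,
) -> tuple[float, float, float, bool]:
    """Covariate-adjusted logistic fit for one miRNA.

    Returns ``(coef, se, z, converged)`` for the miRNA term.  A constant
    miRNA carries no information and is flagged non-converged; perfect
    separation is likewise flagged rather than raised.
    """
    y = _check_labels(labels)
    base = _design_base(y, covariates)
    xv = np.asarray(x, dtype=float)
    if xv.shape[0] != y.shape[0]:
        raise ValueError("expression vector length does not match labels")
    if np.ptp(xv) == 0:
        return np.nan, np.nan, np.nan, False
    return _fit_wald_z(y, np.column_stack([base, xv]))


def compute_z_values(
    expression: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    covariates: pd.DataFrame,
) -> pd.DataFrame:
    """Per-miRNA Wald z-values, one covariate-adjusted fit per column.

    Returns a DataFrame indexed by miRNA id (input column order
    preserved) with columns ``coef``, ``se``, ``z``, ``converged``.
    """
    y = _check_labels(labels)
    if expression.shape[0] != y.shape[0]:
        raise ValueError("expression rows do not match labels")
    base = _design_base(y, covariates)
    design = np.column_stack([base, np.zeros(len(y))])
    values = expression.to_numpy(dtype=float)

    records = np.empty((expression.shape[1], 3))
    converged = np.empty(expression.shape[1], dtype=bool)
    for j in range(expression.shape[1]):
        xv = values[:, j]
        if np.ptp(xv) == 0:
            records[j] = (np.nan, np.nan, np.nan)
            converged[j] = False
            continue
        design[:, -1] = xv
        coef, se, z, ok = _fit_wald_z(y, design)
        records[j] = (coef, se, z)
        converged[j] = ok
    return pd.DataFrame(
        {
            "coef": records[:, 0],
            "se": records[:, 1],
            "z": records[:, 2],
            "converged": converged,
        },
        index=expression.columns,
    )


def select_mirnas(result: pd.DataFrame, T: float) -> list[str]:
    """miRNAs with ``|z| >= T`` among converged fits, in input order.

    Selection is two-sided: protective and risk-increasing miRNAs are
    both informative.  Ties at ``|z| = T`` are included so the grid
    endpoints behave deterministically.
    """
    if T < 0:
        raise ValueError(f"selection threshold T must be >= 0, got {T}")
    keep = result["converged"] & (result["z"].abs() >= T)
    return list(result.index[keep])
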