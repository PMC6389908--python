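"""Supervised-PCA core: PCA on pre-selected miRNAs, logistic regression
on the top principal-component scores, and the prognostic index.

The risk model is

    logit P(case) = b1*PC1 + ... + bm*PCm,     PC_c = sum_j l_jc (x_j - mean_j)

fit without an intercept: the published prognostic-index cutoffs are
defined against this parameterization, and the PC scores are centered so
the intercept is nearly redundant for balanced data.  The prognostic
index PI = sum_i b_i * PC_i is the linear risk score; a sample with PI
strictly above the cutoff is predicted a case.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "PCAModel",
    "RiskModel",
    "fit_pca",
    "project",
    "fit_pc_logistic",
    "prognostic_index",
]


@dataclass
class PCAModel:
    """PCA fitted on the selected-miRNA training submatrix.

    ``loadings`` is a features x components matrix with orthonormal
    columns ordered by decreasing explained variance.  Each column is
    sign-fixed so its largest-magnitude entry is positive, making
    serialized models reproducible across linear-algebra backends.
    Features are centered by the training means but not variance-scaled
    (all miRNAs share the log2 expression scale).
    """

    mirna_ids: list[str]
    center: np.ndarray
    loadings: np.ndarray
    explained_variance: np.ndarray

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


def fit_pca(expression: pd.DataFrame) -> PCAModel:
    """PCA (via SVD of the centered matrix) of the selected miRNAs.

    Keeps ``min(n_features, n_samples - 1)`` components.  Raises if the
    submatrix has zero total variance (no direction to extract).
    """
    if expression.shape[0] < 2:
        raise ValueError("PCA requires at least two samples")
    if expression.shape[1] < 1:
        raise ValueError("PCA requires at least one feature")
    # canonical layout: summation/SVD results independent of how the
    # caller's DataFrame happens to be stored
    X = np.ascontiguousarray(expression.to_numpy(dtype=float))
    center = X.mean(axis=0)
    Xc = X - center
    if not np.any(Xc):
        raise ValueError("selected submatrix has zero variance; PCA undefined")
    n_comp = min(X.shape[1], X.shape[0] - 1)
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    loadings = vt[:n_comp].T
    explained = (s[:n_comp] ** 2) / (X.shape[0] - 1)
    # deterministic sign: largest-|.| entry of each loading column positive
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(n_comp)])
    flip[flip == 0] = 1.0
    loadings = loadings * flip
    return PCAModel(
        mirna_ids=list(expression.columns),
        center=center,
        loadings=loadings,
        explained_variance=explained,
    )


def project(pca: PCAModel, expression: pd.DataFrame) -> np.ndarray:
    """PC scores of (possibly unseen) samples using the training centers."""
    missing = [m for m in pca.mirna_ids if m not in expression.columns]
    if missing:
        raise ValueError(f"expression matrix lacks model miRNA(s): {missing}")
    X = np.ascontiguousarray(expression[pca.mirna_ids].to_numpy(dtype=float))
    return (X - pca.center) @ pca.loadings


def fit_pc_logistic(
    scores: np.ndarray,
    labels: pd.Series | np.ndarray,
    m: int,
    intercept: bool = False,
) -> tuple[np.ndarray, bool]:
    """Maximum-likelihood logistic fit of the top ``m`` PC scores.

    Returns ``(betas, converged)``.  The intercept is omitted by default
    (see module docstring); pass ``intercept=True`` to include one, in
    which case the returned betas still exclude it.
    """
    y = np.asarray(labels, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("labels must contain both classes")
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    if m > scores.shape[1]:
        raise ValueError(
            f"m={m} exceeds the {scores.shape[1]} available PC score(s)"
        )
    design = scores[:, :m]
    if intercept:
        design = np.column_stack([np.ones(len(y)), design])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, design).fit(method="newton", maxiter=100, disp=0)
        except (PerfectSeparationError, np.linalg.LinAlgError):
            return np.full(m, np.nan), False
    betas = np.asarray(res.params[-m:], dtype=float)
    converged = bool(res.mle_retvals.get("converged", False)) and np.all(
        np.isfinite(betas)
    )
    return betas, converged


@dataclass
class RiskModel:
    """Frozen artifact of a fitted supervised-PCA risk model."""

    disease: str
    T: float
    m: int
    pca: PCAModel
    betas: np.ndarray
    pi_cutoff: float | None = None
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.betas = np.asarray(self.betas, dtype=float)
        if self.m > self.pca.n_components:
            raise ValueError(
                f"m={self.m} exceeds the {self.pca.n_components} PCA component(s)"
            )
        if self.betas.shape != (self.m,):
            raise ValueError("betas length must equal m")

    @property
    def mirna_ids(self) -> list[str]:
        return self.pca.mirna_ids

    @property
    def n_selected(self) -> int:
        return len(self.pca.mirna_ids)

    def to_dict(self) -> dict[str, Any]:
        return {
            "disease": self.disease,
            "T": self.T,
            "m": self.m,
            "mirna_ids": self.pca.mirna_ids,
            "center": self.pca.center.tolist(),
            "loadings": self.pca.loadings.tolist(),
            "explained_variance": self.pca.explained_variance.tolist(),
            "betas": self.betas.tolist(),
            "pi_cutoff": self.pi_cutoff,
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, doc: dict[str, Any]) -> "RiskModel":
        pca = PCAModel(
            mirna_ids=list(doc["mirna_ids"]),
            center=np.asarray(doc["center"], dtype=float),
            loadings=np.asarray(doc["loadings"], dtype=float),
            explained_variance=np.asarray(doc["explained_variance"], dtype=float),
        )
        return cls(
            disease=doc["disease"],
            T=float(doc["T"]),
            m=int(doc["m"]),
            pca=pca,
            betas=np.asarray(doc["betas"], dtype=float),
            pi_cutoff=None if doc.get("pi_cutoff") is None else float(doc["pi_cutoff"]),
            provenance=dict(doc.get("provenance", {})),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "RiskModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def prognostic_index(model: RiskModel, expression: pd.DataFrame) -> pd.Series:
    """PI = sum_i beta_i * PC_i for each sample (higher = more case-like)."""
    scores = project(model.pca, expression)
    pi = scores[:, : model.m] @ model.betas
    return pd.Series(pi, index=expression.index, name="prognostic_index")


def classify(model: RiskModel, expression: pd.DataFrame) -> pd.Series:
    """Predicted case indicator: PI strictly greater than the cutoff."""
    if model.pi_cutoff is None:
        raise ValueError("model has no prognostic-index cutoff set")
    pi = prognostic_index(model, expression)
    return (pi > model.pi_cutoff).astype(int).rename("predicted")
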