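"""End-to-end study orchestration and baseline models.

``run_study`` executes the full per-disease workflow — synthetic-cohort
generation (or file input), per-miRNA association, cross-validated
(T, m) grid search, final-model fitting on the whole discovery cohort,
validation-cohort evaluation, and optional prospective prediction —
plus two reference baselines: a clinical-covariate-only logistic model
and an L1-penalized (LASSO) logistic regression over all miRNAs.

Each disease is an independent case-vs-control problem; the discovery/
validation split is fixed once and shared by every method so AUCs are
directly comparable.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Any
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from . import evaluation, io, model_selection, spca_model, synthetic_data
from .association import validate_covariates
from .evaluation import ContingencyTable, Metrics
from .spca_model import RiskModel
from .synthetic_data import SimulationConfig, SyntheticCohort

__all__ = [
    "StudyConfig",
    "StudyReport",
    "run_study",
    "baseline_clinical",
    "baseline_l1",
    "mirna_set_overlap",
    "OverlapResult",
]

logger = logging.getLogger(__name__)


@dataclass
class StudyConfig:
    """Inputs and settings of one per-disease study run.

    Exactly one of ``simulation`` or (``expression_path`` and
    ``metadata_path``) must be given.
    """

    simulation: SimulationConfig | None = None
    expression_path: str | None = None
    metadata_path: str | None = None
    disease: str = "AD"
    t_grid: list[float] | None = None  # None -> 0.1..5.0 step 0.1
    m_grid: list[int] | None = None  # None -> 1..10
    k_folds: int = 10
    seed: int = 0
    out_dir: str | None = None
    with_baselines: bool = False
    prospective_n_converters: int = 0
    prospective_n_nonconverters: int = 0
    prospective_separation: float = 1.0

    def __post_init__(self) -> None:
        from_files = self.expression_path is not None or self.metadata_path is not None
        if (self.simulation is None) == (not from_files):
            raise ValueError(
                "exactly one input source required: a simulation config or "
                "expression/metadata paths"
            )
        if from_files and (self.expression_path is None or self.metadata_path is None):
            raise ValueError("both expression_path and metadata_path are required")


@dataclass
class StudyReport:
    """Every number in the report is recomputable from the serialized
    per-stage artifacts written to the output directory."""

    disease: str
    t_opt: float
    m_opt: int
    n_selected: int
    cv_auc: float
    validation_auc: float
    pi_cutoff: float
    validation_metrics: Metrics
    validation_table: ContingencyTable
    baseline_clinical_auc: float | None = None
    baseline_l1_auc: float | None = None
    prospective_table: ContingencyTable | None = None
    prospective_metrics: Metrics | None = None
    truth_recovered: int | None = None
    truth_total: int | None = None
    provenance: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        def metrics_dict(m: Metrics | None) -> dict | None:
            return None if m is None else vars(m).copy()

        def table_dict(t: ContingencyTable | None) -> dict | None:
            return None if t is None else vars(t).copy()

        return {
            "disease": self.disease,
            "t_opt": self.t_opt,
            "m_opt": self.m_opt,
            "n_selected": self.n_selected,
            "cv_auc": self.cv_auc,
            "validation_auc": self.validation_auc,
            "pi_cutoff": self.pi_cutoff,
            "validation_metrics": metrics_dict(self.validation_metrics),
            "validation_table": table_dict(self.validation_table),
            "baseline_clinical_auc": self.baseline_clinical_auc,
            "baseline_l1_auc": self.baseline_l1_auc,
            "prospective_table": table_dict(self.prospective_table),
            "prospective_metrics": metrics_dict(self.prospective_metrics),
            "truth_recovered": self.truth_recovered,
            "truth_total": self.truth_total,
            "provenance": self.provenance,
        }


def _load_inputs(
    config: StudyConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticCohort | None]:
    if config.simulation is not None:
        cohort = synthetic_data.generate_cohort(config.simulation)
        return cohort.expression, cohort.metadata, cohort
    expression = io.read_expression(config.expression_path)
    metadata = io.read_metadata(config.metadata_path)
    return expression, metadata, None


def run_study(config: StudyConfig) -> StudyReport:
    """Execute the full workflow for one disease.

    Stages: input (or simulation) -> per-fold association + (T, m) grid
    search on the discovery half -> final model on the complete
    discovery cohort -> ROC/metrics on the held-out validation half ->
    optional clinical and LASSO baselines and prospective validation.
    Deterministic given the config seed.
    """
    t0 = time.time()
    expression, metadata, cohort = _load_inputs(config)
    labels_all = (metadata["phenotype"] != "NC").astype(int)
    keep = metadata["phenotype"].isin([config.disease, "NC"])
    expression = expression.loc[keep]
    metadata = metadata.loc[keep]
    labels_all = labels_all.loc[keep]
    covariates = validate_covariates(metadata)
    split = metadata["split"]

    disc = split == "discovery"
    expr_d, y_d, cov_d = expression.loc[disc], labels_all.loc[disc], covariates.loc[disc]
    expr_v, y_v = expression.loc[~disc], labels_all.loc[~disc]

    logger.info(
        "study %s: %d discovery / %d validation samples, %d miRNAs",
        config.disease, disc.sum(), (~disc).sum(), expression.shape[1],
    )

    folds = model_selection.make_folds(y_d, k=config.k_folds, seed=config.seed)
    grid = model_selection.cv_grid_search(
        expr_d, y_d, cov_d, folds, t_grid=config.t_grid, m_grid=config.m_grid
    )
    t_opt, m_opt = model_selection.select_optimum(grid)
    cv_auc = float(
        grid.table.set_index(["T", "m"]).loc[(t_opt, m_opt), "mean_auc"]
    )
    logger.info("optimum (T, m) = (%.1f, %d), CV mean AUC %.3f", t_opt, m_opt, cv_auc)

    provenance = {
        "seed": config.seed,
        "k_folds": config.k_folds,
        "disease": config.disease,
    }
    model = model_selection.fit_final_model(
        expr_d, y_d, cov_d, t_opt, m_opt, disease=config.disease, provenance=provenance
    )

    pi_v = spca_model.prognostic_index(model, expr_v)
    curve_v = evaluation.roc_and_auc(pi_v, y_v)
    predicted = (pi_v.to_numpy() > model.pi_cutoff).astype(int)
    observed = y_v.to_numpy()
    table_v = ContingencyTable(
        tp=int(np.sum((predicted == 1) & (observed == 1))),
        fp=int(np.sum((predicted == 1) & (observed == 0))),
        fn=int(np.sum((predicted == 0) & (observed == 1))),
        tn=int(np.sum((predicted == 0) & (observed == 0))),
    )
    metrics_v = evaluation.confusion_metrics(table_v)

    report = StudyReport(
        disease=config.disease,
        t_opt=t_opt,
        m_opt=m_opt,
        n_selected=model.n_selected,
        cv_auc=cv_auc,
        validation_auc=curve_v.auc,
        pi_cutoff=float(model.pi_cutoff),
        validation_metrics=metrics_v,
        validation_table=table_v,
        provenance=provenance,
    )

    if config.with_baselines:
        report.baseline_clinical_auc = baseline_clinical(labels_all, covariates, split)
        report.baseline_l1_auc, _ = baseline_l1(
            expression, labels_all, split, seed=config.seed
        )

    if cohort is not None and cohort.truth:
        recovered = set(model.mirna_ids) & set(cohort.truth)
        report.truth_recovered = len(recovered)
        report.truth_total = len(cohort.truth)

    if config.prospective_n_converters + config.prospective_n_nonconverters > 0:
        if cohort is None:
            raise ValueError("prospective generation requires a simulated cohort")
        expr_p, conv = synthetic_data.generate_prospective_cohort(
            cohort,
            config.prospective_n_converters,
            config.prospective_n_nonconverters,
            separation=config.prospective_separation,
            seed=config.seed + 1,
        )
        table_p, metrics_p, _ = evaluation.prospective_validate(model, expr_p, conv)
        report.prospective_table = table_p
        report.prospective_metrics = metrics_p

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        io.write_grid(grid.table, out / "grid.tsv")
        model.save(out / f"model_{config.disease}.json")
        (out / "report.json").write_text(
            json.dumps(report.to_dict(), indent=1, sort_keys=True)
        )
    logger.info("study %s finished in %.1f s", config.disease, time.time() - t0)
    return report


def baseline_clinical(
    labels: pd.Series, covariates: pd.DataFrame, split: pd.Series
) -> float:
    """Validation AUC of a logistic model on (sex, age, APOE) alone."""
    cov = validate_covariates(covariates)
    disc = split == "discovery"
    y_d = labels.loc[disc]
    if len(np.unique(y_d)) < 2 or len(np.unique(labels.loc[~disc])) < 2:
        raise ValueError("both classes required in discovery and validation")
    keep_cols = []
    for name in cov.columns:
        if cov.loc[disc, name].nunique() > 1:
            keep_cols.append(name)
        else:
            warnings.warn(
                f"covariate {name!r} is constant and was dropped from the model",
                stacklevel=2,
            )
    if not keep_cols:
        raise ValueError("all covariates are constant in the discovery cohort")
    X_d = sm.add_constant(cov.loc[disc, keep_cols].to_numpy(dtype=float))
    X_v = sm.add_constant(
        cov.loc[~disc, keep_cols].to_numpy(dtype=float), has_constant="add"
    )
    res = sm.Logit(y_d.to_numpy(dtype=float), X_d).fit(disp=0)
    scores = X_v @ res.params
    return evaluation.roc_and_auc(scores, labels.loc[~disc]).auc


def baseline_l1(
    expression: pd.DataFrame,
    labels: pd.Series,
    split: pd.Series,
    k_folds: int = 10,
    n_penalties: int = 10,
    seed: int = 0,
) -> tuple[float, list[str]]:
    """LASSO logistic regression over all miRNAs.

    The penalty is chosen by stratified cross-validation (AUC scoring)
    on the discovery cohort; features are standardized with discovery
    means/SDs.  Returns the validation AUC and the miRNAs with nonzero
    coefficients at the chosen penalty.
    """
    disc = split == "discovery"
    X_d = expression.loc[disc]
    y_d = labels.loc[disc].to_numpy()
    if len(np.unique(y_d)) < 2:
        raise ValueError("discovery cohort must contain both classes")
    cv = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    clf = Pipeline(
        [
            ("scale", StandardScaler()),
            (
                "lasso",
                LogisticRegressionCV(
                    penalty="l1",
                    solver="liblinear",
                    scoring="roc_auc",
                    Cs=n_penalties,
                    cv=cv,
                    max_iter=1000,
                    random_state=seed,
                ),
            ),
        ]
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(X_d.to_numpy(), y_d)
    coefs = clf.named_steps["lasso"].coef_.ravel()
    nonzero = [m for m, c in zip(expression.columns, coefs) if c != 0.0]
    scores = clf.decision_function(expression.loc[~disc].to_numpy())
    return evaluation.roc_and_auc(scores, labels.loc[~disc]).auc, nonzero


@dataclass
class OverlapResult:
    """Venn partition of named miRNA sets.

    ``region_counts`` is keyed by '&'-joined sorted member names, e.g.
    'AD' (exclusive to AD), 'AD&VaD', 'AD&DLB&VaD'.  ``specific_fraction``
    is each set's exclusive count over its size; ``shared_fraction`` is
    the all-set intersection over the union.
    """

    region_counts: dict[str, int]
    specific_fraction: dict[str, float]
    shared_fraction: float
    union_size: int


def mirna_set_overlap(sets: dict[str, set[str]]) -> OverlapResult:
    """Intersection-region counts and sharing fractions of named sets."""
    if len(sets) < 2:
        raise ValueError("at least two named sets are required")
    for name, s in sets.items():
        if not s:
            warnings.warn(f"set {name!r} is empty", stacklevel=2)
    names = sorted(sets)
    union: set[str] = set().union(*sets.values())
    region_counts: dict[str, int] = {}
    for r in range(1, len(names) + 1):
        for members in combinations(names, r):
            inside = set.intersection(*(sets[n] for n in members)) if members else set()
            outside = set().union(
                *(sets[n] for n in names if n not in members), set()
            )
            region_counts["&".join(members)] = len(inside - outside)
    specific = {
        n: (region_counts[n] / len(sets[n])) if sets[n] else float("nan")
        for n in names
    }
    all_shared = set.intersection(*sets.values())
    shared_fraction = len(all_shared) / len(union) if union else float("nan")
    return OverlapResult(
        region_counts=region_counts,
        specific_fraction=specific,
        shared_fraction=shared_fraction,
        union_size=len(union),
    )
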