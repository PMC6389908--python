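# mirisk

Supervised principal-component-analysis (PCA) logistic regression for
building serum-miRNA risk prediction models of dementia subtypes
(Alzheimer's disease, vascular dementia, dementia with Lewy bodies —
each modeled as an independent case-vs-control problem against a shared
normal-control pool).

The package is aimed at researchers who have a high-dimensional miRNA
microarray matrix (a few thousand probes, a few hundred to a few
thousand serum samples) with basic clinical covariates, and who want a
compact, cross-validated linear risk score rather than a black-box
classifier.

## The method

1. **Normalization.** Per array, a trimmed mean/SD of negative-control
   probes defines a detection threshold `mean + 2·SD`; signals above it
   become `log2(signal − mean)`, the rest are floored at the array's
   minimum effective value − 0.1; undetected entries are imputed with
   the per-miRNA mean; arrays are then standardized by the ratio of
   their three internal-control probes (miR-149-3p, miR-2861, miR-4463
   by default).
2. **Feature screening.** For each miRNA *j*, a covariate-adjusted
   logistic regression

   logit P(case) = α₀ + α₁·Sex + α₂·Age + α₃·APOE + α₄·xⱼ

   yields a Wald z-value zⱼ = α̂₄ / SE(α̂₄); miRNAs with |z| ≥ T are
   pre-selected.
3. **Supervised PCA.** PCA on the pre-selected miRNAs, then a logistic
   model on the top *m* PC scores (no intercept):

   logit P(case) = β₁·PC₁ + … + β_m·PC_m,  PCᵢ = Σⱼ lⱼᵢ (xⱼ − x̄ⱼ)

4. **Hyperparameter search.** (T, m) is chosen by 10-fold stratified
   cross-validation on the discovery cohort, maximizing mean held-out
   AUC over the default grid T ∈ {0.1, …, 5.0} × m ∈ {1, …, 10}
   (500 cells). Screening happens inside each fold — never on the full
   cohort.
5. **Scoring.** The prognostic index PI = Σ βᵢ·PCᵢ is a fixed linear
   score; the cutoff maximizing mean(sensitivity, specificity) on the
   discovery ROC curve classifies new samples (PI > cutoff ⇒ predicted
   case), including prospective MCI-conversion prediction.

Two baselines (clinical-covariates-only logistic regression, and LASSO
over all miRNAs) are scored on the identical validation split, and a
Mutual-Rank co-expression module builds MR/PCC-filtered networks with
hub detection.

A seeded synthetic-cohort generator (`mirisk.synthetic_data`) emulates
the statistical structure of such a study — planted differential
miRNAs, block-correlated probes, age/sex/APOE-ε4 covariate contrast,
raw-signal layers — so the entire pipeline is testable offline.

## Worked example

```python
from mirisk import pipeline as pl, synthetic_data as sd

config = pl.StudyConfig(
    simulation=sd.SimulationConfig(
        n_cases=300, n_controls=150, n_mirnas=300, n_informative=10,
        effect_size=1.2, seed=7,
    ),
    disease="AD",
    t_grid=[1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0],
    m_grid=[1, 2, 3, 4, 5],
    seed=7,
    with_baselines=True,
    prospective_n_converters=10,
    prospective_n_nonconverters=22,
)
report = pl.run_study(config)
```

prints (via the report fields):

```
(T*, m*) = (3.5, 5)
selected miRNAs: 10
CV mean AUC: 0.979
validation AUC: 0.992
PI cutoff: -1.070
accuracy 0.956  sensitivity 0.940  specificity 0.987
clinical baseline AUC: 0.798
LASSO baseline AUC: 0.991
prospective 2x2: tp=9 fp=14 fn=1 tn=8
truth recovered: 10/10
```

Reading: the cross-validated optimum kept 10 miRNAs at |z| ≥ 3.5 and
used 5 PC scores; the CV estimate (0.979) closely tracks the AUC on the
untouched validation half (0.992); all 10 planted miRNAs were
recovered. The covariates alone reach only 0.798. In the simulated
32-subject prospective MCI cohort, 9 of 10 converters exceeded the PI
cutoff.

The same workflow is available from the shell:

```bash
mirisk simulate --config sim.yaml --out-dir cohort --raw
mirisk normalize --raw cohort/raw_signals.tsv --probes cohort/probes.tsv --out expr.tsv
mirisk cv-grid --expr expr.tsv --meta cohort/metadata.tsv --out grid.tsv
mirisk fit-final --expr expr.tsv --meta cohort/metadata.tsv --t 3.5 --m 5 --out model.json
mirisk predict --model model.json --expr new_samples.tsv --out pi.tsv
```

## Layout

| module | contents |
| --- | --- |
| `mirisk.synthetic_data` | seeded cohort / raw-array / prospective generators |
| `mirisk.normalization` | background stats, log transform, imputation, internal-control standardization |
| `mirisk.association` | per-miRNA adjusted logistic Wald z, selection |
| `mirisk.spca_model` | PCA, PC-score logistic fit, prognostic index, model (de)serialization |
| `mirisk.model_selection` | stratified folds, (T, m) grid search, final fit |
| `mirisk.evaluation` | ROC/AUC, optimal cutoff, confusion metrics, prospective validation |
| `mirisk.coexpression` | Mutual Rank, edge filtering, hub detection |
| `mirisk.pipeline` | study orchestration, baselines, set-overlap arithmetic |

See `docs/methods.md` for modeling assumptions, parameter defaults and
known limitations.
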