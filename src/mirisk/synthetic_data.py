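"""Seeded synthetic cohorts emulating a serum-miRNA case/control study.

The generator produces, on the normalized log2 scale, a samples x miRNAs
expression matrix with

* a small planted subset of *informative* miRNAs whose case means are
  shifted by a configurable standardized effect size,
* block-correlated noise (consecutive miRNAs share a latent factor),
* clinical covariates — age (older in cases), sex, and APOE epsilon-4
  allele count (enriched in cases) — whose case/control contrast is
  scaled by ``covariate_effect``,
* a stratified discovery/validation split.

Raw-array layers (background probes, three internal controls, undetected
entries) are derived from the normalized matrix by inverting the
normalization transform, so normalization round-trip tests are exact by
construction.  A prospective cohort of MCI-like converters and
non-converters can be drawn from the same generating distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import normalization
from .normalization import DEFAULT_INTERNAL_CONTROLS, RawArraySet

__all__ = [
    "CovariateModel",
    "SimulationConfig",
    "SyntheticCohort",
    "generate_cohort",
    "generate_raw_arrays",
    "generate_prospective_cohort",
]


@dataclass(frozen=True)
class CovariateModel:
    """Per-group covariate distributions (defaults resemble an elderly
    AD-vs-control cohort: cases ~7.5 years older, fewer males, mean APOE
    epsilon-4 count 0.5 vs 0.2)."""

    age_mean_case: float = 79.2
    age_mean_control: float = 71.7
    age_sd: float = 6.0
    sex_male_case: float = 0.30
    sex_male_control: float = 0.52
    apoe_probs_case: tuple[float, float, float] = (0.55, 0.40, 0.05)
    apoe_probs_control: tuple[float, float, float] = (0.82, 0.16, 0.02)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic cohort.

    ``effect_size`` is the standardized (per-SD, log2-scale) mean shift
    added to cases for each informative miRNA.  ``covariate_effect``
    scales the case/control contrast of the covariate model: 0 makes the
    covariate distributions identical between groups, 1 uses the model
    as given.
    """

    n_cases: int
    n_controls: int
    n_mirnas: int = 2562
    n_informative: int = 10
    effect_size: float = 1.0
    block_size: int = 20
    block_rho: float = 0.3
    covariate_model: CovariateModel = field(default_factory=CovariateModel)
    covariate_effect: float = 1.0
    disease: str = "AD"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cases", "n_controls", "n_mirnas", "block_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.n_informative < 0:
            raise ValueError(f"n_informative must be >= 0, got {self.n_informative}")
        if self.n_informative > self.n_mirnas:
            raise ValueError(
                f"n_informative ({self.n_informative}) exceeds n_mirnas "
                f"({self.n_mirnas})"
            )
        if not 0 <= self.block_rho < 1:
            raise ValueError(f"block_rho must lie in [0, 1), got {self.block_rho}")


@dataclass(frozen=True)
class _GeneratorParams:
    """Frozen per-miRNA generating parameters, kept so raw-array and
    prospective layers stay coherent with the parent cohort."""

    mu: np.ndarray  # per-miRNA baseline log2 mean
    sigma: np.ndarray  # per-miRNA log2 SD
    block_of: np.ndarray  # block index per miRNA
    informative_idx: np.ndarray  # positions of planted miRNAs


@dataclass
class SyntheticCohort:
    """A generated cohort: expression, metadata, and planted truth."""

    expression: pd.DataFrame  # samples x miRNAs, normalized log2 scale
    metadata: pd.DataFrame  # sample_id index: phenotype, sex, age, apoe, split
    truth: dict[str, float]  # informative miRNA id -> standardized effect
    config: SimulationConfig
    params: _GeneratorParams

    def __post_init__(self) -> None:
        unknown = set(self.truth) - set(self.expression.columns)
        if unknown:
            raise ValueError(f"truth ids absent from expression: {sorted(unknown)}")

    @property
    def labels(self) -> pd.Series:
        """Binary case indicator (1 = case, 0 = control)."""
        return (self.metadata["phenotype"] != "NC").astype(int)

    @property
    def split_labels(self) -> pd.Series:
        return self.metadata["split"]

    @property
    def covariates(self) -> pd.DataFrame:
        return self.metadata[["sex", "age", "apoe"]]

    def subset(self, split: str) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
        """(expression, labels, covariates) restricted to one split."""
        keep = self.metadata.index[self.metadata["split"] == split]
        return (
            self.expression.loc[keep],
            self.labels.loc[keep],
            self.covariates.loc[keep],
        )


def _mirna_ids(n: int) -> list[str]:
    return [f"MIMAT{i + 1:07d}" for i in range(n)]


def _interp_probs(control: np.ndarray, case: np.ndarray, w: float) -> np.ndarray:
    p = control + w * (case - control)
    p = np.clip(p, 0.0, None)
    return p / p.sum()


def _draw_covariates(
    rng: np.random.Generator, n: int, model: CovariateModel, w: float, case: bool
) -> pd.DataFrame:
    """Group-conditional covariate draw; ``w`` interpolates the case
    parameters toward the control ones (w=0: identical groups)."""
    if case:
        age_mean = model.age_mean_control + w * (
            model.age_mean_case - model.age_mean_control
        )
        sex_p = model.sex_male_control + w * (
            model.sex_male_case - model.sex_male_control
        )
        apoe_p = _interp_probs(
            np.asarray(model.apoe_probs_control),
            np.asarray(model.apoe_probs_case),
            w,
        )
    else:
        age_mean = model.age_mean_control
        sex_p = model.sex_male_control
        apoe_p = np.asarray(model.apoe_probs_control, dtype=float)
        apoe_p = apoe_p / apoe_p.sum()
    age = np.maximum(rng.normal(age_mean, model.age_sd, n), 60.5)
    sex = rng.binomial(1, min(max(sex_p, 0.0), 1.0), n)
    apoe = rng.choice(3, size=n, p=apoe_p)
    return pd.DataFrame({"sex": sex, "age": np.round(age, 1), "apoe": apoe})


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a seeded case/control cohort on the normalized scale.

    Informative miRNAs receive a case-group mean shift of
    ``effect_size * sigma_j``; all miRNAs carry block-correlated unit
    noise with within-block correlation ``block_rho``.  The
    discovery/validation split is a stratified random half within each
    phenotype group.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_cases + config.n_controls
    p = config.n_mirnas

    mu = rng.normal(8.0, 1.5, p)
    sigma = rng.uniform(0.5, 1.2, p)
    block_of = np.arange(p) // config.block_size
    n_blocks = int(block_of.max()) + 1
    informative_idx = np.sort(rng.choice(p, size=config.n_informative, replace=False))

    is_case = np.zeros(n, dtype=bool)
    is_case[: config.n_cases] = True

    factors = rng.standard_normal((n, n_blocks))
    eps = rng.standard_normal((n, p))
    z = (
        np.sqrt(config.block_rho) * factors[:, block_of]
        + np.sqrt(1.0 - config.block_rho) * eps
    )
    z[np.ix_(is_case, informative_idx)] += config.effect_size
    values = mu + sigma * z

    ids = _mirna_ids(p)
    sample_ids = [f"S{i + 1:05d}" for i in range(n)]
    expression = pd.DataFrame(values, index=sample_ids, columns=ids)

    w = config.covariate_effect
    cov_case = _draw_covariates(rng, config.n_cases, config.covariate_model, w, True)
    cov_ctrl = _draw_covariates(
        rng, config.n_controls, config.covariate_model, w, False
    )
    covariates = pd.concat([cov_case, cov_ctrl], ignore_index=True)
    covariates.index = pd.Index(sample_ids)

    phenotype = np.where(is_case, config.disease, "NC")
    split = np.empty(n, dtype=object)
    for group_mask in (is_case, ~is_case):
        idx = np.flatnonzero(group_mask)
        perm = rng.permutation(idx)
        half = (len(idx) + 1) // 2
        split[perm[:half]] = "discovery"
        split[perm[half:]] = "validation"

    metadata = covariates.assign(phenotype=phenotype, split=split)[
        ["phenotype", "sex", "age", "apoe", "split"]
    ]
    truth = {
        ids[j]: float(config.effect_size * 1.0) for j in informative_idx
    }
    params = _GeneratorParams(
        mu=mu, sigma=sigma, block_of=block_of, informative_idx=informative_idx
    )
    return SyntheticCohort(
        expression=expression,
        metadata=metadata,
        truth=truth,
        config=config,
        params=params,
    )


def generate_raw_arrays(
    cohort: SyntheticCohort,
    background_level: float = 50.0,
    background_sd: float = 1.0,
    n_negative_controls: int = 50,
    undetected_rate: float = 0.0,
    signal_noise_sd: float = 0.0,
    array_shift_sd: float = 0.3,
    internal_control_ids: Sequence[str] = DEFAULT_INTERNAL_CONTROLS,
    seed: int = 0,
) -> RawArraySet:
    """Derive linear-scale raw arrays whose normalization reproduces the
    cohort's expression (exactly when ``signal_noise_sd`` is 0 and no
    entry is undetected).

    Per array the generator draws negative-control signals around
    ``background_level``, a per-array log2 shift (mean-centered across
    arrays, emulating labeling/scanning intensity drift) that the
    internal-control standardization must remove, and sets each raw
    signal to ``trimmed_mean + 2**(value + shift + noise)``.  Three
    internal-control probes with array-independent target values are
    appended; internal controls are never flagged undetected.
    """
    if n_negative_controls < 20:
        raise ValueError(
            "n_negative_controls must be >= 20 so that 5% trimming removes at "
            f"least one value per tail, got {n_negative_controls}"
        )
    ic_ids = tuple(internal_control_ids)
    if len(ic_ids) != 3:
        raise ValueError(f"exactly 3 internal-control probes required, got {len(ic_ids)}")
    if not 0 <= undetected_rate <= 1:
        raise ValueError(f"undetected_rate must lie in [0, 1], got {undetected_rate}")

    rng = np.random.default_rng(seed)
    expr = cohort.expression
    n, p = expr.shape

    # per-array multiplicative drift, exactly mean-centered in log2 space so
    # the internal-control anchor (across-array mean) restores the original
    shift = rng.normal(0.0, array_shift_sd, n)
    shift -= shift.mean()

    ic_targets = np.array([10.0, 10.5, 11.0])
    log_values = np.concatenate(
        [expr.to_numpy() + shift[:, None], ic_targets[None, :] + shift[:, None]],
        axis=1,
    )
    if signal_noise_sd > 0:
        log_values = log_values + rng.normal(0.0, signal_noise_sd, log_values.shape)

    negatives = rng.normal(background_level, background_sd, (n, n_negative_controls))
    negatives = np.maximum(negatives, 0.01)
    trimmed_means = np.array(
        [normalization.background_stats(row).mean for row in negatives]
    )

    signals = trimmed_means[:, None] + np.exp2(log_values)
    if undetected_rate > 0:
        mask = rng.random((n, p)) < undetected_rate
        signals[:, :p][mask] = np.nan

    columns = list(expr.columns) + list(ic_ids)
    signals_df = pd.DataFrame(signals, index=expr.index, columns=columns)
    negatives_df = pd.DataFrame(
        negatives,
        index=expr.index,
        columns=[f"NC_PROBE{i + 1:03d}" for i in range(n_negative_controls)],
    )
    return RawArraySet(
        signals=signals_df,
        negative_controls=negatives_df,
        internal_control_ids=ic_ids,
    )


def generate_prospective_cohort(
    cohort: SyntheticCohort,
    n_converters: int,
    n_nonconverters: int,
    separation: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Draw an MCI-like prospective cohort from the parent distribution.

    Converters are drawn from the case distribution with the planted
    effects multiplied by ``separation``; non-converters sit halfway
    between the case and control distributions (effects multiplied by
    ``separation / 2``).  With ``separation=0`` the two groups are
    identically distributed.

    Returns
    -------
    expression, conversion
        expression matrix over the parent cohort's miRNAs and a binary
        conversion indicator (1 = converted).
    """
    if n_converters < 0 or n_nonconverters < 0:
        raise ValueError("subject counts must be >= 0")
    rng = np.random.default_rng(seed)
    cfg = cohort.config
    params = cohort.params
    p = cfg.n_mirnas
    n = n_converters + n_nonconverters
    n_blocks = int(params.block_of.max()) + 1

    factors = rng.standard_normal((n, n_blocks))
    eps = rng.standard_normal((n, p))
    z = (
        np.sqrt(cfg.block_rho) * factors[:, params.block_of]
        + np.sqrt(1.0 - cfg.block_rho) * eps
    )
    effect = np.zeros(p)
    effect[params.informative_idx] = cfg.effect_size
    multiplier = np.concatenate(
        [
            np.full(n_converters, separation),
            np.full(n_nonconverters, separation / 2.0),
        ]
    )
    z += multiplier[:, None] * effect[None, :]
    values = params.mu + params.sigma * z

    sample_ids = [f"MCI{i + 1:04d}" for i in range(n)]
    expression = pd.DataFrame(
        values, index=sample_ids, columns=cohort.expression.columns
    )
    conversion = pd.Series(
        np.concatenate([np.ones(n_converters, int), np.zeros(n_nonconverters, int)]),
        index=sample_ids,
        name="conversion",
    )
    return expression, conversion
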