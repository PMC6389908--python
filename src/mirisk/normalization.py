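"""Microarray signal normalization with negative- and internal-control probes.

The procedure mirrors standard practice for 3D-Gene style miRNA oligo
chips.  Per array:

* a trimmed mean/SD of the negative-control (background) signals defines
  a detection threshold ``mean + 2*SD``;
* signals above the threshold become ``log2(signal - mean)`` and are
  flagged *effective*;
* remaining detected signals are floored at the array's minimum
  effective value minus 0.1 (log2 scale);
* undetected entries are imputed with the per-miRNA mean across arrays;
* finally every array is shifted so the mean of its three
  internal-control probes is constant across arrays (division by the
  internal-control ratio, performed as subtraction in log2 space).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EFFECTIVE",
    "FLOOR",
    "IMPUTED",
    "DEFAULT_INTERNAL_CONTROLS",
    "BackgroundStats",
    "RawArraySet",
    "NormalizedMatrix",
    "background_stats",
    "normalize_array",
    "impute_undetected",
    "standardize_across_arrays",
    "normalize",
]

#: entry provenance codes used in :attr:`NormalizedMatrix.effective_mask`
EFFECTIVE = 0
FLOOR = 1
IMPUTED = 2

#: internal-control miRNAs stably detected across serum arrays
DEFAULT_INTERNAL_CONTROLS = ("hsa-miR-149-3p", "hsa-miR-2861", "hsa-miR-4463")


@dataclass(frozen=True)
class BackgroundStats:
    """Trimmed background statistics of one array's negative controls."""

    mean: float
    sd: float
    threshold: float  # mean + 2 * sd

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("background SD must be non-negative")


@dataclass
class RawArraySet:
    """Raw linear-scale probe signals for a set of arrays.

    Parameters
    ----------
    signals
        samples x probes linear-scale intensities; ``NaN`` marks an
        undetected entry.  Columns include the three internal-control
        probes.
    negative_controls
        samples x probes background signals (negative-control probes).
    internal_control_ids
        exactly three probe ids present in ``signals`` columns.
    """

    signals: pd.DataFrame
    negative_controls: pd.DataFrame
    internal_control_ids: tuple[str, str, str] = field(
        default=DEFAULT_INTERNAL_CONTROLS
    )

    def __post_init__(self) -> None:
        self.internal_control_ids = tuple(self.internal_control_ids)  # type: ignore[assignment]
        if len(self.internal_control_ids) != 3:
            raise ValueError(
                "exactly three internal-control probes are required, got "
                f"{len(self.internal_control_ids)}"
            )
        missing = [
            p for p in self.internal_control_ids if p not in self.signals.columns
        ]
        if missing:
            raise ValueError(f"internal controls absent from signals: {missing}")
        if self.negative_controls.shape[1] == 0:
            raise ValueError("negative_controls must contain at least one probe")
        if not self.signals.index.equals(self.negative_controls.index):
            raise ValueError("signals and negative_controls must share sample index")

    @property
    def sample_ids(self) -> pd.Index:
        return self.signals.index

    def undetected(self, sample: str) -> set[str]:
        """Probe ids with no signal on the given array."""
        row = self.signals.loc[sample]
        return set(row.index[row.isna()])


@dataclass
class NormalizedMatrix:
    """Normalized log2 expression with per-entry provenance flags."""

    values: pd.DataFrame
    effective_mask: pd.DataFrame  # int8 codes EFFECTIVE / FLOOR / IMPUTED

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("normalized matrix must not contain missing entries")

    def drop_probes(self, probes: Sequence[str]) -> "NormalizedMatrix":
        keep = [c for c in self.values.columns if c not in set(probes)]
        return NormalizedMatrix(
            self.values[keep].copy(), self.effective_mask[keep].copy()
        )


def background_stats(
    background: Sequence[float] | np.ndarray, trim_fraction: float = 0.05
) -> BackgroundStats:
    """Trimmed mean/SD of background signals and the detection threshold.

    ``ceil(trim_fraction * k)`` values are removed from each tail (so a
    5% trim of 20 values drops exactly one per tail).  The SD uses the
    sample convention (denominator ``k' - 1``); a single retained value
    yields SD 0.  Threshold is ``mean + 2 * SD`` of the retained values.
    """
    values = np.asarray(background, dtype=float)
    if values.size == 0:
        raise ValueError("background signal list is empty")
    if not 0 <= trim_fraction < 0.5:
        raise ValueError("trim_fraction must lie in [0, 0.5)")
    k = values.size
    n_trim = math.ceil(trim_fraction * k)
    retained = np.sort(values)[n_trim : k - n_trim]
    if retained.size == 0:
        raise ValueError(
            f"trimming {n_trim} values per tail removed all {k} background signals"
        )
    mean = float(retained.mean())
    sd = float(retained.std(ddof=1)) if retained.size > 1 else 0.0
    return BackgroundStats(mean=mean, sd=sd, threshold=mean + 2.0 * sd)


def normalize_array(
    signals: pd.Series, stats: BackgroundStats
) -> tuple[pd.Series, pd.Series]:
    """Background-subtract and log-transform one array.

    Detected signals strictly above ``stats.threshold`` become
    ``log2(signal - mean)`` (*effective*); remaining detected signals are
    replaced by the array's minimum effective value minus 0.1 (*floor*).
    Undetected (``NaN``) entries are left missing for
    :func:`impute_undetected`.

    Returns
    -------
    values, flags
        log2 values (``NaN`` where undetected) and int8 flags
        (:data:`EFFECTIVE` / :data:`FLOOR`; undetected entries carry
        :data:`IMPUTED` as a placeholder for the later imputation).
    """
    raw = signals.to_numpy(dtype=float)
    detected = ~np.isnan(raw)
    effective = detected & (raw > stats.threshold)
    if not effective.any():
        raise ValueError(
            "array has no effective signals above the background threshold "
            f"({stats.threshold:.4g}); floor value undefined"
        )
    values = np.full(raw.shape, np.nan)
    values[effective] = np.log2(raw[effective] - stats.mean)
    floor_value = values[effective].min() - 0.1
    floored = detected & ~effective
    values[floored] = floor_value

    flags = np.full(raw.shape, IMPUTED, dtype=np.int8)
    flags[effective] = EFFECTIVE
    flags[floored] = FLOOR
    return (
        pd.Series(values, index=signals.index),
        pd.Series(flags, index=signals.index),
    )


def impute_undetected(matrix: pd.DataFrame) -> pd.DataFrame:
    """Replace missing entries by the per-miRNA mean of detected values."""
    missing_all = matrix.columns[matrix.isna().all(axis=0)]
    if len(missing_all) > 0:
        raise ValueError(
            "miRNA(s) undetected in every sample, cannot impute: "
            + ", ".join(map(str, missing_all))
        )
    return matrix.fillna(matrix.mean(axis=0))


def standardize_across_arrays(
    matrix: pd.DataFrame, internal_control_ids: Sequence[str]
) -> pd.DataFrame:
    """Remove per-array shifts using the internal-control probes.

    Each array is divided (in linear space; subtracted in log2 space) by
    the ratio of its internal-control mean to the across-array average of
    those means.  Afterwards every array has the same internal-control
    mean, and applying the operation twice equals applying it once.
    """
    ids = list(internal_control_ids)
    for probe in ids:
        if probe not in matrix.columns:
            raise ValueError(f"internal control {probe!r} absent from the matrix")
        col = matrix[probe]
        if col.isna().any():
            sample = col.index[col.isna()][0]
            raise ValueError(
                f"internal control {probe!r} missing in sample {sample!r}"
            )
    control_mean = matrix[ids].mean(axis=1)
    offset = control_mean - control_mean.mean()
    return matrix.sub(offset, axis=0)


def normalize(raw: RawArraySet, trim_fraction: float = 0.05) -> NormalizedMatrix:
    """Full normalization of a raw array set.

    Applies, in order: per-array background statistics from that array's
    negative controls, effective-signal log transform with floor
    replacement, per-miRNA imputation of undetected entries, and
    internal-control standardization across arrays.
    """
    values: dict[str, pd.Series] = {}
    flags: dict[str, pd.Series] = {}
    for sample in raw.sample_ids:
        stats = background_stats(
            raw.negative_controls.loc[sample].to_numpy(), trim_fraction
        )
        values[sample], flags[sample] = normalize_array(raw.signals.loc[sample], stats)
    matrix = pd.DataFrame(values).T.loc[raw.sample_ids, raw.signals.columns]
    mask = (
        pd.DataFrame(flags).T.loc[raw.sample_ids, raw.signals.columns].astype(np.int8)
    )
    matrix = impute_undetected(matrix)
    matrix = standardize_across_arrays(matrix, raw.internal_control_ids)
    return NormalizedMatrix(values=matrix, effective_mask=mask)
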