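"""Tab-separated and JSON readers/writers for the pipeline's artifacts.

Conventions: expression matrices are TSV with samples as rows (first
column ``sample_id``) and miRNA ids as columns; metadata TSV carries
``sample_id, phenotype, sex, age, apoe, split``; raw arrays are a signal
TSV (empty cell = undetected) plus a probe-annotation TSV with columns
``probe_id, role`` where role is one of ``mirna``, ``negative_control``,
``internal_control``.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .normalization import NormalizedMatrix, RawArraySet

__all__ = [
    "read_expression",
    "write_expression",
    "read_metadata",
    "write_metadata",
    "read_raw_arrays",
    "write_raw_arrays",
    "write_association",
    "write_grid",
    "write_edges",
    "write_truth",
]

_METADATA_COLUMNS = ["phenotype", "sex", "age", "apoe", "split"]


def read_expression(path: str | Path) -> pd.DataFrame:
    # round_trip parsing + %.17g writing makes write -> read lossless
    return pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")


def write_expression(matrix: pd.DataFrame, path: str | Path) -> None:
    # %.17g round-trips float64 exactly, so write -> read is lossless
    matrix.to_csv(path, sep="\t", index_label="sample_id", float_format="%.17g")


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col=0)
    missing = [c for c in _METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata lacks column(s): {missing}")
    return meta


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    metadata[_METADATA_COLUMNS].to_csv(path, sep="\t", index_label="sample_id")


def write_raw_arrays(
    raw: RawArraySet, signals_path: str | Path, probes_path: str | Path
) -> None:
    combined = pd.concat([raw.signals, raw.negative_controls], axis=1)
    combined.to_csv(signals_path, sep="\t", index_label="sample_id")
    ic = set(raw.internal_control_ids)
    roles = [
        "internal_control" if p in ic else "mirna" for p in raw.signals.columns
    ] + ["negative_control"] * raw.negative_controls.shape[1]
    pd.DataFrame(
        {"probe_id": list(combined.columns), "role": roles}
    ).to_csv(probes_path, sep="\t", index=False)


def read_raw_arrays(signals_path: str | Path, probes_path: str | Path) -> RawArraySet:
    combined = pd.read_csv(signals_path, sep="\t", index_col=0)
    probes = pd.read_csv(probes_path, sep="\t")
    if not {"probe_id", "role"} <= set(probes.columns):
        raise ValueError("probe annotation needs columns probe_id and role")
    roles = probes.set_index("probe_id")["role"]
    unknown = set(roles.unique()) - {"mirna", "negative_control", "internal_control"}
    if unknown:
        raise ValueError(f"unknown probe role(s): {sorted(unknown)}")
    neg = roles.index[roles == "negative_control"]
    ic = tuple(roles.index[roles == "internal_control"])
    signal_cols = [c for c in combined.columns if c not in set(neg)]
    return RawArraySet(
        signals=combined[signal_cols],
        negative_controls=combined[list(neg)],
        internal_control_ids=ic,
    )


def write_normalized(matrix: NormalizedMatrix, path: str | Path) -> None:
    write_expression(matrix.values, path)


def write_association(result: pd.DataFrame, path: str | Path) -> None:
    result.to_csv(path, sep="\t", index_label="mirna_id")


def write_grid(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_edges(edges: pd.DataFrame, path: str | Path) -> None:
    edges.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_truth(truth: dict[str, float], path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth, indent=1, sort_keys=True))


def read_truth(path: str | Path) -> dict[str, float]:
    return json.loads(Path(path).read_text())
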