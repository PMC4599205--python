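"""Reading and writing of the pipeline's on-disk artifacts.

TSV is the canonical format (CSV accepted on read): count matrices have a
header of sample IDs and a first column of gene IDs; designs are
(sample_id, group) tables; truth labels are (gene_id, label,
zeroed_condition); normalized matrices carry a sidecar JSON with scale,
factors, library sizes and transform parameters.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import CountMatrix, NormalizedMatrix
from .simdata import SimulatedDataset, SimulationConfig

__all__ = [
    "read_count_matrix",
    "write_count_matrix",
    "read_design",
    "write_design",
    "write_truth",
    "read_truth",
    "write_normalized",
    "write_results",
    "read_config",
]


def _read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="," if str(path).endswith(".csv") else "\t", index_col=0)


def read_count_matrix(path, design: pd.Series | None = None) -> CountMatrix:
    """Read a gene x sample count TSV/CSV; validates integer, non-negative counts."""
    df = _read_table(path)
    if df.index.has_duplicates:
        raise ValueError(f"{path}: duplicate gene IDs")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise ValueError(f"{path}: non-numeric counts")
    if np.any(arr < 0):
        raise ValueError(f"{path}: negative counts")
    if not np.allclose(arr, np.round(arr)):
        raise ValueError(f"{path}: counts must be integers")
    df = df.astype(np.int64)
    if design is None:
        # fall back to a two-group design from sample-name prefixes (A*/B*)
        groups = [str(c)[0] for c in df.columns]
        design = pd.Series(groups, index=df.columns)
    return CountMatrix(df, design)


def write_count_matrix(data: CountMatrix, path) -> None:
    df = data.counts.copy()
    df.index.name = df.index.name or "gene_id"
    df.to_csv(path, sep="\t")


def read_design(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: design needs (sample_id, group) columns")
    return pd.Series(df.iloc[:, 1].to_numpy(), index=pd.Index(df.iloc[:, 0], name="sample_id"))


def write_design(design: pd.Series, path) -> None:
    pd.DataFrame({"sample_id": design.index, "group": design.to_numpy()}).to_csv(
        path, sep="\t", index=False
    )


def write_truth(ds: SimulatedDataset, path) -> None:
    pd.DataFrame(
        {
            "gene_id": ds.truth.index,
            "label": np.where(ds.truth, "true", "false"),
            "zeroed_condition": ds.zeroed_condition.fillna("").to_numpy(),
        }
    ).to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    # pandas parses literal true/false cells as booleans; accept either form
    return df["label"].map(
        lambda v: v if isinstance(v, (bool, np.bool_)) else str(v).lower() == "true"
    )


def write_normalized(matrix: NormalizedMatrix, path) -> None:
    """Write values as TSV plus a sidecar <path>.json with provenance."""
    path = Path(path)
    df = matrix.values.copy()
    df.index.name = df.index.name or "gene_id"
    df.to_csv(path, sep="\t")
    sidecar = {
        "scale": matrix.scale,
        "factors": [float(f) for f in matrix.factors],
        "libsizes": [int(l) for l in matrix.libsizes],
        "params": {k: float(v) for k, v in matrix.params.items()},
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def write_results(results: pd.DataFrame, path) -> None:
    df = results.copy()
    df.index.name = df.index.name or "gene_id"
    df.to_csv(path, sep="\t")


def read_config(path) -> SimulationConfig:
    """Load a SimulationConfig from YAML or JSON (unknown keys rejected)."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    for key in ("n_per_group", "phi_filter", "libsize_range"):
        if key in data:
            data[key] = tuple(data[key])
    return SimulationConfig(**data)
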