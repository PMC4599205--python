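"""Core in-memory containers shared across the pipeline.

A count matrix is a genes x samples table of non-negative integers together
with a two-group design (a mapping from sample ID to group label). All
downstream stages — normalization, signal-to-noise, differential-expression
testing and evaluation — operate on these two objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CountMatrix", "NormalizedMatrix", "two_group_masks"]


@dataclass
class CountMatrix:
    """Integer gene x sample count table with a two-group design.

    Parameters
    ----------
    counts
        DataFrame indexed by gene ID with one column per sample.
    design
        Series mapping sample ID -> group label, in the column order of
        ``counts``. Exactly two distinct groups are required by most
        operations.
    """

    counts: pd.DataFrame
    design: pd.Series

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate gene IDs in count matrix")
        if not self.counts.columns.equals(self.design.index):
            self.design = self.design.reindex(self.counts.columns)
            if self.design.isna().any():
                raise ValueError("design does not cover all samples")
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("negative counts are not allowed")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def groups(self) -> list:
        """Group labels in order of first appearance in the design."""
        return list(dict.fromkeys(self.design))

    @property
    def libsizes(self) -> np.ndarray:
        """Per-sample total counts (column sums)."""
        return self.counts.to_numpy().sum(axis=0)

    def values(self) -> np.ndarray:
        return self.counts.to_numpy(dtype=float)


def two_group_masks(design: pd.Series) -> tuple[np.ndarray, np.ndarray, list]:
    """Boolean column masks for the two groups of a design.

    Returns (mask_a, mask_b, [group_a, group_b]); raises if the design does
    not have exactly two groups.
    """
    groups = list(dict.fromkeys(design))
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, got {groups}")
    g = design.to_numpy()
    return g == groups[0], g == groups[1], groups


@dataclass
class NormalizedMatrix:
    """Real-valued gene x sample matrix on a named scale.

    ``scale`` is one of ``linear-cpm``, ``log-cpm`` or ``vst``; ``factors``
    are the TMM normalization factors and ``libsizes`` the raw library sizes
    the values were computed from. ``params`` records transform parameters
    (log offset, glog calibration constant) for provenance.
    """

    values: pd.DataFrame
    scale: str
    factors: np.ndarray
    libsizes: np.ndarray
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scale not in {"linear-cpm", "log-cpm", "vst"}:
            raise ValueError(f"unknown scale {self.scale!r}")
        self.factors = np.asarray(self.factors, dtype=float)
        self.libsizes = np.asarray(self.libsizes)
        if not np.all(np.isfinite(self.factors)) or np.any(self.factors <= 0):
            raise ValueError("normalization factors must be finite and positive")
        if self.scale == "linear-cpm" and (self.values.to_numpy() < 0).any():
            raise ValueError("linear-cpm values must be non-negative")
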