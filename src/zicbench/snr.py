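"""Signal-to-noise (S/N) statistics for genes expressed in only one condition.

The empirical S/N of a gene is mean/sd over the replicates of the condition
that is not all zero. For NB counts with mean mu and variance mu*(1+mu*phi)
the theoretical S/N is 1/sqrt(1/mu + phi), which tends to phi**-0.5 for
large mu — so on the linear scale S/N mostly measures (inverse square-root)
dispersion rather than evidence for differential expression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CountMatrix, NormalizedMatrix, two_group_masks
from .simdata import JointParamPool, NBParams

__all__ = [
    "SnrRecord",
    "empirical_snr",
    "snr_table",
    "theoretical_snr",
    "snr_dispersion_curve",
]


@dataclass(frozen=True)
class SnrRecord:
    gene_id: str
    snr: float  # math.inf sentinel when sd == 0 and mean != 0
    scale: str
    n_used: int
    condition_used: str


def empirical_snr(values) -> float:
    """mean / sample-sd (ddof=1) of a replicate vector.

    Zero variance with non-zero mean returns the +infinity sentinel (a
    maximally consistent signal); the all-constant-zero case returns 0.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("empirical S/N needs at least 2 replicates")
    m = float(np.mean(v))
    s = float(np.std(v, ddof=1))
    if s == 0.0:
        return 0.0 if m == 0.0 else math.inf
    return m / s


def snr_table(
    matrix: NormalizedMatrix, design: pd.Series, raw_counts: CountMatrix
) -> pd.DataFrame:
    """S/N for every gene whose raw counts are all zero in exactly one condition.

    The statistic is computed on ``matrix`` values (whatever its scale) over
    the replicates of the non-zero condition; genes expressed in both
    conditions, or in neither, are excluded. Returns a DataFrame indexed by
    gene_id with columns (snr, scale, n_used, condition_used).
    """
    vals = matrix.values.to_numpy()
    counts = raw_counts.counts.reindex(matrix.values.index).to_numpy()
    mask_a, mask_b, groups = two_group_masks(design)
    zero_a = counts[:, mask_a].sum(axis=1) == 0
    zero_b = counts[:, mask_b].sum(axis=1) == 0
    zic = zero_a ^ zero_b

    rows = []
    for i in np.flatnonzero(zic):
        mask, cond = (mask_b, groups[1]) if zero_a[i] else (mask_a, groups[0])
        v = vals[i, mask]
        rows.append(
            {
                "gene_id": matrix.values.index[i],
                "snr": empirical_snr(v) if v.size >= 2 else math.nan,
                "scale": matrix.scale,
                "n_used": int(v.size),
                "condition_used": cond,
            }
        )
    cols = ["snr", "scale", "n_used", "condition_used"]
    if not rows:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows).set_index("gene_id")[cols]


def theoretical_snr(mu: float | NBParams, phi: float | None = None) -> float:
    """Theoretical NB signal-to-noise 1/sqrt(1/mu + phi).

    Accepts either an NBParams or (mu, phi). Strictly increasing in mu,
    strictly decreasing in phi; bounded by sqrt(mu) (Poisson limit) and by
    phi**-0.5 (large-mu limit).
    """
    if isinstance(mu, NBParams):
        mu, phi = mu.mu, mu.phi
    if phi is None:
        raise TypeError("phi required when mu is a scalar")
    if mu <= 0:
        raise ValueError("mu must be positive")
    if phi < 0:
        raise ValueError("phi must be non-negative")
    return 1.0 / math.sqrt(1.0 / mu + phi)


def snr_dispersion_curve(pool: JointParamPool) -> pd.DataFrame:
    """(mu, phi, theoretical S/N) per pool entry, for plotting S/N vs phi**-0.5."""
    snr = 1.0 / np.sqrt(1.0 / pool.mus + pool.phis)
    with np.errstate(divide="ignore"):
        limit = np.where(pool.phis > 0, pool.phis ** -0.5, np.inf)
    return pd.DataFrame(
        {"mu": pool.mus, "phi": pool.phis, "snr": snr, "snr_large_mu_limit": limit}
    )
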