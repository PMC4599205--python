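"""Normalization and variance transforms.

Counts are normalized with trimmed-mean-of-M-values (TMM) scaling factors
and converted to counts-per-million (CPM). Three analysis scales are
provided: linear CPM, log2-CPM, and a generalized-log variance-stabilizing
transform whose calibration constant is fitted from the data's own mean-sd
trend. The choice of scale changes the mean-variance relationship and hence
any statistic, such as signal-to-noise, computed on the values.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .containers import CountMatrix, NormalizedMatrix, two_group_masks

__all__ = ["tmm_factors", "cpm", "log_cpm", "vst", "mean_var_table"]

logger = logging.getLogger(__name__)


def tmm_factors(
    counts: CountMatrix | pd.DataFrame,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> np.ndarray:
    """Trimmed-mean-of-M-values normalization factors, one per sample.

    The reference sample is the one whose upper-quartile CPM is closest to
    the mean upper-quartile. For each sample, M (log2 ratio vs reference)
    and A (average log2 abundance) are computed over genes positive in both
    libraries; genes in the top/bottom ``trim_m`` of M and ``trim_a`` of A
    are discarded, and the factor is 2**(weighted mean of surviving M
    values) with inverse-asymptotic-variance weights. Factors are rescaled
    to geometric mean 1.
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    y = mat.to_numpy(dtype=float)
    lib = y.sum(axis=0)
    if np.any(lib <= 0):
        raise ValueError("every sample must have a positive total count")
    n_samples = y.shape[1]
    if n_samples < 2:
        raise ValueError("TMM requires at least 2 samples")

    uq = np.array([np.quantile(y[:, j] / lib[j], 0.75) for j in range(n_samples)])
    ref = int(np.argmin(np.abs(uq - uq.mean())))

    factors = np.ones(n_samples)
    for j in range(n_samples):
        if j == ref:
            continue
        factors[j] = 2.0 ** _tmm_pair(y[:, j], lib[j], y[:, ref], lib[ref], trim_m, trim_a)
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


def _tmm_pair(
    yj: np.ndarray, nj: float, yr: np.ndarray, nr: float, trim_m: float, trim_a: float
) -> float:
    """Doubly trimmed, precision-weighted mean of M values for one pair."""
    ok = (yj > 0) & (yr > 0)
    yj, yr = yj[ok], yr[ok]
    if yj.size == 0:
        return 0.0
    pj, pr = yj / nj, yr / nr
    m = np.log2(pj / pr)
    a = 0.5 * np.log2(pj * pr)
    # degenerate: M essentially constant, trimming is meaningless
    if np.max(m) - np.min(m) < 1e-10:
        return float(np.mean(m))
    w = 1.0 / ((nj - yj) / (nj * yj) + (nr - yr) / (nr * yr))

    n = m.size
    idx = np.arange(n)
    lo_m, hi_m = int(np.floor(n * trim_m)) + 1, n - int(np.floor(n * trim_m))
    lo_a, hi_a = int(np.floor(n * trim_a)) + 1, n - int(np.floor(n * trim_a))
    # rank with stable tie-break on (value, gene index)
    rank_m = np.empty(n, dtype=int)
    rank_m[np.lexsort((idx, m))] = np.arange(1, n + 1)
    rank_a = np.empty(n, dtype=int)
    rank_a[np.lexsort((idx, a))] = np.arange(1, n + 1)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 0.0
    return float(np.sum(w[keep] * m[keep]) / np.sum(w[keep]))


def cpm(
    counts: CountMatrix,
    factors: np.ndarray | None = None,
    prior: float = 0.0,
) -> NormalizedMatrix:
    """Counts-per-million on effective library sizes (libsize x TMM factor).

    value(g, j) = (count(g, j) + prior) / (libsize_j * factor_j) * 1e6.
    Default ``prior`` is 0, so all-zero genes map to exactly 0.
    """
    if factors is None:
        factors = tmm_factors(counts)
    factors = np.asarray(factors, dtype=float)
    if np.any(factors <= 0):
        raise ValueError("factors must be positive")
    lib = counts.libsizes.astype(float)
    vals = (counts.values() + prior) / (lib * factors)[None, :] * 1e6
    return NormalizedMatrix(
        pd.DataFrame(vals, index=counts.gene_ids, columns=counts.sample_ids),
        scale="linear-cpm",
        factors=factors,
        libsizes=counts.libsizes,
        params={"prior": prior},
    )


def log_cpm(cpm_matrix: NormalizedMatrix, offset: float = 0.5) -> NormalizedMatrix:
    """log2(CPM + offset); strictly monotone in CPM so rankings survive."""
    if cpm_matrix.scale != "linear-cpm":
        raise ValueError("log_cpm expects a linear-cpm matrix")
    if offset <= 0:
        raise ValueError("offset must be positive")
    vals = np.log2(cpm_matrix.values.to_numpy() + offset)
    return NormalizedMatrix(
        pd.DataFrame(vals, index=cpm_matrix.values.index, columns=cpm_matrix.values.columns),
        scale="log-cpm",
        factors=cpm_matrix.factors,
        libsizes=cpm_matrix.libsizes,
        params={**cpm_matrix.params, "offset": offset},
    )


def glog2(x, c: float):
    """Generalized log: log2((x + sqrt(x^2 + c^2)) / 2); glog2(x; 0) = log2(x)."""
    x = np.asarray(x, dtype=float)
    return np.log2((x + np.sqrt(x * x + c * c)) / 2.0)


def _fit_glog_c(mean: np.ndarray, sd: np.ndarray) -> float:
    """Calibrate c from the sd ~ sqrt(a + b*mean^2) trend.

    The fit is robust nonlinear regression of log(sd) on
    0.5*log(a + b*mean^2) (soft-L1 loss): working on the log scale gives
    genes across the whole expression range comparable influence, so the
    intercept a is pinned by the low-expression plateau and the slope b by
    the high-expression proportional regime. Positivity of (a, b) is
    enforced by an exponential parameterization; a degenerate fit falls
    back to c = 1.
    """
    keep = np.isfinite(mean) & np.isfinite(sd) & (mean > 0) & (sd > 0)
    if keep.sum() < 10:
        return 1.0
    m2 = mean[keep] ** 2
    logsd = np.log(sd[keep])

    def resid(theta):
        a, b = np.exp(theta)
        return 0.5 * np.log(a + b * m2) - logsd

    b0 = np.median(sd[keep] / mean[keep]) ** 2
    a0 = max(np.quantile(sd[keep], 0.1) ** 2, 1e-6)
    try:
        fit = least_squares(resid, x0=np.log([a0, max(b0, 1e-8)]), loss="soft_l1")
        a, b = np.exp(fit.x)
    except Exception:  # pragma: no cover - optimizer failure
        return 1.0
    if not (np.isfinite(a) and np.isfinite(b)) or a <= 0 or b <= 0:
        logger.warning("glog calibration degenerate (a=%.3g, b=%.3g); using c=1", a, b)
        return 1.0
    return float(np.sqrt(a / b))


def vst(counts: CountMatrix, factors: np.ndarray | None = None) -> NormalizedMatrix:
    """Variance-stabilized scale: generalized-log of CPM with fitted c.

    The constant c is chosen so that the per-gene sd is approximately
    independent of the mean: assuming sd ~ sqrt(a + b*mean^2) on the CPM
    scale (fitted robustly over genes), c = sqrt(a/b) flattens the trend
    under the glog transform. Falls back to c = 1 when the fit degenerates.
    """
    lin = cpm(counts, factors=factors, prior=0.0)
    vals = lin.values.to_numpy()
    mean = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=1)
    c = _fit_glog_c(mean, sd)
    out = glog2(vals, c)
    return NormalizedMatrix(
        pd.DataFrame(out, index=lin.values.index, columns=lin.values.columns),
        scale="vst",
        factors=lin.factors,
        libsizes=lin.libsizes,
        params={"glog_c": c},
    )


def mean_var_table(
    matrix: NormalizedMatrix, design: pd.Series, raw_counts: CountMatrix
) -> pd.DataFrame:
    """Per-gene (mean, sd) within the condition that is not all zero.

    For genes whose raw counts are all zero in exactly one condition the
    statistics are taken over the other condition's replicates; genes
    all-zero in both conditions are excluded; genes expressed in both
    conditions are summarized over all samples (``basis`` column records
    which rule applied).
    """
    vals = matrix.values.to_numpy()
    counts = raw_counts.values()
    mask_a, mask_b, groups = two_group_masks(design)
    zero_a = counts[:, mask_a].sum(axis=1) == 0
    zero_b = counts[:, mask_b].sum(axis=1) == 0

    rows = []
    for i, gid in enumerate(matrix.values.index):
        if zero_a[i] and zero_b[i]:
            continue
        if zero_a[i]:
            v, basis = vals[i, mask_b], f"nonzero:{groups[1]}"
        elif zero_b[i]:
            v, basis = vals[i, mask_a], f"nonzero:{groups[0]}"
        else:
            v, basis = vals[i], "all-samples"
        rows.append(
            {
                "gene_id": gid,
                "mean": float(np.mean(v)),
                "sd": float(np.std(v, ddof=1)) if v.size > 1 else 0.0,
                "n_used": int(v.size),
                "basis": basis,
            }
        )
    return pd.DataFrame(rows).set_index("gene_id") if rows else pd.DataFrame(
        columns=["mean", "sd", "n_used", "basis"]
    )
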