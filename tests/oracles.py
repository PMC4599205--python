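"""Independent straight-line oracles used to cross-check the implementation.

Each function here is written directly from the mathematical definition,
with plain loops and no code shared with the package.
"""

from __future__ import annotations

import math

import numpy as np


def brute_tmm(y: np.ndarray, trim_m: float = 0.30, trim_a: float = 0.05) -> np.ndarray:
    """Trimmed-mean-of-M-values factors computed the long way."""
    y = np.asarray(y, dtype=float)
    n_genes, n_samples = y.shape
    lib = y.sum(axis=0)
    cpm = y / lib[None, :] * 1e6
    uq = np.array([np.quantile(cpm[:, j], 0.75) for j in range(n_samples)])
    ref = int(np.argmin(np.abs(uq - uq.mean())))

    log_factors = []
    for j in range(n_samples):
        if j == ref:
            log_factors.append(0.0)
            continue
        genes = [g for g in range(n_genes) if y[g, j] > 0 and y[g, ref] > 0]
        m_vals, a_vals, w_vals = [], [], []
        for g in genes:
            pj, pr = y[g, j] / lib[j], y[g, ref] / lib[ref]
            m_vals.append(math.log2(pj / pr))
            a_vals.append(0.5 * math.log2(pj * pr))
            w_vals.append(
                1.0
                / (
                    (lib[j] - y[g, j]) / (lib[j] * y[g, j])
                    + (lib[ref] - y[g, ref]) / (lib[ref] * y[g, ref])
                )
            )
        n = len(genes)
        if n == 0:
            log_factors.append(0.0)
            continue
        if max(m_vals) - min(m_vals) < 1e-10:
            log_factors.append(float(np.mean(m_vals)))
            continue
        order_m = sorted(range(n), key=lambda i: (m_vals[i], i))
        order_a = sorted(range(n), key=lambda i: (a_vals[i], i))
        rank_m = {i: r + 1 for r, i in enumerate(order_m)}
        rank_a = {i: r + 1 for r, i in enumerate(order_a)}
        lo_m, hi_m = math.floor(n * trim_m) + 1, n - math.floor(n * trim_m)
        lo_a, hi_a = math.floor(n * trim_a) + 1, n - math.floor(n * trim_a)
        num = den = 0.0
        for i in range(n):
            if lo_m <= rank_m[i] <= hi_m and lo_a <= rank_a[i] <= hi_a:
                num += w_vals[i] * m_vals[i]
                den += w_vals[i]
        log_factors.append(num / den if den > 0 else 0.0)

    factors = np.array([2.0**lf for lf in log_factors])
    return factors / np.exp(np.mean(np.log(factors)))


def _log_nb_pmf(k: int, r: float, mean: float) -> float:
    """log NB pmf with shape r and mean."""
    p = r / (r + mean)
    return (
        math.lgamma(k + r)
        - math.lgamma(r)
        - math.lgamma(k + 1)
        + r * math.log(p)
        + k * math.log1p(-p)
    )


def _log_pois_pmf(k: int, mean: float) -> float:
    if mean == 0:
        return 0.0 if k == 0 else -math.inf
    return k * math.log(mean) - mean - math.lgamma(k + 1)


def enum_exact_pvalue(s_a: int, s_b: int, n_a: int, n_b: int, phi: float) -> float:
    """Two-sided conditional exact P by exhaustive enumeration of splits."""
    s = s_a + s_b
    if s == 0:
        return 1.0
    mu = s / (n_a + n_b)
    weights = []
    for x in range(s + 1):
        if phi <= 0:
            lw = _log_pois_pmf(x, n_a * mu) + _log_pois_pmf(s - x, n_b * mu)
        else:
            lw = _log_nb_pmf(x, n_a / phi, n_a * mu) + _log_nb_pmf(
                s - x, n_b / phi, n_b * mu
            )
        weights.append(math.exp(lw))
    total = sum(weights)
    probs = [w / total for w in weights]
    obs = probs[s_a]
    p = sum(w for w in probs if w <= obs * (1.0 + 1e-12))
    return min(max(p, obs), 1.0)


def auc_pairwise(scores_true, scores_false) -> float:
    """AUC as (concordant + 0.5 * tied) / (n_true * n_false) over all pairs."""
    conc = ties = 0
    for st in scores_true:
        for sf in scores_false:
            if st > sf:
                conc += 1
            elif st == sf:
                ties += 1
    return (conc + 0.5 * ties) / (len(scores_true) * len(scores_false))
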