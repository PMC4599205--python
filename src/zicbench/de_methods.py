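"""Surrogate differential-expression tests and dispersion diagnostics.

Two transparent surrogates represent the families compared in the
zero-in-one-condition benchmark:

* ``exact_nb_test`` — a count-based exact test: conditional on the total of
  the two (library-size-equalized) group sums, the two-sided P value sums
  the probabilities of all splits as or less likely than the observed one
  under the negative-binomial model.
* ``moderated_t_test`` — a transform-based test on log-CPM: per-observation
  precision weights from a fitted mean-variance trend, a weighted two-group
  linear fit, and empirical-Bayes variance moderation giving a moderated
  t-statistic with augmented degrees of freedom.

An external-results adapter lets result tables from any other tool enter
the same evaluation. Dispersion estimation uses a per-gene moment estimator
moderated toward a running-median mean-dispersion trend.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.ndimage import median_filter
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .containers import CountMatrix, NormalizedMatrix, two_group_masks
from .simdata import SimulatedDataset

__all__ = [
    "DispersionEstimates",
    "estimate_dispersions",
    "exact_nb_test",
    "moderated_t_test",
    "adjust_bh",
    "load_external_results",
    "dispersion_shift_diagnostic",
]

_TREND_WINDOW = 101  # running-median window (genes), ends extended


# ---------------------------------------------------------------------------
# dispersion estimation
# ---------------------------------------------------------------------------

@dataclass
class DispersionEstimates:
    """Per-gene dispersion table: moment, trend and shrunk estimates."""

    table: pd.DataFrame  # columns: mean, phi_moment, phi_trend, phi_shrunk
    basis: str  # "both-conditions" or "single-nonzero-condition"

    def phi(self) -> pd.Series:
        return self.table["phi_shrunk"]


def _adjusted_counts(counts: CountMatrix) -> np.ndarray:
    """Counts rescaled to the mean library size (removes depth differences)."""
    lib = counts.libsizes.astype(float)
    return counts.values() * (lib.mean() / lib)[None, :]


def _moment_phi(y: np.ndarray, groups: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Moment dispersion from pooled within-group variance on adjusted counts.

    phi = max(0, (var - mean) / mean^2); genes with zero mean get phi 0.
    """
    n_total = sum(int(g.sum()) for g in groups)
    ss = np.zeros(y.shape[0])
    for g in groups:
        sub = y[:, g]
        ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    df = n_total - len(groups)
    if df < 1:
        raise ValueError("need at least 2 replicates in a group to estimate dispersion")
    var = ss / df
    mean = y.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = np.where(mean > 0, (var - mean) / mean**2, 0.0)
    return mean, np.maximum(phi, 0.0)


def _running_median_trend(mean: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Running median of phi over genes ordered by mean, ends extended."""
    n = phi.size
    order = np.lexsort((np.arange(n), mean))
    window = min(_TREND_WINDOW, n if n % 2 == 1 else n - 1)
    window = max(window, 1)
    smoothed = median_filter(phi[order], size=window, mode="nearest")
    trend = np.empty(n)
    trend[order] = smoothed
    return trend


def estimate_dispersions(
    counts: CountMatrix,
    basis: str = "both-conditions",
    shrink_weight: float = 0.7,
    truth: pd.Series | None = None,
) -> DispersionEstimates:
    """Moment, trend and shrunk NB dispersion estimates per gene.

    ``basis="both-conditions"`` pools within-group variance over both
    groups. ``basis="single-nonzero-condition"`` estimates from the one
    condition with positive counts (genes expressed in one condition only;
    others get NaN). The shrunk estimate is the convex combination
    shrink_weight*trend + (1-shrink_weight)*moment.
    """
    if not 0.0 <= shrink_weight <= 1.0:
        raise ValueError("shrink_weight must lie in [0, 1]")
    y = _adjusted_counts(counts)
    mask_a, mask_b, _ = two_group_masks(counts.design)
    trend_mask = None
    if basis == "both-conditions":
        if mask_a.sum() < 2 or mask_b.sum() < 2:
            raise ValueError("both-conditions basis needs >= 2 replicates per group")
        mean, phi_mom = _moment_phi(y, [mask_a, mask_b])
        # genes all-zero in one condition violate the common-mean model (the
        # degenerate group contributes zero variance but full df); they take
        # the trend value at their mean but do not inform the trend fit
        raw = counts.values()
        expressed_both = (raw[:, mask_a].sum(axis=1) > 0) & (raw[:, mask_b].sum(axis=1) > 0)
        trend_mask = expressed_both
    elif basis == "single-nonzero-condition":
        raw = counts.values()
        zero_a = raw[:, mask_a].sum(axis=1) == 0
        zero_b = raw[:, mask_b].sum(axis=1) == 0
        mean = np.full(y.shape[0], np.nan)
        phi_mom = np.full(y.shape[0], np.nan)
        for zero_mask, use in ((zero_a & ~zero_b, mask_b), (zero_b & ~zero_a, mask_a)):
            if use.sum() < 2:
                raise ValueError("single-condition basis needs >= 2 replicates")
            idx = np.flatnonzero(zero_mask)
            if idx.size:
                sub = y[np.ix_(idx, use)]
                m, p = _moment_phi(sub, [np.ones(sub.shape[1], dtype=bool)])
                mean[idx], phi_mom[idx] = m, p
    else:
        raise ValueError(f"unknown basis {basis!r}")

    ok = np.isfinite(phi_mom)
    fit_on = ok if trend_mask is None else (ok & trend_mask)
    if not fit_on.any():
        fit_on = ok
    trend = np.full_like(phi_mom, np.nan)
    if fit_on.sum() >= 1:
        trend_fit = _running_median_trend(mean[fit_on], phi_mom[fit_on])
        trend[fit_on] = trend_fit
        # remaining genes: interpolate the trend at their mean
        rest = ok & ~fit_on
        if rest.any():
            order = np.argsort(mean[fit_on], kind="stable")
            trend[rest] = np.interp(
                mean[rest], mean[fit_on][order], trend_fit[order]
            )
    shrunk = shrink_weight * trend + (1.0 - shrink_weight) * phi_mom
    table = pd.DataFrame(
        {"mean": mean, "phi_moment": phi_mom, "phi_trend": trend, "phi_shrunk": shrunk},
        index=counts.gene_ids,
    )
    return DispersionEstimates(table, basis)


# ---------------------------------------------------------------------------
# exact NB test
# ---------------------------------------------------------------------------

def _equalize_libsizes(counts: CountMatrix, factors: np.ndarray | None) -> np.ndarray:
    """Scale counts to the geometric-mean effective library, rounding half-up."""
    lib = counts.libsizes.astype(float)
    eff = lib * (np.asarray(factors, float) if factors is not None else 1.0)
    common = np.exp(np.mean(np.log(eff)))
    scaled = counts.values() * (common / eff)[None, :]
    return np.floor(scaled + 0.5).astype(np.int64)  # deterministic half-up


def _conditional_logpmf(s: int, n_a: int, n_b: int, phi: float) -> np.ndarray:
    """log pmf of the group-A sum over splits x = 0..s, conditional on total s.

    Group sums are NB with means proportional to group size and shape
    n_g/phi (sum of n_g independent NB(mu, phi)); phi = 0 degenerates to
    Poisson, making the conditional law Binomial(s, n_a/(n_a+n_b)).
    """
    x = np.arange(s + 1)
    n = n_a + n_b
    if phi <= 0:
        lp = stats.binom.logpmf(x, s, n_a / n)
    else:
        mu = s / n
        r_a, r_b = n_a / phi, n_b / phi
        m_a, m_b = n_a * mu, n_b * mu
        la = stats.nbinom.logpmf(x, r_a, r_a / (r_a + m_a))
        lb = stats.nbinom.logpmf(s - x, r_b, r_b / (r_b + m_b))
        lp = la + lb
        lp -= special.logsumexp(lp)
    return lp


def exact_two_sided_pvalue(s_a: int, s_b: int, n_a: int, n_b: int, phi: float) -> float:
    """Two-sided exact P for an observed split (s_a, s_b) of the total.

    Sums the conditional probabilities of every split as or less likely
    than the observed one (ties included). P = 1 when the total is zero.
    """
    s = s_a + s_b
    if s == 0:
        return 1.0
    lp = _conditional_logpmf(s, n_a, n_b, phi)
    obs = lp[s_a]
    p = float(np.exp(special.logsumexp(lp[lp <= obs + 1e-12])))
    return min(max(p, np.exp(obs)), 1.0)


def exact_nb_test(
    counts: CountMatrix,
    dispersions: DispersionEstimates | pd.Series | np.ndarray,
    factors: np.ndarray | None = None,
) -> pd.DataFrame:
    """Exact NB test of a two-group design; returns (pvalue, fdr) per gene.

    Effective library sizes are equalized first (counts scaled to their
    geometric mean and rounded), then each gene's group sums are compared
    conditionally on their total. FDR is the BH adjustment over all genes.
    """
    mask_a, mask_b, _ = two_group_masks(counts.design)
    n_a, n_b = int(mask_a.sum()), int(mask_b.sum())
    y = _equalize_libsizes(counts, factors)
    if isinstance(dispersions, DispersionEstimates):
        phi = dispersions.table["phi_shrunk"].reindex(counts.gene_ids).to_numpy()
    else:
        phi = pd.Series(np.asarray(dispersions, float).ravel(), index=counts.gene_ids) \
            .reindex(counts.gene_ids).to_numpy() if not isinstance(dispersions, pd.Series) \
            else dispersions.reindex(counts.gene_ids).to_numpy()
    phi = np.nan_to_num(phi, nan=0.0)

    s_a = y[:, mask_a].sum(axis=1)
    s_b = y[:, mask_b].sum(axis=1)
    pvals = np.ones(y.shape[0])
    for i in range(y.shape[0]):
        pvals[i] = exact_two_sided_pvalue(int(s_a[i]), int(s_b[i]), n_a, n_b, float(phi[i]))
    return pd.DataFrame(
        {"pvalue": pvals, "fdr": adjust_bh(pvals), "method": "exact-nb"},
        index=counts.gene_ids,
    )


# ---------------------------------------------------------------------------
# moderated t on log-CPM
# ---------------------------------------------------------------------------

def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        return np.inf
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def _fit_prior_variance(s2: np.ndarray, d: int) -> tuple[float, float]:
    """Moment-match (d0, s0^2) of the scaled-inverse-chi^2 variance prior.

    Works on z = log(s^2): Var(z) over genes in excess of trigamma(d/2)
    identifies trigamma(d0/2); when the observed spread is at or below the
    sampling floor, d0 is +inf and the prior collapses to a point.
    """
    ok = np.isfinite(s2) & (s2 > 0)
    z = np.log(s2[ok])
    e_correction = special.digamma(d / 2.0) - np.log(d / 2.0)
    evar = float(np.var(z, ddof=1)) - float(special.polygamma(1, d / 2.0))
    if evar <= 0:
        d0 = np.inf
        s0_log = float(np.mean(z)) - e_correction
    else:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_log = (
            float(np.mean(z))
            - e_correction
            - (special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
        )
    return d0, float(np.exp(s0_log))


def moderated_t_test(
    logdata: NormalizedMatrix,
    raw_counts: CountMatrix,
    lowess_frac: float = 0.5,
) -> pd.DataFrame:
    """Precision-weighted moderated t-test on log-CPM values.

    (a) a lowess trend of sqrt(residual sd) on average log2 count is fitted
    over genes; (b) each observation gets weight 1/trend-predicted variance
    at its fitted value; (c) a weighted two-group fit per gene yields the
    log-fold-change, residual variance s^2 and df d; (d) variances are
    moderated, s~2 = (d0*s0^2 + d*s^2)/(d0 + d), with the prior (d0, s0^2)
    moment-matched from the spread of log s^2 across genes; (e) the
    moderated t uses d0 + d degrees of freedom. FDR is BH over all genes.
    """
    if logdata.scale != "log-cpm":
        raise ValueError("moderated_t_test expects a log-cpm matrix")
    v = logdata.values.to_numpy()
    mask_a, mask_b, _ = two_group_masks(raw_counts.design)
    n_a, n_b = int(mask_a.sum()), int(mask_b.sum())
    d = n_a + n_b - 2
    if d < 1:
        raise ValueError("zero residual degrees of freedom")

    # (a) mean-variance trend on the unweighted fit
    fit0 = np.where(mask_a, v[:, mask_a].mean(axis=1)[:, None], v[:, mask_b].mean(axis=1)[:, None])
    resid = v - fit0
    sd0 = np.sqrt((resid**2).sum(axis=1) / d)
    avg_logcount = np.log2(raw_counts.values().mean(axis=1) + 0.5)
    order = np.argsort(avg_logcount, kind="stable")
    smooth = lowess(
        np.sqrt(sd0)[order], avg_logcount[order], frac=lowess_frac, return_sorted=True
    )
    trend_x, trend_y = smooth[:, 0], np.maximum(smooth[:, 1], 1e-4)

    # (b) weights at per-observation fitted log-counts
    eff = logdata.libsizes.astype(float) * logdata.factors
    fitted_logcount = fit0 + np.log2(eff / 1e6)[None, :]
    pred_sqrt_sd = np.interp(fitted_logcount, trend_x, trend_y)
    w = pred_sqrt_sd ** -4.0

    # (c) weighted two-group fit
    wa, wb = w[:, mask_a], w[:, mask_b]
    swa, swb = wa.sum(axis=1), wb.sum(axis=1)
    ma = (wa * v[:, mask_a]).sum(axis=1) / swa
    mb = (wb * v[:, mask_b]).sum(axis=1) / swb
    coef = mb - ma
    fitted = np.where(mask_a, ma[:, None], mb[:, None])
    s2 = (w * (v - fitted) ** 2).sum(axis=1) / d
    unscaled = 1.0 / swa + 1.0 / swb

    # (d) empirical-Bayes moderation
    d0, s02 = _fit_prior_variance(s2, d)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s02)
        df_total = np.inf
    else:
        s2_post = (d0 * s02 + d * s2) / (d0 + d)
        df_total = d0 + d

    # (e) moderated t
    with np.errstate(divide="ignore", invalid="ignore"):
        t = coef / np.sqrt(s2_post * unscaled)
    t = np.nan_to_num(t, nan=0.0)
    if np.isinf(df_total):
        pvals = 2.0 * stats.norm.sf(np.abs(t))
    else:
        pvals = 2.0 * stats.t.sf(np.abs(t), df_total)
    pvals = np.clip(pvals, 0.0, 1.0)
    return pd.DataFrame(
        {
            "pvalue": pvals,
            "fdr": adjust_bh(pvals),
            "method": "moderated-t",
            "coef": coef,
            "t": t,
        },
        index=logdata.values.index,
    )


# ---------------------------------------------------------------------------
# BH adjustment and external results
# ---------------------------------------------------------------------------

def adjust_bh(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or p.min() < 0 or p.max() > 1:
        raise ValueError("P values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def load_external_results(
    path,
    method: str = "external",
    id_col: str | None = None,
    p_col: str | None = None,
    fdr_col: str | None = None,
) -> pd.DataFrame:
    """Adapter for DE result tables produced by other tools.

    Reads a TSV/CSV with a gene-ID column and a P-value and/or FDR column
    (auto-detected case-insensitively unless names are given); a missing
    FDR column is recomputed with BH. Returns the standard (pvalue, fdr,
    method) frame indexed by gene ID.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    lower = {c.lower(): c for c in df.columns}

    def find(explicit, candidates):
        if explicit is not None:
            if explicit not in df.columns:
                raise ValueError(f"{path}: missing column {explicit!r}")
            return explicit
        for cand in candidates:
            if cand in lower:
                return lower[cand]
        return None

    gid = find(id_col, ["gene_id", "id", "gene", "feature"])
    pcol = find(p_col, ["pvalue", "p.value", "p_value", "p", "pval"])
    fcol = find(fdr_col, ["fdr", "padj", "adj.p.val", "qvalue"])
    if gid is None or (pcol is None and fcol is None):
        raise ValueError(f"{path}: need a gene-ID column and a P-value or FDR column")
    out = pd.DataFrame(index=pd.Index(df[gid].astype(str), name="gene_id"))
    if out.index.has_duplicates:
        raise ValueError(f"{path}: duplicate gene IDs")
    for col, name in ((pcol, "pvalue"), (fcol, "fdr")):
        if col is not None:
            vals = pd.to_numeric(df[col], errors="raise").to_numpy(float)
            if np.any(vals < 0) or np.any(vals > 1):
                raise ValueError(f"{path}: {name} values outside [0, 1]")
            out[name] = vals
    if "pvalue" not in out:
        out["pvalue"] = out["fdr"]  # ranking fallback when only FDR is given
    if "fdr" not in out:
        out["fdr"] = adjust_bh(out["pvalue"].to_numpy())
    out["method"] = method
    return out[["pvalue", "fdr", "method"]]


# ---------------------------------------------------------------------------
# dispersion-shift diagnostic
# ---------------------------------------------------------------------------

def dispersion_shift_diagnostic(
    modified: SimulatedDataset,
    original: CountMatrix | None = None,
    shrink_weight: float = 0.0,
) -> pd.DataFrame:
    """Paired dispersion estimates for zero-injected genes.

    For each true DE gene, the dispersion is estimated (i) from the single
    non-zero condition of the modified data and (ii) from both conditions
    of the unmodified data when available (simulation); pairing the two
    answers whether zeroing one condition drives estimates toward Poisson.
    Default shrink_weight 0 compares raw moment estimates (same estimand on
    both sides).
    """
    truth_idx = modified.truth[modified.truth].index
    if len(truth_idx) == 0:
        return pd.DataFrame(columns=["phi_single_nonzero", "phi_both_conditions"])
    single = estimate_dispersions(
        modified.data, basis="single-nonzero-condition", shrink_weight=shrink_weight
    ).table.loc[truth_idx]
    if original is not None:
        both = estimate_dispersions(
            original, basis="both-conditions", shrink_weight=shrink_weight
        ).table.loc[truth_idx]
    else:
        # real data: match each true gene to expressed genes of similar mean
        both_all = estimate_dispersions(
            modified.data, basis="both-conditions", shrink_weight=shrink_weight
        ).table
        expressed = both_all.drop(index=truth_idx)
        order = expressed["mean"].to_numpy()
        matched = []
        for m in single["mean"]:
            j = int(np.argmin(np.abs(order - m)))
            matched.append(expressed["phi_moment"].iloc[j])
        both = pd.DataFrame({"phi_moment": matched}, index=truth_idx)
    return pd.DataFrame(
        {
            "phi_single_nonzero": single["phi_moment"],
            "phi_both_conditions": both["phi_moment"],
        },
        index=truth_idx,
    )
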