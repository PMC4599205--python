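"""Synthetic two-group negative-binomial count data with zero-in-one-condition
differential expression as ground truth.

The simulator emulates a bulk RNA-seq experiment: per-gene NB parameters
(mean mu at a reference depth, dispersion phi; variance mu*(1 + mu*phi)) are
sampled jointly from a parameter pool, counts are drawn for two groups with
per-sample library sizes, and "true DE" genes are created by setting all
counts of one randomly chosen condition to zero — the situation where a gene
is expressed in only one condition. Zero injection is weighted toward
low-expression genes, mirroring how all-zero-in-one-condition genes
concentrate at low expression in real datasets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rand import substream
from .containers import CountMatrix, two_group_masks

__all__ = [
    "NBParams",
    "JointParamPool",
    "SimulationConfig",
    "SimulatedDataset",
    "REFERENCE_LIBSIZE",
    "make_surrogate_pool",
    "load_param_pool",
    "simulate_null_counts",
    "introduce_zeros",
    "simulate_dataset",
    "empirical_zero_profile",
]

logger = logging.getLogger(__name__)

#: Library size at which pool means are expressed (mid-range bulk depth).
REFERENCE_LIBSIZE = 2e7


@dataclass(frozen=True)
class NBParams:
    """Negative-binomial mean/dispersion pair: variance = mu*(1 + mu*phi)."""

    mu: float
    phi: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.mu) and self.mu > 0):
            raise ValueError(f"mu must be finite and > 0, got {self.mu}")
        if not (np.isfinite(self.phi) and self.phi >= 0):
            raise ValueError(f"phi must be finite and >= 0, got {self.phi}")


@dataclass
class JointParamPool:
    """Ordered pool of (mu, phi) pairs preserving their joint structure.

    ``source`` tags whether the pool came from an empirical estimate table
    (``empirical-file``) or the built-in parametric surrogate
    (``parametric-surrogate``).
    """

    mus: np.ndarray
    phis: np.ndarray
    source: str = "parametric-surrogate"

    def __post_init__(self) -> None:
        self.mus = np.asarray(self.mus, dtype=float)
        self.phis = np.asarray(self.phis, dtype=float)
        if self.mus.size == 0:
            raise ValueError("empty parameter pool")
        if self.mus.shape != self.phis.shape:
            raise ValueError("mus and phis must have equal length")
        ok = np.isfinite(self.mus) & (self.mus > 0) & np.isfinite(self.phis) & (self.phis >= 0)
        if not ok.all():
            raise ValueError("pool entries violate NB parameter invariants")

    def __len__(self) -> int:
        return int(self.mus.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"mu": self.mus, "phi": self.phis})


@dataclass
class SimulationConfig:
    """Study-design parameters of the zero-in-one-condition simulation.

    Defaults are the full-scale design: 30,000 features, 5 vs 5 samples,
    zero-counts introduced to 5% of features with low-expression weighting,
    library sizes uniform on the 16-39 million read depths typical of the
    emulated experiment, three simulation replicates.
    """

    n_features: int = 30_000
    n_per_group: tuple[int, int] = (5, 5)
    frac_zero_de: float = 0.05
    phi_filter: tuple[float, float] = (0.0, 5.0)
    low_expr_weight_exponent: float = 1.0
    libsize_range: tuple[int, int] = (16_000_000, 39_000_000)
    n_reps: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        if min(self.n_per_group) < 1:
            raise ValueError("group sizes must be >= 1")
        if not 0.0 <= self.frac_zero_de <= 1.0:
            raise ValueError("frac_zero_de must lie in [0, 1]")
        if self.low_expr_weight_exponent < 0:
            raise ValueError("low_expr_weight_exponent must be >= 0")
        if self.libsize_range[0] > self.libsize_range[1]:
            raise ValueError("libsize_range min must be <= max")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")


@dataclass
class SimulatedDataset:
    """A simulated count matrix plus its ground truth.

    ``truth`` is a boolean Series over genes (True = zero-injected DE gene),
    ``zeroed_condition`` maps each true gene to the group that was zeroed,
    and ``params`` records the NB parameters actually used per gene.
    """

    data: CountMatrix
    truth: pd.Series
    zeroed_condition: pd.Series
    params: pd.DataFrame = field(repr=False, default=None)


def make_surrogate_pool(n: int, seed: int) -> JointParamPool:
    """Parametric surrogate for an empirical joint (mean, dispersion) pool.

    log10-means are drawn from a truncated normal spanning roughly four
    orders of magnitude of expression (means in [5, 1e5] counts at the
    reference depth — empirical pools derive from expression-filtered
    genes, so very low means do not occur). Dispersions follow the standard
    decreasing mean-dispersion trend phi(mu) = a/mu + b (a=2, b=0.05) with
    lognormal multiplicative noise, so Spearman(mu, phi) < 0 as in real
    RNA-seq estimate tables.
    """
    if n < 1:
        raise ValueError("pool size must be >= 1")
    rng = substream(seed, "surrogate-pool")
    lo, hi = np.log10(5.0), 5.0
    logmu = np.empty(0)
    while logmu.size < n:
        draw = rng.normal(2.0, 0.8, size=2 * n)
        logmu = np.concatenate([logmu, draw[(draw >= lo) & (draw <= hi)]])
    mus = 10.0 ** logmu[:n]
    trend = 2.0 / mus + 0.05
    phis = trend * rng.lognormal(mean=0.0, sigma=0.4, size=n)
    phis = np.clip(phis, 0.0, 5.0)
    return JointParamPool(mus, phis, source="parametric-surrogate")


def load_param_pool(path, phi_filter: tuple[float, float] = (0.0, 5.0)) -> JointParamPool:
    """Load a two-column (mean, dispersion) TSV, filtering invalid rows.

    Rows with non-positive/non-finite means, negative dispersions, or
    dispersions outside ``phi_filter`` are dropped (the count is logged);
    order of surviving rows is preserved.
    """
    df = pd.read_csv(path, sep=r"\s+|\t|,", engine="python", header=None, comment="#")
    # tolerate an optional header row
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (mean, dispersion)")
    df = df.iloc[:, :2]
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.iloc[0].isna().any():
        numeric = numeric.iloc[1:]
    numeric = numeric.dropna()
    mu = numeric.iloc[:, 0].to_numpy(float)
    phi = numeric.iloc[:, 1].to_numpy(float)
    lo, hi = phi_filter
    keep = (
        np.isfinite(mu) & (mu > 0)
        & np.isfinite(phi) & (phi >= 0)
        & (phi >= lo) & (phi <= hi)
    )
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("load_param_pool: removed %d of %d rows", n_removed, keep.size)
    if not keep.any():
        raise ValueError(f"{path}: no rows survive filtering")
    return JointParamPool(mu[keep], phi[keep], source="empirical-file")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Vectorized NB(mean, phi) draw via gamma-Poisson; phi=0 is Poisson."""
    mean = np.asarray(mean, dtype=float)
    phi = np.broadcast_to(np.asarray(phi, dtype=float), mean.shape)
    out = np.empty(mean.shape, dtype=np.int64)
    pois = phi == 0
    if pois.any():
        out[pois] = rng.poisson(mean[pois])
    if (~pois).any():
        shape = 1.0 / phi[~pois]
        lam = rng.gamma(shape, mean[~pois] * phi[~pois])
        out[~pois] = rng.poisson(lam)
    return out


def simulate_null_counts(
    pool: JointParamPool, config: SimulationConfig, rep: int = 0
) -> SimulatedDataset:
    """Simulate a two-group NB count matrix with no differential expression.

    For feature g with pool parameters (mu_g, phi_g) and sample j with
    library size L_j, the count is NB with mean mu_g * L_j / L_ref and
    dispersion phi_g, identically in both groups. Library sizes are drawn
    uniformly from ``config.libsize_range``. Deterministic given
    (config.seed, rep).
    """
    rng = substream(config.seed, "simulate", rep)
    n = config.n_features
    idx = rng.integers(0, len(pool), size=n)
    mus, phis = pool.mus[idx], pool.phis[idx]

    n_a, n_b = config.n_per_group
    n_samples = n_a + n_b
    lo, hi = config.libsize_range
    libsizes = rng.integers(lo, hi + 1, size=n_samples)

    means = mus[:, None] * (libsizes[None, :] / REFERENCE_LIBSIZE)
    counts = _nb_draw(rng, means, phis[:, None])

    gene_ids = pd.Index([f"g{i+1:06d}" for i in range(n)], name="gene_id")
    sample_ids = [f"A{j+1}" for j in range(n_a)] + [f"B{j+1}" for j in range(n_b)]
    design = pd.Series(["A"] * n_a + ["B"] * n_b, index=pd.Index(sample_ids, name="sample_id"))
    cm = CountMatrix(pd.DataFrame(counts, index=gene_ids, columns=sample_ids), design)
    truth = pd.Series(False, index=gene_ids, name="truth")
    zeroed = pd.Series(pd.NA, index=gene_ids, name="zeroed_condition", dtype="object")
    params = pd.DataFrame({"mu": mus, "phi": phis}, index=gene_ids)
    return SimulatedDataset(cm, truth, zeroed, params)


def introduce_zeros(
    data: SimulatedDataset, config: SimulationConfig, rep: int = 0
) -> SimulatedDataset:
    """Create true DE genes by zeroing one condition of selected features.

    Exactly ``round(frac_zero_de * n_features)`` features are selected
    without replacement, with selection probability proportional to
    rank(mean expression, lowest first) ** (-low_expr_weight_exponent)
    (exponent 0 = uniform). For each, a fair coin picks the condition whose
    counts are set to zero; draws that would leave the gene with no positive
    count in the other condition are rejected and redrawn, so every true
    gene is expressed in exactly one condition.
    """
    if data.truth.any():
        raise ValueError("introduce_zeros expects a pure-null dataset")
    n = config.n_features
    n_true = int(round(config.frac_zero_de * n))
    if n_true == 0:
        return data

    rng = substream(config.seed, "introduce-zeros", rep)
    counts = data.data.counts.to_numpy().copy()
    mask_a, mask_b, groups = two_group_masks(data.data.design)

    pos_a = counts[:, mask_a].sum(axis=1) > 0
    pos_b = counts[:, mask_b].sum(axis=1) > 0
    eligible = np.flatnonzero(pos_a | pos_b)
    if n_true > eligible.size:
        raise ValueError(
            f"cannot select {n_true} zero-DE features: only {eligible.size} "
            "features have a non-zero condition"
        )

    mean_expr = counts.mean(axis=1)
    # rank 1 = lowest expression; stable tie-break by feature index
    order = np.lexsort((np.arange(n), mean_expr))
    rank = np.empty(n, dtype=float)
    rank[order] = np.arange(1, n + 1)
    weights = rank[eligible] ** (-config.low_expr_weight_exponent)

    available = np.ones(eligible.size, dtype=bool)
    chosen: list[int] = []
    zero_a: list[bool] = []
    while len(chosen) < n_true:
        w = np.where(available, weights, 0.0)
        w_sum = w.sum()
        if w_sum == 0:
            raise ValueError("ran out of feasible features during zero injection")
        j = rng.choice(eligible.size, p=w / w_sum)
        gi = eligible[j]
        zero_first = bool(rng.integers(0, 2))  # fair coin: zero group A?
        other_positive = pos_b[gi] if zero_first else pos_a[gi]
        if not other_positive:
            continue  # redraw: the non-zeroed condition must stay expressed
        available[j] = False
        chosen.append(gi)
        zero_a.append(zero_first)

    truth = data.truth.copy()
    zeroed = data.zeroed_condition.copy()
    gene_ids = data.data.gene_ids
    for gi, za in zip(chosen, zero_a):
        counts[gi, mask_a if za else mask_b] = 0
        truth.iloc[gi] = True
        zeroed.iloc[gi] = groups[0] if za else groups[1]

    cm = CountMatrix(
        pd.DataFrame(counts, index=gene_ids, columns=data.data.sample_ids),
        data.data.design,
    )
    return SimulatedDataset(cm, truth, zeroed, data.params)


def simulate_dataset(
    pool: JointParamPool, config: SimulationConfig, rep: int = 0
) -> SimulatedDataset:
    """Convenience: null simulation followed by zero injection."""
    return introduce_zeros(simulate_null_counts(pool, config, rep), config, rep)


def empirical_zero_profile(data: CountMatrix, n_bins: int = 10) -> pd.DataFrame:
    """Fraction of all-zero-in-one-condition genes by expression-strength bin.

    Genes are placed on an average log2-CPM axis — computed over the
    non-zero condition for all-zero-in-one-condition genes, over all samples
    otherwise — then split into ``n_bins`` equal-occupancy bins ordered by
    expression. Returns one row per bin with the fraction of
    zero-in-one-condition genes; empty when no such genes exist is fine
    (fractions are then all zero).
    """
    counts = data.values()
    mask_a, mask_b, _ = two_group_masks(data.design)
    libsizes = counts.sum(axis=0)
    cpm = counts / libsizes[None, :] * 1e6

    zero_a = counts[:, mask_a].sum(axis=1) == 0
    zero_b = counts[:, mask_b].sum(axis=1) == 0
    zic = zero_a ^ zero_b  # all-zero in exactly one condition
    both_zero = zero_a & zero_b

    logcpm = np.log2(cpm + 0.5)
    expr = logcpm.mean(axis=1)
    expr[zic & zero_a] = logcpm[np.ix_(zic & zero_a, mask_b)].mean(axis=1)
    expr[zic & zero_b] = logcpm[np.ix_(zic & zero_b, mask_a)].mean(axis=1)

    keep = ~both_zero
    expr, zic = expr[keep], zic[keep]
    order = np.lexsort((np.arange(expr.size), expr))
    rows = []
    for b, chunk in enumerate(np.array_split(order, n_bins)):
        if chunk.size == 0:
            continue
        rows.append(
            {
                "bin": b,
                "expr_lo": float(expr[chunk].min()),
                "expr_hi": float(expr[chunk].max()),
                "n_genes": int(chunk.size),
                "frac_zero_in_one": float(zic[chunk].mean()),
            }
        )
    return pd.DataFrame(rows)
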