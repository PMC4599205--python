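"""Benchmark evaluation: truth labels, ROC curves and achieved-FDR analysis.

Two labeling schemes are supported. The percentile scheme derives labels
from the signal-to-noise distribution of zero-in-one-condition genes: the
top fraction (default 40%) are "true" DE genes, the bottom fraction
(default 20%) "false", with a gray zone of uncertainty in between that is
excluded from ROC construction. The simulation scheme uses hard ground
truth (zero-injected vs untouched genes), which additionally permits
achieved-FDR analysis: the actual false-discovery rate among genes called
at a nominal BH cutoff, which a well-calibrated method should keep at or
below the nominal level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn import metrics as _skm

from . import de_methods, normtransform, simdata, snr as snr_mod

__all__ = [
    "TruthLabels",
    "RocCurve",
    "FdrPerformance",
    "percentile_labels",
    "roc_curve",
    "tpr_fdr_curve",
    "benchmark_run",
]

DEFAULT_CUTOFFS = (0.01, 0.05, 0.1)


@dataclass
class TruthLabels:
    """Per-gene label in {'true', 'false', 'gray'} plus the labeling scheme."""

    labels: pd.Series
    scheme: str  # "snr-percentile" or "simulation"

    def __post_init__(self) -> None:
        bad = set(self.labels.unique()) - {"true", "false", "gray"}
        if bad:
            raise ValueError(f"invalid labels {bad}")
        if self.scheme == "simulation" and (self.labels == "gray").any():
            raise ValueError("simulation truth admits no gray labels")

    @classmethod
    def from_simulation(cls, truth: pd.Series) -> "TruthLabels":
        return cls(truth.map({True: "true", False: "false"}), "simulation")

    def subset(self, which: str) -> pd.Index:
        return self.labels[self.labels == which].index


@dataclass
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    marker: tuple[float, float] | None = None  # (fpr, tpr) at 5% estimated FDR


@dataclass
class FdrPerformance:
    """Per-nominal-cutoff operating points of one method on hard truth."""

    table: pd.DataFrame  # columns: cutoff, n_called, achieved_fdr, tpr, controlled
    curve: pd.DataFrame = field(repr=False, default=None)  # full achieved-FDR/TPR trace


def percentile_labels(
    snr_table: pd.DataFrame,
    true_top_fraction: float = 0.40,
    false_bottom_fraction: float = 0.20,
) -> TruthLabels:
    """Percentile truth labels from an S/N table.

    Genes ranked by S/N descending (+inf sentinel first, ties broken by
    gene ID); the top ceil(f_true * n) are 'true', the bottom
    floor(f_false * n) 'false', the middle 'gray'.
    """
    if true_top_fraction <= 0 or false_bottom_fraction <= 0:
        raise ValueError("label fractions must be positive")
    if true_top_fraction + false_bottom_fraction > 1.0:
        raise ValueError("label fractions must sum to at most 1")
    s = snr_table["snr"] if isinstance(snr_table, pd.DataFrame) else snr_table
    s = s.dropna()
    n = len(s)
    if n == 0:
        raise ValueError("empty S/N table")
    order = sorted(s.index, key=lambda g: (-s[g] if math.isfinite(s[g]) else -math.inf
                                           if s[g] > 0 else math.inf, str(g)))
    n_true = math.ceil(true_top_fraction * n)
    n_false = math.floor(false_bottom_fraction * n)
    labels = pd.Series("gray", index=s.index, dtype=object)
    labels[order[:n_true]] = "true"
    if n_false > 0:
        labels[order[n - n_false:]] = "false"
    return TruthLabels(labels, "snr-percentile")


def roc_curve(scores: pd.Series, truth: TruthLabels) -> RocCurve:
    """ROC over descending score thresholds; gray genes excluded first.

    Tied scores are grouped (one point per distinct score); AUC by the
    trapezoid rule, equal to the pairwise concordance probability.
    """
    labels = truth.labels[truth.labels != "gray"]
    y = (labels == "true").astype(int)
    sc = scores.reindex(labels.index)
    if sc.isna().any():
        raise ValueError("every labeled gene needs a score")
    if y.sum() == 0 or (1 - y).sum() == 0:
        raise ValueError("degenerate labels: need at least one true and one false gene")
    fpr, tpr, _ = _skm.roc_curve(y.to_numpy(), sc.to_numpy(), drop_intermediate=False)
    if fpr[0] != 0 or tpr[0] != 0:
        fpr, tpr = np.r_[0.0, fpr], np.r_[0.0, tpr]
    if fpr[-1] != 1 or tpr[-1] != 1:
        fpr, tpr = np.r_[fpr, 1.0], np.r_[tpr, 1.0]
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(fpr, tpr, auc)


def _roc_with_marker(
    results: pd.DataFrame, truth: TruthLabels, fdr_cutoff: float = 0.05
) -> RocCurve:
    """ROC on -log10 P with the operating point at the estimated-FDR cutoff."""
    score = -np.log10(np.maximum(results["pvalue"], 1e-300))
    curve = roc_curve(score, truth)
    labels = truth.labels[truth.labels != "gray"]
    called = results["fdr"].reindex(labels.index) <= fdr_cutoff
    is_true = labels == "true"
    n_t, n_f = int(is_true.sum()), int((~is_true).sum())
    tp = int((called & is_true).sum())
    fp = int((called & ~is_true).sum())
    curve.marker = (fp / max(n_f, 1), tp / max(n_t, 1))
    return curve


def tpr_fdr_curve(
    results: pd.DataFrame,
    truth: TruthLabels,
    cutoffs=DEFAULT_CUTOFFS,
) -> FdrPerformance:
    """TPR and achieved FDR at nominal BH cutoffs, on hard simulation truth.

    achieved_fdr = FP / max(1, FP + TP) among genes with fdr <= cutoff
    (0 when nothing is called, counted as controlled); tpr = TP / #true.
    The full trace over all distinct estimated-FDR values is also returned.
    """
    if truth.scheme != "simulation":
        raise ValueError("achieved-FDR analysis requires simulation (hard) truth")
    fdr = results["fdr"].reindex(truth.labels.index)
    if fdr.isna().any():
        raise ValueError("every gene in the truth set needs an FDR value")
    is_true = (truth.labels == "true").to_numpy()
    n_true = int(is_true.sum())
    fdr_v = fdr.to_numpy()

    def point(q: float) -> dict:
        called = fdr_v <= q
        tp = int((called & is_true).sum())
        fp = int((called & ~is_true).sum())
        achieved = fp / max(1, fp + tp)
        return {
            "cutoff": q,
            "n_called": int(called.sum()),
            "achieved_fdr": achieved,
            "tpr": tp / max(1, n_true),
            "controlled": achieved <= q,
        }

    table = pd.DataFrame([point(q) for q in cutoffs])
    grid = np.unique(fdr_v)
    trace = pd.DataFrame([point(q) for q in grid])[["cutoff", "achieved_fdr", "tpr"]]
    return FdrPerformance(table, trace)


def _run_methods(ds: simdata.SimulatedDataset) -> dict[str, pd.DataFrame]:
    """Both surrogate DE tests on one simulated dataset."""
    factors = normtransform.tmm_factors(ds.data)
    disp = de_methods.estimate_dispersions(ds.data)
    lin = normtransform.cpm(ds.data, factors=factors)
    log = normtransform.log_cpm(lin)
    return {
        "exact-nb": de_methods.exact_nb_test(ds.data, disp, factors),
        "moderated-t": de_methods.moderated_t_test(log, ds.data),
    }


def benchmark_run(
    config: simdata.SimulationConfig,
    pool: simdata.JointParamPool | None = None,
    cutoffs=DEFAULT_CUTOFFS,
    label_fractions: tuple[float, float] = (0.40, 0.20),
    scales: tuple[str, ...] = ("linear-cpm", "log-cpm", "vst"),
) -> dict:
    """Full zero-in-one-condition benchmark.

    Runs ``config.n_reps`` simulation replicates, applies both surrogate DE
    methods to each, and reports per-replicate and pooled (gene-level
    results concatenated across replicates) ROC/achieved-FDR performance
    against simulation truth, plus per-scale percentile-label ROC curves on
    the first replicate (identical labels across methods within a scale).
    """
    if pool is None:
        pool = simdata.make_surrogate_pool(
            max(10_000, config.n_features), seed=config.seed
        )
    per_rep: list[dict] = []
    pooled: dict[str, list[pd.DataFrame]] = {}
    pooled_truth: list[pd.Series] = []
    first_ds: simdata.SimulatedDataset | None = None

    first_results: dict[str, pd.DataFrame] | None = None
    for rep in range(config.n_reps):
        ds = simdata.simulate_dataset(pool, config, rep=rep)
        results = _run_methods(ds)
        if first_ds is None:
            first_ds, first_results = ds, results
        truth = TruthLabels.from_simulation(ds.truth)
        rep_report = {"rep": rep, "methods": {}}
        for name, res in results.items():
            curve = _roc_with_marker(res, truth)
            perf = tpr_fdr_curve(res, truth, cutoffs)
            rep_report["methods"][name] = {"roc": curve, "fdr_performance": perf}
            pooled.setdefault(name, []).append(
                res.set_index(pd.Index([f"r{rep}:{g}" for g in res.index]))
            )
        pooled_truth.append(
            ds.truth.set_axis([f"r{rep}:{g}" for g in ds.truth.index])
        )
        per_rep.append(rep_report)

    truth_all = TruthLabels.from_simulation(pd.concat(pooled_truth))
    aggregate = {}
    for name, frames in pooled.items():
        res_all = pd.concat(frames)
        aggregate[name] = {
            "roc": _roc_with_marker(res_all, truth_all),
            "fdr_performance": tpr_fdr_curve(res_all, truth_all, cutoffs),
        }

    # percentile-label ROC per scale on the first replicate
    factors = normtransform.tmm_factors(first_ds.data)
    lin = normtransform.cpm(first_ds.data, factors=factors)
    mats = {"linear-cpm": lin, "log-cpm": normtransform.log_cpm(lin),
            "vst": normtransform.vst(first_ds.data, factors=factors)}
    results1 = first_results
    by_scale: dict[str, dict] = {}
    for scale in scales:
        table = snr_mod.snr_table(mats[scale], first_ds.data.design, first_ds.data)
        if len(table) < 10:
            continue
        labels = percentile_labels(table, *label_fractions)
        scale_report = {"labels": labels, "methods": {}}
        for name, res in results1.items():
            score = -np.log10(np.maximum(res["pvalue"], 1e-300))
            scale_report["methods"][name] = roc_curve(score, labels)
        by_scale[scale] = scale_report

    return {
        "config": config,
        "per_rep": per_rep,
        "aggregate": aggregate,
        "percentile_roc_by_scale": by_scale,
    }
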