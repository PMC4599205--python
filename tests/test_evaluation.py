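import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import zicbench as z

from oracles import auc_pairwise


def snr_frame(values, ids=None):
    ids = ids or [f"g{i}" for i in range(len(values))]
    return pd.DataFrame({"snr": values}, index=pd.Index(ids, name="gene_id"))


class TestPercentileLabels:
    def test_forty_twenty_split_of_ten(self):
        labels = z.percentile_labels(snr_frame(range(1, 11)))
        lab = labels.labels
        assert set(lab[lab == "true"].index) == {"g9", "g8", "g7", "g6"}
        assert set(lab[lab == "false"].index) == {"g0", "g1"}
        assert (lab == "gray").sum() == 4

    def test_all_tied_uses_id_tiebreak(self):
        labels = z.percentile_labels(snr_frame([3.0] * 10))
        lab = labels.labels
        assert (lab == "true").sum() == 4
        assert (lab == "false").sum() == 2
        # deterministic lexicographic assignment
        assert set(lab[lab == "true"].index) == {"g0", "g1", "g2", "g3"}

    def test_infinity_sentinel_ranks_first(self):
        labels = z.percentile_labels(snr_frame([1.0, math.inf, 2.0, 3.0, 4.0]))
        assert labels.labels["g1"] == "true"

    def test_no_gray_zone_and_overlap_error(self):
        labels = z.percentile_labels(snr_frame(range(10)), 0.5, 0.5)
        assert (labels.labels == "gray").sum() == 0
        with pytest.raises(ValueError):
            z.percentile_labels(snr_frame(range(10)), 0.6, 0.5)

    @given(st.integers(5, 200), st.floats(0.05, 0.6), st.floats(0.05, 0.39))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_label_counts_follow_ceil_floor_rule(self, n, ft, ff):
        labels = z.percentile_labels(
            snr_frame(np.random.default_rng(0).normal(size=n)), ft, ff
        ).labels
        assert (labels == "true").sum() == math.ceil(ft * n)
        assert (labels == "false").sum() == math.floor(ff * n)
        assert len(labels) == n


class TestRocCurve:
    def _truth(self, n_true, n_false):
        lab = ["true"] * n_true + ["false"] * n_false
        ids = [f"g{i}" for i in range(len(lab))]
        return z.TruthLabels(pd.Series(lab, index=ids), "simulation"), ids

    def test_perfect_separation(self):
        truth, ids = self._truth(4, 4)
        scores = pd.Series([10, 9, 8, 7, 3, 2, 1, 0], index=ids, dtype=float)
        c = z.roc_curve(scores, truth)
        assert c.auc == pytest.approx(1.0)
        assert c.fpr[0] == 0 and c.tpr[-1] == 1

    def test_all_tied_scores(self):
        truth, ids = self._truth(3, 3)
        c = z.roc_curve(pd.Series(1.0, index=ids), truth)
        assert c.auc == pytest.approx(0.5)

    def test_matches_pairwise_oracle(self):
        rng = np.random.default_rng(31)
        for _ in range(10):
            n_t, n_f = rng.integers(2, 15), rng.integers(2, 15)
            truth, ids = self._truth(n_t, n_f)
            sc = rng.integers(0, 8, size=n_t + n_f).astype(float)
            c = z.roc_curve(pd.Series(sc, index=ids), truth)
            assert c.auc == pytest.approx(
                auc_pairwise(sc[:n_t], sc[n_t:]), abs=1e-10
            )

    def test_monotone_transform_invariance(self):
        truth, ids = self._truth(5, 5)
        sc = pd.Series(np.random.default_rng(1).normal(size=10), index=ids)
        a1 = z.roc_curve(sc, truth).auc
        a2 = z.roc_curve(np.exp(sc * 3), truth).auc
        assert a1 == pytest.approx(a2)

    def test_gray_excluded_and_degenerate_error(self):
        lab = pd.Series(["true", "gray", "false"], index=["a", "b", "c"])
        truth = z.TruthLabels(lab, "snr-percentile")
        sc = pd.Series([2.0, np.nan, 1.0], index=["a", "b", "c"])
        assert z.roc_curve(sc, truth).auc == 1.0  # gray gene's NaN score ignored
        bad = z.TruthLabels(pd.Series(["true", "true"], index=["a", "b"]), "simulation")
        with pytest.raises(ValueError):
            z.roc_curve(pd.Series([1.0, 2.0], index=["a", "b"]), bad)


class TestTprFdrCurve:
    def _results(self, fdrs, truths):
        ids = [f"g{i}" for i in range(len(fdrs))]
        res = pd.DataFrame(
            {"pvalue": fdrs, "fdr": fdrs}, index=pd.Index(ids, name="gene_id")
        )
        truth = z.TruthLabels(
            pd.Series(["true" if t else "false" for t in truths], index=res.index),
            "simulation",
        )
        return res, truth

    def test_empty_call_convention(self):
        res, truth = self._results([0.5, 0.6, 0.7], [True, False, False])
        t = z.tpr_fdr_curve(res, truth).table
        row = t[t.cutoff == 0.01].iloc[0]
        assert row.achieved_fdr == 0 and row.tpr == 0 and row.controlled

    def test_pure_true_calls(self):
        res, truth = self._results([0.001, 0.002, 0.9], [True, True, False])
        row = z.tpr_fdr_curve(res, truth).table.iloc[1]  # cutoff 0.05
        assert row.achieved_fdr == 0 and row.tpr == 1.0

    def test_two_fp_eight_tp(self):
        fdrs = [0.01] * 10 + [0.9] * 10
        truths = [True] * 8 + [False] * 2 + [True] * 2 + [False] * 8
        res, truth = self._results(fdrs, truths)
        row = z.tpr_fdr_curve(res, truth).table.iloc[1]
        assert row.achieved_fdr == pytest.approx(0.2)
        assert row.tpr == pytest.approx(0.8)

    def test_monotone_in_cutoff(self):
        rng = np.random.default_rng(7)
        res, truth = self._results(rng.uniform(size=50), rng.uniform(size=50) < 0.3)
        t = z.tpr_fdr_curve(res, truth).table
        assert (t["n_called"].diff().dropna() >= 0).all()
        assert (t["tpr"].diff().dropna() >= -1e-12).all()

    def test_percentile_scheme_rejected(self):
        res, _ = self._results([0.5, 0.5], [True, False])
        labels = z.TruthLabels(
            pd.Series(["true", "false"], index=res.index), "snr-percentile"
        )
        with pytest.raises(ValueError):
            z.tpr_fdr_curve(res, labels)


class TestBenchmarkRun:
    @pytest.fixture(scope="class")
    def small_report(self):
        cfg = z.SimulationConfig(n_features=400, n_reps=2, seed=17)
        return z.benchmark_run(cfg), cfg

    def test_deterministic_and_seed_sensitive(self, small_report):
        report, cfg = small_report
        again = z.benchmark_run(cfg)
        other = z.benchmark_run(
            z.SimulationConfig(n_features=400, n_reps=2, seed=18)
        )
        for m in report["aggregate"]:
            assert report["aggregate"][m]["roc"].auc == again["aggregate"][m]["roc"].auc
            assert report["aggregate"][m]["roc"].auc != other["aggregate"][m]["roc"].auc

    def test_both_methods_detect_injected_genes(self, small_report):
        report, _ = small_report
        for m, agg in report["aggregate"].items():
            assert agg["roc"].auc > 0.9, m

    def test_label_sets_differ_between_linear_and_log(self, small_report):
        report, _ = small_report
        by_scale = report["percentile_roc_by_scale"]
        lin = by_scale["linear-cpm"]["labels"].subset("true")
        log = by_scale["log-cpm"]["labels"].subset("true")
        assert len(set(lin) ^ set(log)) > 0

    def test_random_scores_are_a_negative_control(self, small_sim):
        ds, _ = small_sim
        rng = np.random.default_rng(3)
        p = rng.uniform(size=len(ds.truth))
        res = pd.DataFrame(
            {"pvalue": p, "fdr": p}, index=ds.truth.index
        )
        truth = z.TruthLabels.from_simulation(ds.truth)
        sc = pd.Series(-np.log10(p), index=ds.truth.index)
        assert abs(z.roc_curve(sc, truth).auc - 0.5) < 0.1
        row = z.tpr_fdr_curve(res, truth).table.iloc[1]
        assert row.achieved_fdr > 0.5  # uncontrolled by a wide margin
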