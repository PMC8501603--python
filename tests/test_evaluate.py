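import math

import numpy as np
import pandas as pd
import pytest

from annocomplex.evaluate import (
    alignment_metrics,
    de_metrics,
    ground_truth_filter,
    grouped_report,
    nrmse,
    quant_metrics,
    ranking_auc,
    simple_de_test,
    tercile_groups,
    true_de_labels,
)
from annocomplex.quantify import AlignmentTable, cpm_transform
from annocomplex.simulate import CountMatrix


def _origin(tx_of: dict[str, str]) -> pd.DataFrame:
    return pd.DataFrame(
        {"transcript_id": list(tx_of.values()), "sample": "s1"},
        index=pd.Index(list(tx_of.keys()), name="read_id"),
    )


class TestAlignmentMetrics:
    def test_all_correct_gives_ones(self):
        origin = _origin({f"r{i}": "t" for i in range(5)})
        aln = AlignmentTable(rows={f"r{i}": frozenset({"t"}) for i in range(5)})
        m = alignment_metrics(origin, aln)
        assert (m.recall, m.precision, m.f1) == (1.0, 1.0, 1.0)

    def test_mixed_outcomes_counted_directly(self):
        # 10 reads: 8 contain their origin, 1 maps elsewhere only, 1 unmapped
        origin = _origin({f"r{i}": "t" for i in range(10)})
        rows = {f"r{i}": frozenset({"t", "other"}) for i in range(8)}
        rows["r8"] = frozenset({"other"})
        rows["r9"] = frozenset()
        m = alignment_metrics(origin, AlignmentTable(rows=rows))
        assert m.recall == pytest.approx(8 / 9)
        assert m.precision == pytest.approx(8 / 9)
        assert m.f1 == pytest.approx(8 / 9)

    def test_all_unmapped_precision_undefined_not_zero(self):
        origin = _origin({"r0": "t", "r1": "t"})
        aln = AlignmentTable(rows={"r0": frozenset(), "r1": frozenset()})
        m = alignment_metrics(origin, aln)
        assert m.recall == 0.0
        assert math.isnan(m.precision)


class TestGroundTruthFilter:
    @staticmethod
    def _cm(values):
        df = pd.DataFrame(values)
        groups = {c: ("Control" if "control" in c else "Case") for c in df.columns}
        return CountMatrix(values=df, groups=groups, truth=pd.Series(1.0, index=df.index))

    def test_boundary_is_strict_under(self):
        # column totals 1e8, so a count of 25 is exactly 0.25 CPM, 24 is 0.24
        cm = self._cm(
            {
                "control_1": pd.Series({"at": 25, "below": 24, "filler": 99_999_951}),
                "case_1": pd.Series({"at": 25, "below": 25, "filler": 99_999_950}),
            }
        )
        kept = ground_truth_filter(cm, 0.25)
        assert "at" in kept  # exactly at threshold survives
        assert "below" not in kept  # under threshold in one sample is enough
        assert "filler" in kept

    def test_toy_matrix_matches_manual_cpm(self):
        # totals: control 8 -> CPM = count/8 * 1e6 ; case 4 -> count/4 * 1e6
        cm = self._cm(
            {
                "control_1": pd.Series({"a": 2, "b": 1, "c": 0, "d": 5}),
                "case_1": pd.Series({"a": 1, "b": 1, "c": 1, "d": 1}),
            }
        )
        assert sorted(ground_truth_filter(cm, 0.25)) == ["a", "b", "d"]

    def test_raising_threshold_never_adds_transcripts(self):
        rng = np.random.default_rng(0)
        cm = self._cm(
            {
                "control_1": pd.Series(rng.integers(0, 100, 50), index=[f"t{i}" for i in range(50)]),
                "case_1": pd.Series(rng.integers(0, 100, 50), index=[f"t{i}" for i in range(50)]),
            }
        )
        prev = set(ground_truth_filter(cm, 0.0))
        for thr in (1, 1000, 10_000, 50_000):
            cur = set(ground_truth_filter(cm, thr))
            assert cur <= prev
            prev = cur


class TestQuantMetrics:
    def test_perfect_estimate(self):
        m = pd.DataFrame({"s1": [1.0, 2.0, 3.0, 4.0]}, index=list("abcd"))
        rho, err = quant_metrics(m, m, list("abcd"))
        assert rho == pytest.approx(1.0)
        assert err == pytest.approx(0.0)

    def test_monotone_transform_keeps_rank_but_not_error(self):
        true = pd.DataFrame({"s1": [1.0, 2.0, 3.0, 4.0]}, index=list("abcd"))
        est = true**2
        rho, err = quant_metrics(est, true, list("abcd"))
        assert rho == pytest.approx(1.0)
        assert err > 0

    def test_four_point_hand_computation(self):
        est = pd.DataFrame({"s1": [1.0, 2.0, 3.0, 4.0]}, index=list("abcd"))
        true = pd.DataFrame({"s1": [1.0, 2.0, 4.0, 8.0]}, index=list("abcd"))
        rho, err = quant_metrics(est, true, list("abcd"))
        assert rho == pytest.approx(1.0)
        # RMSE = sqrt((0 + 0 + 1 + 16) / 4), range of truth = 7
        assert err == pytest.approx(math.sqrt(17 / 4) / 7)

    def test_zero_true_range_is_undefined(self):
        assert math.isnan(nrmse(np.array([1.0, 2.0]), np.array([3.0, 3.0])))


def _bh_by_hand(pvals: np.ndarray) -> np.ndarray:
    """Independent BH step-up: q_(i) = min_{j>=i} p_(j) * m / j."""
    m = len(pvals)
    order = np.argsort(pvals)
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        q[i] = running
    return q


class TestSimpleDeTest:
    @staticmethod
    def _counts(control, case):
        df = pd.DataFrame(
            np.column_stack([control, case]),
            columns=[f"control_{j}" for j in range(1, control.shape[1] + 1)]
            + [f"case_{j}" for j in range(1, case.shape[1] + 1)],
            index=[f"t{i}" for i in range(control.shape[0])],
        )
        groups = {c: ("Control" if c.startswith("control") else "Case") for c in df.columns}
        return df, groups

    def test_identical_groups_make_no_calls(self):
        rng = np.random.default_rng(0)
        x = rng.integers(50, 150, size=(20, 3))
        df, groups = self._counts(x, x)
        de = simple_de_test(df, groups)
        assert (de["log2fc"] == 0).all()
        assert not de["call"].any()

    def test_strongly_shifted_transcript_is_called(self):
        rng = np.random.default_rng(1)
        base = rng.poisson(200, size=(20, 5))
        case = base + rng.integers(-5, 6, size=(20, 5))
        case[0] = base[0] * 4  # one 4x up-regulated transcript, tight replicates
        df, groups = self._counts(base, case)
        de = simple_de_test(df, groups)
        assert de.loc["t0", "call"]
        assert de.loc["t0", "log2fc"] > 1.5
        assert de["call"].sum() == 1

    def test_bh_step_up_example(self):
        # frozen arithmetic: p = (.01,.02,.03,.04), m=4 -> all q = .04
        assert np.allclose(_bh_by_hand(np.array([0.01, 0.02, 0.03, 0.04])), 0.04)

    def test_qvalues_match_independent_bh(self):
        rng = np.random.default_rng(2)
        df, groups = self._counts(
            rng.poisson(100, size=(40, 3)), rng.poisson(110, size=(40, 3))
        )
        de = simple_de_test(df, groups)
        assert np.allclose(de["qvalue"], _bh_by_hand(de["pvalue"].to_numpy()))

    def test_qvalues_monotone_in_pvalue_rank(self):
        rng = np.random.default_rng(3)
        df, groups = self._counts(
            rng.poisson(50, size=(30, 3)), rng.poisson(60, size=(30, 3))
        )
        de = simple_de_test(df, groups).sort_values("pvalue")
        assert (np.diff(de["qvalue"]) >= -1e-12).all()

    def test_zero_variance_equal_means_gives_p_one(self):
        control = np.full((2, 3), 7)
        df, groups = self._counts(control, control.copy())
        de = simple_de_test(df, groups)
        assert (de["pvalue"] == 1.0).all()


def _pairwise_auc(pvals, abs_lfc, y) -> float:
    """Oracle: explicit pairwise comparison of the (-p, |lfc|) key."""
    keys = list(zip([-p for p in pvals], abs_lfc))
    pos = [k for k, t in zip(keys, y) if t]
    neg = [k for k, t in zip(keys, y) if not t]
    total = 0.0
    for kp in pos:
        for kn in neg:
            total += 1.0 if kp > kn else (0.5 if kp == kn else 0.0)
    return total / (len(pos) * len(neg))


class TestDeMetrics:
    def test_perfect_separation_gives_auc_one(self):
        p = np.array([0.001, 0.002, 0.8, 0.9])
        y = np.array([True, True, False, False])
        assert ranking_auc(p, np.abs(np.zeros(4)), y) == 1.0

    def test_six_transcript_hand_enumeration(self):
        # positives at p=.01 (beats all) and p=.04 (beats 3 of 4): AUC = 7/8
        p = np.array([0.01, 0.2, 0.03, 0.5, 0.9, 0.04])
        y = np.array([True, False, False, False, False, True])
        auc = ranking_auc(p, np.zeros(6), y)
        assert auc == pytest.approx(7 / 8)

    def test_permuted_labels_give_chance_auc(self):
        rng = np.random.default_rng(4)
        p = rng.random(10_000)
        y = rng.random(10_000) < 0.3
        assert ranking_auc(p, np.zeros(10_000), y) == pytest.approx(0.5, abs=0.02)

    @pytest.mark.parametrize("seed", range(10))
    def test_rank_formula_equals_pairwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 100))
        p = np.round(rng.random(n), 2)  # rounding forces ties
        lfc = np.round(rng.normal(0, 2, n), 1)
        y = rng.random(n) < 0.4
        if y.all() or not y.any():
            return
        assert ranking_auc(p, np.abs(lfc), y) == pytest.approx(
            _pairwise_auc(p, np.abs(lfc), y), abs=1e-12
        )

    def test_true_de_definition_is_fold_change_magnitude(self):
        theta = pd.Series({"up": 2.0, "down": 0.5, "weak": 1.5, "none": 1.0})
        labels = true_de_labels(theta)
        assert labels["up"] and labels["down"]
        assert not labels["weak"] and not labels["none"]

    def test_confusion_counts_and_single_class_auc(self):
        de = pd.DataFrame(
            {
                "log2fc": [2.0, 0.1, -1.5],
                "pvalue": [0.001, 0.9, 0.01],
                "qvalue": [0.003, 0.9, 0.02],
                "call": [True, False, True],
            },
            index=["a", "b", "c"],
        )
        theta = pd.Series({"a": 4.0, "b": 1.0, "c": 1.0})
        m = de_metrics(de, theta, ["a", "b", "c"])
        assert (m["tp"], m["fp"], m["tn"], m["fn"]) == (1, 1, 1, 0)
        single = de_metrics(de, pd.Series({"a": 4.0, "b": 4.0, "c": 4.0}), ["a", "b", "c"])
        assert math.isnan(single["auc"])


class TestTercileGroups:
    def test_values_one_to_nine(self):
        values = pd.Series({f"i{v}": v for v in range(1, 10)})
        labels, bounds = tercile_groups(values)
        assert sorted(values[labels == "low"]) == [1, 2, 3]
        assert sorted(values[labels == "middle"]) == [4, 5, 6]
        assert sorted(values[labels == "high"]) == [7, 8, 9]
        assert bounds["low"] == (1, 3) and bounds["high"] == (7, 9)

    def test_n_ten_sizes_follow_ceiling_rule(self):
        values = pd.Series({f"i{v:02d}": v for v in range(10)})
        labels, _ = tercile_groups(values)
        assert labels.value_counts()[["low", "middle", "high"]].tolist() == [4, 3, 3]

    def test_all_equal_values_grouped_by_id_order(self):
        values = pd.Series(1.0, index=[f"i{v}" for v in range(6)])
        labels, _ = tercile_groups(values)
        assert (labels[["i0", "i1"]] == "low").all()
        assert (labels[["i4", "i5"]] == "high").all()

    def test_too_few_ids_rejected(self):
        with pytest.raises(ValueError):
            tercile_groups(pd.Series({"a": 1.0, "b": 2.0}))


class TestGroupedReport:
    @staticmethod
    def _setup(n=36, seed=5):
        rng = np.random.default_rng(seed)
        ids = [f"t{i:02d}" for i in range(n)]
        mu = rng.lognormal(4, 1, n)
        theta = np.where(rng.random(n) < 0.3, 2.0, 1.0)
        cols = {}
        for j in range(1, 4):
            cols[f"control_{j}"] = rng.poisson(mu)
            cols[f"case_{j}"] = rng.poisson(mu * theta)
        values = pd.DataFrame(cols, index=ids) + 1  # keep everything expressed
        groups = {c: ("Control" if c.startswith("control") else "Case") for c in values.columns}
        cm = CountMatrix(values=values, groups=groups, truth=pd.Series(theta, index=ids))
        mapp = pd.Series(rng.random(n), index=ids)
        return cm, mapp

    def test_overall_rows_match_direct_metric_computation(self):
        cm, mapp = self._setup()
        est = cm.values.astype(float)
        report = grouped_report(true_counts=cm, est_counts=est, mappability=mapp)
        kept = ground_truth_filter(cm, 0.25)
        true_log2 = np.log2(cm.cpm() + 1.0)
        est_log2 = cpm_transform(est, log2=True, prior=1.0)
        rho, err = quant_metrics(est_log2, true_log2, kept)
        assert report.value("quantification", "spearman_rho") == pytest.approx(rho)
        assert report.value("quantification", "nrmse") == pytest.approx(err)
        de = simple_de_test(est.loc[kept], cm.groups)
        direct = de_metrics(de, cm.truth, kept)
        assert report.value("de", "auc") == pytest.approx(direct["auc"])

    def test_perfect_estimates_give_perfect_quantification(self):
        cm, mapp = self._setup(seed=6)
        report = grouped_report(true_counts=cm, est_counts=cm.values.astype(float), mappability=mapp)
        assert report.value("quantification", "spearman_rho") == pytest.approx(1.0)
        assert report.value("quantification", "nrmse") == pytest.approx(0.0)

    def test_empty_cells_reported_as_missing_not_zero(self):
        cm, _ = self._setup(seed=7)
        # mappability perfectly ordered with mean abundance: DE facet cells
        # off the diagonal are empty and must come back NaN
        mean_cpm = cm.cpm().mean(axis=1)
        mapp = mean_cpm.rank() / len(mean_cpm)
        report = grouped_report(true_counts=cm, est_counts=cm.values.astype(float), mappability=mapp)
        t = report.table
        off_diag = t[
            (t.step == "de")
            & (t.metric == "auc")
            & (t.mappability_group == "low")
            & (t.abundance_group == "high")
        ]
        assert len(off_diag) == 1
        assert off_diag["n"].iloc[0] == 0
        assert math.isnan(off_diag["value"].iloc[0])
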