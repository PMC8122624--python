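"""Metrics, wrapper selection, and nested cross-validation."""

import json
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import fatiguemark as fm
from fatiguemark.classify import (
    ModelConfig,
    confusion_counts,
    fit_predict,
    point_biserial_r2,
)

from conftest import make_toy_table


class TestComputeMetrics:
    def test_hand_computed_example(self):
        m = fm.compute_metrics(tp=9, fp=1, tn=7, fn=3)
        assert m["precision"] == pytest.approx(0.9)
        assert m["sensitivity"] == pytest.approx(0.75)
        assert m["f1"] == pytest.approx(0.8182, abs=5e-5)

    def test_equal_precision_sensitivity_harmonic_mean(self):
        # precision = sensitivity = 0.8 -> F1 = 0.8
        m = fm.compute_metrics(tp=8, fp=2, tn=8, fn=2)
        assert m["precision"] == m["sensitivity"] == pytest.approx(0.8)
        assert m["f1"] == pytest.approx(0.8)

    def test_degenerate_specificity_flags_balanced_accuracy(self):
        m = fm.compute_metrics(tp=5, fp=0, tn=0, fn=2)
        assert math.isnan(m["specificity"])
        assert math.isnan(m["balanced_accuracy"])

    def test_f1_zero_when_rates_vanish(self):
        m = fm.compute_metrics(tp=0, fp=3, tn=5, fn=4)
        assert m["f1"] == 0.0

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            fm.compute_metrics(-1, 0, 0, 2)
        with pytest.raises(ValueError):
            fm.compute_metrics(0, 0, 0, 0)

    @given(st.integers(0, 200), st.integers(0, 200),
           st.integers(0, 200), st.integers(0, 200))
    def test_identities_hold(self, tp, fp, tn, fn):
        if tp + fp + tn + fn == 0:
            return
        m = fm.compute_metrics(tp, fp, tn, fn)
        for v in m.values():
            assert math.isnan(v) or 0.0 <= v <= 1.0
        if not math.isnan(m["balanced_accuracy"]):
            assert m["balanced_accuracy"] == pytest.approx(
                (m["sensitivity"] + m["specificity"]) / 2, abs=1e-12
            )
        if not (math.isnan(m["precision"]) or math.isnan(m["sensitivity"])):
            p, s = m["precision"], m["sensitivity"]
            expect = 0.0 if p + s == 0 else 2 * p * s / (p + s)
            assert m["f1"] == pytest.approx(expect, abs=1e-12)


class TestAllPositiveBaseline:
    def test_reported_unbalanced_case(self):
        # mean trial counts 202 correct / 518 incorrect -> 84%
        assert 100 * fm.all_positive_baseline(518, 202) == pytest.approx(83.68, abs=0.01)

    def test_balanced_case_from_mean_counts(self):
        assert fm.all_positive_baseline(270, 254) == pytest.approx(540 / 794)

    def test_no_negatives_gives_one(self):
        assert fm.all_positive_baseline(10, 0) == 1.0

    def test_needs_a_positive(self):
        with pytest.raises(ValueError):
            fm.all_positive_baseline(0, 10)


class TestWrapperSelect:
    def test_separating_feature_selected_first(self):
        table = make_toy_table(n_trials=80, n_noise=12, separation=6.0, seed=1)
        X = table.values.to_numpy(float)
        res = fm.wrapper_select(X, table.labels, table.feature_names, k_max=3)
        assert res.selected[0] == "delta.LO"

    def test_selection_curve_envelope_non_decreasing(self):
        table = make_toy_table(n_trials=80, n_noise=10, seed=2)
        X = table.values.to_numpy(float)
        res = fm.wrapper_select(X, table.labels, table.feature_names, k_max=6)
        env = np.maximum.accumulate(res.curve)
        assert all(b >= a for a, b in zip(env, env[1:]))
        assert len(res.selected) <= len(res.picks)

    def test_k_max_validation(self):
        table = make_toy_table(n_trials=40, n_noise=4)
        with pytest.raises(ValueError):
            fm.wrapper_select(
                table.values.to_numpy(float), table.labels,
                table.feature_names, k_max=0,
            )

    def test_deterministic(self):
        table = make_toy_table(n_trials=60, n_noise=10, seed=3)
        X = table.values.to_numpy(float)
        a = fm.wrapper_select(X, table.labels, table.feature_names, k_max=4, seed=5)
        b = fm.wrapper_select(X, table.labels, table.feature_names, k_max=4, seed=5)
        assert a.selected == b.selected and a.curve == b.curve

    def test_screening_keeps_informative_column(self):
        table = make_toy_table(n_trials=80, n_noise=40, separation=6.0, seed=4)
        X = table.values.to_numpy(float)
        res = fm.wrapper_select(
            X, table.labels, table.feature_names, k_max=3, screen_top_m=5
        )
        assert res.selected[0] == "delta.LO"


class TestStumpOracle:
    def test_single_tree_depth_one_equals_best_threshold_stump(self):
        """One depth-1 tree on one separable feature = the exhaustive-scan
        decision stump."""
        rng = np.random.default_rng(6)
        x = np.concatenate([rng.normal(-2, 0.5, 40), rng.normal(2, 0.5, 40)])
        y = np.repeat([0, 1], 40)
        idx = rng.permutation(80)
        x, y = x[idx], y[idx]
        cfg = ModelConfig(n_trees=1, max_depth=1, base_score=0.5)
        pred = fit_predict(x[:, None], y, x[:, None], cfg)

        # independent oracle: scan all midpoints for best training accuracy
        order = np.argsort(x)
        xs, ys = x[order], y[order]
        best_acc, best_thr, best_sign = -1.0, None, 1
        for i in range(len(xs) - 1):
            thr = (xs[i] + xs[i + 1]) / 2
            for sign in (1, -1):
                acc = np.mean(((x > thr).astype(int) if sign == 1
                               else (x <= thr).astype(int)) == y)
                if acc > best_acc:
                    best_acc, best_thr, best_sign = acc, thr, sign
        oracle = (x > best_thr).astype(int) if best_sign == 1 else (x <= best_thr).astype(int)
        np.testing.assert_array_equal(pred, oracle)


class TestNestedCV:
    def test_informative_table_beats_baseline(self):
        table = make_toy_table(n_trials=120, n_noise=12, separation=3.0, seed=7)
        rep = fm.nested_cv_evaluate(table, condition="combined", k_max=3, seed=0)
        assert rep.pooled["f1"] > rep.baseline_f1
        assert rep.n_trials == 120

    def test_report_is_deterministic_json(self):
        table = make_toy_table(n_trials=80, n_noise=8, seed=8)
        a = fm.nested_cv_evaluate(table, k_max=2, seed=1).to_json()
        b = fm.nested_cv_evaluate(table, k_max=2, seed=1).to_json()
        assert a == b
        payload = json.loads(a)
        assert payload["audit"]["folds"][0]["train_hash"]

    def test_outer_folds_disjoint_and_cover(self):
        table = make_toy_table(n_trials=100, n_noise=8, seed=9)
        rep = fm.nested_cv_evaluate(table, k_max=2, seed=0)
        sizes = [f["n_test"] for f in rep.audit["folds"]]
        assert sum(sizes) == 100
        hashes = {f["test_hash"] for f in rep.audit["folds"]}
        assert len(hashes) == 5

    def test_duplicated_columns_do_not_change_metrics(self):
        table = make_toy_table(n_trials=100, n_noise=8, separation=4.0, seed=10)
        dup = table.values.copy()
        registry = dict(table.registry)
        for c in list(dup.columns):
            dup[c + ".copy"] = dup[c]
            registry[c + ".copy"] = registry[c]
        from fatiguemark.biomarkers import FeatureTable

        table2 = FeatureTable(values=dup, labels=table.labels.copy(), registry=registry)
        r1 = fm.nested_cv_evaluate(table, k_max=3, seed=0)
        r2 = fm.nested_cv_evaluate(table2, k_max=3, seed=0)
        assert r1.pooled == r2.pooled

    def test_too_few_trials_advises_more_data(self):
        table = make_toy_table(n_trials=20, n_noise=6)
        with pytest.raises(ValueError, match="more data"):
            fm.nested_cv_evaluate(table, k_max=2)

    def test_imputation_uses_training_folds_only(self):
        table = make_toy_table(n_trials=100, n_noise=8, separation=4.0, seed=11)
        vals = table.values.copy()
        vals.iloc[::7, 0] = np.nan  # degrade the informative column
        from fatiguemark.biomarkers import FeatureTable

        nan_table = FeatureTable(
            values=vals, labels=table.labels.copy(), registry=dict(table.registry)
        )
        rep = fm.nested_cv_evaluate(nan_table, k_max=3, seed=0)
        assert rep.pooled["f1"] > rep.baseline_f1  # still learnable


class TestSingleChannelEvaluation:
    def test_per_channel_f1_covers_all_electrodes(self, small_table):
        out = fm.single_channel_evaluation(small_table, k_max=2, seed=0)
        assert len(out) == 10
        for f1 in out.values():
            assert 0.0 <= f1 <= 1.0


class TestPointBiserial:
    def test_matches_numpy_corrcoef(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(60, 4))
        y = rng.integers(0, 2, 60)
        r2 = point_biserial_r2(X, y)
        for j in range(4):
            expect = np.corrcoef(X[:, j], y)[0, 1] ** 2
            assert r2[j] == pytest.approx(expect, abs=1e-12)

    def test_constant_column_scores_zero(self):
        X = np.ones((30, 2))
        y = np.arange(30) % 2
        assert point_biserial_r2(X, y).tolist() == [0.0, 0.0]


def test_confusion_counts_total():
    rng = np.random.default_rng(13)
    y = rng.integers(0, 2, 50)
    p = rng.integers(0, 2, 50)
    tp, fp, tn, fn = confusion_counts(y, p)
    assert tp + fp + tn + fn == 50
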