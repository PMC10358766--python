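"""Composite loss, metrics, fold construction and the CV/ablation runners."""

import json
import warnings

import numpy as np
import pandas as pd
import pytest

from stt_eeg.autograd import Tensor
from stt_eeg.errors import ConfigError, DataError
from stt_eeg.model import ModelConfig, SttModel, SttOutputs
from stt_eeg.train import (
    AMSGrad,
    ConfusionCounts,
    TrainConfig,
    ablation_grid,
    composite_loss,
    compute_metrics,
    confusion_counts,
    evaluate,
    groups_to_batch,
    kfold_split,
    label_to_index,
    macro_metrics,
    run_cv,
    train_model,
)

from conftest import make_dummy_groups


def outputs_from(ys, yt, y=None):
    ys, yt = np.asarray(ys, float), np.asarray(yt, float)
    y = ys + yt if y is None else np.asarray(y, float)
    return SttOutputs(Tensor(ys, requires_grad=True),
                      Tensor(yt, requires_grad=True),
                      Tensor(y, requires_grad=True))


class TestCompositeLoss:
    @staticmethod
    def logits_with_ce(ce):
        """One-sample binary logits whose cross entropy is exactly `ce`."""
        p = np.exp(-ce)
        return [[np.log(p), np.log1p(-p)]]

    def test_weighted_arithmetic(self):
        outs = outputs_from(self.logits_with_ce(2.0), self.logits_with_ce(1.0))
        loss = composite_loss(outs, np.array([0]), alpha=0.3,
                              fused_loss_weight=0.0)
        assert float(loss.data) == pytest.approx(0.3 * 2.0 + 0.7 * 1.0, rel=1e-5)

    def test_affine_in_alpha(self):
        rng = np.random.default_rng(0)
        ys, yt = rng.standard_normal((2, 6, 3))
        labels = np.array([0, 1, 2, 1, 0, 2])
        vals = [
            float(composite_loss(outputs_from(ys, yt), labels, a,
                                 fused_loss_weight=0.0).data)
            for a in (0.0, 0.5, 1.0)
        ]
        assert vals[1] == pytest.approx((vals[0] + vals[2]) / 2, abs=1e-10)

    def test_alpha_one_sends_no_gradient_to_temporal(self):
        rng = np.random.default_rng(1)
        outs = outputs_from(rng.standard_normal((4, 2)),
                            rng.standard_normal((4, 2)))
        loss = composite_loss(outs, np.array([0, 1, 0, 1]), alpha=1.0,
                              fused_loss_weight=0.0)
        loss.backward()
        assert outs.y_temporal.grad is None or np.all(outs.y_temporal.grad == 0)
        assert np.any(outs.y_spatial.grad != 0)

    def test_alpha_out_of_range_rejected(self):
        outs = outputs_from([[0.0, 1.0]], [[0.0, 1.0]])
        with pytest.raises(ConfigError):
            composite_loss(outs, np.array([0]), alpha=1.2)


class TestMetrics:
    def test_textbook_counts(self):
        sens, spec, acc = compute_metrics(ConfusionCounts(95, 5, 90, 10))
        assert (sens, spec, acc) == (0.95, 0.90, 0.925)

    def test_perfect_classifier(self):
        assert compute_metrics(ConfusionCounts(10, 0, 10, 0)) == (1.0, 1.0, 1.0)

    def test_zero_denominator_is_nan_with_warning(self):
        with pytest.warns(RuntimeWarning, match="sensitivity"):
            sens, spec, acc = compute_metrics(ConfusionCounts(0, 0, 5, 5))
        assert np.isnan(sens)
        assert spec == 0.5

    def test_macro_metrics_match_bruteforce_recount(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            y_true = rng.integers(0, 3, 60)
            y_pred = rng.integers(0, 3, 60)
            sens, spec, acc = macro_metrics(y_true, y_pred, 3)
            # independent recount: explicit loops per class
            s_list, p_list = [], []
            for c in range(3):
                tp = sum(1 for t, p in zip(y_true, y_pred) if t == c and p == c)
                fn = sum(1 for t, p in zip(y_true, y_pred) if t == c and p != c)
                tn = sum(1 for t, p in zip(y_true, y_pred) if t != c and p != c)
                fp = sum(1 for t, p in zip(y_true, y_pred) if t != c and p == c)
                s_list.append(tp / (tp + fn))
                p_list.append(tn / (tn + fp))
            assert sens == pytest.approx(np.mean(s_list))
            assert spec == pytest.approx(np.mean(p_list))
            assert acc == pytest.approx(np.mean(y_true == y_pred))

    def test_swapping_positive_class_swaps_sensitivity_specificity(self):
        rng = np.random.default_rng(3)
        y_true = rng.integers(0, 2, 80)
        y_pred = rng.integers(0, 2, 80)
        c0, c1 = confusion_counts(y_true, y_pred, 2)
        s0, p0, a0 = compute_metrics(c0)
        s1, p1, a1 = compute_metrics(c1)
        assert (s0, p0) == (p1, s1)
        assert a0 == a1

    def test_counts_partition_the_sample(self):
        rng = np.random.default_rng(4)
        y_true = rng.integers(0, 3, 45)
        y_pred = rng.integers(0, 3, 45)
        for c in confusion_counts(y_true, y_pred, 3):
            assert c.n == 45


class TestKFold:
    def test_ten_equal_test_sets(self):
        groups = make_dummy_groups(50)  # 100 groups, two labels
        splits = kfold_split(groups, k=10, seed=0)
        assert all(len(test) == 10 for _, test in splits)

    def test_test_sets_partition_all_groups(self):
        groups = make_dummy_groups(30)
        splits = kfold_split(groups, k=10, seed=1)
        seen = sorted(i for _, test in splits for i in test)
        assert seen == list(range(len(groups)))
        for train, test in splits:
            assert set(train).isdisjoint(test)
            assert len(train) + len(test) == len(groups)

    def test_stratification_balances_labels_per_fold(self):
        groups = make_dummy_groups(120)  # 240 binary groups
        labels = np.array([g.label for g in groups])
        for _, test in kfold_split(groups, k=10, seed=2):
            assert np.sum(labels[test] == 1) == 12
            assert np.sum(labels[test] == -1) == 12

    def test_subject_wise_split_keeps_subjects_whole(self):
        groups = make_dummy_groups(20, n_subjects=4)
        splits = kfold_split(groups, k=4, seed=0, subject_wise=True)
        for train, test in splits:
            tr = {groups[i].subject_id for i in train}
            te = {groups[i].subject_id for i in test}
            assert tr.isdisjoint(te)

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(DataError):
            kfold_split(make_dummy_groups(2), k=10)


class TestTraining:
    def test_amsgrad_second_moment_never_decreases(self):
        p = {"w": Tensor(np.zeros(3), requires_grad=True)}
        opt = AMSGrad(p, lr=0.1)
        p["w"].grad = np.array([1.0, -2.0, 0.5], dtype=np.float32)
        opt.step()
        vhat1 = opt.vhat["w"].copy()
        p["w"].grad = np.array([0.1, 0.1, 0.1], dtype=np.float32)
        opt.step()
        assert np.all(opt.vhat["w"] >= vhat1)

    def test_loss_decreases_on_separable_data(self, tiny_corpus_groups):
        groups = tiny_corpus_groups
        y, _ = label_to_index(g.label for g in groups)
        batch = groups_to_batch(groups)
        cfg = ModelConfig(n_classes=3, D=16, L=1, n_heads=2, seed=0)
        model = SttModel(cfg)
        hist = train_model(model, batch, y,
                           TrainConfig(max_epochs=8, batch_size=8, seed=0))
        assert hist[-1] < hist[0]

    def test_validation_checkpointing_restores_best(self, tiny_corpus_groups):
        groups = tiny_corpus_groups
        y, _ = label_to_index(g.label for g in groups)
        batch = groups_to_batch(groups)
        cfg = ModelConfig(n_classes=3, D=16, L=1, n_heads=2, seed=0)
        m1 = SttModel(cfg)
        train_model(m1, batch, y, TrainConfig(max_epochs=3, batch_size=8,
                                              seed=0, val_fraction=0.2))
        # deterministic: rerunning reproduces the checkpointed parameters
        m2 = SttModel(cfg)
        train_model(m2, batch, y, TrainConfig(max_epochs=3, batch_size=8,
                                              seed=0, val_fraction=0.2))
        for k in m1.params:
            np.testing.assert_array_equal(m1.params[k].data, m2.params[k].data)


@pytest.fixture(scope="module")
def quick_setup(tiny_corpus_groups):
    cfg = ModelConfig(n_classes=3, D=16, L=1, n_heads=2, seed=0)
    tc = TrainConfig(max_epochs=4, batch_size=8, seed=0)
    return tiny_corpus_groups, cfg, tc


class TestRunners:
    def test_report_structure_and_fold_conservation(self, quick_setup):
        groups, cfg, tc = quick_setup
        rep = run_cv(groups, cfg, tc, k=2)
        assert len(rep.per_fold) == 2
        assert set(rep.aggregate) == {"combined", "spatial", "temporal"}
        for triple in rep.aggregate.values():
            assert all(0.0 <= v <= 1.0 for v in triple)
        agg = np.mean([f["combined"] for f in rep.per_fold], axis=0)
        np.testing.assert_allclose(agg, rep.aggregate["combined"])

    def test_report_json_roundtrip(self, quick_setup, tmp_path):
        groups, cfg, tc = quick_setup
        rep = run_cv(groups, cfg, tc, k=2)
        path = tmp_path / "report.json"
        rep.save(path)
        loaded = json.loads(path.read_text())
        assert loaded["aggregate"]["combined"] == rep.aggregate["combined"]

    def test_single_cell_grid_matches_run_cv(self, quick_setup):
        groups, cfg, tc = quick_setup
        rep = run_cv(groups, cfg, tc, k=2, split_seed=tc.seed)
        table = ablation_grid(groups, [cfg.n_heads], [cfg.L], cfg, tc, k=2)
        assert len(table) == 1
        assert table.accuracy.iloc[0] == pytest.approx(rep.accuracy())

    def test_grid_resumes_from_completed_cells(self, quick_setup):
        groups, cfg, tc = quick_setup
        done = pd.DataFrame([{"model": "STT_2_1", "n_heads": 2,
                              "n_layers": 1, "accuracy": 0.123}])
        table = ablation_grid(groups, [2], [1, 2], cfg, tc, k=2, done=done)
        assert len(table) == 2
        row = table[(table.n_heads == 2) & (table.n_layers == 1)]
        assert row.accuracy.iloc[0] == 0.123  # copied, not recomputed

    def test_too_few_groups_per_class_rejected(self, quick_setup):
        groups, cfg, tc = quick_setup
        with pytest.raises(DataError):
            run_cv(groups[:6], cfg, tc, k=5)
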