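"""Grouped cross-validation, training plumbing, and evaluation contracts."""

import numpy as np
import pytest

from dualgait.classifier import (
    DualBranchCNNLSTM,
    FoldModel,
    ModelConfig,
    apply_class_scheme,
    build_and_train,
    evaluate,
    grouped_folds,
)
from dualgait.preprocessing import WindowSet


class TestGroupedFolds:
    def _subjects(self, n=60, n_classes=4):
        subs = [f"S{i:03d}" for i in range(n)]
        labels = [f"c{i % n_classes}" for i in range(n)]
        return subs, labels

    def test_partition_contract(self):
        subs, labels = self._subjects()
        plan = grouped_folds(subs, labels, n_folds=5, seed=0)
        for k in range(5):
            assert len(plan.test_subjects[k]) == 12
            assert not (set(plan.train_subjects[k]) & set(plan.test_subjects[k]))
            assert not (set(plan.val_subjects[k]) & set(plan.test_subjects[k]))

    def test_every_subject_in_exactly_one_test_fold(self):
        subs, labels = self._subjects()
        plan = grouped_folds(subs, labels, n_folds=5, seed=0)
        seen = [s for fold in plan.test_subjects for s in fold]
        assert sorted(seen) == sorted(subs)

    def test_order_invariance_and_seed_dependence(self):
        subs, labels = self._subjects()
        plan_a = grouped_folds(subs, labels, n_folds=5, seed=1)
        order = np.random.default_rng(0).permutation(len(subs))
        plan_b = grouped_folds(
            [subs[i] for i in order], [labels[i] for i in order], n_folds=5, seed=1
        )
        assert plan_a.test_subjects == plan_b.test_subjects
        plan_c = grouped_folds(subs, labels, n_folds=5, seed=2)
        assert plan_a.test_subjects != plan_c.test_subjects

    def test_small_class_warns(self):
        subs = [f"S{i}" for i in range(10)]
        labels = ["a"] * 8 + ["b"] * 2
        with pytest.warns(UserWarning, match="fewer subjects"):
            grouped_folds(subs, labels, n_folds=5, seed=0)

    def test_no_leakage_on_random_cohorts(self):
        """Zero train/test subject overlap across 1,000 random cohorts."""
        rng = np.random.default_rng(0)
        for trial in range(1000):
            n = int(rng.integers(10, 40))
            n_folds = int(rng.integers(2, min(n, 8)))
            subs = [f"S{i}" for i in range(n)]
            labels = [f"c{rng.integers(0, 3)}" for _ in range(n)]
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                plan = grouped_folds(subs, labels, n_folds=n_folds, seed=trial)
            covered = []
            for k in range(n_folds):
                tr = set(plan.train_subjects[k]) | set(plan.val_subjects[k])
                te = set(plan.test_subjects[k])
                assert not (tr & te)
                covered.extend(te)
            assert sorted(covered) == sorted(subs)


class TestClassScheme:
    def test_six_to_three(self):
        labels = np.array(
            ["healthy", "hemi_left", "hemi_right", "pd_td", "pd_ar", "pd_pigd"],
            dtype=object,
        )
        out = apply_class_scheme(labels, "three")
        assert list(out) == ["healthy", "stroke", "stroke", "pd", "pd", "pd"]

    def test_six_to_four(self):
        labels = np.array(["healthy", "hemi_left", "pd_td", "pd_pigd"], dtype=object)
        out = apply_class_scheme(labels, "four")
        assert list(out) == ["healthy", "hemi_left", "pd", "pd"]


def _stub_windowset(n_subjects=6, per_subject=4, n_classes=2, seed=0):
    rng = np.random.default_rng(seed)
    data, subs, labels = [], [], []
    for i in range(n_subjects):
        label = f"c{i % n_classes}"
        for _ in range(per_subject):
            data.append(rng.normal(size=(4, 20)))
            subs.append(f"S{i}")
            labels.append(label)
    n = len(data)
    return WindowSet(
        np.stack(data),
        np.array(subs, dtype=object),
        np.array(labels, dtype=object),
        np.array([f"w{i}" for i in range(n)], dtype=object),
        np.zeros(n, dtype=bool),
    )


class _PerfectStub:
    """Predicts the true class, via a lookup captured at construction."""

    def __init__(self, windows, classes, scheme="six"):
        self.config = ModelConfig(class_scheme=scheme)
        self._lookup = {
            tuple(np.round(windows.data[i, 0, :3], 6)): classes.index(
                windows.labels[i]
            )
            for i in range(len(windows))
        }

    def predict(self, x):
        return np.array([self._lookup[tuple(np.round(r[0, :3], 6))] for r in x])


class _ConstantStub:
    def __init__(self, k, scheme="six"):
        self.config = ModelConfig(class_scheme=scheme)
        self._k = k

    def predict(self, x):
        return np.full(x.shape[0], self._k, dtype=int)


class TestEvaluate:
    def _plan_and_windows(self):
        ws = _stub_windowset()
        subs = sorted(set(ws.subject_ids))
        labels = [ws.labels[list(ws.subject_ids).index(s)] for s in subs]
        plan = grouped_folds(subs, labels, n_folds=2, seed=0)
        return ws, plan

    def test_perfect_stub_identity_confusion(self):
        ws, plan = self._plan_and_windows()
        classes = sorted(set(ws.labels))
        models = [
            FoldModel(
                model=_PerfectStub(ws, classes),
                classes=classes,
                train_subjects=set(plan.train_subjects[k])
                | set(plan.val_subjects[k]),
                val_subjects=set(plan.val_subjects[k]),
            )
            for k in range(plan.n_folds)
        ]
        res = evaluate(models, ws, plan, "fused")
        assert res.accuracy_pct == pytest.approx(100.0)
        off_diag = res.confusion - np.diag(np.diag(res.confusion))
        assert off_diag.sum() == 0

    def test_constant_stub_accuracy_equals_prevalence(self):
        ws, plan = self._plan_and_windows()
        classes = sorted(set(ws.labels))
        models = [
            FoldModel(
                model=_ConstantStub(0),
                classes=classes,
                train_subjects=set(plan.train_subjects[k])
                | set(plan.val_subjects[k]),
                val_subjects=set(plan.val_subjects[k]),
            )
            for k in range(plan.n_folds)
        ]
        res = evaluate(models, ws, plan, "fused")
        prevalence = 100.0 * np.mean(ws.labels == classes[0])
        assert res.accuracy_pct == pytest.approx(prevalence)

    def test_accuracy_consistent_with_confusion(self):
        ws, plan = self._plan_and_windows()
        classes = sorted(set(ws.labels))
        models = [
            FoldModel(
                model=_ConstantStub(1),
                classes=classes,
                train_subjects=set(plan.train_subjects[k])
                | set(plan.val_subjects[k]),
                val_subjects=set(plan.val_subjects[k]),
            )
            for k in range(plan.n_folds)
        ]
        res = evaluate(models, ws, plan, "fused")
        assert res.accuracy_pct == pytest.approx(
            100.0 * np.trace(res.confusion) / res.confusion.sum()
        )

    def test_leakage_detected(self):
        ws, plan = self._plan_and_windows()
        classes = sorted(set(ws.labels))
        models = [
            FoldModel(
                model=_ConstantStub(0),
                classes=classes,
                train_subjects=set(plan.test_subjects[k]),  # deliberate leak
                val_subjects=set(),
            )
            for k in range(plan.n_folds)
        ]
        with pytest.raises(RuntimeError, match="leakage"):
            evaluate(models, ws, plan, "fused")


class TestTraining:
    def test_loss_decreases_over_first_epochs(self, small_separable_windows):
        windows, manifest = small_separable_windows
        plan = grouped_folds(
            manifest["subject_id"], manifest["class_label"], n_folds=2, seed=0
        )
        cfg = ModelConfig.compact(max_epochs=5, early_stop_patience=5)
        models = build_and_train(windows, plan, cfg, "fused", seed=0)
        hist = models[0].history
        assert hist[-1]["train_loss"] < hist[0]["train_loss"]

    def test_reproducible_under_seed(self, small_separable_windows):
        windows, manifest = small_separable_windows
        plan = grouped_folds(
            manifest["subject_id"], manifest["class_label"], n_folds=2, seed=0
        )
        cfg = ModelConfig.compact(max_epochs=4, early_stop_patience=4)
        res_a = evaluate(
            build_and_train(windows, plan, cfg, "fused", seed=5), windows, plan, "fused"
        )
        res_b = evaluate(
            build_and_train(windows, plan, cfg, "fused", seed=5), windows, plan, "fused"
        )
        assert abs(res_a.accuracy_pct - res_b.accuracy_pct) <= 0.5

    def test_forward_shapes_per_modality(self):
        cfg = ModelConfig.compact()
        for modality, n_ch in [("fused", 4), ("plantar_only", 1), ("strain_only", 3)]:
            model = DualBranchCNNLSTM(cfg, 3, modality, seed=0)
            x = np.random.default_rng(0).normal(size=(2, n_ch, 300))
            logits = model.forward(x)
            assert logits.shape == (2, 3)
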