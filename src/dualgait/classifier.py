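"""Dual-branch CNN-LSTM gait-disorder classifier with subject-wise CV.

Architecture: the plantar-pressure channel passes through two convolutional
blocks (conv -> batch-norm -> ReLU -> max-pool); the three muscle-strain
channels pass through a three-layer convolutional stack (pooled to the same
temporal length).  The branch outputs are concatenated along the channel
axis, an LSTM summarizes the temporal dynamics, and a dropout-regularized
fully connected layer with softmax produces class probabilities.  Training
uses Adam with stepwise learning-rate halving, L2 weight decay, and early
stopping on an inner subject-wise validation split.

Evaluation is strictly subject-wise: every subject's windows (including
augmented copies, which inherit the subject ID) live in exactly one split,
and `evaluate` hard-fails if any held-out subject was seen in training.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from . import nn
from .preprocessing import WindowSet, augment_windowset

__all__ = [
    "ModelConfig",
    "FoldPlan",
    "EvalResult",
    "DualBranchCNNLSTM",
    "grouped_folds",
    "build_and_train",
    "evaluate",
    "modality_ablation",
    "apply_class_scheme",
]

MODALITY_CHANNELS = {
    "plantar_only": (0,),
    "strain_only": (1, 2, 3),
    "fused": (0, 1, 2, 3),
}


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the dual-branch CNN-LSTM."""

    plantar_channels: tuple = (16, 32)
    strain_channels: tuple = (16, 32, 64)
    kernel: int = 5
    lstm_hidden: int = 64
    dropout_rate: float = 0.3
    weight_decay: float = 1e-4
    learning_rate: float = 1e-3
    lr_decay_every: int = 20          # epochs between halvings
    max_epochs: int = 100
    early_stop_patience: int = 10
    batch_size: int = 32
    augment_copies: int = 1           # augmented copies per training window
    class_scheme: str = "six"         # six | four | three

    def __post_init__(self) -> None:
        if self.kernel % 2 == 0:
            raise ValueError("kernel size must be odd")
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout must lie in [0, 1)")
        if self.lstm_hidden <= 0:
            raise ValueError("lstm_hidden must be positive")

    @classmethod
    def compact(cls, **overrides) -> "ModelConfig":
        """A desk-scale configuration that trains in seconds per fold."""
        base = dict(
            plantar_channels=(8, 16),
            strain_channels=(8, 16, 32),
            lstm_hidden=32,
            max_epochs=25,
            early_stop_patience=6,
            lr_decay_every=10,
            augment_copies=1,
        )
        base.update(overrides)
        return cls(**base)


def apply_class_scheme(labels: np.ndarray, scheme: str) -> np.ndarray:
    """Coarsen 6-group labels to 4 (merge PD subtypes) or 3 (merge stroke sides)."""
    labels = np.asarray(labels, dtype=object)
    if scheme == "six":
        return labels
    out = labels.copy()
    if scheme in ("four", "three"):
        out = np.where([str(v).startswith("pd") for v in out], "pd", out)
    if scheme == "three":
        out = np.where([str(v).startswith("hemi") for v in out], "stroke", out)
    if scheme not in ("four", "three"):
        raise ValueError("class_scheme must be 'six', 'four' or 'three'")
    return out.astype(object)


@dataclass
class FoldPlan:
    """Subject-level fold assignments for grouped cross-validation."""

    test_subjects: List[List[str]]        # per fold
    val_subjects: List[List[str]]         # inner early-stopping split, per fold
    train_subjects: List[List[str]]       # per fold (excludes val and test)

    @property
    def n_folds(self) -> int:
        return len(self.test_subjects)

    def validate(self) -> None:
        all_test: List[str] = []
        for k in range(self.n_folds):
            tr, va, te = (
                set(self.train_subjects[k]),
                set(self.val_subjects[k]),
                set(self.test_subjects[k]),
            )
            if tr & te or va & te or tr & va:
                raise ValueError(f"fold {k}: overlapping subject splits")
            all_test.extend(te)
        if len(all_test) != len(set(all_test)):
            raise ValueError("a subject appears in more than one test fold")


def grouped_folds(
    subject_ids: Sequence[str],
    labels: Sequence[str],
    n_folds: int = 5,
    seed: int = 0,
    val_per_class: int = 1,
) -> FoldPlan:
    """Stratified-by-class round-robin assignment of subjects to test folds.

    Deterministic under ``seed`` and independent of input ordering.  Each
    fold's inner validation split takes ``val_per_class`` training subjects
    per class for early stopping, leaving the test fold untouched.
    """
    subj_label: Dict[str, str] = {}
    for s, lab in zip(subject_ids, labels):
        if s in subj_label and subj_label[s] != lab:
            raise ValueError(f"subject {s} has conflicting labels")
        subj_label[s] = lab
    subjects = sorted(subj_label)
    if n_folds > len(subjects):
        raise ValueError("more folds than subjects")
    rng = np.random.default_rng(seed)

    fold_test: List[List[str]] = [[] for _ in range(n_folds)]
    offset = 0
    for lab in sorted(set(subj_label.values())):
        members = [s for s in subjects if subj_label[s] == lab]
        if len(members) < n_folds:
            warnings.warn(
                f"class {lab!r} has fewer subjects ({len(members)}) than folds "
                f"({n_folds}); best-effort stratification",
                stacklevel=2,
            )
        members = list(rng.permutation(members))
        for i, s in enumerate(members):
            fold_test[(i + offset) % n_folds].append(s)
        offset += len(members)  # rotate start fold to balance sizes

    fold_val: List[List[str]] = []
    fold_train: List[List[str]] = []
    for k in range(n_folds):
        test = set(fold_test[k])
        pool = [s for s in subjects if s not in test]
        val: List[str] = []
        for lab in sorted(set(subj_label.values())):
            members = [s for s in pool if subj_label[s] == lab]
            members = list(rng.permutation(members))
            val.extend(members[:val_per_class])
        val_set = set(val)
        fold_val.append(sorted(val_set))
        fold_train.append(sorted(s for s in pool if s not in val_set))
    plan = FoldPlan(fold_test, fold_val, fold_train)
    plan.validate()
    return plan


class DualBranchCNNLSTM:
    """The two-branch convolutional front end with an LSTM head."""

    def __init__(
        self,
        config: ModelConfig,
        n_classes: int,
        modality: str = "fused",
        seed: int = 0,
    ):
        if modality not in MODALITY_CHANNELS:
            raise ValueError(f"modality must be one of {sorted(MODALITY_CHANNELS)}")
        self.config = config
        self.modality = modality
        self.n_classes = n_classes
        rng = np.random.default_rng(seed)
        k = config.kernel

        self.plantar_branch: Optional[nn.Sequential] = None
        self.strain_branch: Optional[nn.Sequential] = None
        feat = 0
        if modality in ("plantar_only", "fused"):
            c1, c2 = config.plantar_channels
            self.plantar_branch = nn.Sequential(
                [
                    nn.Conv1d(1, c1, k, rng),
                    nn.BatchNorm1d(c1),
                    nn.ReLU(),
                    nn.MaxPool1d(2),
                    nn.Conv1d(c1, c2, k, rng),
                    nn.BatchNorm1d(c2),
                    nn.ReLU(),
                    nn.MaxPool1d(2),
                ]
            )
            feat += c2
        if modality in ("strain_only", "fused"):
            s1, s2, s3 = config.strain_channels
            self.strain_branch = nn.Sequential(
                [
                    nn.Conv1d(3, s1, k, rng),
                    nn.ReLU(),
                    nn.MaxPool1d(2),
                    nn.Conv1d(s1, s2, k, rng),
                    nn.ReLU(),
                    nn.MaxPool1d(2),
                    nn.Conv1d(s2, s3, k, rng),
                    nn.ReLU(),
                ]
            )
            feat += s3

        self.lstm = nn.LSTM(feat, config.lstm_hidden, rng)
        self.dropout = nn.Dropout(config.dropout_rate, rng)
        self.head = nn.Dense(config.lstm_hidden, n_classes, rng)
        self._feat_split = (
            config.plantar_channels[-1] if self.plantar_branch is not None else 0
        )

    # -- parameter plumbing -------------------------------------------------
    def _modules(self):
        mods = []
        if self.plantar_branch is not None:
            mods.append(self.plantar_branch)
        if self.strain_branch is not None:
            mods.append(self.strain_branch)
        mods.extend([self.lstm, self.head])
        return mods

    def params(self):
        return [p for m in self._modules() for p in m.params()]

    def grads(self):
        return [g for m in self._modules() for g in m.grads()]

    def state(self):
        return copy.deepcopy([p.copy() for p in self.params()])

    def load_state(self, state):
        for p, s in zip(self.params(), state):
            p[...] = s

    # -- forward/backward ---------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits for windows ``x`` of shape (N, n_channels, L).

        Channel layout follows the modality: fused expects 4 channels
        (plantar first), plantar_only 1, strain_only 3.
        """
        pieces = []
        if self.modality == "fused":
            pieces.append(self.plantar_branch.forward(x[:, :1], train))
            pieces.append(self.strain_branch.forward(x[:, 1:], train))
        elif self.modality == "plantar_only":
            pieces.append(self.plantar_branch.forward(x, train))
        else:
            pieces.append(self.strain_branch.forward(x, train))
        z = pieces[0] if len(pieces) == 1 else np.concatenate(pieces, axis=1)
        seq = np.transpose(z, (0, 2, 1))  # (N, T, F)
        h = self.lstm.forward(seq, train)
        h = self.dropout.forward(h, train)
        return self.head.forward(h, train)

    def backward(self, dlogits: np.ndarray) -> None:
        dh = self.head.backward(dlogits)
        dh = self.dropout.backward(dh)
        dseq = self.lstm.backward(dh)
        dz = np.transpose(dseq, (0, 2, 1))
        if self.modality == "fused":
            self.plantar_branch.backward(dz[:, : self._feat_split])
            self.strain_branch.backward(dz[:, self._feat_split :])
        elif self.modality == "plantar_only":
            self.plantar_branch.backward(dz)
        else:
            self.strain_branch.backward(dz)

    def predict(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        preds = []
        for i in range(0, x.shape[0], batch_size):
            logits = self.forward(x[i : i + batch_size], train=False)
            preds.append(logits.argmax(axis=1))
        return np.concatenate(preds) if preds else np.empty(0, dtype=int)


@dataclass
class FoldModel:
    """A trained fold model plus the provenance needed for leakage checks."""

    model: DualBranchCNNLSTM
    classes: List[str]
    train_subjects: set
    val_subjects: set
    history: List[dict] = field(default_factory=list)


@dataclass
class EvalResult:
    """Pooled held-out evaluation across folds."""

    confusion: np.ndarray        # rows = true class, cols = predicted
    classes: List[str]
    accuracy_pct: float
    per_fold_accuracy_pct: List[float]
    modality: str

    @property
    def precision(self) -> np.ndarray:
        col = self.confusion.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(col > 0, np.diag(self.confusion) / col, np.nan)

    @property
    def recall(self) -> np.ndarray:
        row = self.confusion.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(row > 0, np.diag(self.confusion) / row, np.nan)

    def to_dict(self) -> dict:
        return {
            "modality": self.modality,
            "classes": list(self.classes),
            "accuracy_pct": self.accuracy_pct,
            "per_fold_accuracy_pct": list(self.per_fold_accuracy_pct),
            "confusion": self.confusion.tolist(),
        }


def _train_single(
    model: DualBranchCNNLSTM,
    X: np.ndarray,
    y: np.ndarray,
    Xval: np.ndarray,
    yval: np.ndarray,
    config: ModelConfig,
    rng: np.random.Generator,
) -> List[dict]:
    opt = nn.Adam(
        model.params(),
        model.grads(),
        lr=config.learning_rate,
        weight_decay=config.weight_decay,
    )
    best_state = model.state()
    best_val = -np.inf
    patience_left = config.early_stop_patience
    history: List[dict] = []
    n = X.shape[0]
    for epoch in range(config.max_epochs):
        opt.lr = config.learning_rate * 0.5 ** (epoch // config.lr_decay_every)
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, config.batch_size):
            idx = order[i : i + config.batch_size]
            logits = model.forward(X[idx], train=True)
            loss, dlogits = nn.softmax_cross_entropy(logits, y[idx])
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
        if Xval.shape[0]:
            val_acc = float(np.mean(model.predict(Xval) == yval))
        else:
            val_acc = float(np.mean(model.predict(X) == y))
        history.append({"epoch": epoch, "train_loss": float(np.mean(losses)), "val_acc": val_acc})
        if val_acc > best_val + 1e-12:
            best_val = val_acc
            best_state = model.state()
            patience_left = config.early_stop_patience
        else:
            patience_left -= 1
            if patience_left <= 0:
                break
    model.load_state(best_state)
    return history


def build_and_train(
    windows: WindowSet,
    plan: FoldPlan,
    config: ModelConfig,
    modality: str = "fused",
    seed: int = 0,
) -> List[FoldModel]:
    """Train one model per fold on its training subjects' windows.

    Training windows are augmented in place (``config.augment_copies``
    extra copies per window); validation and test windows never are.
    """
    channels = MODALITY_CHANNELS[modality]
    labels = apply_class_scheme(windows.labels, config.class_scheme)
    classes = sorted(set(labels))
    class_to_idx = {c: i for i, c in enumerate(classes)}
    y_all = np.array([class_to_idx[c] for c in labels])
    X_all = windows.data[:, list(channels), :]

    fold_models: List[FoldModel] = []
    for k in range(plan.n_folds):
        train_set = set(plan.train_subjects[k])
        val_set = set(plan.val_subjects[k])
        tr_mask = np.isin(windows.subject_ids, list(train_set))
        va_mask = np.isin(windows.subject_ids, list(val_set)) & ~windows.augmented
        if not tr_mask.any():
            raise ValueError(f"fold {k}: empty training split")

        tr_windows = WindowSet(
            windows.data[tr_mask],
            windows.subject_ids[tr_mask],
            labels[tr_mask],
            windows.sources[tr_mask],
            windows.augmented[tr_mask],
        )
        if config.augment_copies > 0:
            tr_windows = augment_windowset(
                tr_windows, config.augment_copies, seed=seed * 1000 + k
            )
        Xtr = tr_windows.data[:, list(channels), :]
        ytr = np.array([class_to_idx[c] for c in tr_windows.labels])

        model = DualBranchCNNLSTM(
            config, len(classes), modality, seed=seed * 100 + k
        )
        rng = np.random.default_rng(seed * 10000 + k)
        history = _train_single(
            model, Xtr, ytr, X_all[va_mask], y_all[va_mask], config, rng
        )
        fold_models.append(
            FoldModel(
                model=model,
                classes=classes,
                train_subjects=train_set | val_set,
                val_subjects=val_set,
                history=history,
            )
        )
    return fold_models


def evaluate(
    models: List[FoldModel],
    windows: WindowSet,
    plan: FoldPlan,
    modality: str = "fused",
) -> EvalResult:
    """Pooled confusion matrix and accuracy over held-out subjects only.

    Augmented windows are excluded from evaluation.  Any overlap between a
    fold's test subjects and the subjects its model trained on raises.
    """
    if len(models) != plan.n_folds:
        raise ValueError("one trained model per fold is required")
    channels = MODALITY_CHANNELS[modality]
    classes = models[0].classes
    class_to_idx = {c: i for i, c in enumerate(classes)}
    K = len(classes)
    confusion = np.zeros((K, K), dtype=int)
    per_fold_acc: List[float] = []

    for k, fm in enumerate(models):
        test_set = set(plan.test_subjects[k])
        leaked = test_set & fm.train_subjects
        if leaked:
            raise RuntimeError(
                f"subject leakage in fold {k}: {sorted(leaked)} were trained on"
            )
        mask = np.isin(windows.subject_ids, list(test_set)) & ~windows.augmented
        if not mask.any():
            per_fold_acc.append(np.nan)
            continue
        labels = apply_class_scheme(windows.labels[mask], fm.model.config.class_scheme)
        y_true = np.array([class_to_idx[c] for c in labels])
        y_pred = fm.model.predict(windows.data[mask][:, list(channels), :])
        for t, p in zip(y_true, y_pred):
            confusion[t, p] += 1
        per_fold_acc.append(100.0 * float(np.mean(y_pred == y_true)))

    total = confusion.sum()
    accuracy = 100.0 * np.trace(confusion) / total if total else np.nan
    return EvalResult(
        confusion=confusion,
        classes=classes,
        accuracy_pct=float(accuracy),
        per_fold_accuracy_pct=per_fold_acc,
        modality=modality,
    )


def modality_ablation(
    windows: WindowSet,
    plan: FoldPlan,
    config: ModelConfig,
    seed: int = 0,
) -> Dict[str, EvalResult]:
    """Train and evaluate plantar-only, strain-only and fused models.

    All three runs share the identical fold plan and seed so that the
    comparison isolates the input modality.
    """
    results: Dict[str, EvalResult] = {}
    for modality in ("plantar_only", "strain_only", "fused"):
        models = build_and_train(windows, plan, config, modality, seed)
        results[modality] = evaluate(models, windows, plan, modality)
    return results
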