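"""Subject-exclusive cross-validation and the training loop.

Subjects (never trials) are dealt into k folds so that the three groups are
evenly represented in every fold (per-fold group counts differ by at most
one) and all trials of a subject share one fold. A split takes 1 fold for
test, the next 2 (cyclically) for validation, the remaining 7 for training.
Training runs mini-batch Adam on the weighted NLL loss; the checkpoint with
the best validation accuracy is kept. Everything is driven by one seeded
NumPy generator, so a (seed, config) pair reproduces the final weights
bitwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..containers import ValidationError
from .losses import nll_loss
from .metrics import EvaluationReport, evaluation_report
from .model import ArchitectureSpec, Sequential, build_model
from .optim import Adam, TrainConfig


@dataclass
class FoldAssignment:
    """subject -> fold index, with the 1:2:7 test/validation/train split rule."""

    fold_of: dict[str, int]
    k: int = 10

    def subjects_in(self, folds) -> list[str]:
        folds = set(folds)
        return [s for s, f in self.fold_of.items() if f in folds]

    def split(self, test_fold: int) -> tuple[list[str], list[str], list[str]]:
        """(train, validation, test) subject lists for one split."""
        test = {test_fold % self.k}
        val = {(test_fold + 1) % self.k, (test_fold + 2) % self.k}
        train = set(range(self.k)) - test - val
        return (self.subjects_in(train), self.subjects_in(val),
                self.subjects_in(test))


def assign_folds(subject_groups: dict[str, str], k: int = 10,
                 seed: int = 0) -> FoldAssignment:
    """Deal subjects into k folds, balanced per group, deterministic per seed."""
    if k > len(subject_groups):
        raise ValidationError(
            f"cannot make {k} folds from {len(subject_groups)} subjects")
    rng = np.random.default_rng(seed)
    fold_of: dict[str, int] = {}
    offset = 0
    for group in sorted(set(subject_groups.values())):
        members = sorted(s for s, g in subject_groups.items() if g == group)
        rng.shuffle(members)
        for i, s in enumerate(members):
            fold_of[s] = (i + offset) % k
        offset += len(members)
    return FoldAssignment(fold_of=fold_of, k=k)


@dataclass
class ClassifiedDataset:
    """Samples ready for the CNN: (N, 1, H, W) inputs with labels and owners."""

    X: np.ndarray
    y: np.ndarray
    subjects: np.ndarray
    label_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.int64)
        self.subjects = np.asarray(self.subjects)
        if self.X.ndim != 4 or self.X.shape[1] != 1:
            raise ValidationError("X must be (N, 1, height, width)")
        if not (len(self.X) == len(self.y) == len(self.subjects)):
            raise ValidationError("X, y and subjects must align")

    def subset(self, subject_list) -> "ClassifiedDataset":
        mask = np.isin(self.subjects, list(subject_list))
        return ClassifiedDataset(self.X[mask], self.y[mask],
                                 self.subjects[mask], self.label_names)

    @property
    def subject_groups(self) -> dict[str, str]:
        return {str(s): self.label_names[self.y[i]]
                for i, s in enumerate(self.subjects)}


@dataclass
class TrainResult:
    model: Sequential
    curves: pd.DataFrame  # epoch, train_loss, train_acc, val_loss, val_acc
    best_epoch: int
    best_val_accuracy: float
    test_report: EvaluationReport | None = None


def _predict(model: Sequential, X: np.ndarray,
             batch_size: int = 256) -> np.ndarray:
    out = []
    for i in range(0, len(X), batch_size):
        out.append(model.forward(X[i:i + batch_size], training=False))
    return np.concatenate(out) if out else np.empty((0, model.spec.n_classes))


def _eval_split(model: Sequential, X, y, weights) -> tuple[float, float]:
    logp = _predict(model, X)
    loss, _ = nll_loss(logp, y, weights)
    acc = float((logp.argmax(axis=1) == y).mean())
    return loss, acc


def train(dataset: ClassifiedDataset, folds: FoldAssignment,
          arch: ArchitectureSpec, config: TrainConfig,
          test_fold: int = 0) -> TrainResult:
    """Train one cross-validation split end to end.

    Subject exclusivity between the three splits is asserted structurally
    on every run.
    """
    train_s, val_s, test_s = folds.split(test_fold)
    for a, b in ((train_s, val_s), (train_s, test_s), (val_s, test_s)):
        overlap = set(a) & set(b)
        if overlap:
            raise ValidationError(f"subjects span splits: {sorted(overlap)}")
    tr, va, te = (dataset.subset(s) for s in (train_s, val_s, test_s))
    for name, part in (("training", tr), ("validation", va), ("test", te)):
        if len(part.X) == 0:
            raise ValidationError(f"{name} split is empty")

    rng = np.random.default_rng(config.seed)
    model = build_model(arch, seed=int(rng.integers(2 ** 31)))
    opt = Adam(model, config)
    weights = config.class_weights

    rows = []
    best_state, best_epoch, best_val_acc = model.get_state(), 0, -1.0
    n = len(tr.X)
    for ep in range(1, config.epochs + 1):
        order = rng.permutation(n)
        ep_loss, ep_hits = 0.0, 0
        for i in range(0, n, config.batch_size):
            idx = order[i:i + config.batch_size]
            xb, yb = tr.X[idx], tr.y[idx]
            logp = model.forward(xb, training=True, rng=rng)
            loss, grad = nll_loss(logp, yb, weights)
            model.backward(grad)
            opt.step()
            ep_loss += loss * len(idx)
            ep_hits += int((logp.argmax(axis=1) == yb).sum())
        val_loss, val_acc = _eval_split(model, va.X, va.y, weights)
        rows.append({"epoch": ep, "train_loss": ep_loss / n,
                     "train_accuracy": ep_hits / n,
                     "val_loss": val_loss, "val_accuracy": val_acc})
        if val_acc > best_val_acc:
            best_val_acc, best_epoch = val_acc, ep
            best_state = model.get_state()
    model.set_state(best_state)
    report = evaluate(model, te)
    return TrainResult(model=model, curves=pd.DataFrame(rows),
                       best_epoch=best_epoch, best_val_accuracy=best_val_acc,
                       test_report=report)


def evaluate(model: Sequential, test: ClassifiedDataset) -> EvaluationReport:
    """Accuracy, per-class precision/recall/F1 and Macro-F1 on a test split."""
    logp = _predict(model, test.X)
    y_pred = logp.argmax(axis=1)
    return evaluation_report(test.y, y_pred, model.spec.n_classes,
                             label_names=test.label_names)
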