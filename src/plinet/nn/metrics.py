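"""Classification evaluation: accuracy, per-class F1, Macro-F1.

F1 per class is the harmonic mean of precision and recall computed from the
confusion matrix; Macro-F1 is their unweighted mean. A class absent from
the test labels has undefined F1 and is excluded from the macro mean with a
warning (a class that is present but never predicted scores 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass
class EvaluationReport:
    accuracy: float
    precision: dict[int, float]
    recall: dict[int, float]
    f1: dict[int, float]
    macro_f1: float
    confusion: np.ndarray
    n_samples: int
    label_names: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "macro_f1": self.macro_f1,
            "precision": {str(k): v for k, v in self.precision.items()},
            "recall": {str(k): v for k, v in self.recall.items()},
            "f1": {str(k): v for k, v in self.f1.items()},
            "confusion": self.confusion.tolist(),
            "n_samples": self.n_samples,
            "label_names": list(self.label_names),
        }


def confusion_matrix(y_true: np.ndarray, y_pred: np.ndarray,
                     n_classes: int) -> np.ndarray:
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    for t, p in zip(np.asarray(y_true), np.asarray(y_pred)):
        cm[int(t), int(p)] += 1
    return cm


def evaluation_report(y_true: np.ndarray, y_pred: np.ndarray,
                      n_classes: int, label_names=()) -> EvaluationReport:
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    cm = confusion_matrix(y_true, y_pred, n_classes)
    accuracy = float((y_true == y_pred).mean()) if y_true.size else 0.0
    precision, recall, f1 = {}, {}, {}
    macro_terms = []
    for c in range(n_classes):
        support = cm[c].sum()
        if support == 0:
            warnings.warn(
                f"class {c} absent from test labels; excluded from Macro-F1",
                stacklevel=2)
            continue
        tp = cm[c, c]
        predicted = cm[:, c].sum()
        precision[c] = float(tp / predicted) if predicted else 0.0
        recall[c] = float(tp / support)
        denom = precision[c] + recall[c]
        f1[c] = 2 * precision[c] * recall[c] / denom if denom else 0.0
        macro_terms.append(f1[c])
    macro_f1 = float(np.mean(macro_terms)) if macro_terms else 0.0
    return EvaluationReport(accuracy=accuracy, precision=precision,
                            recall=recall, f1=f1, macro_f1=macro_f1,
                            confusion=cm, n_samples=int(y_true.size),
                            label_names=tuple(label_names))
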