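"""Weighted negative log-likelihood on log-probability outputs.

For a batch of N samples with true classes y_n and optional class weights
w, the loss is the weighted mean

    L = sum_n w_{y_n} * (-logp_{n, y_n}) / sum_n w_{y_n},

so uniform weights give the plain mean of -logp on the true class (ln 3 for
a uniform 3-class prediction). The returned gradient is with respect to the
log-probabilities, to be chained through the log-softmax layer.
"""

from __future__ import annotations

import numpy as np

from ..containers import ValidationError


def nll_loss(log_probs: np.ndarray, labels: np.ndarray,
             weights: np.ndarray | None = None
             ) -> tuple[float, np.ndarray]:
    log_probs = np.asarray(log_probs, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    n, c = log_probs.shape
    if labels.shape != (n,):
        raise ValidationError("labels must be one integer per sample")
    if labels.min(initial=0) < 0 or labels.max(initial=0) >= c:
        raise ValidationError(f"labels must lie in [0, {c - 1}]")
    if weights is None:
        weights = np.ones(c)
    weights = np.asarray(weights, dtype=np.float64)
    if weights.shape != (c,):
        raise ValidationError(f"need one weight per class, got {weights.shape}")
    w_n = weights[labels]
    denom = w_n.sum()
    loss = float(-(w_n * log_probs[np.arange(n), labels]).sum() / denom)
    grad = np.zeros_like(log_probs)
    grad[np.arange(n), labels] = -w_n / denom
    return loss, grad
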