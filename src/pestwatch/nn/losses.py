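"""Softmax cross-entropy, the classification loss of every network here."""

from __future__ import annotations

import numpy as np

__all__ = ["softmax", "softmax_cross_entropy"]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray
                          ) -> tuple[float, np.ndarray]:
    """Mean cross-entropy between softmax(logits) and integer labels ``y``.

    Returns the loss and its gradient w.r.t. the logits, ``(p - onehot)/N``.
    """
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    idx = (np.arange(n), y)
    loss = float(-np.log(np.maximum(p[idx], 1e-300)).mean())
    dlogits = p
    dlogits[idx] -= 1.0
    return loss, (dlogits / n).astype(logits.dtype)
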