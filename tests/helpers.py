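"""Test doubles and small oracles shared across the suite."""

from __future__ import annotations

import numpy as np

from diffcnn.models import HeadSpec


class LinearGraph:
    """An affine scoring model f_c(x) = <w_c, x> + b_c used as an exactly
    solvable oracle for the attribution methods.  Implements the same duck
    interface as ModelGraph (predict_logits / input_gradients / head_spec)
    but in float64, independent of the layer framework."""

    def __init__(self, w: np.ndarray, b: np.ndarray | None = None, head: str = "out"):
        self.w = np.asarray(w, dtype=np.float64)  # (C, 4, L)
        self.b = np.zeros(self.w.shape[0]) if b is None else np.asarray(b, float)
        self.head = head
        self._spec = HeadSpec(head, "classification",
                              tuple(f"c{i}" for i in range(self.w.shape[0])))

    @property
    def input_length(self):
        return self.w.shape[2]

    def head_spec(self, head):
        assert head == self.head
        return self._spec

    def predict_logits(self, X, head, batch_size=256):
        return np.tensordot(X, self.w, axes=([1, 2], [1, 2])) + self.b

    def predict_proba(self, X, head, batch_size=256):
        from diffcnn.nn import softmax
        return softmax(self.predict_logits(X, head))

    def input_gradients(self, X, head, class_index, batch_size=256):
        return np.broadcast_to(self.w[class_index], X.shape).copy()


def brute_force_window_max(scores: np.ndarray, window: int) -> tuple[int, float]:
    """Exhaustive search oracle for the strongest sliding window."""
    best_start, best = 0, -np.inf
    for s in range(len(scores) - window + 1):
        v = scores[s:s + window].sum()
        if v > best + 1e-12:
            best, best_start = v, s
    return best_start, best


def poisson_tail_series(k: int, lam: float) -> float:
    """Direct-series oracle for the Poisson upper tail P(X >= k)."""
    if k <= 0:
        return 1.0
    # 1 - sum_{j<k} e^-lam lam^j / j!
    term = np.exp(-lam)
    cdf = 0.0
    for j in range(k):
        cdf += term
        term *= lam / (j + 1)
    return max(0.0, 1.0 - cdf)
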