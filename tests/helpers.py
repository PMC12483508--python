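"""Independent oracles used by the test suite.

These deliberately avoid the code paths they validate: nonnegative least
squares by exhaustive active-set enumeration, AUROC by the rank-sum identity,
and the exponential kernel built as an explicit dense matrix.
"""

from itertools import combinations

import numpy as np


def exponential_kernel_matrix(n_frames: int, gamma: float) -> np.ndarray:
    K = np.zeros((n_frames, n_frames))
    for j in range(n_frames):
        K[j:, j] = gamma ** np.arange(n_frames - j)
    return K


def nnls_by_enumeration(A: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Exact NNLS by trying every support set (tiny problems only)."""
    n = A.shape[1]
    assert n <= 14, "enumeration oracle is exponential in columns"
    best, best_obj = np.zeros(n), float(np.sum(y**2))
    for k in range(1, n + 1):
        for support in combinations(range(n), k):
            sol, *_ = np.linalg.lstsq(A[:, support], y, rcond=None)
            if np.any(sol < -1e-12):
                continue
            x = np.zeros(n)
            x[list(support)] = np.clip(sol, 0, None)
            obj = float(np.sum((y - A @ x) ** 2))
            if obj < best_obj - 1e-12:
                best, best_obj = x, obj
    return best


def auroc_rank_sum(scores: np.ndarray, positive: np.ndarray) -> float:
    """AUROC via the Mann-Whitney identity U / (n_pos * n_neg)."""
    pos = np.asarray(scores)[positive]
    neg = np.asarray(scores)[~np.asarray(positive, dtype=bool)]
    wins = 0.0
    for p in pos:
        for q in neg:
            wins += 1.0 if p > q else (0.5 if p == q else 0.0)
    return wins / (len(pos) * len(neg))


class ScoreStub:
    """Minimal classifier stand-in exposing decision scores for AUROC tests."""

    def __init__(self, scores: np.ndarray, classes: np.ndarray):
        self._scores = np.asarray(scores, dtype=float)
        self.classes_ = np.asarray(classes)

    def decision_function(self, X):
        return self._scores
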