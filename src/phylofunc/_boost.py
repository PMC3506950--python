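"""Seeded gradient boosting with regression stumps, for covariate selection.

The association stage does not use boosting for prediction: the object
of interest is, per covariate, the fraction of boosting iterations whose
stump splits on it.  That statistic requires access to each round's
split, so the booster is implemented here as a compact numba kernel:

- squared-error loss, depth-1 trees (additive stumps);
- per round, a without-replacement row subsample is drawn, the single
  best (feature, threshold) split by SSE reduction is fit to the current
  residuals on the subsample, and predictions on all rows are updated by
  ``learning_rate`` times the leaf means;
- rounds where no strictly improving split exists count as no split.

Given the same seed the kernel is bit-reproducible across runs.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _boost_kernel(X, y, order, valid, n_rounds, learning_rate, subsample, seed):
    n, p = X.shape
    np.random.seed(seed)
    pred = np.full(n, y.mean())
    split_counts = np.zeros(p, np.int64)
    gains = np.zeros(p, np.float64)
    k = int(round(subsample * n))
    if k < 2:
        k = 2
    if k > n:
        k = n
    insub = np.zeros(n, np.bool_)
    for _ in range(n_rounds):
        resid = y - pred
        perm = np.random.permutation(n)
        insub[:] = False
        for t in range(k):
            insub[perm[t]] = True
        total = 0.0
        for i in range(n):
            if insub[i]:
                total += resid[i]
        best_gain = 1e-12  # require a strictly improving split
        best_j = -1
        best_thr = 0.0
        best_left = 0.0
        best_right = 0.0
        for j in range(p):
            cum_sum = 0.0
            cum_n = 0
            for pos in range(n - 1):
                idx = order[j, pos]
                if insub[idx]:
                    cum_sum += resid[idx]
                    cum_n += 1
                if valid[j, pos] and 0 < cum_n < k:
                    rest = total - cum_sum
                    gain = (
                        cum_sum * cum_sum / cum_n
                        + rest * rest / (k - cum_n)
                        - total * total / k
                    )
                    if gain > best_gain:
                        best_gain = gain
                        best_j = j
                        best_thr = 0.5 * (X[idx, j] + X[order[j, pos + 1], j])
                        best_left = cum_sum / cum_n
                        best_right = rest / (k - cum_n)
        if best_j >= 0:
            split_counts[best_j] += 1
            gains[best_j] += best_gain
            for i in range(n):
                if X[i, best_j] <= best_thr:
                    pred[i] += learning_rate * best_left
                else:
                    pred[i] += learning_rate * best_right
    return split_counts, gains


def boost_split_counts(
    X: np.ndarray,
    y: np.ndarray,
    *,
    n_rounds: int = 1000,
    learning_rate: float = 0.01,
    subsample: float = 0.5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Run the stump booster; return per-column split counts and summed gains.

    ``X`` is the (n_samples, n_columns) encoded design; ``y`` the
    response.  Split thresholds are midpoints between adjacent distinct
    column values, so constant columns can never be split on.
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    n, p = X.shape
    if n < 4:
        raise ValueError("boosting needs at least 4 samples")
    order = np.empty((p, n), dtype=np.int64)
    valid = np.zeros((p, n), dtype=np.bool_)
    for j in range(p):
        order[j] = np.argsort(X[:, j], kind="mergesort")
        col = X[order[j], j]
        valid[j, : n - 1] = col[:-1] < col[1:]
    return _boost_kernel(
        X, y, order, valid,
        np.int64(n_rounds), float(learning_rate), float(subsample),
        np.int64(seed) % np.int64(2**31),
    )
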