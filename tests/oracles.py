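"""Independent reference implementations used only to check the package.

Each oracle takes the most literal route available — exhaustive dynamic
programming, double loops, explicit least-squares — and never shares code
with the implementation it validates.
"""

from __future__ import annotations

import numpy as np
from sklearn.linear_model import LinearRegression


def sw_affine_dp(a: str, b: str, sub, gap_open: float, gap_extend: float) -> float:
    """Exhaustive Gotoh local-alignment DP with affine gaps.

    A gap of length L costs ``gap_open + (L - 1) * gap_extend``.  ``sub`` is
    a callable (res, res) -> score.  Returns the optimal local score (>= 0
    via the empty-alignment floor).
    """
    n, m = len(a), len(b)
    neg = -1e18
    M = np.zeros((n + 1, m + 1))      # alignment ends in a match/mismatch
    Ix = np.full((n + 1, m + 1), neg)  # ends in a gap in b (vertical)
    Iy = np.full((n + 1, m + 1), neg)  # ends in a gap in a (horizontal)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            Ix[i, j] = max(M[i - 1, j] - gap_open, Ix[i - 1, j] - gap_extend)
            Iy[i, j] = max(M[i, j - 1] - gap_open, Iy[i, j - 1] - gap_extend)
            s = sub(a[i - 1], b[j - 1])
            M[i, j] = max(
                0.0,
                s + max(M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1]),
            )
            best = max(best, M[i, j])
    return best


def ci_double_loop(y, yhat) -> float:
    """Concordance index by literal enumeration of ordered label pairs."""
    num = 0.0
    z = 0
    n = len(y)
    for i in range(n):
        for j in range(n):
            if y[i] > y[j]:
                z += 1
                d = yhat[i] - yhat[j]
                num += 1.0 if d > 0 else (0.5 if d == 0 else 0.0)
    if z == 0:
        raise ValueError("no ordered pairs")
    return num / z


def rm2_regression(y, yhat) -> float:
    """Modified r^2 via explicit least-squares fits (sklearn), predictions
    regressed on observations with and without intercept."""
    y = np.asarray(y, dtype=float).reshape(-1, 1)
    yhat = np.asarray(yhat, dtype=float)
    r2 = LinearRegression().fit(y, yhat).score(y, yhat)
    r0 = LinearRegression(fit_intercept=False).fit(y, yhat).score(y, yhat)
    return r2 * (1.0 - np.sqrt(abs(r2 - r0)))


def aupr_enumeration(labels, scores) -> float:
    """Average precision by stepping through the distinct score thresholds."""
    labels = np.asarray(labels, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    thresholds = np.unique(scores)[::-1]
    total_pos = labels.sum()
    ap = 0.0
    prev_recall = 0.0
    for t in thresholds:
        called = scores >= t
        tp = int((labels & called).sum())
        precision = tp / int(called.sum())
        recall = tp / total_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap
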