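"""Independent brute-force oracles used by the test suite.

These deliberately re-derive quantities from first principles (O(n^2)
pairwise definitions, direct enumeration) and stay independent of the
package's implementations they are used to check.
"""

from __future__ import annotations

import numpy as np


def auc_pairwise(scores, labels, positive: str = "PD") -> float:
    """AUC as the proportion of correctly ordered (positive, negative)
    pairs, counting ties as 1/2 — the Mann-Whitney definition."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == positive]
    neg = scores[labels != positive]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (pos.size * neg.size)


def delong_components_bruteforce(scores, is_pos):
    """DeLong structural components from the full O(m*n) kernel matrix.

    psi(x, y) = 1 if x > y, 1/2 if x == y, 0 otherwise; the per-positive
    component is the row mean and the per-negative component the column
    mean of psi evaluated over all (positive, negative) pairs.
    """
    scores = np.asarray(scores, dtype=float)
    is_pos = np.asarray(is_pos, dtype=bool)
    pos = scores[is_pos]
    neg = scores[~is_pos]
    psi = np.where(pos[:, None] > neg[None, :], 1.0,
                   np.where(pos[:, None] == neg[None, :], 0.5, 0.0))
    return float(psi.mean()), psi.mean(axis=1), psi.mean(axis=0)


def delong_variance_bruteforce(scores_a, scores_b, is_pos) -> float:
    """Variance of AUC_a - AUC_b from the brute-force components."""
    _, v10a, v01a = delong_components_bruteforce(scores_a, is_pos)
    _, v10b, v01b = delong_components_bruteforce(scores_b, is_pos)
    m, n = v10a.size, v01a.size
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    return float((s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
                 + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n)


def disk_mask(radius: int, pad: int = 3) -> np.ndarray:
    """Rasterized filled disk: pixel centres with x^2 + y^2 <= r^2."""
    n = 2 * radius + 2 * pad + 1
    yy, xx = np.mgrid[:n, :n]
    c = n // 2
    return (yy - c) ** 2 + (xx - c) ** 2 <= radius**2


def rect_mask(height: int, width: int, pad: int = 5) -> np.ndarray:
    m = np.zeros((height + 2 * pad, width + 2 * pad), dtype=bool)
    m[pad : pad + height, pad : pad + width] = True
    return m
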