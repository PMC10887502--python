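"""Independent reference implementations used only to cross-check the package.

These deliberately use the slowest, most transparent formulation available
(quadratic dynamic programming, exhaustive simplex grids) and never call the
code paths they verify.
"""

from __future__ import annotations

import numpy as np


def dp_levenshtein(a: str, b: str) -> int:
    """Textbook quadratic DP edit distance."""
    n, m = len(a), len(b)
    prev = list(range(m + 1))
    for i in range(1, n + 1):
        cur = [i] + [0] * m
        for j in range(1, m + 1):
            cur[j] = min(
                prev[j] + 1,
                cur[j - 1] + 1,
                prev[j - 1] + (a[i - 1] != b[j - 1]),
            )
        prev = cur
    return prev[m]


def simplex_grid(k: int, step: float) -> np.ndarray:
    """All points of the k-simplex on a grid of the given step."""
    n = int(round(1.0 / step))
    if k == 1:
        return np.array([[1.0]])
    if k == 2:
        a = np.arange(n + 1) / n
        return np.stack([a, 1.0 - a], axis=1)
    if k == 3:
        pts = []
        for i in range(n + 1):
            for j in range(n + 1 - i):
                pts.append((i / n, j / n, (n - i - j) / n))
        return np.asarray(pts)
    raise NotImplementedError("grid oracle supports up to 3 components")


def grid_mixture_mle(ll_matrix: np.ndarray, step: float = 0.001) -> np.ndarray:
    """Brute-force ML mixture proportions over a simplex grid.

    ``ll_matrix`` is (N fragments, H candidates) of per-fragment
    log-likelihoods; the mixture log-likelihood of a grid point pi is
    sum_i log(sum_h pi_h exp(ll_ih)). Evaluated in chunks to bound memory.
    """
    N, H = ll_matrix.shape
    grid = simplex_grid(H, step)
    shift = ll_matrix.max(axis=1, keepdims=True)
    lik = np.exp(ll_matrix - shift)  # (N, H), scaled per fragment
    best_val = -np.inf
    best_pt = grid[0]
    for lo in range(0, len(grid), 20000):
        chunk = grid[lo : lo + 20000]
        mix = chunk @ lik.T  # (G, N)
        with np.errstate(divide="ignore"):
            vals = np.log(mix).sum(axis=1)
        i = int(np.argmax(vals))
        if vals[i] > best_val:
            best_val = float(vals[i])
            best_pt = chunk[i]
    return best_pt
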