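"""Independent brute-force oracles used to pin the fast implementations.

These deliberately share no code with the package: DTW is evaluated by
exhaustively enumerating every monotone warping path, and TOM by the
textbook triple loop.
"""

import numpy as np


def dtw_brute_force(a, b) -> float:
    """Minimum path cost over ALL monotone warping paths (no DP reuse)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    m, n = len(a), len(b)

    def walk(i, j):
        cost = abs(a[i] - b[j])
        if i == m - 1 and j == n - 1:
            return cost
        options = []
        if i + 1 < m:
            options.append(walk(i + 1, j))
        if j + 1 < n:
            options.append(walk(i, j + 1))
        if i + 1 < m and j + 1 < n:
            options.append(walk(i + 1, j + 1))
        return cost + min(options)

    return walk(0, 0)


def tom_brute_force(A) -> np.ndarray:
    """Triple-loop topological overlap of a symmetric zero-diagonal adjacency."""
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    k = A.sum(axis=1)
    tom = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                tom[i, j] = 1.0
                continue
            shared = sum(A[i, u] * A[u, j] for u in range(n) if u != i and u != j)
            tom[i, j] = (shared + A[i, j]) / (min(k[i], k[j]) + 1.0 - A[i, j])
    return tom
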