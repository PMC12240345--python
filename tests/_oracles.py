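"""Independent brute-force oracles used by the tests.

These are deliberately naive re-implementations (plain double loops,
direct rescans) kept separate from the package so that agreement between
the optimized code paths and these oracles is meaningful.
"""

import math

import numpy as np


def naive_correlation_sum(embedded, r, metric="euclidean"):
    """O(N^2) double-loop correlation sum; pairs at distance exactly r count."""
    X = np.asarray(embedded, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = len(X)
    count = 0
    for i in range(n):
        for j in range(i + 1, n):
            if metric == "euclidean":
                s = 0.0
                for k in range(X.shape[1]):
                    t = X[i, k] - X[j, k]
                    s += t * t
                dist = math.sqrt(s)
            else:
                dist = max(abs(X[i, k] - X[j, k]) for k in range(X.shape[1]))
            if dist <= r:
                count += 1
    return 2.0 * count / (n * (n - 1))


def naive_run_durations(states):
    """Rescan a boolean sequence for maximal runs; returns (active, rest) lists."""
    active, rest = [], []
    current = bool(states[0])
    length = 0
    for s in states:
        s = bool(s)
        if s == current:
            length += 1
        else:
            (active if current else rest).append(length)
            current = s
            length = 1
    (active if current else rest).append(length)
    return active, rest


def naive_sample_entropy(series, d, r_abs):
    """Direct template-counting sample entropy (Chebyshev metric).

    Counts matching template pairs of lengths d and d+1 over the same
    n - d starting positions and returns -ln(A / B).
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    m = n - d
    b = 0  # length-d matches
    a = 0  # length-(d+1) matches
    for i in range(m):
        for j in range(i + 1, m):
            if max(abs(x[i + k] - x[j + k]) for k in range(d)) <= r_abs:
                b += 1
                if abs(x[i + d] - x[j + d]) <= r_abs:
                    a += 1
    if a == 0 or b == 0:
        return float("nan")
    return -math.log(a / b)
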