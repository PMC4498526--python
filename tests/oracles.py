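"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (exhaustive grids, straight-line loops)
and independent of the library's optimized code paths, so agreement between
the two is meaningful.
"""

import math

import numpy as np


def simplex_grid(k: int, step: float = 0.01) -> np.ndarray:
    """All points of the probability simplex on a regular grid (rows sum to 1)."""
    m = int(round(1.0 / step))
    if k == 1:
        return np.ones((1, 1))
    axes = np.meshgrid(*[np.arange(m + 1)] * (k - 1), indexing="ij")
    parts = np.stack([a.ravel() for a in axes], axis=1)
    keep = parts.sum(axis=1) <= m
    parts = parts[keep]
    last = m - parts.sum(axis=1)
    grid = np.column_stack([parts, last]).astype(float) / m
    return grid


def grid_min_hyperplane_distance(x, H, w, step: float = 0.01) -> float:
    """Exhaustive minimum of ``w^T |x - H alpha|`` over the gridded simplex."""
    grid = simplex_grid(H.shape[1], step)
    residuals = x[None, :] - grid @ H.T  # (M, D)
    return float((np.abs(residuals) @ w).min())


def brute_class_neighbors(x, X, y, class_label, k, w, exclude_index=None):
    """Neighbor search by sorting all (distance, index) pairs explicitly."""
    pairs = []
    for i in range(len(y)):
        if y[i] != class_label or i == exclude_index:
            continue
        d = sum(w[j] * abs(X[i, j] - x[j]) for j in range(len(x)))
        pairs.append((d, i))
    pairs.sort()
    return [i for _, i in pairs[:k]]


def weighted_1nn_label(x, X, y, w, exclude_index=None):
    """Plain weighted-Manhattan 1-NN, ties by index then smaller label."""
    best = None
    for i in range(len(y)):
        if i == exclude_index:
            continue
        d = float(np.dot(w, np.abs(X[i] - x)))
        if best is None or d < best[0] - 1e-15:
            best = (d, int(y[i]))
        elif abs(d - best[0]) <= 1e-15 and int(y[i]) < best[1]:
            best = (best[0], int(y[i]))
    return best[1]


def naive_penalized_objective(dataset, v, config, alpha_solver):
    """Straight-line re-evaluation of the penalized leave-one-out margin error.

    Re-implements the neighbor search, nearest-hit/nearest-miss choice,
    degenerate-margin rules, sigmoid, and l1 penalty with plain Python loops;
    only the simplex-coefficient solve is delegated to ``alpha_solver`` so
    both evaluations see identical hyperplane coefficients.
    """
    X, y = dataset.features, dataset.labels
    n, d = X.shape
    w = [v[j] * v[j] for j in range(d)]
    total = 0.0
    for i in range(n):
        dists = {}
        for label in sorted(set(int(t) for t in y)):
            pairs = []
            for t in range(n):
                if int(y[t]) != label or t == i:
                    continue
                dist = sum(w[j] * abs(X[t, j] - X[i, j]) for j in range(d))
                pairs.append((dist, t))
            pairs.sort()
            idx = [t for _, t in pairs[: config.k]]
            H = X[idx].T
            alpha = alpha_solver(X[i], H, np.asarray(w))
            s = H @ alpha
            dists[label] = sum(w[j] * abs(X[i, j] - s[j]) for j in range(d))
        own = int(y[i])
        d_nh = dists[own]
        d_nm = min(v_ for lab, v_ in dists.items() if lab != own)
        if d_nm == 0.0:
            r = 1.0 if d_nh == 0.0 else config.ratio_cap
        else:
            r = d_nh / d_nm
        total += 1.0 / (1.0 + math.exp(config.beta * (1.0 - r)))
    penalty = config.lam * sum(w)
    return total / n + penalty
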