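"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (enumeration, O(n^2) loops, normal
equations) and shares no code with the package.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def auc_bruteforce(scores, labels) -> float:
    """Pairwise concordance AUC: 1 per concordant pair, 0.5 per tie."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pos = scores[labels]
    neg = scores[~labels]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


def mannwhitney_exact_enumeration(x, y) -> tuple[float, float]:
    """Two-sided exact Mann-Whitney p by full enumeration (tie-free data)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    u1_obs = sum(1 for a in x for b in y if a > b)
    u_obs = min(u1_obs, n1 * n2 - u1_obs)
    positions = range(n1 + n2)
    count = 0
    total = 0
    for xs in combinations(positions, n1):
        xs_set = set(xs)
        ys = [p for p in positions if p not in xs_set]
        u1 = sum(1 for a in xs for b in ys if a > b)
        u = min(u1, n1 * n2 - u1)
        if u <= u_obs:
            count += 1
        total += 1
    return float(u_obs), count / total


def neighbor_counts_bruteforce(xs, ys, radius) -> np.ndarray:
    """O(n^2) neighbor counting among immune centroids."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    n = len(xs)
    counts = np.zeros(n, dtype=int)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = np.hypot(xs[i] - xs[j], ys[i] - ys[j])
            if d <= radius:
                counts[i] += 1
    return counts


def ols_coefficients(X, y) -> tuple[np.ndarray, float]:
    """Least-squares fit with intercept via normal equations."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    design = np.column_stack([np.ones(len(y)), X])
    beta = np.linalg.solve(design.T @ design, design.T @ y)
    return beta[1:], float(beta[0])


def press_bruteforce(X, y, a: int, fit_fn) -> float:
    """LOO PRESS by explicitly refitting n models via the supplied fitter.

    ``fit_fn(X_train, y_train, a)`` must return an object with a
    ``predict(X_new)`` method operating on the original scale.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    press = 0.0
    for i in range(len(y)):
        mask = np.ones(len(y), dtype=bool)
        mask[i] = False
        model = fit_fn(X[mask], y[mask], a)
        pred = model.predict(X[i : i + 1])[0]
        press += (y[i] - pred) ** 2
    return press
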