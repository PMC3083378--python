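"""Independent brute-force oracles used to validate the optimized implementations.

These deliberately avoid the vectorized code paths of the package: the Otsu
oracle is a plain Python loop over every candidate gray level, and the DP
oracle explores the full path tree recursively (no cost table).
"""

from __future__ import annotations

import numpy as np


def otsu_bruteforce(values, candidate_levels):
    """Exhaustive between-class-variance maximization.

    Returns ``(best_criterion, low_class_mask)`` where ``low_class_mask`` is
    the boolean partition (value <= chosen level) of ``values``.  Ties keep
    the lowest candidate level, matching a first-maximum scan.
    """
    v = np.asarray(values, dtype=np.float64).ravel()
    best_crit = -1.0
    best_level = None
    for level in candidate_levels:
        low = v <= level
        n0 = int(low.sum())
        n1 = v.size - n0
        if n0 == 0 or n1 == 0:
            continue
        mu0 = float(v[low].sum()) / n0
        mu1 = float(v[~low].sum()) / n1
        crit = float(n0) * float(n1) * (mu0 - mu1) ** 2
        if crit > best_crit:
            best_crit = crit
            best_level = level
    assert best_level is not None, "no valid split found"
    return best_crit, v <= best_level


def _offset_preference(d_r):
    order = [0]
    for j in range(1, d_r + 1):
        order.extend([-j, j])
    return order


def dp_exhaustive(values, weights, alpha, d_r, prior_radius=None):
    """Optimal closed-path cost and path by exhaustive tree search.

    Enumerates every feasible path (|radial jump| <= d_r per column) via a
    memoization-free recursion whose cost accumulation and tie-breaking
    mirror the stated contract: smallest |j| preferred (negative before
    positive), endpoint ties resolved toward the prior radius then the
    smaller row.  Returns ``(total_cost, path_radii)``.
    """
    v = np.asarray(values, dtype=np.float64)
    w = np.asarray(weights, dtype=np.float64)
    m, k = v.shape
    prefs = _offset_preference(d_r)

    def best_ending_at(x, y):
        if x == 0:
            return v[y, 0], [y]
        best_cost = None
        best_path = None
        for j in prefs:
            src = y + j
            if not 0 <= src < m:
                continue
            prev_cost, prev_path = best_ending_at(x - 1, src)
            cand = prev_cost + alpha * abs(j)
            if best_cost is None or cand < best_cost:
                best_cost = cand
                best_path = prev_path
        return w[y] * v[y, x] + best_cost, best_path + [y]

    finals = [best_ending_at(k - 1, y) for y in range(m)]
    costs = [c for c, _ in finals]
    best = min(costs)
    ties = [y for y in range(m) if costs[y] == best]
    if prior_radius is not None and len(ties) > 1:
        dmin = min(abs((y + 1) - prior_radius) for y in ties)
        ties = [y for y in ties if abs((y + 1) - prior_radius) == dmin]
    end = ties[0]
    return best, np.asarray(finals[end][1]) + 1
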