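"""Independent brute-force oracles used by unit and acceptance tests.

Everything here is written from first principles (plain loops, textbook
formulas) and never calls the implementation it checks.
"""

from __future__ import annotations

import itertools

import numpy as np


def brute_force_peaks(y: np.ndarray) -> list[tuple[int, int, int, float]]:
    """All strict local maxima with bounds at the nearest flanking minima
    and directly summed background-subtracted areas.

    Equivalent to detection with no prominence/SNR/merging thresholds.
    Returns (left, apex, right, area) tuples sorted by apex.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    out = []
    for apex in range(1, n - 1):
        if not (y[apex] > y[apex - 1] and y[apex] > y[apex + 1]):
            continue
        left = apex
        while left > 0 and y[left - 1] < y[left]:
            left -= 1
        right = apex
        while right < n - 1 and y[right + 1] < y[right]:
            right += 1
        area = 0.0
        for i in range(left, right + 1):
            if right == left:
                bg = y[left]
            else:
                bg = y[left] + (y[right] - y[left]) * (i - left) / (right - left)
            area += max(0.0, y[i] - bg)
        out.append((left, apex, right, area))
    return out


def step_up_bh(pvalues: list[float]) -> np.ndarray:
    """Benjamini-Hochberg by the step-up definition: sort ascending,
    q(i) = min_{j >= i} p(j) * m / j, capped at 1, back in input order."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        q[idx] = min(running, 1.0)
    return q


def naive_average_linkage(dist: np.ndarray) -> list[float]:
    """O(n^3) agglomeration returning the sorted merge heights.

    Average linkage between clusters A and B is the mean of all pairwise
    original distances; at each step the closest pair of clusters merges.
    """
    n = dist.shape[0]
    clusters: list[list[int]] = [[i] for i in range(n)]
    heights: list[float] = []
    while len(clusters) > 1:
        best = (np.inf, None)
        for a, b in itertools.combinations(range(len(clusters)), 2):
            d = float(np.mean([dist[i, j] for i in clusters[a]
                               for j in clusters[b]]))
            if d < best[0]:
                best = (d, (a, b))
        d, (a, b) = best
        heights.append(d)
        merged = clusters[a] + clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)]
        clusters.append(merged)
    return heights


def pooled_ttest_formula(groups: dict[str, np.ndarray], pair: tuple[str, str]
                         ) -> tuple[float, float]:
    """Explicit pooled-variance t-test over all groups (R pairwise.t.test)."""
    from scipy.stats import t as t_dist
    ss = sum(float(np.sum((v - v.mean()) ** 2)) for v in groups.values())
    big_n = sum(len(v) for v in groups.values())
    k = len(groups)
    df = big_n - k
    sp = np.sqrt(ss / df)
    xa, xb = groups[pair[0]], groups[pair[1]]
    se = sp * np.sqrt(1 / len(xa) + 1 / len(xb))
    t = (xa.mean() - xb.mean()) / se
    return float(t), float(2 * t_dist.sf(abs(t), df))


def pearson_formula(x: np.ndarray, y: np.ndarray) -> float:
    """Textbook covariance / sd formula."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    cov = np.mean((x - x.mean()) * (y - y.mean()))
    return float(cov / (x.std() * y.std()))
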