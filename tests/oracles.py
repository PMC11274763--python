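"""Brute-force reference implementations of every graph measure.

Deliberately naive (explicit loops, Floyd–Warshall, exhaustive geodesic
counting) and independent of the package's vectorized code paths; used to
validate the fast implementations on small graphs.
"""

import numpy as np


def oracle_distances(a):
    """Floyd–Warshall with explicit triple loop."""
    n = a.shape[0]
    d = np.full((n, n), np.inf)
    for i in range(n):
        d[i, i] = 0.0
    for i in range(n):
        for j in range(n):
            if a[i, j]:
                d[i, j] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def oracle_clustering(a):
    """Per-node triangle enumeration."""
    n = a.shape[0]
    c = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if a[i, j]]
        k = len(nbrs)
        if k < 2:
            continue
        e = sum(a[u, v] for ui, u in enumerate(nbrs) for v in nbrs[ui + 1:])
        c[i] = 2.0 * e / (k * (k - 1))
    return c, float(np.mean(c))


def oracle_path_length(a):
    d = oracle_distances(a)
    n = a.shape[0]
    li = np.full(n, np.nan)
    for i in range(n):
        vals = [d[i, j] for j in range(n) if j != i and np.isfinite(d[i, j])]
        if vals:
            li[i] = float(np.mean(vals))
    finite = li[np.isfinite(li)]
    return li, float(np.mean(finite)) if finite.size else float("nan")


def oracle_global_efficiency(a):
    d = oracle_distances(a)
    n = a.shape[0]
    if n < 2:
        return 0.0
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]) and d[i, j] > 0:
                total += 1.0 / d[i, j]
    return total / (n * (n - 1))


def oracle_local_efficiency(a):
    n = a.shape[0]
    el = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if a[i, j]]
        if len(nbrs) < 2:
            continue
        sub = a[np.ix_(nbrs, nbrs)]
        el[i] = oracle_global_efficiency(sub)
    return el, float(np.mean(el))


def _count_geodesics(a, d):
    """sigma[h, j] = number of shortest h-j paths, by dynamic programming
    over increasing distance."""
    n = a.shape[0]
    sigma = np.zeros((n, n))
    for h in range(n):
        sigma[h, h] = 1.0
        order = sorted(
            (j for j in range(n) if j != h and np.isfinite(d[h, j])),
            key=lambda j: d[h, j],
        )
        for j in order:
            sigma[h, j] = sum(
                sigma[h, k] for k in range(n) if a[k, j] and d[h, k] == d[h, j] - 1
            )
    return sigma


def oracle_betweenness(a):
    """Ordered-pair normalized betweenness from exhaustive geodesic counts."""
    n = a.shape[0]
    if n < 3:
        return np.zeros(n)
    d = oracle_distances(a)
    sigma = _count_geodesics(a, d)
    b = np.zeros(n)
    for i in range(n):
        total = 0.0
        for h in range(n):
            for j in range(n):
                if h == j or h == i or j == i:
                    continue
                if not np.isfinite(d[h, j]) or sigma[h, j] == 0:
                    continue
                if d[h, i] + d[i, j] == d[h, j]:
                    total += sigma[h, i] * sigma[i, j] / sigma[h, j]
        b[i] = total / ((n - 1) * (n - 2))
    return b


def oracle_modularity(a, m):
    """Direct double-sum of the modularity formula with l = sum of degrees."""
    n = a.shape[0]
    k = a.sum(axis=1).astype(float)
    l = float(k.sum())
    if l == 0:
        return 0.0
    q = 0.0
    for i in range(n):
        for j in range(n):
            if m[i] == m[j]:
                q += a[i, j] - k[i] * k[j] / l
    return q / l


def oracle_participation(a, m):
    n = a.shape[0]
    y = np.zeros(n)
    for i in range(n):
        k = float(a[i].sum())
        if k == 0:
            continue
        s = 0.0
        for mod in set(m):
            kim = sum(a[i, j] for j in range(n) if m[j] == mod)
            s += (kim / k) ** 2
        y[i] = 1.0 - s
    return y, float(np.mean(y))


def oracle_assortativity(a):
    """Pearson correlation of end-point degrees over the edge list (both
    orientations), via the textbook correlation formula."""
    k = a.sum(axis=1).astype(float)
    xs, ys = [], []
    n = a.shape[0]
    for i in range(n):
        for j in range(n):
            if i != j and a[i, j]:
                xs.append(k[i])
                ys.append(k[j])
    if not xs:
        return float("nan")
    x = np.array(xs)
    y = np.array(ys)
    sx = x.std()
    sy = y.std()
    if sx == 0 or sy == 0:
        return float("nan")
    return float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))
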