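"""Independent brute-force implementations of the six clustering metrics.

Written as plain double loops straight from the definitions; deliberately
kept free of any code shared with the package so they can serve as oracles.
"""

import numpy as np


def ripley_k_bruteforce(xy, area, radii):
    n = len(xy)
    out = []
    for r in radii:
        count = 0
        for i in range(n):
            for j in range(n):
                if i != j and np.hypot(*(xy[i] - xy[j])) <= r:
                    count += 1
        out.append(area / n**2 * count)
    return np.array(out)


def clustering_pct_bruteforce(xy, area, radii, n_steps):
    k = ripley_k_bruteforce(xy, area, radii)
    return 100.0 * sum(kk - np.pi * r**2 > 0 for kk, r in zip(k, radii)) / n_steps


def knn_edges_bruteforce(xy, k, eps=0.5):
    n = len(xy)
    d = np.array([[np.hypot(*(a - b)) for b in xy] for a in xy])
    edges = set()
    for i in range(n):
        order = sorted((j for j in range(n) if j != i), key=lambda j: d[i, j])
        for j in order[:k]:
            edges.add((min(i, j), max(i, j)))
    weights = {e: 1.0 / max(d[e], eps) ** 2 for e in edges}
    return edges, weights


def assortativity_bruteforce(xy, k):
    edges, weights = knn_edges_bruteforce(xy, k)
    n = len(xy)
    s = np.zeros(n)
    for (i, j), w in weights.items():
        s[i] += w
        s[j] += w
    xs, ys = [], []
    for i, j in edges:
        xs += [s[i], s[j]]
        ys += [s[j], s[i]]
    xs, ys = np.array(xs), np.array(ys)
    if xs.var() < 1e-30:
        return 0.0
    return float(((xs - xs.mean()) * (ys - ys.mean())).mean() / xs.var())


def modularity_bruteforce(xy, k, membership):
    """Weighted Q of a given partition, straight from the definition."""
    edges, weights = knn_edges_bruteforce(xy, k)
    n = len(xy)
    strength = np.zeros(n)
    for (i, j), w in weights.items():
        strength[i] += w
        strength[j] += w
    two_m = strength.sum()
    q = 0.0
    for i in range(n):
        for j in range(n):
            a_ij = weights.get((min(i, j), max(i, j)), 0.0) if i != j else 0.0
            if membership[i] == membership[j]:
                q += a_ij - strength[i] * strength[j] / two_m
    return q / two_m


def morans_i_bruteforce(xy):
    n = len(xy)
    vals = []
    for ax in range(2):
        x = xy[:, ax] - xy[:, ax].mean()
        if (x**2).sum() <= 1e-30:
            continue
        num = 0.0
        wsum = 0.0
        for i in range(n):
            for j in range(n):
                dij2 = ((xy[i] - xy[j]) ** 2).sum()
                w = 1.0 / dij2 if dij2 > 0 else 0.0
                num += w * x[i] * x[j]
                wsum += w
        vals.append(n * num / (wsum * (x**2).sum()))
    return float(np.mean(vals))


def mnnd_bruteforce(xy):
    n = len(xy)
    total = 0.0
    for i in range(n):
        total += min(np.hypot(*(xy[i] - xy[j])) for j in range(n) if j != i)
    return total / n


def dispersion_bruteforce(xy):
    d = [
        np.hypot(*(xy[i] - xy[j]))
        for i in range(len(xy))
        for j in range(i + 1, len(xy))
    ]
    d = np.array(d)
    return float(d.var(ddof=0) / d.mean())
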