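"""Independent reference implementations (oracles) shared across tests."""

import numpy as np


def brute_force_maxima(bp, params):
    """Independent enumeration of strict neighborhood maxima above the
    percentile threshold (plateau ties to smallest row-major index)."""
    positive = bp[bp > 0]
    if positive.size == 0:
        return []
    thr = np.percentile(positive, params.percentile)
    hw = max(1, int(params.separation) // 2)
    H, W = bp.shape
    out = []
    for y in range(H):
        for x in range(W):
            v = bp[y, x]
            if v <= thr:
                continue
            is_max = True
            for ny in range(max(0, y - hw), min(H, y + hw + 1)):
                for nx in range(max(0, x - hw), min(W, x + hw + 1)):
                    if (ny, nx) == (y, x):
                        continue
                    nv = bp[ny, nx]
                    if nv > v or (nv == v and (ny, nx) < (y, x)):
                        is_max = False
                        break
                if not is_max:
                    break
            if is_max:
                out.append((y, x))
    return out


def brute_force_dbscan(X, eps, min_samples):
    """O(N^2) reference density clustering with the same border tie rule."""
    n = len(X)
    d = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    neighbors = [np.flatnonzero(d[i] <= eps) for i in range(n)]
    core = np.array([len(nb) >= min_samples for nb in neighbors])
    labels = np.full(n, -1)
    cluster = 0
    for i in range(n):
        if not core[i] or labels[i] >= 0:
            continue
        stack = [i]
        labels[i] = cluster
        while stack:
            j = stack.pop()
            for k in neighbors[j]:
                if core[k] and labels[k] < 0:
                    labels[k] = cluster
                    stack.append(k)
        cluster += 1
    for i in range(n):
        if not core[i]:
            cores = [j for j in neighbors[i] if core[j]]
            if cores:
                labels[i] = labels[min(cores)]
    return labels


def partitions_equal(a, b):
    """Same partition up to label permutation, including the noise set."""
    a, b = np.asarray(a), np.asarray(b)
    if not np.array_equal(a == -1, b == -1):
        return False
    clusters_a = {frozenset(np.flatnonzero(a == k)) for k in np.unique(a) if k >= 0}
    clusters_b = {frozenset(np.flatnonzero(b == k)) for k in np.unique(b) if k >= 0}
    return clusters_a == clusters_b


def random_instance(seed):
    """Seeded blob mixture with random eps/min_samples, N <= 300."""
    rng = np.random.default_rng(seed)
    n_blobs = rng.integers(1, 5)
    dim = rng.integers(2, 5)
    pts = []
    for _ in range(n_blobs):
        center = rng.uniform(-5, 5, dim)
        pts.append(center + rng.normal(0, rng.uniform(0.1, 0.6), (rng.integers(20, 80), dim)))
    X = np.vstack(pts)[:300]
    eps = rng.uniform(0.2, 1.0)
    min_samples = int(rng.integers(2, 10))
    return X, eps, min_samples
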