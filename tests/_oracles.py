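"""Independent brute-force reference implementations used as oracles."""

import numpy as np


def naive_average_linkage_heights(D):
    """O(n^3) agglomerative average linkage on a square distance matrix:
    repeatedly merge the closest pair of clusters, where cluster distance
    is the plain mean of all cross-pair leaf distances.  Returns the
    sorted merge heights."""
    n = D.shape[0]
    clusters = {i: [i] for i in range(n)}
    heights = []
    next_id = n
    while len(clusters) > 1:
        best, best_h = None, np.inf
        keys = sorted(clusters)
        for ai, i in enumerate(keys):
            for j in keys[ai + 1 :]:
                h = np.mean([D[a, b] for a in clusters[i] for b in clusters[j]])
                if h < best_h - 1e-15:
                    best, best_h = (i, j), h
        i, j = best
        heights.append(best_h)
        clusters[next_id] = clusters.pop(i) + clusters.pop(j)
        next_id += 1
    return sorted(heights)


def stepup_bh(p):
    """Brute-force Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m - 1, -1, -1):
        running = min(running, p[order[rank]] * m / (rank + 1))
        adj[order[rank]] = running
    return adj
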