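"""Independent brute-force oracles used only by the tests.

These deliberately avoid the library's code paths: graph metrics are
computed from the adjacency matrix with hand-rolled BFS / triangle counting,
modularity by complete enumeration of restricted-growth label vectors, and
PERMANOVA from explicit group centroids in a Euclidean embedding.
"""

from __future__ import annotations

from collections import deque

import numpy as np


# --------------------------------------------------------------------------
# graph metrics from an adjacency matrix
# --------------------------------------------------------------------------

def bfs_all_pairs(adj: np.ndarray) -> np.ndarray:
    """All-pairs shortest path lengths by explicit BFS; -1 = unreachable."""
    n = adj.shape[0]
    dist = -np.ones((n, n), dtype=int)
    for s in range(n):
        dist[s, s] = 0
        q = deque([s])
        while q:
            u = q.popleft()
            for v in np.flatnonzero(adj[u]):
                if dist[s, v] < 0:
                    dist[s, v] = dist[s, u] + 1
                    q.append(v)
    return dist

def floyd_warshall(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    d = np.where(adj > 0, 1.0, np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        d = np.minimum(d, d[:, k:k + 1] + d[k:k + 1, :])
    return d

def brute_topology(adj: np.ndarray) -> dict:
    """The seven non-modularity topology metrics, from first principles."""
    n = adj.shape[0]
    e = int(adj.sum()) // 2
    degrees = adj.sum(axis=1)
    out = {
        "node_number": n,
        "edge_number": e,
        "average_degree": 2.0 * e / n,
        "graph_density": 2.0 * e / (n * (n - 1)) if n > 1 else 0.0,
    }
    dist = bfs_all_pairs(adj)
    reach = dist[(dist > 0)]
    out["average_path_length"] = float(reach.mean()) if len(reach) else float("nan")
    out["diameter"] = float(reach.max()) if len(reach) else float("nan")
    local = np.zeros(n)
    for u in range(n):
        nbrs = np.flatnonzero(adj[u])
        k = len(nbrs)
        if k >= 2:
            links = adj[np.ix_(nbrs, nbrs)].sum() / 2
            local[u] = 2.0 * links / (k * (k - 1))
    out["clustering_coefficient"] = float(local.mean())
    return out


# --------------------------------------------------------------------------
# exhaustive modularity
# --------------------------------------------------------------------------

def _restricted_growth_strings(n: int):
    """All set partitions of range(n) as label vectors (canonical form)."""
    labels = np.zeros(n, dtype=int)
    while True:
        yield labels.copy()
        # increment rightmost position that can grow
        i = n - 1
        while i > 0:
            if labels[i] <= labels[:i].max():
                labels[i] += 1
                labels[i + 1 :] = 0
                break
            i -= 1
        else:
            return

def modularity_of_labels(adj: np.ndarray, labels: np.ndarray) -> float:
    m = adj.sum() / 2.0
    k = adj.sum(axis=1)
    q = 0.0
    for c in np.unique(labels):
        idx = labels == c
        q += adj[np.ix_(idx, idx)].sum() / (2.0 * m) - (k[idx].sum() / (2.0 * m)) ** 2
    return q

def exhaustive_max_modularity(adj: np.ndarray) -> float:
    return max(
        modularity_of_labels(adj, lab) for lab in _restricted_growth_strings(adj.shape[0])
    )


# --------------------------------------------------------------------------
# PERMANOVA via explicit centroids in an exact Euclidean embedding
# --------------------------------------------------------------------------

def permanova_f_from_coords(coords: np.ndarray, labels: np.ndarray) -> float:
    """Pseudo-F from explicit group centroids of embedded points.

    For a Euclidean distance matrix this equals the distance-based
    decomposition (Anderson 2001).
    """
    grand = coords.mean(axis=0)
    uniq = np.unique(labels)
    n, a = len(labels), len(uniq)
    ss_within = 0.0
    ss_among = 0.0
    for g in uniq:
        pts = coords[labels == g]
        c = pts.mean(axis=0)
        ss_within += ((pts - c) ** 2).sum()
        ss_among += len(pts) * ((c - grand) ** 2).sum()
    return (ss_among / (a - 1)) / (ss_within / (n - a))
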