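"""Independent brute-force reference implementations used as test oracles.

Everything here works directly on explicit edge sets / adjacency matrices
with naive algorithms (edge scans, Floyd-Warshall, recursive shortest-path
enumeration, full eigendecomposition), deliberately sharing no code with
the package's implementations.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from agonet.ingest import PenNetwork


def make_net(edges, n=None, pen_id="pen", weights=None):
    """Build a PenNetwork over integer-named nodes from an edge iterable."""
    edges = list(edges)
    if n is None:
        n = max((max(i, j) for i, j in edges), default=-1) + 1
    nodes = tuple(f"n{k}" for k in range(n))
    w = {}
    for k, (i, j) in enumerate(edges):
        wt = 1 if weights is None else weights[k]
        w[(nodes[i], nodes[j])] = w.get((nodes[i], nodes[j]), 0) + wt
    return PenNetwork(pen_id=pen_id, nodes=nodes, weights=w)


def all_digraphs(n):
    """Yield every simple digraph on n labelled nodes as an edge list."""
    slots = [(i, j) for i in range(n) for j in range(n) if i != j]
    for mask in range(2 ** len(slots)):
        yield [e for k, e in enumerate(slots) if mask >> k & 1]


def random_digraph(rng, n, p=0.3):
    return [
        (i, j) for i in range(n) for j in range(n)
        if i != j and rng.random() < p
    ]


def brute_degrees(edges, n):
    """(in, out, all) per node by scanning the edge list."""
    edges = set(edges)
    in_d = [sum(1 for (a, b) in edges if b == v) for v in range(n)]
    out_d = [sum(1 for (a, b) in edges if a == v) for v in range(n)]
    return in_d, out_d, [i + o for i, o in zip(in_d, out_d)]


def brute_dist(edges, n):
    """Directed unweighted distances via Floyd-Warshall; inf if unreachable."""
    d = np.full((n, n), math.inf)
    np.fill_diagonal(d, 0)
    for i, j in edges:
        d[i, j] = 1
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def brute_closeness(edges, n):
    """1 / sum_j d(i,j), with unreachable pairs charged distance n."""
    d = brute_dist(edges, n)
    out = []
    for i in range(n):
        total = sum(
            (d[i, j] if math.isfinite(d[i, j]) else n)
            for j in range(n) if j != i
        )
        out.append(1.0 / total)
    return out


def brute_betweenness(edges, n):
    """Fractional-count betweenness by enumerating all shortest paths."""
    adj = [[] for _ in range(n)]
    for i, j in edges:
        adj[i].append(j)
    d = brute_dist(edges, n)

    def shortest_paths(s, t):
        # all node sequences s -> t of length exactly d[s, t]
        if not math.isfinite(d[s, t]):
            return []
        paths = []

        def walk(u, trail):
            if u == t:
                paths.append(tuple(trail))
                return
            for v in adj[u]:
                if d[u, t] == d[v, t] + 1:
                    walk(v, trail + [v])

        walk(s, [s])
        return paths

    scores = [0.0] * n
    for s in range(n):
        for t in range(n):
            if s == t:
                continue
            paths = shortest_paths(s, t)
            if not paths:
                continue
            sigma = len(paths)
            for v in range(n):
                if v in (s, t):
                    continue
                through = sum(1 for p in paths if v in p)
                scores[v] += through / sigma
    return scores


def brute_eigenvector(weight_matrix):
    """Principal eigenvector of the symmetrized matrix, max-scaled to 1."""
    a = np.asarray(weight_matrix, dtype=float)
    a = a + a.T
    vals, vecs = np.linalg.eigh(a)
    v = np.abs(vecs[:, np.argmax(vals)])
    return v / v.max()


def brute_density(edges, n):
    return len(set(edges)) / (n * (n - 1))


def brute_reciprocity(edges):
    edges = set(edges)
    return sum(1 for (i, j) in edges if (j, i) in edges) / len(edges)


def brute_hamming(edges_a, edges_b):
    return len(set(edges_a) ^ set(edges_b))


def rand_index(labels_a, labels_b):
    """Plain Rand index: pairwise co-assignment agreement."""
    items = list(labels_a)
    agree = total = 0
    for x, y in itertools.combinations(items, 2):
        same_a = labels_a[x] == labels_a[y]
        same_b = labels_b[x] == labels_b[y]
        agree += same_a == same_b
        total += 1
    return agree / total
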