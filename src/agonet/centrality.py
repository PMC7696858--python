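"""Individual network centrality measures for pen aggression networks.

Six per-animal measures: in-, out- and all-degree (distinct-partner edge
counts), closeness and betweenness on the unweighted directed graph, and
eigenvector centrality on the symmetrized weighted graph.

Conventions
-----------
* Degrees count distinct directed edges, not summed weights: an animal's
  out-degree is the number of pen-mates it attacked at least once.
* Shortest-path measures ignore weights (attack counts are interaction
  tallies, not distances) and follow edge direction.
* Closeness uses the finite-penalty convention for unreachable pairs:
  d(i, j) = n when no directed path i -> j exists, so every score is
  defined even on the mostly disconnected graphs that sparse aggression
  produces. An isolated animal in a pen of n then scores 1 / (n (n - 1)).
* Betweenness is raw (unnormalized) Freeman betweenness with fractional
  counting of tied shortest paths.
* Eigenvector centrality is the principal eigenvector of W + W^T, found by
  power iteration and rescaled so the maximum score is 1; a directed
  variant would be ill-defined on pens that are not strongly connected.
"""

from __future__ import annotations

from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .ingest import PenNetwork

__all__ = [
    "degree_centralities",
    "closeness_centrality",
    "betweenness_centrality",
    "eigenvector_centrality",
    "centrality_table",
    "MEASURES",
]

#: Column order of the per-animal centrality table.
MEASURES = (
    "all_degree",
    "in_degree",
    "out_degree",
    "closeness",
    "eigenvector",
    "betweenness",
)


def degree_centralities(
    net: PenNetwork,
) -> tuple[dict[str, int], dict[str, int], dict[str, int]]:
    """Return (in_degree, out_degree, all_degree) per animal.

    Degrees are unweighted counts of distinct directed edges, so
    all_degree = in_degree + out_degree always holds.
    """
    in_deg = {a: 0 for a in net.nodes}
    out_deg = {a: 0 for a in net.nodes}
    for i, j in net.edges:
        out_deg[i] += 1
        in_deg[j] += 1
    all_deg = {a: in_deg[a] + out_deg[a] for a in net.nodes}
    return in_deg, out_deg, all_deg


def closeness_centrality(net: PenNetwork) -> dict[str, float]:
    """Closeness c(i) = 1 / sum_j d(i, j) with unreachable d := n.

    Directed unweighted shortest paths; requires n >= 2.
    """
    n = net.n
    if n < 2:
        raise ValueError("closeness needs at least 2 animals")
    g = net.to_networkx(binary=True)
    scores: dict[str, float] = {}
    for i in net.nodes:
        dist = nx.single_source_shortest_path_length(g, i)
        total = sum(dist.get(j, n) for j in net.nodes if j != i)
        scores[i] = 1.0 / total
    return scores


def betweenness_centrality(net: PenNetwork) -> dict[str, float]:
    """Raw directed betweenness: sum over (s, t) of sigma_st(v)/sigma_st."""
    if net.n < 2:
        raise ValueError("betweenness needs at least 2 animals")
    g = net.to_networkx(binary=True)
    return dict(nx.betweenness_centrality(g, normalized=False, weight=None))


def eigenvector_centrality(
    net: PenNetwork, *, tol: float = 1e-10, max_iter: int = 100_000
) -> dict[str, float]:
    """Principal-eigenvector scores on the symmetrized weighted graph.

    The adjacency used is A = W + W^T (total aggression between each pair,
    regardless of direction). Power iteration runs to ``tol`` in the
    infinity norm and the vector is rescaled so max = 1. An edgeless
    network has every score defined as 0.
    """
    n = net.n
    a = np.zeros((n, n))
    idx = {node: k for k, node in enumerate(net.nodes)}
    for (i, j), w in net.weights.items():
        a[idx[i], idx[j]] += w
    a = a + a.T
    if not a.any():
        return {node: 0.0 for node in net.nodes}
    # Power iteration on A + I: same Perron vector, but the shift makes the
    # dominant eigenvalue strictly largest in magnitude, so the iteration
    # also converges on bipartite components (where lambda_min = -lambda_max).
    shifted = a + np.eye(n)
    v = np.ones(n) / np.sqrt(n)
    for _ in range(max_iter):
        nxt = shifted @ v
        norm = np.linalg.norm(nxt)
        if norm == 0:  # pragma: no cover - nonneg symmetric A with an edge
            break
        nxt /= norm
        if np.max(np.abs(nxt - v)) < tol:
            v = nxt
            break
        v = nxt
    v = np.abs(v)
    v /= v.max()
    return {node: float(v[idx[node]]) for node in net.nodes}


def centrality_table(net: PenNetwork) -> pd.DataFrame:
    """All six measures for every animal in one pen (tidy wide table)."""
    in_deg, out_deg, all_deg = degree_centralities(net)
    closeness = closeness_centrality(net)
    betweenness = betweenness_centrality(net)
    eigen = eigenvector_centrality(net)
    return pd.DataFrame(
        {
            "pen_id": net.pen_id,
            "animal_id": list(net.nodes),
            "all_degree": [all_deg[a] for a in net.nodes],
            "in_degree": [in_deg[a] for a in net.nodes],
            "out_degree": [out_deg[a] for a in net.nodes],
            "closeness": [closeness[a] for a in net.nodes],
            "eigenvector": [eigen[a] for a in net.nodes],
            "betweenness": [betweenness[a] for a in net.nodes],
        }
    )


def centrality_long(table: pd.DataFrame) -> pd.DataFrame:
    """Melt a wide centrality table to tidy (pen_id, animal_id, measure, value)."""
    return table.melt(
        id_vars=["pen_id", "animal_id"],
        value_vars=list(MEASURES),
        var_name="measure",
        value_name="value",
    )
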