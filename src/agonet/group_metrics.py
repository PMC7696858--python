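"""Pen-level network statistics.

Density, reciprocity, Freeman group centralization for the four
score-based measures, and Newman modularity with greedy community
detection on the symmetrized weighted aggression graph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping

import numpy as np
import pandas as pd

from . import centrality as _centrality
from .ingest import PenNetwork

__all__ = [
    "GroupMetrics",
    "density",
    "reciprocity",
    "centralization",
    "detect_communities",
    "modularity",
    "group_metrics",
]

#: Measures for which Freeman group centralization is reported.
CENTRALIZATION_MEASURES = ("degree", "eigenvector", "betweenness", "closeness")


@dataclass(frozen=True)
class GroupMetrics:
    """One pen's group-level network statistics."""

    pen_id: str
    n_animals: int
    density: float
    reciprocity: float
    centralization_degree: float
    centralization_eigenvector: float
    centralization_betweenness: float
    centralization_closeness: float
    modularity: float
    n_communities: int
    partition: Mapping[str, int]


def density(net: PenNetwork) -> float:
    """|E| / (n (n - 1)) for the binarized directed simple graph."""
    n = net.n
    if n < 2:
        raise ValueError("density needs at least 2 animals")
    return len(net.edges) / (n * (n - 1))


def reciprocity(net: PenNetwork) -> float:
    """Fraction of directed edges whose reverse edge also exists.

    Weights are ignored. An edgeless network is defined as 0 with a
    warning (reciprocity of nothing is vacuous).
    """
    edges = net.edges
    if not edges:
        warnings.warn(
            f"pen {net.pen_id!r}: reciprocity of an edgeless network "
            "defined as 0",
            stacklevel=2,
        )
        return 0.0
    mutual = sum(1 for (i, j) in edges if (j, i) in edges)
    return mutual / len(edges)


def _star_network(n: int) -> PenNetwork:
    """Bidirectional star on n nodes: the Freeman maximal configuration."""
    nodes = tuple(f"v{k}" for k in range(n))
    weights = {}
    for leaf in nodes[1:]:
        weights[(nodes[0], leaf)] = 1
        weights[(leaf, nodes[0])] = 1
    return PenNetwork(pen_id="star", nodes=nodes, weights=weights)


def _measure_scores(net: PenNetwork, measure: str) -> dict[str, float]:
    if measure == "degree":
        _, _, all_deg = _centrality.degree_centralities(net)
        return {a: float(v) for a, v in all_deg.items()}
    if measure == "closeness":
        return _centrality.closeness_centrality(net)
    if measure == "betweenness":
        return _centrality.betweenness_centrality(net)
    if measure == "eigenvector":
        return _centrality.eigenvector_centrality(net)
    raise ValueError(f"unknown measure {measure!r}")


@lru_cache(maxsize=None)
def _star_max(measure: str, n: int) -> float:
    """Theoretical maximum of sum(c_max - c_i), attained on the star."""
    scores = _measure_scores(_star_network(n), measure)
    c_max = max(scores.values())
    return sum(c_max - c for c in scores.values())


def centralization(
    scores: Mapping[str, float], measure: str, n: int | None = None
) -> float:
    """Freeman group centralization of per-animal scores, in [0, 1].

    sum_i (c_max - c_i) divided by the value that sum takes on the star
    configuration of the same size (Freeman's normalizing graph), then
    clamped to [0, 1]. Scores must come from the matching individual
    measure; ``n`` defaults to ``len(scores)``.
    """
    if measure not in CENTRALIZATION_MEASURES:
        raise ValueError(f"unknown measure {measure!r}")
    if n is None:
        n = len(scores)
    if n < 3:
        raise ValueError("centralization needs n >= 3 (degenerate denominator)")
    c_max = max(scores.values())
    numerator = sum(c_max - c for c in scores.values())
    denom = _star_max(measure, n)
    if denom <= 0:  # pragma: no cover - star sums are positive for n >= 3
        return 0.0
    return float(min(1.0, max(0.0, numerator / denom)))


def _symmetrized(net: PenNetwork) -> tuple[np.ndarray, list[str]]:
    nodes = list(net.nodes)
    idx = {a: k for k, a in enumerate(nodes)}
    w = np.zeros((len(nodes), len(nodes)))
    for (i, j), wt in net.weights.items():
        w[idx[i], idx[j]] += wt
    return w + w.T, nodes


def modularity(net: PenNetwork, partition: Mapping[str, int]) -> float:
    """Weighted Newman modularity Q of a partition, on W + W^T.

    Q = sum_c [ w_c / (2m) - (s_c / (2m))^2 ] with w_c the symmetrized
    weight inside community c (both orientations), s_c the summed node
    strength of c, and 2m the total symmetrized weight. Every node must
    be labelled. Q = 0 by convention on an edgeless network.
    """
    missing = [a for a in net.nodes if a not in partition]
    if missing:
        raise ValueError(f"unlabelled node(s): {missing}")
    a_sym, nodes = _symmetrized(net)
    two_m = a_sym.sum()
    if two_m == 0:
        return 0.0
    labels = np.asarray([partition[a] for a in nodes])
    strength = a_sym.sum(axis=1)
    q = 0.0
    for c in np.unique(labels):
        members = labels == c
        w_c = a_sym[np.ix_(members, members)].sum()
        s_c = strength[members].sum()
        q += w_c / two_m - (s_c / two_m) ** 2
    return float(q)


def detect_communities(net: PenNetwork) -> dict[str, int]:
    """Greedy agglomerative modularity maximization (CNM style).

    Starts from singleton communities on the symmetrized weighted graph
    and repeatedly merges the pair of communities with the largest
    modularity gain (ties broken by the lexicographically smallest pair
    of community representatives), stopping when no merge improves Q.
    The best partition encountered is returned; if nothing beats the
    trivial single community (Q = 0) that is returned instead, so the
    detected Q is never negative. Zero-degree animals always end up in
    singleton communities.
    """
    a_sym, nodes = _symmetrized(net)
    n = len(nodes)
    two_m = a_sym.sum()
    if two_m == 0:
        return {a: k for k, a in enumerate(nodes)}

    strength = a_sym.sum(axis=1)
    # communities as dict: representative (min node index) -> member indices
    comms: dict[int, list[int]] = {k: [k] for k in range(n)}
    # cached per-community totals
    w_in = {k: a_sym[k, k] for k in range(n)}  # zero: no self-loops
    s_tot = {k: strength[k] for k in range(n)}
    # cross weights between communities
    cross: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            if a_sym[i, j] > 0:
                cross[(i, j)] = 2.0 * a_sym[i, j]

    def q_now() -> float:
        return sum(
            w_in[c] / two_m - (s_tot[c] / two_m) ** 2 for c in comms
        )

    best_q = q_now()
    best_partition = {nodes[k]: rep for rep, mem in comms.items() for k in mem}

    # Merge connected community pairs all the way down the dendrogram,
    # always taking the largest modularity gain (negative gains included:
    # the optimum cut can lie past a locally bad merge), and keep the best
    # partition seen. Pairs in different components are never merged —
    # such a merge strictly lowers Q and cannot enable a better one.
    while len(comms) > 1 and cross:
        best_gain = -np.inf
        best_pair: tuple[int, int] | None = None
        for (ci, cj), w_between in cross.items():
            gain = w_between / two_m - 2 * (s_tot[ci] / two_m) * (
                s_tot[cj] / two_m
            )
            if gain > best_gain + 1e-15 or (
                abs(gain - best_gain) <= 1e-15
                and (best_pair is None or (ci, cj) < best_pair)
            ):
                best_gain = gain
                best_pair = (ci, cj)
        assert best_pair is not None
        ci, cj = best_pair
        # merge cj into ci
        w_in[ci] = w_in[ci] + w_in[cj] + cross.pop((ci, cj))
        s_tot[ci] += s_tot.pop(cj)
        comms[ci].extend(comms.pop(cj))
        del w_in[cj]
        for other in list(comms):
            if other in (ci, cj):
                continue
            key_j = (min(other, cj), max(other, cj))
            key_i = (min(other, ci), max(other, ci))
            if key_j in cross:
                cross[key_i] = cross.get(key_i, 0.0) + cross.pop(key_j)
        q = q_now()
        if q > best_q:
            best_q = q
            best_partition = {
                nodes[k]: rep for rep, mem in comms.items() for k in mem
            }

    if best_q < 0:
        best_partition = {a: 0 for a in nodes}

    # pull zero-strength animals out into their own singleton communities
    # (their modularity contribution is exactly 0 either way)
    partition = dict(best_partition)
    next_label = max(partition.values()) + 1
    for k, node in enumerate(nodes):
        if strength[k] == 0:
            partition[node] = next_label
            next_label += 1
    # relabel compactly in roster order
    relabel: dict[int, int] = {}
    for node in nodes:
        lab = partition[node]
        if lab not in relabel:
            relabel[lab] = len(relabel)
        partition[node] = relabel[lab]
    return partition


def group_metrics(net: PenNetwork) -> GroupMetrics:
    """Bundle all pen-level statistics for one network."""
    part = detect_communities(net)
    scores = {m: _measure_scores(net, m) for m in CENTRALIZATION_MEASURES}
    return GroupMetrics(
        pen_id=net.pen_id,
        n_animals=net.n,
        density=density(net),
        reciprocity=reciprocity(net),
        centralization_degree=centralization(scores["degree"], "degree"),
        centralization_eigenvector=centralization(
            scores["eigenvector"], "eigenvector"
        ),
        centralization_betweenness=centralization(
            scores["betweenness"], "betweenness"
        ),
        centralization_closeness=centralization(
            scores["closeness"], "closeness"
        ),
        modularity=modularity(net, part),
        n_communities=len(set(part.values())),
        partition=part,
    )


def group_metrics_frame(metrics: list[GroupMetrics]) -> pd.DataFrame:
    """One row per pen, ready for CSV export."""
    return pd.DataFrame(
        [
            {
                "pen_id": m.pen_id,
                "n_animals": m.n_animals,
                "density": m.density,
                "reciprocity": m.reciprocity,
                "centralization_degree": m.centralization_degree,
                "centralization_eigenvector": m.centralization_eigenvector,
                "centralization_betweenness": m.centralization_betweenness,
                "centralization_closeness": m.centralization_closeness,
                "modularity": m.modularity,
                "n_communities": m.n_communities,
            }
            for m in metrics
        ]
    )
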