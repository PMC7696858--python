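"""Between-pen comparison of aggression patterns.

Pens of equal size are compared by the Hamming distance between their
binarized directed edge sets, with animals matched across pens by roster
position (slot index). The resulting distance matrix is projected to two
dimensions with classical (Torgerson) multidimensional scaling.

Because different pens house different animals, there is no natural node
correspondence between them; matching by roster slot measures the
dissimilarity of labelled structure, which is what standard network
Hamming routines compute. Two pens at distance 0 have identical adjacency
patterns slot-for-slot, not merely isomorphic ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ingest import PenNetwork

__all__ = [
    "hamming_distance",
    "group_distance_matrix",
    "classical_mds",
    "MDSProjection",
]


def _slot_edges(net: PenNetwork) -> frozenset[tuple[int, int]]:
    idx = {a: k for k, a in enumerate(net.nodes)}
    return frozenset((idx[i], idx[j]) for (i, j) in net.edges)


def hamming_distance(net_a: PenNetwork, net_b: PenNetwork) -> int:
    """Edge additions/deletions turning one pen's edge set into the other's.

    Weights are binarized; nodes correspond by roster position. Defined
    only for pens with equal node counts.
    """
    if net_a.n != net_b.n:
        raise ValueError(
            f"Hamming distance needs equal pen sizes: {net_a.pen_id!r} has "
            f"{net_a.n} animals, {net_b.pen_id!r} has {net_b.n}"
        )
    return len(_slot_edges(net_a) ^ _slot_edges(net_b))


def group_distance_matrix(nets: list[PenNetwork]) -> pd.DataFrame:
    """Symmetric pairwise Hamming distance matrix for equal-size pens."""
    if len(nets) < 2:
        raise ValueError("need at least 2 pens to compare")
    sizes = {net.n for net in nets}
    if len(sizes) != 1:
        raise ValueError(f"mixed pen sizes {sorted(sizes)}: cannot compare")
    labels = [net.pen_id for net in nets]
    edge_sets = [_slot_edges(net) for net in nets]
    m = np.zeros((len(nets), len(nets)), dtype=int)
    for i in range(len(nets)):
        for j in range(i + 1, len(nets)):
            d = len(edge_sets[i] ^ edge_sets[j])
            m[i, j] = m[j, i] = d
    return pd.DataFrame(m, index=labels, columns=labels)


@dataclass(frozen=True)
class MDSProjection:
    """Classical MDS embedding: coordinates plus the full eigenvalue spectrum."""

    coords: pd.DataFrame  # index: pen id; columns: dim1..dimk
    eigenvalues: np.ndarray


def classical_mds(dist: pd.DataFrame | np.ndarray, k: int = 2) -> MDSProjection:
    """Torgerson classical scaling of a symmetric zero-diagonal matrix.

    B = -1/2 J D^2 J is double-centered; the top-k eigenpairs give
    coordinates X = V sqrt(Lambda). Negative eigenvalues (non-Euclidean
    input, common for graph distances) trigger a warning and are
    truncated at zero wherever they reach the top k. Requires k < number
    of points.
    """
    if isinstance(dist, pd.DataFrame):
        labels = list(dist.index)
        d = dist.to_numpy(dtype=float)
    else:
        d = np.asarray(dist, dtype=float)
        labels = [str(i) for i in range(d.shape[0])]
    n = d.shape[0]
    if d.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0):
        raise ValueError("distance matrix must have a zero diagonal")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of pens ({n})")
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    if (eigval < -1e-9 * max(1.0, abs(eigval[0]))).any():
        warnings.warn(
            "negative eigenvalues truncated at 0: the distances are not "
            "exactly Euclidean-embeddable",
            stacklevel=2,
        )
    top = np.clip(eigval[:k], 0.0, None)
    coords = eigvec[:, :k] * np.sqrt(top)
    frame = pd.DataFrame(
        coords, index=labels, columns=[f"dim{i + 1}" for i in range(k)]
    )
    return MDSProjection(coords=frame, eigenvalues=eigval)
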