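"""Structural node metrics: degree, eigenvector/closeness/betweenness
centrality, hop distances, k-shell, and the density quantities the
heat-conduction score composes.

Conventions
-----------
* Eigenvector centrality is L2-normalized (sum of squared scores = 1) with a
  non-negative orientation — the convention under which the worked example's
  published values check out.
* Distances are BFS hop counts; unreachable pairs carry ``UNREACHABLE`` (-1).
* Closeness on a disconnected graph is computed within each node's component,
  using the component size in place of N.
* Betweenness excludes endpoints and is pair-normalized by 2/((N-1)(N-2)).
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Mapping
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .network import Network

__all__ = [
    "ScoreVector",
    "DistanceMatrix",
    "UNREACHABLE",
    "ConvergenceError",
    "degree_vector",
    "degree_centrality",
    "eigenvector_centrality",
    "all_pairs_distances",
    "closeness_centrality",
    "network_density",
    "degree_density",
    "k_shell",
    "betweenness_centrality",
]

UNREACHABLE: int = -1


class ConvergenceError(RuntimeError):
    """Power iteration failed to converge within ``max_iter``."""


class ScoreVector(Mapping[str, float]):
    """Mapping node label -> finite real score, in a fixed label order.

    The common currency of the package: degrees, centralities,
    heat-conduction capacities and simulated influence all come back as
    ScoreVectors, so they can be ranked and compared uniformly.
    """

    def __init__(self, scores: Mapping[str, float] | Iterable[tuple[str, float]]):
        self._scores = dict(scores)
        vals = np.asarray(list(self._scores.values()), dtype=float)
        if vals.size and not np.all(np.isfinite(vals)):
            raise ValueError("scores must all be finite")

    def __getitem__(self, label: str) -> float:
        return self._scores[label]

    def __iter__(self):
        return iter(self._scores)

    def __len__(self) -> int:
        return len(self._scores)

    def __repr__(self) -> str:
        return f"ScoreVector({self._scores!r})"

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self._scores)

    def values_array(self, order: Iterable[str] | None = None) -> np.ndarray:
        """Scores as a float array, in ``order`` (default: own label order)."""
        labels = self.labels if order is None else tuple(order)
        return np.asarray([self._scores[l] for l in labels], dtype=float)

    def ranked(self) -> list[str]:
        """Labels in non-increasing score order; ties keep label order."""
        return sorted(self._scores, key=lambda l: -self._scores[l])

    def to_frame(self) -> pd.DataFrame:
        """Columns ``node, score, rank`` (rank 1 = highest, competition style)."""
        order = self.ranked()
        rank_of: dict[str, int] = {}
        prev_score, prev_rank = None, 0
        for pos, label in enumerate(order, start=1):
            s = self._scores[label]
            rank_of[label] = prev_rank if s == prev_score else pos
            prev_score, prev_rank = s, rank_of[label]
        return pd.DataFrame(
            {
                "node": list(self._scores),
                "score": [self._scores[l] for l in self._scores],
                "rank": [rank_of[l] for l in self._scores],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class DistanceMatrix:
    """All-pairs BFS hop counts with ``UNREACHABLE`` (-1) for cross-component
    pairs and zeros on the diagonal."""

    labels: tuple[str, ...]
    hops: np.ndarray  # (N, N) int array

    def __post_init__(self):
        object.__setattr__(
            self, "_index", {l: i for i, l in enumerate(self.labels)}
        )

    def get(self, u: str, v: str) -> int:
        """Hop count between ``u`` and ``v`` (``UNREACHABLE`` if disconnected)."""
        return int(self.hops[self._index[u], self._index[v]])

    def is_reachable(self, u: str, v: str) -> bool:
        return self.get(u, v) != UNREACHABLE


def degree_vector(net: Network) -> ScoreVector:
    """Node degrees (sum over the adjacency row)."""
    return ScoreVector({l: float(net.degree(l)) for l in net.labels})


def degree_centrality(net: Network) -> ScoreVector:
    """Degree normalized by N-1, in [0, 1]."""
    if net.N < 2:
        raise ValueError("degree centrality undefined for N < 2")
    return ScoreVector({l: net.degree(l) / (net.N - 1) for l in net.labels})


def eigenvector_centrality(
    net: Network, tol: float = 1e-10, max_iter: int = 1000
) -> ScoreVector:
    """Principal-eigenvector scores of the adjacency matrix.

    Power iteration on A + I (the shift leaves eigenvectors unchanged and
    prevents the period-2 oscillation bipartite graphs would otherwise cause),
    started from a uniform positive vector.  Convergence is declared when the
    max-norm difference of successive L2-normalized iterates falls below
    ``tol``.  The result is non-negative with unit Euclidean norm.

    Raises
    ------
    ValueError
        If the graph has no edges (the principal eigenvalue is 0).
    ConvergenceError
        If ``max_iter`` iterations do not reach ``tol``; the error message
        reports the final residual.
    """
    if net.M == 0:
        raise ValueError("eigenvector centrality undefined for an edgeless graph")
    a = nx.to_numpy_array(net.to_networkx(), nodelist=net.labels)
    n = net.N
    x = np.full(n, 1.0 / math.sqrt(n))
    residual = math.inf
    for _ in range(max_iter):
        y = a @ x + x
        y /= np.linalg.norm(y)
        residual = float(np.max(np.abs(y - x)))
        x = y
        if residual < tol:
            break
    else:
        raise ConvergenceError(
            f"power iteration did not converge in {max_iter} iterations "
            f"(residual {residual:.3e} > tol {tol:.1e})"
        )
    x = np.abs(x)  # Perron vector: fix orientation, clear sign noise
    x /= np.linalg.norm(x)
    return ScoreVector(dict(zip(net.labels, x.tolist())))


def all_pairs_distances(net: Network) -> DistanceMatrix:
    """BFS hop counts between every node pair (O(N·M) total)."""
    n = net.N
    hops = np.full((n, n), UNREACHABLE, dtype=np.int64)
    g = net.to_networkx()
    for src, lengths in nx.all_pairs_shortest_path_length(g):
        i = net.index(src)
        for dst, d in lengths.items():
            hops[i, net.index(dst)] = d
    return DistanceMatrix(net.labels, hops)


def closeness_centrality(
    net: Network, dist: DistanceMatrix | None = None
) -> ScoreVector:
    """Closeness (N-1) / sum of hop distances, per connected component.

    On a disconnected graph each node is scored within its own component
    with that component's size standing in for N; isolated nodes score 0.
    """
    if net.N < 2:
        raise ValueError("closeness undefined for N < 2")
    if dist is None:
        dist = all_pairs_distances(net)
    hops = dist.hops
    scores: dict[str, float] = {}
    for i, label in enumerate(net.labels):
        row = hops[i]
        reachable = row != UNREACHABLE
        n_comp = int(reachable.sum())  # includes self
        total = int(row[reachable].sum())
        scores[label] = (n_comp - 1) / total if total > 0 else 0.0
    return ScoreVector(scores)


def network_density(net: Network) -> float:
    """Fraction of realized edges: 2·M / (N·(N-1))."""
    if net.N < 2:
        raise ValueError("network density undefined for N < 2")
    return 2.0 * net.M / (net.N * (net.N - 1))


def degree_density(
    receiver_degree: int, distance: int, mode: str = "quadratic"
) -> float:
    """Degree of the receiving node spread over the "contact area" at hop
    distance R.

    ``mode="quadratic"`` uses the area of a circle of radius R, D/(π·R²);
    ``mode="exponential"`` uses D/π^R, the convention under which the worked
    example's published output values reproduce (see :mod:`hcmnet.hcm`).
    """
    if distance < 1:
        raise ValueError(f"distance must be >= 1 (reachable), got {distance}")
    if receiver_degree < 0:
        raise ValueError("receiver_degree must be >= 0")
    if mode == "quadratic":
        return receiver_degree / (math.pi * distance**2)
    if mode == "exponential":
        return receiver_degree / math.pi**distance
    raise ValueError(f"mode must be 'quadratic' or 'exponential', got {mode!r}")


def k_shell(net: Network) -> ScoreVector:
    """Core index from recursive removal of nodes by increasing degree."""
    core = nx.core_number(net.to_networkx())
    return ScoreVector({l: float(core[l]) for l in net.labels})


def betweenness_centrality(net: Network) -> ScoreVector:
    """Shortest-path betweenness, endpoints excluded, pair-normalized."""
    bc = nx.betweenness_centrality(net.to_networkx(), normalized=True)
    return ScoreVector({l: float(bc[l]) for l in net.labels})
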