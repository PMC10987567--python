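"""Undirected simple graphs from plain-text edge lists.

Every other module operates on :class:`Network`: an undirected, unweighted,
simple graph with opaque string node labels.  Labels keep first-appearance
order, which is also the deterministic tie-break order used by every ranking
in the package.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Sequence
from pathlib import Path

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "Network",
    "read_edge_list",
    "write_edge_list",
    "example_network",
    "largest_component",
    "generate_er",
    "generate_ba",
]


class Network:
    """An undirected, unweighted, simple graph.

    Parameters
    ----------
    edges
        Iterable of ``(u, v)`` label pairs.  Self-loops and duplicate pairs
        (in either orientation) are dropped with a logged warning.
    nodes
        Optional extra labels (e.g. isolated nodes), prepended to the
        first-appearance order ahead of labels introduced by ``edges``.

    Attributes
    ----------
    labels : tuple of str
        Node labels in first-appearance order.
    edges : tuple of (str, str)
        Each unordered pair once, oriented by first-appearance index.
    """

    def __init__(
        self,
        edges: Iterable[tuple[str, str]] = (),
        nodes: Iterable[str] = (),
    ) -> None:
        index: dict[str, int] = {}

        def intern(label: str) -> int:
            if label not in index:
                index[label] = len(index)
            return index[label]

        for label in nodes:
            intern(str(label))

        seen: set[tuple[int, int]] = set()
        kept: list[tuple[str, str]] = []
        n_loops = n_dups = 0
        for u, v in edges:
            u, v = str(u), str(v)
            iu, iv = intern(u), intern(v)
            if iu == iv:
                n_loops += 1
                continue
            key = (iu, iv) if iu < iv else (iv, iu)
            if key in seen:
                n_dups += 1
                continue
            seen.add(key)
            kept.append((u, v) if iu < iv else (v, u))
        if n_loops:
            logger.warning("dropped %d self-loop(s)", n_loops)
        if n_dups:
            logger.warning("dropped %d duplicate edge(s)", n_dups)

        self._index = index
        self.labels: tuple[str, ...] = tuple(index)
        self.edges: tuple[tuple[str, str], ...] = tuple(kept)
        self._adj: dict[str, list[str]] = {label: [] for label in self.labels}
        for u, v in self.edges:
            self._adj[u].append(v)
            self._adj[v].append(u)
        # neighbor lists in first-appearance order, for deterministic iteration
        for label in self.labels:
            self._adj[label].sort(key=self._index.__getitem__)

    # -- basic accessors ---------------------------------------------------

    @property
    def N(self) -> int:
        """Node count."""
        return len(self.labels)

    @property
    def M(self) -> int:
        """Edge count."""
        return len(self.edges)

    def index(self, label: str) -> int:
        return self._index[label]

    def degree(self, label: str) -> int:
        return len(self._adj[label])

    def neighbors(self, label: str) -> Sequence[str]:
        return self._adj[label]

    def has_edge(self, u: str, v: str) -> bool:
        return v in self._adj[u]

    def __contains__(self, label: str) -> bool:
        return label in self._index

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Network):
            return NotImplemented
        return set(self.labels) == set(other.labels) and {
            frozenset(e) for e in self.edges
        } == {frozenset(e) for e in other.edges}

    def __hash__(self) -> int:  # labels are orderable strings
        return hash((frozenset(self.labels), frozenset(frozenset(e) for e in self.edges)))

    def __repr__(self) -> str:
        return f"Network(N={self.N}, M={self.M})"

    def to_networkx(self) -> nx.Graph:
        """Equivalent :class:`networkx.Graph`, node order = label order."""
        g = nx.Graph()
        g.add_nodes_from(self.labels)
        g.add_edges_from(self.edges)
        return g

    def subgraph(self, keep: Iterable[str]) -> "Network":
        """Induced subgraph; label order inherited from this network."""
        keep_set = set(keep)
        nodes = [l for l in self.labels if l in keep_set]
        edges = [(u, v) for u, v in self.edges if u in keep_set and v in keep_set]
        return Network(edges, nodes=nodes)

    def connected_components(self) -> list[list[str]]:
        """Components as label lists, ordered by smallest first-appearance member."""
        comps = nx.connected_components(self.to_networkx())
        ordered = [sorted(c, key=self._index.__getitem__) for c in comps]
        ordered.sort(key=lambda c: self._index[c[0]])
        return ordered


def read_edge_list(
    path: str | Path,
    delimiter: str | None = None,
    comment_prefix: str = "#",
) -> Network:
    """Load a :class:`Network` from a plain-text edge list.

    One edge per line, two labels separated by whitespace (or ``delimiter``);
    lines starting with ``comment_prefix`` and blank lines are ignored.
    With ``delimiter=None`` a comma is auto-detected per line, falling back
    to whitespace.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    ValueError
        On a non-comment line with fewer than two fields, naming the line.
    """
    path = Path(path)
    edges: list[tuple[str, str]] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(comment_prefix):
                continue
            if delimiter is not None:
                fields = [f for f in line.split(delimiter) if f.strip()]
            elif "," in line:
                fields = [f for f in line.split(",") if f.strip()]
            else:
                fields = line.split()
            if len(fields) < 2:
                raise ValueError(
                    f"{path}:{lineno}: expected at least two fields, got {line!r}"
                )
            edges.append((fields[0].strip(), fields[1].strip()))
    return Network(edges)


def write_edge_list(net: Network, path: str | Path) -> None:
    """Write one tab-separated ``u<TAB>v`` line per edge (each pair once)."""
    path = Path(path)
    with path.open("w") as fh:
        for u, v in net.edges:
            fh.write(f"{u}\t{v}\n")


#: Edge set of the 11-node worked example, reconstructed from the published
#: distance table (the pairs at hop distance 1).
_EXAMPLE_EDGES: tuple[tuple[str, str], ...] = (
    ("v1", "v2"), ("v1", "v3"), ("v1", "v8"), ("v1", "v9"),
    ("v2", "v3"), ("v2", "v7"),
    ("v3", "v4"),
    ("v4", "v5"), ("v4", "v6"), ("v4", "v7"),
    ("v6", "v7"),
    ("v8", "v9"), ("v8", "v11"),
    ("v9", "v10"), ("v9", "v11"),
    ("v10", "v11"),
)


def example_network() -> Network:
    """The 11-node / 16-edge worked-example network.

    Node ``v1`` bridges the two halves of the graph: removing it splits the
    network into two components, which is why it tops every sensible
    importance ranking of this fixture.
    """
    return Network(_EXAMPLE_EDGES, nodes=[f"v{i}" for i in range(1, 12)])


def largest_component(net: Network) -> Network:
    """Induced subgraph on the largest connected component.

    Ties are broken toward the component containing the earliest
    first-appearance label.  Needed because hop-distance-based scores
    (closeness, heat-conduction capacity) are undefined across components.
    """
    comps = net.connected_components()
    best = max(comps, key=len)  # max() keeps the first among equal sizes
    return net.subgraph(best)


def generate_er(n: int, p: float, seed: int) -> Network:
    """Erdős–Rényi G(n, p) graph with string labels ``"0".."n-1"``."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    g = nx.gnp_random_graph(n, p, seed=seed)
    return Network(
        ((str(u), str(v)) for u, v in g.edges()),
        nodes=(str(i) for i in range(n)),
    )


def generate_ba(n: int, m: int, seed: int) -> Network:
    """Barabási–Albert preferential-attachment graph, ``m`` edges per new node."""
    if not 1 <= m < n:
        raise ValueError(f"require 1 <= m < n, got m={m}, n={n}")
    g = nx.barabasi_albert_graph(n, m, seed=seed)
    return Network(
        ((str(u), str(v)) for u, v in g.edges()),
        nodes=(str(i) for i in range(n)),
    )
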