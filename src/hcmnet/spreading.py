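"""Stochastic spreading processes used as ground truth for node importance.

Two agent-based processes on the graph:

* a synchronous discrete-time SIR: each step every infective node infects
  each susceptible neighbor independently with probability alpha, then
  recovers with probability beta (recovery is processed after infection, so
  with beta = 1 each infective node gets exactly one infection round);
* the independent cascade (IC): each newly activated node gets a single
  chance, with probability p, to activate each inactive neighbor.

With beta = 1 the SIR final-size distribution coincides with bond
percolation at per-edge probability alpha, and hence with the IC at p =
alpha.  That equivalence gives an exact small-graph oracle: enumerate all
2^M edge subsets (:func:`exact_mean_outbreak`,
:func:`exact_percolation_influence`).

A node's influence score is the mean number of initially susceptible nodes
it ever infects, averaged over Monte-Carlo runs with that node as the sole
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections.abc import Iterable, Sequence

import numpy as np

from .metrics import ScoreVector
from .network import Network

__all__ = [
    "SIRConfig",
    "SpreadResult",
    "sir_run",
    "sir_spread",
    "sir_influence",
    "ic_run",
    "ic_spread",
    "exact_mean_outbreak",
    "exact_percolation_influence",
]


@dataclass(frozen=True)
class SIRConfig:
    """Parameters of the discrete-time SIR process.

    alpha
        Per-contact infection probability per step.
    beta
        Per-step recovery probability of an infective node (default 1: a
        node is infective for exactly one step).
    t_max
        Step horizon; with beta = 1 epidemics die out within the graph
        diameter, so the default 30 rarely truncates.
    runs
        Monte-Carlo repetitions for averaged quantities.
    seed
        Master RNG seed; per-node / per-run substreams are derived from it
        deterministically.
    """

    alpha: float
    beta: float = 1.0
    t_max: int = 30
    runs: int = 1000
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if not 0.0 < self.beta <= 1.0:
            raise ValueError(f"beta must be in (0, 1], got {self.beta}")
        if self.t_max < 1:
            raise ValueError("t_max must be >= 1")
        if self.runs < 1:
            raise ValueError("runs must be >= 1")


@dataclass
class SpreadResult:
    """Per-run and averaged outcomes of a stochastic spreading experiment."""

    final_counts: np.ndarray  # one final count per run
    trajectory_mean: np.ndarray  # mean cumulative count per step
    meta: dict = field(default_factory=dict)

    @property
    def mean_final(self) -> float:
        return float(self.final_counts.mean())

    @property
    def sem_final(self) -> float:
        """Monte-Carlo standard error of the mean final count."""
        n = len(self.final_counts)
        return float(self.final_counts.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0


def _check_seeds(net: Network, seeds: Iterable[str]) -> list[str]:
    seeds = list(dict.fromkeys(seeds))
    if not seeds:
        raise ValueError("seed set must be non-empty")
    missing = [s for s in seeds if s not in net]
    if missing:
        raise ValueError(f"seed node(s) not in network: {missing}")
    return sorted(seeds, key=net.index)


def sir_run(
    net: Network,
    seeds: Iterable[str],
    config: SIRConfig,
    rng: np.random.Generator | None = None,
) -> tuple[int, list[int]]:
    """One SIR realization.

    Returns ``(infection_value, trajectory)``: the number of initially
    susceptible nodes ever infected (seeds excluded), and the cumulative
    count of those nodes at the end of each step.  Nodes are processed in
    first-appearance order so a fixed RNG stream gives a reproducible run.
    """
    seeds = _check_seeds(net, seeds)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    infective = list(seeds)
    ever = set(seeds)
    n_new_total = 0
    trajectory: list[int] = []
    for _ in range(config.t_max):
        if not infective:
            break
        newly: list[str] = []
        for u in infective:
            for v in net.neighbors(u):
                if v not in ever and rng.random() < config.alpha:
                    ever.add(v)
                    newly.append(v)
        survivors = [u for u in infective if rng.random() >= config.beta]
        infective = survivors + newly
        n_new_total += len(newly)
        trajectory.append(n_new_total)
    return n_new_total, trajectory


def sir_spread(
    net: Network, seeds: Iterable[str], config: SIRConfig
) -> SpreadResult:
    """Monte-Carlo SIR from a fixed seed set: final counts and mean trajectory."""
    seeds = _check_seeds(net, seeds)
    ss = np.random.SeedSequence(config.seed)
    finals = np.empty(config.runs, dtype=np.int64)
    trajs = np.zeros((config.runs, config.t_max), dtype=np.float64)
    for r, child in enumerate(ss.spawn(config.runs)):
        final, traj = sir_run(net, seeds, config, np.random.default_rng(child))
        finals[r] = final
        # carry the cumulative count forward to t_max after extinction
        trajs[r, : len(traj)] = traj
        trajs[r, len(traj):] = traj[-1] if traj else 0
    return SpreadResult(
        final_counts=finals,
        trajectory_mean=trajs.mean(axis=0),
        meta={"process": "sir", "alpha": config.alpha, "beta": config.beta,
              "runs": config.runs, "seed": config.seed, "seeds": list(seeds)},
    )


def sir_influence(net: Network, config: SIRConfig) -> ScoreVector:
    """Mean infection value of every node as a single seed.

    Each node gets its own deterministic RNG substream spawned from
    ``config.seed``, so scores are reproducible and independent of the
    order nodes are processed in.
    """
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(net.N)
    scores: dict[str, float] = {}
    for i, label in enumerate(net.labels):
        rng = np.random.default_rng(children[i])
        total = 0
        for _ in range(config.runs):
            final, _ = sir_run(net, [label], config, rng)
            total += final
        scores[label] = total / config.runs
    return ScoreVector(scores)


def ic_run(
    net: Network,
    seeds: Iterable[str],
    p: float,
    rng: np.random.Generator | None = None,
    include_seeds: bool = True,
) -> int:
    """One independent-cascade realization; returns the activated count.

    Each newly activated node makes one attempt, with probability ``p``,
    on each of its not-yet-active neighbors; the cascade stops when a round
    activates nobody.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    seeds = _check_seeds(net, seeds)
    if rng is None:
        rng = np.random.default_rng()
    active = set(seeds)
    frontier = list(seeds)
    while frontier:
        nxt: list[str] = []
        for u in frontier:
            for v in net.neighbors(u):
                if v not in active and rng.random() < p:
                    active.add(v)
                    nxt.append(v)
        frontier = nxt
    return len(active) if include_seeds else len(active) - len(seeds)


def ic_spread(
    net: Network,
    seeds: Iterable[str],
    p: float,
    runs: int = 1000,
    seed: int = 0,
    include_seeds: bool = True,
) -> SpreadResult:
    """Mean IC activation over ``runs`` independent cascades."""
    seeds = _check_seeds(net, seeds)
    ss = np.random.SeedSequence(seed)
    finals = np.empty(runs, dtype=np.int64)
    for r, child in enumerate(ss.spawn(runs)):
        finals[r] = ic_run(net, seeds, p, np.random.default_rng(child), include_seeds)
    return SpreadResult(
        final_counts=finals,
        trajectory_mean=np.array([finals.mean()]),
        meta={"process": "ic", "p": p, "runs": runs, "seed": seed,
              "seeds": list(seeds), "include_seeds": include_seeds},
    )


# ---------------------------------------------------------------------------
# Exact bond-percolation oracles (2^M edge-subset enumeration)
# ---------------------------------------------------------------------------

_MAX_EXACT_EDGES = 20


def _component_sizes_per_subset(net: Network) -> tuple[np.ndarray, np.ndarray]:
    """For every edge subset: a component label per node, plus subset sizes.

    Returns ``(comp_labels, popcounts)`` where ``comp_labels[s, i]`` is the
    root of node i's component when exactly the edges in bitmask ``s`` are
    kept.  Only feasible for M <= 20.
    """
    m, n = net.M, net.N
    if m > _MAX_EXACT_EDGES:
        raise ValueError(f"exact enumeration limited to M <= {_MAX_EXACT_EDGES}, got {m}")
    edge_idx = [(net.index(u), net.index(v)) for u, v in net.edges]
    comp = np.empty((1 << m, n), dtype=np.int8)
    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for s in range(1 << m):
        for i in range(n):
            parent[i] = i
        for e in range(m):
            if s >> e & 1:
                ra, rb = find(edge_idx[e][0]), find(edge_idx[e][1])
                if ra != rb:
                    parent[rb] = ra
        comp[s] = [find(i) for i in range(n)]
    pop = np.array([bin(s).count("1") for s in range(1 << m)], dtype=np.int64)
    return comp, pop


def _subset_weights(m: int, pop: np.ndarray, p: float) -> np.ndarray:
    with np.errstate(divide="ignore"):
        logw = pop * np.log(p) if p > 0 else np.where(pop == 0, 0.0, -np.inf)
        logq = (m - pop) * np.log(1 - p) if p < 1 else np.where(pop == m, 0.0, -np.inf)
    return np.exp(logw + logq)


def exact_mean_outbreak(
    net: Network, seeds: Iterable[str], p: float, include_seeds: bool = True
) -> float:
    """Exact expected outbreak size from ``seeds`` under bond percolation
    with per-edge probability ``p`` — the β=1 SIR / IC final-size mean.

    Enumerates all 2^M edge subsets; M <= 20 only.
    """
    seeds = _check_seeds(net, seeds)
    comp, pop = _component_sizes_per_subset(net)
    seed_idx = [net.index(s) for s in seeds]
    seed_roots = comp[:, seed_idx]  # (2^M, |seeds|)
    reached = (comp[:, :, None] == seed_roots[:, None, :]).any(axis=2).sum(axis=1)
    w = _subset_weights(net.M, pop, p)
    mean = float(w @ reached)
    return mean if include_seeds else mean - len(seeds)


def exact_percolation_influence(net: Network, p: float) -> ScoreVector:
    """Exact single-seed influence of every node under bond percolation:
    the expected size of the node's percolation component minus one."""
    comp, pop = _component_sizes_per_subset(net)
    w = _subset_weights(net.M, pop, p)
    scores: dict[str, float] = {}
    for i, label in enumerate(net.labels):
        sizes = (comp == comp[:, [i]]).sum(axis=1)
        scores[label] = float(w @ (sizes - 1))
    return ScoreVector(scores)
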