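"""Experiment drivers: score a network with several algorithms, sweep the
SIR infection rate for Kendall-tau agreement, tabulate top-k selections,
and measure multi-seed spreading from each algorithm's top nodes.

These functions return pandas DataFrames; the CLI wraps them and writes
CSV.  Every stochastic quantity is driven by one master seed so reruns
with an identical configuration are identical.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd

from .evaluation import kendall_tau, top_k
from .hcm import HCMConfig, hcm_scores
from .metrics import (
    ScoreVector,
    betweenness_centrality,
    closeness_centrality,
    degree_centrality,
    eigenvector_centrality,
    k_shell,
)
from .network import Network
from .spreading import SIRConfig, ic_spread, sir_influence, sir_spread

__all__ = [
    "ALGORITHMS",
    "compute_scores",
    "compare_experiment",
    "topk_experiment",
    "spread_experiment",
]

#: Registry of implemented ranking algorithms.  Extensible: register a
#: callable ``(net, area_mode) -> ScoreVector`` under a new name.
ALGORITHMS = {
    "hcm": lambda net, area_mode: hcm_scores(net, HCMConfig(area_mode=area_mode)),
    "dc": lambda net, area_mode: degree_centrality(net),
    "ec": lambda net, area_mode: eigenvector_centrality(net),
    "cc": lambda net, area_mode: closeness_centrality(net),
    "bc": lambda net, area_mode: betweenness_centrality(net),
    "kshell": lambda net, area_mode: k_shell(net),
}


def compute_scores(
    net: Network, algorithm: str, area_mode: str = "exponential"
) -> ScoreVector:
    """Score every node with a registered algorithm."""
    try:
        fn = ALGORITHMS[algorithm]
    except KeyError:
        raise ValueError(
            f"unknown algorithm {algorithm!r}; available: {sorted(ALGORITHMS)}"
        ) from None
    return fn(net, area_mode)


def compare_experiment(
    net: Network,
    algorithms: Sequence[str],
    alphas: Iterable[float],
    beta: float = 1.0,
    runs: int = 1000,
    seed: int = 0,
    variant: str = "b",
    t_max: int = 30,
    area_mode: str = "exponential",
) -> pd.DataFrame:
    """Kendall tau of each algorithm against SIR influence at each alpha.

    The SIR ground truth at a given alpha is computed once and shared by
    all algorithms.  Returns long-form rows ``algorithm, alpha, tau,
    variant, runs`` plus one ``alpha = "mean"`` summary row per algorithm.
    """
    alphas = [float(a) for a in alphas]
    scores = {a: compute_scores(net, a, area_mode) for a in algorithms}
    rows = []
    taus: dict[str, list[float]] = {a: [] for a in algorithms}
    for alpha in alphas:
        cfg = SIRConfig(alpha=alpha, beta=beta, t_max=t_max, runs=runs, seed=seed)
        influence = sir_influence(net, cfg)
        for algo in algorithms:
            res = kendall_tau(scores[algo], influence, variant=variant)
            taus[algo].append(res.tau)
            rows.append({"algorithm": algo, "alpha": alpha, "tau": res.tau,
                         "variant": variant, "runs": runs})
    for algo in algorithms:
        rows.append({"algorithm": algo, "alpha": "mean",
                     "tau": float(np.mean(taus[algo])), "variant": variant,
                     "runs": runs})
    return pd.DataFrame(rows)


def topk_experiment(
    net: Network,
    algorithms: Sequence[str],
    k: int,
    alpha: float = 0.1,
    beta: float = 1.0,
    runs: int = 1000,
    seed: int = 0,
    area_mode: str = "exponential",
) -> pd.DataFrame:
    """Top-k nodes per algorithm, with overlap against the SIR top-k.

    Rows ``algorithm, position, node, in_sir_topk`` plus an ``overlap``
    summary row per algorithm (|algorithm top-k ∩ SIR top-k|).
    """
    cfg = SIRConfig(alpha=alpha, beta=beta, runs=runs, seed=seed)
    sir_scores = sir_influence(net, cfg)
    sir_top = set(top_k(sir_scores, k))
    rows = []
    for algo in list(algorithms) + ["sir"]:
        scores = sir_scores if algo == "sir" else compute_scores(net, algo, area_mode)
        picks = top_k(scores, k)
        for pos, node in enumerate(picks, start=1):
            rows.append({"algorithm": algo, "position": pos, "node": node,
                         "in_sir_topk": node in sir_top})
        rows.append({"algorithm": algo, "position": "overlap",
                     "node": sum(n in sir_top for n in picks),
                     "in_sir_topk": True})
    return pd.DataFrame(rows)


def spread_experiment(
    net: Network,
    algorithms: Sequence[str],
    seed_counts: Sequence[int] = (2, 4, 6, 8, 10),
    alpha: float = 0.5,
    beta: float = 1.0,
    t_max: int = 30,
    p: float = 0.5,
    runs: int = 1000,
    seed: int = 0,
    area_mode: str = "exponential",
) -> pd.DataFrame:
    """Multi-seed spreading from each algorithm's top nodes.

    For each algorithm and seed count: the SIR mean trajectory (cumulative
    newly infected per step, seeds excluded) and the IC mean activation
    (seeds included).  Long-form rows ``algorithm, n_seeds, process, step,
    value``; IC rows carry ``step = "final"``.
    """
    if max(seed_counts) > net.N:
        raise ValueError("seed count exceeds network size")
    rows = []
    for algo in algorithms:
        scores = compute_scores(net, algo, area_mode)
        for n_seeds in seed_counts:
            seeds = top_k(scores, n_seeds)
            cfg = SIRConfig(alpha=alpha, beta=beta, t_max=t_max, runs=runs, seed=seed)
            sir_res = sir_spread(net, seeds, cfg)
            for step, value in enumerate(sir_res.trajectory_mean, start=1):
                rows.append({"algorithm": algo, "n_seeds": n_seeds,
                             "process": "sir", "step": step, "value": value})
            ic_res = ic_spread(net, seeds, p, runs=runs, seed=seed)
            rows.append({"algorithm": algo, "n_seeds": n_seeds, "process": "ic",
                         "step": "final", "value": ic_res.mean_final})
    return pd.DataFrame(rows)
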