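"""Ranking-agreement statistics between an importance score and simulated
spreading ground truth: Kendall tau, tau-versus-alpha curves, top-k
selection, and the re-sorted infection-value curve.

Kendall tau comes in two variants here.  Variant "a" is the plain pairwise
formula tau = 2·(n_c - n_d)/(n·(n-1)), with tied pairs counted as neither
concordant nor discordant — which systematically deflates tau when the
ground-truth scores carry ties (Monte-Carlo influence averages often do).
Variant "b" applies the standard tie correction and is the default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .metrics import ScoreVector
from .network import Network
from .spreading import SIRConfig, sir_influence

__all__ = ["TauResult", "TauCurve", "kendall_tau", "tau_curve", "top_k", "resort_curve", "ResortResult"]


@dataclass(frozen=True)
class TauResult:
    """Kendall rank-correlation outcome over n·(n-1)/2 node pairs."""

    tau: float
    n_concordant: int
    n_discordant: int
    n: int
    variant: str


def kendall_tau(x: ScoreVector, y: ScoreVector, variant: str = "b") -> TauResult:
    """Kendall tau between two score vectors aligned by node identity.

    Both vectors must cover the same node set (n >= 2).  A pair of nodes is
    concordant when the two scores order it the same way, discordant when
    they order it oppositely; pairs tied in either vector count as neither.
    Variant "a" divides n_c - n_d by the total pair count; variant "b"
    divides by the geometric mean of the untied pair counts.
    """
    if variant not in ("a", "b"):
        raise ValueError(f"variant must be 'a' or 'b', got {variant!r}")
    if set(x.labels) != set(y.labels):
        raise ValueError("score vectors must cover the same node set")
    labels = x.labels
    n = len(labels)
    if n < 2:
        raise ValueError("need at least two nodes")
    xv = x.values_array(labels)
    yv = y.values_array(labels)
    iu = np.triu_indices(n, k=1)
    dx = np.sign(xv[:, None] - xv[None, :])[iu]
    dy = np.sign(yv[:, None] - yv[None, :])[iu]
    prod = dx * dy
    n_c = int(np.sum(prod > 0))
    n_d = int(np.sum(prod < 0))
    n0 = n * (n - 1) // 2
    if variant == "a":
        tau = 2.0 * (n_c - n_d) / (n * (n - 1))
    else:
        tied_x = int(np.sum(dx == 0))
        tied_y = int(np.sum(dy == 0))
        denom = math.sqrt((n0 - tied_x) * (n0 - tied_y))
        tau = (n_c - n_d) / denom if denom > 0 else 0.0
    return TauResult(tau=tau, n_concordant=n_c, n_discordant=n_d, n=n, variant=variant)


@dataclass(frozen=True)
class TauCurve:
    """Tau between a score vector and SIR influence across infection rates."""

    alphas: tuple[float, ...]
    results: dict[float, TauResult]
    variant: str

    @property
    def mean_tau(self) -> float:
        return float(np.mean([r.tau for r in self.results.values()]))


def tau_curve(
    net: Network,
    scores: ScoreVector,
    alphas,
    beta: float = 1.0,
    runs: int = 1000,
    seed: int = 0,
    variant: str = "b",
    t_max: int = 30,
    influence_cache: dict[float, ScoreVector] | None = None,
) -> TauCurve:
    """Kendall tau between ``scores`` and SIR influence at each alpha.

    ``influence_cache`` lets several algorithms share one set of SIR runs
    per alpha (keyed by alpha), as a comparison sweep should.
    """
    alphas = tuple(float(a) for a in alphas)
    results: dict[float, TauResult] = {}
    for alpha in alphas:
        if influence_cache is not None and alpha in influence_cache:
            influence = influence_cache[alpha]
        else:
            cfg = SIRConfig(alpha=alpha, beta=beta, t_max=t_max, runs=runs, seed=seed)
            influence = sir_influence(net, cfg)
            if influence_cache is not None:
                influence_cache[alpha] = influence
        results[alpha] = kendall_tau(scores, influence, variant=variant)
    return TauCurve(alphas=alphas, results=results, variant=variant)


def top_k(scores: ScoreVector, k: int) -> list[str]:
    """The k highest-scoring nodes, ties broken by first-appearance order."""
    if k > len(scores):
        raise ValueError(f"k={k} exceeds the {len(scores)} scored nodes")
    if k < 0:
        raise ValueError("k must be >= 0")
    return scores.ranked()[:k]


@dataclass(frozen=True)
class ResortResult:
    """Ground-truth values listed in an algorithm's rank order."""

    nodes: tuple[str, ...]
    values: np.ndarray
    violations: int  # strict ascents; 0 iff the algorithm sorts the truth perfectly


def resort_curve(scores: ScoreVector, infection_values: ScoreVector) -> ResortResult:
    """Re-sort ground-truth infection values by the algorithm's ranking.

    A perfect ranking yields a non-increasing sequence; each strict ascent
    (a later node with a larger infection value than its predecessor) is a
    monotonicity violation.
    """
    if set(scores.labels) != set(infection_values.labels):
        raise ValueError("score vectors must cover the same node set")
    order = scores.ranked()
    vals = np.asarray([infection_values[l] for l in order], dtype=float)
    violations = int(np.sum(np.diff(vals) > 0))
    return ResortResult(nodes=tuple(order), values=vals, violations=violations)
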