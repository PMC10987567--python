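"""Heat-conduction-model (HCM) node importance.

The score treats the network as a heat-conducting solid, mapping Fourier's
law Q = ΔT·K·A/ΔL onto structural quantities:

* temperature difference ΔT  ->  e^(EC(v_i) - EC(v_j)), the eigenvector
  centrality gap between sender and receiver,
* conductivity K             ->  the network density,
* contact area A             ->  the receiver's degree density Dd(v_j) at
  hop distance R,
* distance ΔL                ->  the hop distance R itself,
* scaled by the sender's degree D(v_i).

A node's importance I(v_i) is its mean output value Q(v_i, v_j) over all
other nodes.  Two conventions exist for the contact-area term: the circle
area π·R² ("quadratic"), and π^R ("exponential").  The worked example's
published per-pair output values and capacities reproduce only under the
exponential convention, which is therefore the default; the quadratic form
is kept selectable.  The two coincide at R = 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .metrics import (
    DistanceMatrix,
    ScoreVector,
    UNREACHABLE,
    all_pairs_distances,
    degree_vector,
    eigenvector_centrality,
    network_density,
)
from .network import Network

__all__ = ["HCMConfig", "output_value", "output_capacity", "hcm_scores", "rank_nodes"]

_AREA_MODES = ("exponential", "quadratic")


@dataclass(frozen=True)
class HCMConfig:
    """Knobs of the heat-conduction score.

    area_mode
        Contact-area convention inside Q: ``"exponential"`` (D_j/π^R, the
        default — reproduces the published worked example) or
        ``"quadratic"`` (D_j/(π·R²), the circle-area formula as written).
    unreachable_policy
        How cross-component pairs enter the capacity sum.  Only ``"skip"``
        is defined: such pairs contribute 0 while the 1/(N-1) normalizer is
        unchanged.
    """

    area_mode: str = "exponential"
    unreachable_policy: str = "skip"

    def __post_init__(self):
        if self.area_mode not in _AREA_MODES:
            raise ValueError(f"area_mode must be one of {_AREA_MODES}, got {self.area_mode!r}")
        if self.unreachable_policy != "skip":
            raise ValueError("only unreachable_policy='skip' is supported")


def output_value(
    D_i: float,
    EC_i: float,
    EC_j: float,
    density: float,
    D_j: float,
    R_ij: int,
    config: HCMConfig = HCMConfig(),
) -> float:
    """Heat output Q(v_i, v_j) of sender i toward receiver j.

    Exponential mode: ``D_i · e^(EC_i - EC_j) · density · D_j / (R · π^R)``.
    Quadratic mode:   ``D_i · e^(EC_i - EC_j) · density · D_j / (π · R³)``.

    Non-negative; zero iff either endpoint has degree zero.  The pair must
    be reachable (R >= 1) — callers apply the unreachable policy first.
    """
    if R_ij < 1:
        raise ValueError(f"R_ij must be a reachable hop count >= 1, got {R_ij}")
    if not 0.0 <= density <= 1.0:
        raise ValueError(f"density must be in [0, 1], got {density}")
    if config.area_mode == "exponential":
        area = D_j / math.pi**R_ij
    else:
        area = D_j / (math.pi * R_ij**2)
    return D_i * math.exp(EC_i - EC_j) * density * area / R_ij


def output_capacity(
    net: Network,
    degrees: ScoreVector | None = None,
    ec: ScoreVector | None = None,
    dist: DistanceMatrix | None = None,
    density: float | None = None,
    config: HCMConfig = HCMConfig(),
) -> ScoreVector:
    """Output capacity I(v_i) = (1/(N-1)) · Σ_{j≠i} Q(v_i, v_j).

    All intermediate metrics are computed once up front (or accepted
    precomputed) and reused for every pair, keeping the whole scoring pass
    O(N²).  Unreachable pairs contribute 0; the normalizer stays N-1.
    """
    if net.N < 2:
        raise ValueError("output capacity undefined for N < 2")
    if degrees is None:
        degrees = degree_vector(net)
    if ec is None:
        ec = eigenvector_centrality(net)
    if dist is None:
        dist = all_pairs_distances(net)
    if density is None:
        density = network_density(net)

    labels = net.labels
    d = degrees.values_array(labels)
    x = ec.values_array(labels)
    hops = dist.hops
    n = net.N
    scores: dict[str, float] = {}
    for i, label in enumerate(labels):
        total = 0.0
        for j in range(n):
            r = int(hops[i, j])
            if j == i or r == UNREACHABLE:
                continue
            total += output_value(d[i], x[i], x[j], density, d[j], r, config)
        scores[label] = total / (n - 1)
    return ScoreVector(scores)


def hcm_scores(net: Network, config: HCMConfig = HCMConfig()) -> ScoreVector:
    """Convenience wrapper: compute all metrics and the capacity in one call."""
    return output_capacity(net, config=config)


def rank_nodes(scores: ScoreVector) -> list[str]:
    """Nodes in non-increasing score order; ties keep first-appearance order."""
    return scores.ranked()
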