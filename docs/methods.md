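# Methods

## Scope and data model

`hcmnet` operates on undirected, unweighted, simple graphs. Edge lists are
parsed with opaque string labels kept in first-appearance order; self-loops
and duplicate edges are dropped with a warning rather than rejected, because
public edge lists are messy and the model assumes a simple graph. All
rankings break ties by first-appearance order, which makes every output
deterministic. Weighted, directed and temporal graphs are out of scope.

## The heat-conduction score

For sender `v_i` and receiver `v_j` at hop distance `R`:

```
Q(v_i, v_j) = D(v_i) · e^(EC(v_i) − EC(v_j)) · Density(G) · Dd_j(R) / R
I(v_i)      = (1/(N−1)) · Σ_{j≠i} Q(v_i, v_j)
```

with `D` the degree, `EC` the unit-L2 eigenvector centrality, `Density(G) =
2M/(N(N−1))`, and `Dd_j(R)` the receiver's degree density.

**Contact-area conventions.** Two forms of the degree density circulate:
the circle-area form `D_j/(π·R²)` ("quadratic") and `D_j/π^R`
("exponential"). They disagree from hop distance 2 on. The published
worked-example tables for this method are internally split: the printed
per-node degree densities follow the quadratic form, but every printed
per-pair output value and every capacity — including the headline
I(v1) = 0.615762 — follows the exponential form. Reproducing the published
end results was judged the overriding concern, so `area_mode="exponential"`
is the default, the quadratic form is selectable, and `hcm example` checks
the degree-density table under the quadratic convention while checking
output values and capacities under the configured mode (flagging the
inevitable deviations when run with `--mode quadratic`). The two modes
coincide exactly for all pairs at distance 1.

**Eigenvector centrality.** Power iteration on `A + I` from a uniform
positive start; the identity shift leaves the eigenvectors unchanged while
preventing the period-2 oscillation that plain power iteration exhibits on
bipartite graphs. Convergence is declared when successive L2-normalized
iterates differ by less than `tol` (default 1e−10) in max-norm, with a
`ConvergenceError` reporting the residual after `max_iter` (default 1000)
iterations. The result is oriented non-negative and L2-normalized — the
convention under which the worked example's printed values satisfy
Σ EC² = 1. The networkx implementation serves as an independent
cross-check in the tests, never as the implementation.

**Disconnected inputs.** Q is defined only for reachable pairs. Unreachable
pairs contribute 0 to the capacity sum while the normalizer stays `N−1`, so
I remains well defined on disconnected graphs; `largest_component` is
provided for users who prefer to restrict to the giant component, as hop-
distance-based scores are more meaningful there. Closeness on a
disconnected graph is computed within each node's component, with the
component size standing in for N; isolated nodes score 0. Isolated nodes
export no heat (Q = 0 by convention).

**Cost.** Degrees, eigenvector scores, distances and density are computed
once and reused for every pair, so a full scoring pass is O(N²) after the
O(N·M) BFS distance computation.

## Spreading ground truth

**SIR.** Synchronous discrete time. Each step, every infective node
independently infects each susceptible neighbor with probability α; then
each infective node recovers with probability β. Recovery is processed
after infection, so with β = 1 each node is infective for exactly one
round — the ordering required for the final-size distribution to coincide
with bond percolation at per-edge probability α, and hence with the
independent cascade at P = α. The mean-field ODE reading of the S/I/R rate
equations is deliberately not implemented; all experiments are agent-based.
A node's influence is the mean number of initially susceptible nodes ever
infected over `runs` Monte-Carlo repetitions with that node as sole seed
(seeds excluded from the count; the IC activation count includes seeds by
default — both toggleable). Defaults follow the standard benchmark
settings: β = 1, t_max = 30 (with β = 1 epidemics die within the graph
diameter, so the horizon almost never truncates), 1000 runs.

**Reproducibility.** One master seed; per-node and per-run substreams are
spawned from a `numpy` `SeedSequence`, so results are independent of
processing order and byte-stable across reruns.

**Exact oracle.** For graphs with M ≤ 20 edges, `exact_mean_outbreak` and
`exact_percolation_influence` enumerate all 2^M edge subsets, weight each
by p^k(1−p)^(M−k), and read outbreak sizes off union-find components. The
simulators are validated against these exact values within three
Monte-Carlo standard errors.

## Ranking agreement

Kendall tau is computed between score vectors aligned by node identity, not
between rank permutations. Variant "a" is the plain pairwise formula
`2(n_c − n_d)/(n(n−1))` with tied pairs counted as neither concordant nor
discordant; variant "b" applies the standard tie correction. Monte-Carlo
influence averages tie frequently at realistic run counts, and variant "a"
systematically deflates under ties, so "b" is the default and every
experiment output records the variant used. Both variants are verified
against an O(n²) brute-force pair counter, and "b" against
`scipy.stats.kendalltau`. The re-sort curve lists ground-truth infection
values in an algorithm's rank order and counts strict ascents as
monotonicity violations (0 for a perfect ranking).

## Experiment drivers and problem sizes

The comparison sweep computes SIR influence once per α and shares it across
all algorithms, as a fair comparison requires. The bundled baselines are
degree, eigenvector, closeness and betweenness centrality plus the k-shell
index; the registry is extensible for further algorithms. Betweenness
excludes endpoints and is pair-normalized by `2/((N−1)(N−2))`.

Tests and the acceptance script run at desk scale: the 11-node worked
example, Erdős–Rényi graphs up to N = 50 for distance oracles, n = 200 for
tau oracles, and 10⁴ Monte-Carlo runs for simulator validation. These sizes
make the exact oracles (2^16 subset enumeration, brute-force path
enumeration) feasible; the package itself scales to the tens-of-thousands-
of-nodes range, where the O(N²) distance and scoring passes dominate.

## What the synthetic graphs do and do not show

Erdős–Rényi and Barabási–Albert generators stand in for real benchmark
networks in the tests. They exercise correctness — metric identities,
oracle agreement, determinism — but ER graphs lack the heavy-tailed degree
distributions, clustering and community structure of real social and
biological networks, and BA graphs capture only the degree tail. Passing
tests therefore certify that the algorithms compute what they claim, not
that the heat-conduction ranking outperforms any baseline on a particular
real network; that judgement requires running `hcm compare` on the network
of interest.

## Known limitations

- The exponential/quadratic ambiguity is resolved in favor of reproducing
  the published worked example; which convention produced any given
  external benchmark figure cannot be determined from the score values
  alone, so both are exposed.
- Exact percolation oracles are limited to M ≤ 20 edges by design.
- Continuous-time (Gillespie) epidemics, SIS/SEIR variants and influence
  maximization (seed-set optimization) are out of scope; seed sets for the
  spreading experiments come from rankings.
- Tau values against simulated influence carry Monte-Carlo noise of order
  1/√runs; at the default 1000 runs, differences below ~0.03 between
  algorithms should not be over-interpreted.
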