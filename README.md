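# hcmnet

Identify influential spreaders in undirected, unweighted networks with a
heat-conduction importance score, and benchmark any node ranking against
stochastic spreading ground truth (SIR and independent-cascade simulations)
using Kendall-tau agreement statistics.

The intended users are network epidemiologists and network scientists who
have a plain-text edge list and want (a) a ranked list of the nodes most
capable of seeding a large outbreak or cascade, and (b) a principled way to
check how well that ranking — or any competing centrality — predicts
simulated spreading.

## The model

The score treats the network as a heat-conducting solid and asks how much
heat each node would export to every other node under Fourier's law,
*Q* = ΔT·K·A/ΔL, with the physical quantities mapped onto structure:

- **temperature difference ΔT** → `exp(EC(v_i) − EC(v_j))`, the gap in
  eigenvector centrality (unit-L2-normalized principal eigenvector of the
  adjacency matrix) between sender and receiver;
- **conductivity K** → the network density `2M / (N(N−1))`;
- **contact area A** → the receiver's *degree density* at hop distance R —
  by default `D(v_j)/π^R` (the convention under which the method's published
  worked example reproduces; the circle-area form `D(v_j)/(πR²)` is available
  as `area_mode="quadratic"`);
- **distance ΔL** → the BFS hop distance `R(v_i, v_j)`;
- scaled by the sender's degree `D(v_i)`.

The per-pair output value is therefore (exponential convention)

    Q(v_i, v_j) = D(v_i) · e^(EC(v_i) − EC(v_j)) · Density(G) · D(v_j) / (R_ij · π^R_ij)

and a node's importance is its **output capacity**, the mean output over all
other nodes:

    I(v_i) = (1 / (N−1)) · Σ_{j≠i} Q(v_i, v_j)

Nodes are ranked by descending capacity. For ground truth the package ships
a discrete-time network SIR process (per-contact infection probability α,
per-step recovery probability β) and the independent cascade (activation
probability P); with β = 1 both are equivalent to bond percolation, which
yields an exact outbreak-size oracle on small graphs by enumerating all 2^M
edge subsets.

## Worked example

The package carries an 11-node, 16-edge example network whose node `v1`
bridges two halves of the graph. Verify every published quantity and print
the full calculation:

```bash
$ hcm example
Worked example (area_mode=exponential)
Density(G) = 0.29091
node  D  EC       CC       I
  v1  4  0.44507  0.55556  0.615762
  v2  3  0.29872  0.50000  0.333430
...
I(v1) = 0.615762
ranking: v1 > v9 > v4 > v3 > v8 > v2 > v7 > v11 > v6 > v10 > v5
all values match the published tables
```

`Density(G) = 0.29091` is the edge fraction; `I(v1) = 0.615762` is v1's mean
heat output to the other ten nodes and the largest capacity in the network,
so v1 ranks first — consistent with v1 being the articulation node whose
removal disconnects the graph. The same from Python:

```python
from hcmnet import example_network, hcm_scores, rank_nodes

net = example_network()
scores = hcm_scores(net)
print(round(scores["v1"], 6))   # 0.615762
print(rank_nodes(scores)[:3])   # ['v1', 'v9', 'v4']
```

Typical command-line workflow on your own edge list (two labels per line,
`#` comments, whitespace or comma separated):

```bash
hcm rank   --input edges.tsv --output scores.csv
hcm sir    --input edges.tsv --alpha 0.04 --runs 1000 --seed 7 --output influence.csv
hcm tau    --input edges.tsv --scores scores.csv --alphas 0.01:0.1:0.01 --seed 7 --out tau.csv
hcm compare --input edges.tsv --algorithms hcm,dc,ec,cc,bc,kshell \
            --alphas 0.01:0.1:0.01 --runs 1000 --seed 7 --out compare.csv
```

All stochastic commands are fully seeded: identical options produce
byte-identical output files.

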