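# dircp — directed core–periphery ("L"-structure) detection

`dircp` detects and assesses a *directed* core–periphery structure in
directed, unweighted networks.  Classical core–periphery analysis splits an
undirected network into a dense core and a sparse periphery; in directed
networks (hiring flows, trade, citation, information diffusion) the role of a
node additionally depends on edge direction.  `dircp` partitions the node set
into **four** sets:

| set    | role                                                        |
|--------|-------------------------------------------------------------|
| `Cout` | core-out: densely sends to all receiving sets, internally dense |
| `Cin`  | core-in: densely receives from all sending sets, internally dense |
| `Pout` | periphery-out: sends into `Cin` only                        |
| `Pin`  | periphery-in: receives from `Cout` only                     |

In block-matrix form the idealized pattern has ones exactly on the blocks
Pout→Cin, Cin→Cin, Cout→Cin, Cout→Cout and Cout→Pin — an "L" shape.  The
generative model behind everything is the four-block stochastic block model
**DCP(p₁, p₂)**: ordered node pairs inside the "L" carry an edge with
probability p₁ (signal), all other pairs with probability p₂ (noise),
p₁ > p₂; self-loops are permitted.  The one-parameter family
DCP(½ + p, ½ − p) interpolates between a uniform random digraph (p = 0) and
the perfect "L" (p = 0.5).

The package is aimed at network scientists and systems biologists who want
to (i) detect this structure in an empirical digraph, (ii) decide whether the
detected structure is statistically distinguishable from chance, and (iii)
benchmark detectors on synthetic networks with planted ground truth.

## What is inside

* **Detectors** (all end with k-means++ clustering of per-node scores and a
  maximum-profile-likelihood naming of the four clusters):
  * `hits` — hub/authority scores (principal singular vectors of the
    adjacency matrix); fastest.
  * `advhits` — iterative four-score propagation with a ±1 reward–penalty
    matrix derived from the "L" mask; more accurate.
  * `maxlike` — Kernighan–Lin single-node-move maximization of the DCP
    profile log-likelihood with random restarts; most accurate, slowest.
  * `degree` — naive baseline clustering raw (in-degree, out-degree) pairs.
* **Quality measures**: directed core–periphery modularity
  `DCPM(g) = (1/m) Σ_{u,v} (A_uv − m/n²) M_{g_u g_v}` and a Monte Carlo
  significance test whose statistic is the within-"L" minus off-"L" edge
  density, with directed Erdős–Rényi and degree-preserving configuration
  nulls (the detector is re-run on every null replicate).
* **Benchmarks**: three synthetic accuracy experiments and a
  quality-measure validation grid, with adjusted Rand index and Kendall τ
  summaries, emitting tidy DataFrames/CSV.
* A statsmodels-style facade (`DirectedCorePeriphery` → `fit()` →
  `CorePeripheryResults`) and a `dircp` command-line tool.

## Worked example

```python
from dircp import DCPParams, DirectedCorePeriphery, sample_dcp
from dircp.benchmarks import adjusted_rand_index

# a 400-node network with a planted L-structure at signal level p = 0.1
graph, planted = sample_dcp(DCPParams((100, 100, 100, 100), 0.6, 0.4), seed=7)

res = DirectedCorePeriphery(graph).fit(method="maxlike", seed=1)
print(res.summary())
print("ARI vs planted:", round(adjusted_rand_index(res.partition, planted), 3))
mc = res.monte_carlo_test(null_model="er", replicates=99, seed=2)
print("ER-null p-value:", round(mc.p_value, 3))
```

Output:

```
Directed core-periphery (L-structure) results
==============================================
method:         maxlike
nodes, edges:   n = 400, m = 74038
set sizes:      Pout = 101, Cin = 100, Cout = 100, Pin = 99
p1_hat (in-L):  0.5970
p2_hat (off-L): 0.4017
log-likelihood: -107818.891
DCPM:           0.0906
L-statistic:    0.1952

ARI vs planted: 0.993
ER-null p-value: 0.01
```

The fitted within-"L" density `p1_hat ≈ 0.597` and off-"L" density
`p2_hat ≈ 0.402` recover the generating probabilities (0.6, 0.4); the
partition agrees with the planted one almost perfectly (ARI 0.993); and the
Monte Carlo test puts the observed L-density contrast at the significance
floor — the structure is not plausibly a fluke of a random digraph with the
same edge count.

The same pipeline from a shell:

```bash
dircp sample --sizes 100,100,100,100 --p1 0.6 --p2 0.4 --seed 7 \
      --edges-out net.tsv --partition-out planted.tsv
dircp detect --method maxlike --edges net.tsv --seed 1 \
      --partition-out found.tsv --report-out report.json
dircp quality --edges net.tsv --method maxlike --null both --replicates 99 \
      --seed 2 --report-out quality.json
dircp benchmark --id 1 --reps 10 --seed 0 --p-grid 0.1,0.05 --out bench1.csv
```

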