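# logicnet

Qualitative analysis of signed gene-regulatory networks.

Curated signalling maps — the kind assembled from the literature for a
disease system, with activation and inhibition edges and occasional
AND connectors — encode more than their picture: translated into a
Boolean model, they determine a finite set of *stable states*
(candidate long-term expression phenotypes) and a complete table of
which genes any single knockout or overexpression forces ON or OFF.
`logicnet` computes all of that exactly:

* **Topology** — strongly connected components and a census of signed
  feedback loops (a loop is negative iff it carries an odd number of
  inhibitions), with per-gene participation fractions.
* **Stable states** — a state `x` is stable when the synchronous update
  map fixes it, `f(x) = x`, i.e. it solves the consistency system
  `f_i(x) = x_i` for every node `i`.  The solver groups these equations
  into blocks of bounded joint support, enumerates block solutions, and
  patches them with relational joins; the answer is held as disjoint
  *cubes* (pinned assignment + free variables), so models with millions
  of stable states are counted and summarized without expansion.
* **Statistics** — exact per-gene ON rates over all stable states,
  k-means clustering of the (standardized) state matrix into phenotype
  clusters, two-group merges, and difference/ratio tables with
  selection flags.
* **Control effects** — clamp gene *k* to 0 or 1, propagate constants
  to a fixed point of implications, collect the four forced sets
  A(k,0), A(k,1), B(k,0), B(k,1), and encode each (controller,
  target) pair as an integer code (3 co-expressed, −3 opposite, ±2/±1
  one-sided, 5 unclear, 0 none).  Predictions can be validated against
  expression matrices by median high/low splits and fold-change sign
  agreement.
* **Synthetic data** — seeded generators for random signed networks,
  planted-cluster state matrices and model-faithful noisy expression
  data, so the whole pipeline is testable end to end without any
  external download.

It is aimed at systems biologists working with literature-curated
logical models (tens to low hundreds of nodes) who want exact,
reproducible answers rather than simulation-based sampling.

## Worked example

Generate a small random network shaped like a curated map, then run the
whole pipeline:

```
$ net-suite synth network --n-nodes 12 --n-inputs 3 --seed 11 --out net.tsv
$ net-suite topology --network net.tsv --out-dir topo
nodes=12 edges=20 largest_scc=6 loops=4 negative=2 positive=2

$ net-suite fixedpoints --network net.tsv --out-dir fp
stable_states=6 cubes=3

$ net-suite run-all --network net.tsv --seed 1 --k 2 --out-dir run
{"nodes": 12, "edges": 20, "largest_scc": 6, "loops": 4, "negative_loops": 2,
 "stable_states": 6, "nonconstant_nodes": 11, "cluster_sizes": [4, 2],
 "selected_genes": 11, "nonzero_effects": 39}
```

Reading the numbers: the 12-gene network has a 6-gene strongly
connected core carrying 4 feedback loops, 2 of them negative.  Its
Boolean model (inhibitor-dominant convention; the 3 input genes get
identity rules) has exactly 6 stable states, stored as 3 cubes of 2
states each — `fp/fixedpoints.csv` begins

```
assignment,free,count
g02=0;g03=0;g04=1;g05=1;g06=0;g07=0;g08=1;g09=0;g10=1;g11=0;g12=0,g01,2
```

i.e. one cube pins 11 genes and leaves input `g01` free, covering 2
states.  Eleven genes vary across the stable states
(`nonconstant_nodes`), the states split into clusters of 4 and 2, and
39 (controller, target) pairs show a complete control effect.  Exact
ON rates come from the cubes without expansion, e.g.:

```python
>>> from logicnet import read_network, build_model, solve, rate_of_one
>>> fps = solve(build_model(read_network("net.tsv")))
>>> rate_of_one(fps)["g02"]
0.6666666666666666
```

The same operations are available as library functions
(`logicnet.solve`, `enumerate_loops`, `kmeans_cluster`,
`control_sets`, …); the CLI is a thin wrapper.

To analyze a transcribed curated model instead of a synthetic one, see
`fixtures/crpc/README.md`.

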