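# rnnimean

Mean (centroid) summary trees for samples of ranked phylogenetic time
trees in RNNI treespace.

RNNI treespace is the graph on *ranked trees* — rooted binary trees whose
internal nodes carry unique ranks 1..n−1 increasing towards the root —
with rank moves and ranked-NNI moves as edges; the RNNI distance is
shortest-path length. This package provides:

* **core tree model** (`rnnimean.trees`) — ranked/time trees encoded as
  rank-ordered cluster sequences, Newick/NEXUS (BEAST-style translate
  table) parsing and writing, ultrametricisation of non-ultrametric
  inputs, burn-in handling, configurable treatment of tied node heights;
* **RNNI geometry** (`rnnimean.rnni`) — moves, neighbourhood enumeration,
  exact shortest paths and distances via the FindPath construction
  (O(n²) per pair), plus exhaustive enumeration and BFS oracles for
  small n and the treespace diameter (closed form (n−1)(n−2)/2,
  BFS-validated for n ≤ 6);
* **mean estimation** (`rnnimean.mean`) — the sum-of-squared-distances
  (Fréchet variance) objective, a strict hill-descent centroid search
  over RNNI neighbourhoods with seeded tie-breaking, and a Sturm-style
  shrinking-step starting tree;
* **annotation** (`rnnimean.annotation`) — rank-height annotation (mean
  of each rank's height across the sample; never re-ranks the topology)
  and a maximum-clade-credibility baseline with common-ancestor heights;
* **comparison metrics** (`rnnimean.metrics`) — clade age error, clade
  rank error, RNNI (raw/normalised), rooted Robinson–Foulds and weighted
  Robinson–Foulds, per-metric win counts, and Pearson/Spearman
  diagnostics correlating treespace geometry with user-supplied per-tree
  scores;
* **synthetic data** (`rnnimean.simulate`) — an exactly uniform ranked
  tree generator (uniform pair merging), RNNI random-walk clouds around
  a focal tree, and node-height jitter samples;
* **CLI** (`rnnimean.cli`) — `summarize`, `compare`, `simulate`,
  `diagnose`.

## Quick start

```python
from rnnimean import parse_trees, summarize, annotate_rank_heights

sample = parse_trees(open("posterior.trees").read(), format="nexus", burnin=0.1)
result = summarize(sample, seed=1)          # Sturm start + centroid descent
annotated = annotate_rank_heights(result.tree, sample)
print(annotated.newick())
```

## CLI

```sh
# simulate a concentrated sample of 100 trees on 8 taxa
rnnimean simulate --taxa 8 --mode walk --m 100 --lambda 3 --seed 1 --out sample.nex

# centroid summary (annotated NEXUS + SoS trajectory + run log)
rnnimean summarize --trees sample.nex --format nexus --seed 1 --out summary.nex

# MCC baseline with common-ancestor heights
rnnimean summarize --trees sample.nex --format nexus --method mcc --out mcc.nex

# compare two summaries against a reference tree
rnnimean compare --summary summary.nwk --summary2 mcc.nwk --truth truth.nwk --out wins.tsv

# correlate per-tree scores (e.g. log-likelihoods) with SoS values
rnnimean diagnose --trees sample.nex --format nexus --scores scores.tsv --out diag.json
```

Exit codes: 0 success, 2 validation error, 3 I/O error. Given the same
input, configuration and seed, outputs are byte-identical across runs.

## Tests and acceptance

```sh
python -m pytest -q tests/            # unit + property + acceptance suite
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance script re-runs the end-to-end property checks (distance
oracle equivalence against BFS, metric axioms, the cluster property,
centroid global optimality on exhaustively enumerable spaces, parameter
recovery on random-walk clouds, annotation recovery, generator
uniformity, MCC sanity, CLI determinism) and writes the target map to
`--out`; there are no numeric acceptance targets, so the map is empty.
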