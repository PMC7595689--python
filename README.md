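# nims

Bottom-up identification of organizational modules in small networks,
designed for anatomical network analysis (bones as nodes, articulations as
edges) where global modularity-Q optimization suffers from resolution
limits and seed sensitivity.

The pipeline has six sequential steps:

1. **Local modules** — for every node, find the member set containing it
   that maximizes cohesion (realized minus configuration-model-expected
   internal links) by replicated single-community spin-glass annealing.
2. **Deduplicate** — collapse modules with identical member sets.
3. **Drop nested** — remove modules wholly contained in larger ones. If a
   single module remains, the network is fully integrated and analysis
   stops.
4. **Intersection test** — exact null distribution of the overlap of every
   combination of ≥ 2 modules (chained hypergeometric convolution), with
   Bonferroni correction.
5. **Informed merging** — greedily merge significantly overlapping modules,
   preferring larger overlaps, then smaller corrected p-values; supersets
   that shrink an accepted overlap are rejected. An interactive mode lets
   the analyst confirm each merge.
6. **Cohesion test** — each final cover (merged or surviving module) is
   verified with a one-sided paired Wilcoxon signed-rank test of per-node
   in-group vs. out-group link counts.

## CLI

```sh
nims validate --network skull.graphml
nims run --network skull.graphml --format graphml \
         --replicates 10 --seed 1 --alpha 0.05 --out results/
```

`nims run` writes `report.json`, `intersections.tsv`, `covers.tsv` and
`cohesion.tsv`. Annealing parameters (`--gamma`, `--replicates`,
`--t-start`, `--t-stop`, `--cooling`, `--seed`) can also be supplied via
`--config config.yaml`; explicit flags win. `--interactive` prompts before
committing each candidate merge. Networks are undirected simple graphs in
GraphML (optional `side` node attribute with values `L`/`R`/`U`) or
headerless two-column CSV edge lists.

## Library

```python
import nims

net, truth = nims.planted_network(
    nims.PlantedSpec(module_sizes=(6, 6), p_in=0.9, p_out=0.05, overlap=1)
)
report = nims.run_nims(net, nims.SpinglassConfig(seed=1))
for cover in report.covers:
    print(cover.label, sorted(cover.members))
```

`nims.synthetic_fixtures` generates planted overlapping-module networks
(optionally mirrored into bilaterally symmetric halves), single-edge
perturbations emulating intraspecific variation, the Zachary karate club
benchmark, and standard-anatomy reconstructions of the 21-bone adult human
skull suture network (`human_skull_type`, `human_skull_variant`).

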