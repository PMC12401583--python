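# netscreen

Network-medicine screening on interactomes: quantify how localized a set of
genes is (largest-connected-component significance), how close a drug's
targets sit to a disease module (proximity), and how much two modules overlap
(separation) — each benchmarked against degree-aware null models with
Z-scores and empirical p-values, and scaled to all-pairs drug × disease
screening through a precomputed all-pairs distance matrix.

## Features

- **Distance metrics**: shortest paths (weighted or hop counts), random walk
  with restart, degree-biased random walk, communicability (matrix
  exponential), plus user-defined plug-ins. All-pairs matrices are cached to a
  versioned binary file and reused across analyses.
- **Null models**: perfect degree match, logarithmic (greedy) degree binning,
  strength binning, uniform, or a user-provided sampler. Draws are without
  replacement and exactly size-matched.
- **Scores**: asymmetric AMSPL proximity (averaged over the first/source
  set), symmetric proximity, separation `s_AB = d_AB − (d_AA + d_BB)/2`, and
  LCC-size significance. Z-scores use the population standard deviation of
  the null; empirical p-values use the add-one convention and never reach 0.
- **Screening**: every source set against every target set in parallel, with
  per-pair RNG streams keyed by `(seed, source name, target name)` — results
  are byte-identical for any worker count and stable when sets are added.
- **Synthetic fixtures**: seeded Erdős–Rényi / Barabási–Albert generators,
  planted connected modules, and a node-set perturbation utility for
  robustness analyses. No downloads needed to exercise the full pipeline.

## CLI quickstart

```bash
# 1. synthesize a network with a planted 20-node module
netscreen synth --kind er --n 500 --p 0.01 --seed 7 \
    --out net.tsv --module-size 20 --module-out sets.json

# 2. compute and cache the all-pairs shortest-path matrix
netscreen distances --network net.tsv --metric shortest_path --out net.nmd

# 3. localization significance of the planted module
netscreen lcc --network net.tsv --sets sets.json --set module \
    --null degree_match --iters 500 --seed 7

# 4. proximity between two sets, using the cached distances
netscreen proximity --network net.tsv --distances net.nmd --sets sets.json \
    --source module --target module2 --null log_binning --bin-size 25 \
    --iters 1000 --seed 7 --out result.json

# 5. all-pairs screening, deterministic under --workers
netscreen screen --network net.tsv --distances net.nmd \
    --sources drugs.json --targets diseases.json --score proximity \
    --null log_binning --iters 1000 --seed 7 --workers 4 --out screen.csv
```

Node sets are JSON objects mapping a set name to a list of node ids; networks
are edge-list TSV (`source<TAB>target[<TAB>weight]`, header auto-detected) or
GraphML. Every command accepts `--config file.yaml` (flags override file
values) and `--verbose`. Exit codes: 0 success, 2 usage, 3 data problem,
4 compute problem.

Notes on conventions:

- the asymmetric proximity averages over the **first** (source) set —
  conventionally the drug targets;
- duplicate edges collapse to the maximum weight, self-loops are dropped;
- unreachable pairs are `+inf`; set members with no finite distance to the
  other set are excluded from averages with a logged warning;
- with `--null log_binning` the default minimum bin size (100) targets
  interactome-scale graphs — lower it (`--bin-size`) on small networks.

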