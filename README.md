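# matenet

Metrics of assortative mating by mating success on bipartite sexual
networks, with a sperm-competition-aware decomposition of the Bateman
gradient and a simulation framework for sensitivity analysis.

A mating population is modelled as an m x f binary incidence matrix
(males are rows, females are columns; a 1 means the pair copulated),
optionally weighted by copulation counts. Node degree equals mating
success. On top of that the package provides:

- **Degree assortativity** (`newman_assortativity`) — the Pearson
  correlation between the degrees at the two ends of each edge, in a
  directed (one observation per mating pair) and an undirected (both
  orientations) variant.
- **NODF nestedness** (`nodf`) — percentage overlap under decreasing
  fill across all row pairs and column pairs of the degree-sorted
  matrix, 0–100.
- **Sperm competition intensity** (`sperm_competition_intensity`) — the
  harmonic mean of a male's partners' mating successes (reciprocal of
  his mean fair-raffle paternity share), with a copulation-count-weighted
  variant, and its population-level association with male mating success
  (`scic`, as a Pearson correlation or mean-standardised slope).
- **Bateman decomposition** (`bateman_gradient`,
  `bateman_decomposition`) — the slope of reproductive success on mating
  success, split into a partial gradient controlling for sperm
  competition plus an indirect sperm-competition path, with the exact
  least-squares identity checked; plus a fair-raffle paternity generator
  (deterministic expectations or multinomial sampling).
- **Simulator** (`random_mating_network`) — uniform random networks with
  fixed size, sex ratio and mating density under the constraint that
  every individual mates at least once (rejection sampling), plus a
  library of deterministic archetype networks.
- **Sensitivity study** (`run_axis_experiment`, `run_full_study`) — 
  replicate batches along population-size, sex-ratio and mating-density
  axes, tidy per-replicate metric tables with explicit NA reasons, and
  Spearman/Pearson correlation summaries; `nodf_null_zscore` z-transforms
  NODF against its uniform null model.

Degenerate inputs are reported honestly: correlation-type metrics return
an explicit `NA:<reason>` state (e.g. `no-male-degree-variance` under
monogamy) instead of NaN.

## Command line

```sh
# metric report for one network (edge-list or matrix CSV)
matenet compute --input edges.csv --format edgelist --out report.json

# fair-raffle paternity + Bateman decomposition
matenet bateman --edges edges.csv --fecundity fec.csv --mode multinomial --seed 1

# random networks as edge-list CSVs + manifest
matenet simulate --males 20 --females 20 --density 0.5 --reps 100 --seed 1 --out sims/

# the full sensitivity study (tidy results + correlation tables)
matenet experiment --axis all --reps 1000 --seed 1 --out study/
```

File formats: edge-list CSV with header `male_id,female_id,count`
(count optional, default 1; duplicate rows accumulate), or matrix CSV
with female ids in the first row, male ids in the first column, and
copulation counts in the cells.

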