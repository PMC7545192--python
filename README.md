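# densiscale

Rural–urban population **density scaling** analysis for regional indicator
data: crime, property transactions, mortality, and age demographics — or any
per-region counts.

Urban scaling studies relate a regional indicator *Y* to population by a
power law; `densiscale` works with the density variant that puts rural and
urban regions on one continuum: indicator density *y = Y/A* against
population density *d = n/A* (people per hectare, *A* the land area),

&nbsp;&nbsp;&nbsp;&nbsp;*y = y₀ d^β*,

with the option of a **segmented** law that changes exponent at a critical
density *d\** (the empirical rural–urban boundary), continuous at the break:

&nbsp;&nbsp;&nbsp;&nbsp;log y = log y₀ + β_L log d (d < d\*),&nbsp;&nbsp;
log y = log y₁ + β_H log d (d ≥ d\*),&nbsp;&nbsp;
log y₁ = log y₀ + (β_L − β_H) log d\*.

The package is for quantitative geographers, epidemiologists and
criminologists who want scale-adjusted (not per-capita) views of regional
behaviour. It provides, as a library and a `densiscale` command line:

* **scaling** — per-indicator OLS fits of the single and segmented laws on
  log10 scales, breakpoint estimation by profile search with golden-section
  refinement, Davies' test for a change of slope, and Davies+BIC model
  selection at the 99% level;
* **dsam** — density scale adjusted metrics: residuals *z = log y − log ŷ(d)*
  from the selected law (positive = above scaling expectation);
* **association** — Pearson/Spearman/Kendall/cosine/Jaccard similarity of
  DSAM vectors, the chord distance δ = √(2(1−sm)), and hierarchical
  clustering of indicators or regions (Newick export);
* **network** — bootstrap-significant Pearson correlation networks (2000
  resamples, percentile CI) with Louvain community detection;
* **som** — an 8×8 hexagonal self-organizing map of regional DSAM profiles
  with gap-statistic selection of the number of codebook clusters;
* **synthetic** — a generator that plants known scaling laws, critical
  densities and block-modular residual correlation, so every stage can be
  validated against ground truth.

## Worked example

```python
from densiscale import (SyntheticSpec, simulate, compute_density_matrix,
                        fit_all_indicators, compute_dsams, build_network,
                        detect_communities)

table = simulate(SyntheticSpec(seed=1))          # 348 regions, 12 indicators
dm = compute_density_matrix(table)
fits = fit_all_indicators(dm)
print(f"{fits.n_segmented}/{len(fits)} indicators segmented; "
      f"median d* = {fits.median_d_star:.1f} p/ha")
f = fits["crime_robbery"]
print(f"crime_robbery: beta_L = {f.beta_L:.2f}, beta_H = {f.beta_H:.2f}, "
      f"d* = {f.d_star:.1f} p/ha (Davies p = {f.davies_p:.1e})")

zm = compute_dsams(dm, fits)
net = build_network(zm, b=2000, level=0.99, seed=2)
partition, q = detect_communities(net, seed=3)
print(f"network: {net.graph.number_of_nodes()} nodes, "
      f"{net.graph.number_of_edges()} edges of {net.n_pairs_tested} pairs; "
      f"Q = {q:.3f}, {len(set(partition.values()))} communities")
```

prints

```
8/12 indicators segmented; median d* = 27.4 p/ha
crime_robbery: beta_L = 0.82, beta_H = 1.37, d* = 30.5 p/ha (Davies p = 3.8e-17)
network: 12 nodes, 18 edges of 66 pairs; Q = 0.667, 3 communities
```

The generator planted d\* = 27 p/ha with exponents 0.8 → 1.4 for the crime
family, a single β = 0.9 law for the mortality family, and residual
correlation 0.6 inside each of three indicator families: the fits recover
the break near 27 p/ha, the Davies test flags the slope change decisively,
and the correlation network's three communities are exactly the planted
families (hence the high modularity).

The same run from a shell:

```sh
densiscale simulate --seed 1 --out regions.csv --truth truth.json
densiscale fit regions.csv --out fits.csv
densiscale dsam regions.csv --out residuals.csv
densiscale network residuals.csv --out-prefix net
densiscale som residuals.csv --out-prefix som
# or everything at once, reproducibly, from one YAML config:
densiscale run --config pipeline.yaml
```

`run` writes all artifacts (fit table, residuals, similarity/distance
matrices, dendrogram, edge list, GraphML, SOM assignments, cluster means)
plus a manifest with every derived seed and a SHA-256 per artifact; reruns
with the same config are bit-identical.

Real data enter as a CSV with one row per region: an id column, land area
in hectares, resident population, and one column per indicator count
(`read_region_table` takes a column-name schema; densities are always
derived from counts and area, never read from a file).

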