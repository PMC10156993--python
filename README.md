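# phylounits

Tools for asking a simple biogeographic question rigorously: **which spatial
study unit best explains where the phylogenetic clades of a widespread
organism occur?**

Field surveys of widespread microbes — the motivating case is the
nematode-trapping fungus *Arthrobotrys oligospora* sampled across Yunnan's
six major river watersheds — often find the species itself randomly
distributed, while its intraspecific clades are strongly structured. Whether
that structure is visible depends on the analysis unit: natural watersheds,
arbitrary grids, or data-driven Voronoi tessellations. `phylounits`
implements the full evaluation pipeline for researchers in phylogeography
and microbial biogeography, with a synthetic-data generator so every stage
runs at desk scale without any field data.

## The core procedure

For a partition of the study region into units $U_1,\dots,U_m$ and sites
with clade labels $c_i$, each unit is assigned its modal (majority) clade
$\hat c(U)$, and the **unit accuracy** is

$$\mathrm{acc} = \frac{1}{n}\sum_i \mathbf{1}\{c_i = \hat c(U(i))\},$$

with error rate $1-\mathrm{acc}$: the share of sites whose clade does not
match their unit's majority. The benchmark opponent is a family of Voronoi
tessellations: a random training subset (fractions 5–45% of sites) seeds a
nearest-neighbour classifier — membership in a Voronoi cell is equivalent to
nearest-training-site classification — and *all* $n$ sites are scored
against it. Twenty-five runs (5 fractions × 5 iterations) form an experiment
table; a one-sample t-test compares the 25 accuracies with the fixed-unit
accuracy.

Supporting statistics: occurrence frequencies $OF_{site}=n/N\times100\%$ and
$OF_{sample}=s/S\times100\%$; Ripley's $\hat K(r)$ with Monte-Carlo CSR
envelopes and quadrat $\chi^2$ tests of spatial randomness; patristic
distance matrices from Newick trees; permutation Mantel tests of
phylogenetic vs geographic/environmental distance; and the gene-flow
conversion $N_m = \theta M / x$ ($x=4$ for nuclear loci).

## Worked example

```python
from phylounits import SimulationConfig, SpatialUnitModel, generate_dataset

dataset = generate_dataset(SimulationConfig(seed=1))   # 149 sites, 6 watersheds, 5 clades
model = SpatialUnitModel(dataset.sites, tree=dataset.tree,
                         covariates=dataset.covariates)
results = model.fit(seed=7)
print(results.summary())
```

```
Spatial-unit evaluation of clade distribution
============================================================
Sites: 149    units: 6 (watershed)    clades: 5

Fixed-unit majority-clade accuracy: 0.68  (error rate 0.32)
Voronoi benchmark (25 runs, metric=planar): mean 0.54  median 0.59  min 0.24  max 0.71

Comparison (one-sample t, benchmark vs fixed units):
  t = -5.50  |t| = 5.50  df = 24  discrepancy = -0.14  p = 1.17e-05

Per-unit breakdown:
        W1  majority=C1  n=  15  accuracy=0.67
        W2  majority=C2  n=  37  accuracy=0.57
        W3  majority=C3  n=  48  accuracy=0.75
        W4  majority=C4  n=  21  accuracy=0.81
        W5  majority=C5  n=  16  accuracy=0.56
        W6  majority=C5  n=  12  accuracy=0.67
```

Reading the output: watershed units explain 68% of sites' clades, while the
average Voronoi tessellation grown from random training subsets reaches only
54%; the negative discrepancy (−0.14) with p ≈ 10⁻⁵ says the watershed
partition is a significantly better unit than data-driven polygons on this
dataset. `results.mantel_tests()` adds the distance-correlation diagnostics,
and `results.plot_map()` draws the units and clade-labelled sites.

The same stages are scriptable from the shell:

```bash
phylounits simulate --out data/ --seed 1
phylounits evaluate-units --sites data/sites.csv --partition data/watersheds.geojson
phylounits voronoi-bench --sites data/sites.csv --seed 7 --reference-accuracy 0.68
phylounits pointpattern --sites data/sites.csv --nsim 99 --seed 1
phylounits pipeline --config config.json
```

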