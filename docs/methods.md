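# Methods

This note documents the statistical procedures implemented in `phylounits`,
the assumptions behind them, the synthetic-data generator that stands in for
field data, and the numerical and design choices that were genuinely open.

## 1. The unit-evaluation model

**Majority-clade classifier.** Given a partition of the study region into
units and a set of georeferenced sites each carrying one clade label (one
sequenced strain per site), each unit is assigned its modal clade; ties go
to the lexicographically smallest clade label so results are reproducible
without a random tie-break. Unit accuracy is
the fraction of sites whose clade equals their unit's modal clade; the error
rate is its complement. Accuracy is invariant under bijective relabelling of
clades.

**Voronoi benchmark.** The opposing unit family is built from the data: a
simple random sample without replacement of `round(f·n)` sites (training
fraction `f`) seeds a Voronoi tessellation, and membership in a Voronoi cell
equals nearest-training-site classification — so the implementation performs
a nearest-neighbour search rather than constructing polygons, which is
mathematically identical and avoids degenerate-geometry handling. Explicit
polygons exist only for plotting. Two conventions matter and are fixed by
the arithmetic of the reference benchmark table:

- **All-sites denominator.** Accuracy is `n_correct / n_total` with
  `n_correct` counted over *all* sites, training included (training sites
  are self-nearest and hence always correct). In the reference table one
  run has Correct = 85 > Test = 79, and every printed accuracy equals
  Correct/149 to two decimals, while Correct/Test matches no row — only the
  all-sites convention is consistent.
- **Training fractions.** The published five splits (55%–95%) are *test*
  shares; training fractions default to (0.05, 0.15, 0.25, 0.35, 0.45),
  matching the increasing train sizes of the reference table (≈10 → ≈65 of
  149). The printed train counts do not match any single base population
  exactly, so fractions are free parameters with these defaults.
- **Metric.** Default distance is planar Euclidean on raw (lon, lat),
  mimicking a Voronoi layer tessellated in a GIS's geographic coordinates;
  great-circle distance is available via `metric="geodesic"`.

The experiment runs 5 fractions × 5 iterations = 25 runs labelled V1…V25,
grouped by fraction then iteration, all draws from one seeded generator.
Reported accuracies are rounded to two decimals (exact values retained).

**Comparison test.** The benchmark accuracies are compared to the fixed-unit
accuracy with a **one-sample** t-test: t = (x̄ − a₀)/(s/√25), df = 24. The
reference analysis is sometimes described as an independent-samples test,
but its printed df = 24 (n−1 for 25 runs) and discrepancy −0.18 = 0.50−0.68
are only consistent with the one-sample form, which is therefore the
default; a two-sample variant (`two_sample_t`) is provided. t is reported
signed, with |t| alongside, since published magnitudes omit the sign.

## 2. Supporting statistics

**Occurrence frequencies.** `OF_site = 100·n/N` over sites, `OF_sample =
100·s/S` within a site. In the pipeline, "occupied" means a site whose
record carries a clade label.

**Geodesic distance.** Haversine on a sphere of radius 6371.0088 km (IUGG
mean radius). Point-pattern work uses an equirectangular projection — x
scaled by cos(mean latitude) — which preserves local distances at
study-area scale (≈10⁰ km); no other projection is attempted.

**Ripley's K.** The plain estimator K̂(r) = A/(n(n−1))·#{ordered pairs with
d ≤ r}, with no edge correction: the published analysis names no correction,
and the CSR verdict comes from a simulation envelope (min/max of K̂ over
n_sim ≥ 19 CSR patterns with the same n and window), which is consistent
whatever the estimator's boundary bias. Without correction E[K̂] < πr² as r
grows; on the unit square the exact expectation is πr² − (8/3)r³ + r⁴/2,
which the tests use as the oracle. The quadrat χ² test uses
X² = Σ(O−E)²/E over an r×c division of the window, df = rc−1, upper-tail
p from χ²; the default grid is the largest square grid keeping E ≥ 5 (cells
with E < 1 trigger a warning but the statistic is still computed).

**Patristic distances.** Tip-to-tip path-length sums, computed through
dendropy's phylogenetic distance matrix and re-checked in tests against a
naive path-walk oracle and the four-point condition. One strain per site
makes tip-to-tip distance the only well-defined site-to-site phylogenetic
distance; no multi-strain aggregation is needed. Clades are specified by
the user as MRCA(two defining tips) rather than inferred by tree cutting:
published clade delineations come from inspecting a drawn tree, which no
automated cut could verifiably reproduce. Zero-length branches are allowed
(missing lengths parse to 0 with a warning); negative lengths are rejected.

**Mantel test.** Implemented from first principles: r is the Pearson
correlation of upper-triangle entries; the null jointly permutes rows and
columns of the second matrix; two-sided p = (1 + #{|r*| ≥ |r|})/(1 + n_perm)
(add-one rule), or the exact fraction over all n! permutations in exact
mode (used for n ≤ 6). Distance design mirrored from the reference
analysis: geographic = great-circle km, elevation and each climate factor =
absolute difference, one Mantel test per factor, no multiple-testing
correction (none was applied in the reference analysis; raw p-values are
reported). scikit-bio's `mantel` serves as an independent cross-check in
the test suite only.

**Gene flow.** Nm = θ·M/x, with x = 4 for nuclear loci. The matrix form
follows the coalescent-migration convention that the *receiving*
population's θ scales each ordered pair: Nm(i→j) = θⱼ·M(i→j)/x; mean and
population-sd of the off-diagonal entries summarise the matrix. Estimating
θ and M themselves (Bayesian migration inference) is out of scope; the
package only post-processes such a table.

**PCA covariate selection.** Covariates are standardised (PCA on the
correlation matrix, via SVD); for each of the first k components the
covariate with the largest absolute loading is chosen, skipping ones
already selected, giving k distinct representatives. "Select k principal
factors" is ambiguous in the reference description; the max-|loading|
representative rule is the interpretation adopted. Constant covariates are
dropped with a warning. Note that with only two indicators of a latent
factor, a 2×2 correlation block has symmetric eigenvectors and the "driver"
is not identifiable — the selection property is only testable with ≥3
indicators per factor.

## 3. The synthetic-data generator

The generator emulates the *statistical* structure the analysis assumes,
not the geography it came from:

- **Watersheds** are nearest-seed Voronoi tessellations of `n_watersheds`
  uniform seed points, clipped to the bounding box — they tile it exactly.
  Only the partition property matters downstream; no drainage modelling.
- **Sites** are complete-spatial-randomness uniform draws over the box
  (the reference survey's site pattern tested as CSR), assigned to their
  containing watershed.
- **Clade labels**: watershed w's designated clade with probability
  `majority_prob[w]`, else uniform over the remaining clades. The
  designation is a fixed bijection for the first min(n_clades,
  n_watersheds) watersheds; extra watersheds reuse the last clade,
  mirroring a merged unit with no clade of its own. Labels are spatially
  unstructured *within* a watershed — the reference data do not report
  within-unit clustering, so none is simulated; real data may show local
  autocorrelation that would raise Voronoi-benchmark accuracy relative to
  this model.
- **Tree**: a star backbone joins each realised clade's ancestor to the
  root at depth `between_clade_depth`; below each ancestor a random
  coalescent-topology ultrametric subtree of depth `within_clade_depth`
  spans that clade's tips (tips named by site id). Defaults 0.05 / 0.005
  substitutions-per-site keep between-clade patristic distances an order
  of magnitude above within-clade ones, the "deep backbone, shallow tips"
  shape of a multi-locus intraspecific phylogeny. Empty clades are absent,
  a single realised clade returns its subtree directly.
- **Covariates**: each is `intercept + a·lon + b·lat + c·elev + N(0, σ)`,
  with elevation itself a smooth mountain-plateau surface (≈800–3500 m)
  plus N(0, 50 m) noise. Default factors imitate two temperature-type
  (latitude gradient; −6.5 °C/km lapse rate) and two precipitation-type
  (longitude/latitude gradients) bioclimatic variables. They are linear
  with independent noise — real bioclimatic surfaces are non-linear and
  mutually collinear, so Mantel/PCA results on synthetic data demonstrate
  correctness of the machinery, not climate realism.

Defaults are the reference survey's conditions: 149 sites, 6 watersheds,
5 clades, majority probabilities (0.674, 0.633, 0.659, 0.833, 0.667) with
the sixth watershed at 0.667 sharing clade 5, and a bounding box spanning
97.5–106.2°E, 21.1–29.3°N. One integer seed drives everything through a
`SeedSequence` spawned in the fixed order watersheds → sites → tree →
covariates; identical seeds give byte-identical serialised datasets.

Under these defaults the expected watershed accuracy is the site-weighted
mean of the majority probabilities (≈0.69), and the Voronoi benchmark mean
is structurally lower (≈0.55–0.60): a nearest neighbour in the same
watershed matches a test site's clade with probability ≈ p² + (1−p)²/(k−1)
≈ 0.49, so even generous training fractions cannot reach the fixed-unit
accuracy when labels are spatially unstructured within units. This is the
qualitative headline the acceptance property tests assert (fixed units beat
the benchmark in ≥95% of seeds; empirically 100/100).

## 4. Numerical choices and degenerate inputs

- Ties everywhere break to the lexicographic minimum (unit ids in boundary
  point-in-polygon assignment, site ids in nearest-neighbour searches,
  clade labels in modal counts) — documented, deterministic, no RNG.
- Distance matrices enforce symmetry to 1e-12 (relative), an exactly zero
  diagonal, unique labels; Mantel refuses zero-variance triangles;
  one-sample t refuses zero-variance samples and n < 2.
- Point-in-polygon uses shapely `intersects` (boundary-inclusive); probe
  points interior to exactly one polygon are cross-checked against an
  even-odd ray-casting oracle in tests.
- `voronoi_run` requires 1 ≤ n_train < n; `majority_map` omits empty units
  and `unit_accuracy` raises if a site's unit is unmapped.
- Permutation p-values use the add-one rule, so p ≥ 1/(n_perm+1) > 0.
- The parameter-recovery acceptance test scores synthetic sites against the
  *generating* (designated) majority map, which makes the correct count an
  exact binomial sum; the empirically re-estimated modal map adds a small
  positive selection bias (< 0.01 at 149 sites across 5–6 units), which the
  test bounds separately rather than folding into the binomial CI.

## 5. Problem sizes used in the automated checks

Property checks run at sizes chosen to make their statistical tolerances
tight while keeping the whole suite fast on one CPU: 500 generator seeds
for parameter recovery, 100 seeds × 25 benchmark runs for the headline
comparison, 500 CSR replicates of n = 200 points for K̂ calibration,
200 replicates × 199 permutations for Mantel type-I error, and exhaustive
4!–5! enumeration for the exact-Mantel oracle. The full suite completes in
well under a minute.

## 6. Known limitations

- No edge-corrected K estimators (Ripley isotropic/translation) and no
  projections beyond equirectangular; results at radii comparable to the
  window size underestimate K by construction.
- The published absolute numbers that depend on unreleased site-level data
  (the 68% watershed accuracy, per-clade consistency percentages, the
  specific quadrat χ², Mantel r values, gene-flow matrix) cannot be
  recomputed; the package reproduces their printed-table arithmetic
  (benchmark summary, t-test) and validates everything else by parameter
  recovery and independent oracles on synthetic data.
- The generator's CSR site placement and within-unit label exchangeability
  are idealisations; passing tests demonstrate estimator correctness and
  the direction of the watershed-vs-Voronoi contrast under the stated
  model, not conclusions about any real landscape.
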