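# Methods

## Patch delineation

Habitat patches are connected components of (suitable ∧ masked) raster
cells. Component labelling uses 8-connectivity by default (diagonal
neighbours merge), configurable to 4-connectivity; 8-connectivity avoids
splitting diagonal chains of small water bodies into artificial fragments.
Binarization uses the comparator `suitability ≥ threshold`; nodata cells
are never suitable. The default threshold choice is the ROC point
minimizing |sensitivity − specificity| over the observed score values,
with ties broken toward the smaller candidate; it is computed on the
unmasked map. HSI is the mean continuous suitability over exactly the
patch's member cells, and area is cell count × cell-size². No ensemble
suitability model is bundled: the pipeline consumes any continuous
suitability raster in [0, 1].

## Dispersal kernel and network assembly

Edge formation follows a negative-exponential kernel parameterized by the
cost distance `d0` reached by a proportion `p` of dispersers:
`cost = log(prob)/log(p) · d0`, hence `prob(cost) = p^(cost/d0)`. With
`p = 0.5` (so `d0` is the median dispersal distance) and an edge-formation
probability cutoff of 1e-4, the cost threshold below which an edge is
drawn is `log(1e-4)/log(0.5) · d0 ≈ 13.29 · d0`. A maximum dispersal
distance `D` maps to `d0 = round(D · log(0.5)/log(1e-4))`, nearest-integer
metres; the round trip back to a cost threshold errs by at most 7 m across
the 300 m–10 km distance grid. (For `D = 1760 m` nearest-integer rounding
gives `d0 = 132`, whereas 133 has circulated elsewhere; 1760·log 0.5/log 1e-4
= 132.45, so 132 is retained.)

Interpatch cost is measured patch boundary to patch boundary — the minimum
over member cells — not centroid to centroid, which would systematically
inflate costs for large patches. On a uniform resistance surface the
default mode computes exact Euclidean distances between patch polygons
(shapely, with an STRtree `dwithin` prefilter at the cost cap). The grid
mode runs a multi-source Dijkstra per patch over the 8-neighbour cell
graph, step cost = mean of the endpoint resistances × centre distance
(diagonals × √2), with early termination at the cost cap; untraversable
cells (nonpositive or non-finite resistance) are excluded. Grid costs obey
the octile metric and therefore exceed straight-line distances by at most
≈ 8.2% for unobstructed pairs. The edge test is strict (`cost <
threshold`). One cost table computed at the largest threshold of a sweep
is filtered to produce every smaller network, so the expensive pass runs
once per landscape.

## Per-patch predictors

- degree: incident edge count.
- third-order neighborhood: nodes within unweighted geodesic distance 3,
  excluding the focal node (BFS, depth 3).
- betweenness: unnormalized shortest-path betweenness on the unweighted
  graph, unordered pairs counted once; cross-component pairs contribute
  nothing.
- strength: sum of incident edge dispersal probabilities.
- habitat availability: `HA_i = a_i + Σ_j a_j · p*_ij` where `p*_ij` is
  the maximum over paths of the product of edge probabilities, computed
  exactly as a Dijkstra shortest path on `w = −log(probability)`.
  `include_self` defaults to true (the probability-of-connectivity double
  sum includes the `i = j` term) and is exposed as a flag because
  node-level adaptations differ on this point.
- HSI and area enter the predictor set untransformed.

## Occurrence-state from opportunistic records

A "visit" is a distinct (patch, date) pair with at least one record of any
target-group species; date granularity is the natural sampling unit in
opportunistic databases. Records are assigned to the patch containing
them; a snap distance (default 0, strict containment) optionally assigns
near-miss records — measured to the nearest patch cell centre — because
real records often sit on pond banks. State 1 requires ≥ 1 focal
detection; state 0 requires zero focal detections and visits ≥ an
intensity threshold; other patches are unlabeled and excluded from
fitting. The default threshold heuristic reads the detection curve (mean
focal detections per visit-count stratum) and returns the smallest visit
count where the curve's cumulative maximum reaches 90% of its overall
maximum. This heuristic is one concrete, seed-stable reading of a
plot-based choice; with strongly monotone detection curves it is
conservative (high thresholds, few absences), so a manual override is
accepted, logged, and recommended when reproducing a specific study — the
pipeline's own demonstration and recovery runs use a threshold of 2
visits.

## Boosted regression trees

The boosting core is sklearn's `GradientBoostingClassifier` (binomial
deviance, shrinkage = learning rate, `max_depth` = tree complexity,
`subsample` = bag fraction). The stepwise tree-count search and evaluation
are implemented here: trees are added `step_size` at a time; after each
increment every stratified CV fold's model is grown (warm start) and its
holdout Bernoulli deviance recorded; the search stops once the mean
holdout deviance has failed to improve for `patience = 5` consecutive
increments (or at `max_trees`), and the tree count minimizing mean holdout
deviance is selected. AUC-cv is the mean of per-fold holdout AUCs at the
selected count (not pooled) — folds are stratified by class, and a fold
degenerating to one class is skipped with a warning. The final model is
refitted on all labelled rows at the selected count; relative influence is
the per-predictor share of total split improvement rescaled to sum to 100;
partial dependence fixes one predictor on a grid spanning its observed
range, averages the link-scale score over the observed joint values of the
others, and centres the curve to mean zero. Replicates derive independent
seeds from a master seed and vary only the stochastic elements (bagging
and fold assignment). Default settings: learning rate 0.001, tree
complexity 5, bag fraction 0.75, 10 folds, 50-tree steps, 10000-tree cap,
100 replicates.

## Sensitivity sweep

The design crosses each species with the fixed distance grid {300 m, 1,
2, 4, 6, 8, 10 km} plus a species-specific literature distance,
deduplicated when the two coincide. Occurrence-state is computed once per
species — it depends on the records, not on the network — and joined to
every distance's predictor table. Per-task seeds derive from the master
seed and the task identity, so results are invariant to execution order.
The per-species distance regression is OLS of replicate-level (not
mean-level) AUC-cv on distance, reporting slope, p-value, R², standard
error and the slope's 95% CI.

## Synthetic landscapes

The generator emulates the statistical structure the analysis assumes:

- Suitability: Gaussian-smoothed white noise rescaled to [0, 1];
  correlation length 500 m on 100 m cells. Simple, seed-stable and
  sufficient for realistic patchiness; it does not emulate an
  environmental-predictor-driven suitability model.
- Aquatic mask: uniform random sites buffered by 120 m; default 1500
  sites on a 25.6 × 25.6 km grid yield roughly 400 patches after
  intersection with suitable cells at the 0.6 binarization default.
- True occupancy: iterative settlement. Initial occupancy is
  Bernoulli(logistic(η)), η = −12 + 8·HSI + 0.5·log a; each of 5
  settlement rounds adds 2·S_i, with S_i the summed edge probabilities to
  currently occupied neighbours in the truth network (kernel scale
  d0 = 301 m, i.e. a 4 km maximum dispersal distance), then resamples.
  The coefficients were chosen once to give a realistic occupancy
  prevalence near 0.5–0.6 with both a quality and a connectivity signal;
  5 rounds induce connectivity dependence without simulating a full
  metapopulation equilibrium.
- Sampling: visit counts per patch are negative binomial (shape 1) with
  mean 3 — overdispersed, as in non-systematic databases, including many
  unvisited patches; each visit records 1 + Poisson(0.7) target-group
  species out of 13; the focal species is recorded per visit with
  probability 0.7 where it truly occurs, and never elsewhere (no false
  positives, by construction). Dates are sequential day labels from
  2006-01-01; one visit is one (patch, date) pair.

What passing tests on these landscapes show: the pipeline recovers a known
connectivity signal (performance peaks at thresholds covering the
generating kernel; quality importance fades with distance) and stays
calibrated under the null (no connectivity effect ⇒ AUC–distance slope
CI covers zero at nominal rate). What they do not show: behaviour under
real spatial biases — detection varying with habitat, spatially clustered
sampling effort, suitability error, or non-uniform movement resistance.

## Numerical choices and degenerate inputs

Degenerate flat suitability fields rescale to a constant 0.5. An all-zero
detection curve makes the intensity threshold undefined and raises an
error prompting a manual choice. A boosted fit in which no tree ever
splits returns uniform influence shares. Empty patch sets yield empty cost
tables; unreachable pairs are simply absent. ROC threshold ties break
toward the smaller candidate; the binarization comparator is ≥. All
stochastic components consume `numpy` `SeedSequence`-derived streams, so
every stage is bitwise reproducible from its config and master seed.

## Reduced-scale test profile

The test and demonstration suites run the boosting at learning rate
0.05–0.1 with small tree caps (50–100), 4–5 folds and 2–20 replicates on
landscapes of roughly 100–400 patches — the package's reduced-scale
profile for fast, deterministic end-to-end checks. The scientific
defaults (0.001, depth 5, 10 folds, up to 10000 trees, 100 replicates)
remain the configuration defaults used for full studies.

## Known limitations

- The Euclidean cost mode is exact only on uniform resistance; the grid
  mode discretizes movement to 8 directions (octile overestimate ≤ 8.2%).
- The sampling-intensity threshold heuristic is a stand-in for a
  plot-based expert choice and is conservative on monotone detection
  curves; override it when reproducing a specific study.
- Replicate runs vary only bagging and fold assignment, not data
  resampling.
- No spatial cross-validation or autocorrelation correction; replicate
  rows in the distance regression are not independent, so its p-values
  are anti-conservative and should be read comparatively.
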