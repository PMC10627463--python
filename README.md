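# habnet

Habitat-network models predict where a species occurs by treating suitable
habitat patches as nodes of a graph whose edges represent potential
dispersal. The edges depend on a single, notoriously uncertain parameter:
the species' maximum dispersal distance. `habnet` implements, as a tested
and reusable Python pipeline, a sensitivity analysis of such models to that
parameter: it builds habitat networks over a range of maximum dispersal
distances, predicts patch occurrence-state (presence / likely absence)
from topological and habitat-quality predictors with boosted regression
trees, and quantifies how predictive performance, network structure and
predictor importance respond to the distance threshold. It is aimed at
spatial ecologists working with patch-based connectivity models and
opportunistic (non-systematic) species records, such as amphibian
monitoring databases.

## The model

**Patches.** A continuous habitat-suitability raster (values in [0, 1]) is
binarized — by default at the ROC threshold balancing sensitivity and
specificity — and intersected with an environmental mask (water bodies,
spawning sites). Connected components of the masked suitable cells are the
habitat patches; each carries its area *a<sub>i</sub>* and habitat
suitability index HSI (mean suitability over member cells).

**Edges.** Interpatch least costs (boundary-to-boundary; exact Euclidean on
a uniform resistance surface, grid least-cost otherwise) are converted to
dispersal probabilities by a negative-exponential kernel,

```
cost = log(prob) / log(p) · d0,        prob(cost) = p^(cost / d0)
```

where *d0* is the cost distance reached by a proportion *p* of dispersers
(*p* = 0.5 makes *d0* the median dispersal distance). An edge is drawn
when the dispersal probability exceeds a cutoff (default 10⁻⁴), so a
maximum dispersal distance *D* corresponds to the integer kernel scale
*d0* = round(*D* · log *p* / log 10⁻⁴); e.g. *D* = 1500 m gives
*d0* = 113 m.

**Predictors.** Per patch: degree, third-order neighborhood, unnormalized
betweenness centrality, strength (sum of incident edge probabilities), and
habitat availability HA<sub>i</sub> = a<sub>i</sub> + Σ<sub>j</sub>
a<sub>j</sub>·p\*<sub>ij</sub> with p\*<sub>ij</sub> the maximum-product
path probability (after the probability-of-connectivity index) — plus HSI
and area.

**Response.** Occurrence-state from opportunistic multi-species records by
sampling intensity: a patch with a focal-species record is a presence (1);
a patch visited at least a threshold number of times for the target group
without a focal record is a likely absence (0, target-group absence);
other patches stay unlabeled.

**Fit.** Stochastic gradient boosting of shallow trees on Bernoulli
deviance (learning rate 0.001, tree depth 5, bag fraction 0.75 by
default), with the tree count chosen stepwise by cross-validated deviance.
Per network the pipeline reports cross-validated AUC (mean of per-fold
holdout AUCs), training AUC, tree count, relative influence per predictor
and centered partial-dependence curves, over replicate runs; per species
it regresses replicate-level AUC-cv on distance (OLS).

A fully seeded synthetic-landscape module generates suitability surfaces,
aquatic masks, connectivity-driven true occupancy and visit-based records
with imperfect detection, so the entire analysis is testable without
external data.

## Worked example

The packaged demonstration study (synthetic landscape, three dispersal
distances, reduced boosting profile):

```bash
habnet run --config examples/demo.yml --out demo_out \
       --stages simulate,delineate,occurrence,sweep,report
```

`demo_out/sweep_summary.csv` then contains (selected columns):

| distance (m) | edges | components | mean AUC-cv | HSI influence (%) |
|---:|---:|---:|---:|---:|
| 300 | 211 | 218 | 0.698 | 37.3 |
| 4000 | 6584 | 1 | 0.782 | 10.6 |
| 10000 | 29792 | 1 | 0.757 | 13.5 |

The synthetic truth generated occupancy with a connectivity effect at a
4 km dispersal threshold. The fragmented 300 m network (218 components)
predicts occurrence worst and leans most on habitat quality (HSI); once
the threshold covers the generating kernel the network collapses to one
component, AUC-cv rises, and topological predictors take over — the
qualitative sensitivity pattern the pipeline is designed to expose.
`demo_out/regressions.csv` reports the replicate-level OLS of AUC-cv on
distance (here slope 5.2e-6 per m, p = 0.035), and `demo_out/figures/`
holds the component, AUC and importance curves.

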