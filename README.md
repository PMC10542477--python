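# orchidsdm

Species distribution modelling (SDM) for orchids, stratified by life form and
including a quantified human-influence predictor, with county-level
prioritization of critical habitat. The package is aimed at spatial
ecologists who want to (a) test whether splitting occurrence data by
physiological life form (terrestrial / epiphytic / mycoheterotrophic)
improves suitability models, (b) score anthropogenic pressure as a raster
predictor, and (c) turn suitability maps into a defensible shortlist of
administrative units for conservation. Because deposits of rare-orchid
occurrences are restricted, the package ships a first-class synthetic
landscape generator that reproduces the statistical structure of a
mountainous study system, so the whole analysis runs end to end without any
external data.

## The analysis

**Human-influence (HI) factor.** Five indexes, each scored 0–10 on a shared
1-km equal-area grid, summed with equal weights (range [1, 50]):

- *population*: density > 1000 people/km² scores 10, otherwise
  `3.333 · log10(d + 1)`;
- *grazing*: county sheep-equivalent density `x_i = (5·cattle + sheep)/area`,
  scored `log(x_i)/log(x_max) · 10` (one head of cattle counts as five sheep);
- *road access*: per road class, distance bins 0–90 / 90–500 / 500–1000 /
  1000–3000 m map to published scores (e.g. national highway 10/8/6/4),
  0 beyond 3 km; classes combine by maximum;
- *night light*: radiance deciles 1–10 (quantile grading);
- *land use*: construction 10, arable 7, forest/irrigated 3, grassland 1,
  other 0.

**Models.** Presences (thinned to one record per 1-km cell) and 2000
uniformly drawn pseudo-absence cells per dataset (three independent sets)
feed three algorithms: a penalized binomial GLM with all pairwise
interactions (level 1), a 1000-tree random forest, and a MaxEnt-style
presence–background model (weighted L1 logistic on linear + quadratic
features). Each of the 4 datasets (all / t / e / m) × 3 algorithms × HI
on/off is fitted over 3 pseudo-absence sets × 5 stratified 70/30 splits
(15 runs per strategy).

**Evaluation.** AUC (rank-based, ties half-credited), TSS
(sensitivity + specificity − 1) and Cohen's κ at the metric-maximizing
threshold; strategies compared by paired two-sided t-tests over matched
runs (α = 0.05).

**Maps and prioritization.** Committee-mean suitability is binarized at 0.5
(strictly greater), the three life-form maps are fused by cell-wise OR into
a "total" layer and differenced against the pooled "overall" map, and
per-county suitable areas go through a double ranking: the top 30% of
counties by area, intersected with the smallest top-area prefix holding 50%
of total suitable habitat; counties passing both screens under every
modelling strategy form the consensus.

## Worked example

```python
import numpy as np
import orchidsdm as o

params = o.LandscapeParams(
    seed=42,
    grid=o.GridSpec(0.0, 60_000.0, 60, 60, crs_id="synthetic-equal-area"),
    n_counties=10,
)
landscape = o.generate_landscape(params)
hi = o.compute_hi(landscape)                       # five indexes + sum
stack = o.assemble_stack(landscape, hi)            # 14 predictors

niche = o.default_niches()["epiphytic"]
niche.n_points = 60
occ = o.generate_occurrences(stack, niche, seed=7)

from orchidsdm.prep import (occurrence_cells, sample_pseudo_absence,
                            split_train_test, thin_occurrences)
cells = occurrence_cells(thin_occurrences(occ, stack.grid), stack.grid)
(pa,) = sample_pseudo_absence(stack.grid, cells, n=500, n_sets=1, seed=8)
data = np.concatenate([cells, pa])
labels = np.concatenate([np.ones(cells.size, int), np.zeros(pa.size, int)])
(train, test), = split_train_test(labels, n_repeats=1, seed=9)

model = o.train_model("glm", stack, data[train], labels[train])
from orchidsdm.models import extract_table
scores = model.predict_table(extract_table(stack, data[test]))
print("held-out AUC:", round(o.auc(scores, labels[test]), 3))

binary = o.binarize(o.predict_suitability(model, stack))
areas = o.zonal_area(binary.raster, landscape.counties)
print("suitable area:", binary.area_km2, "km2")
print("top-30% counties:", sorted(o.rank_sequential(areas, 0.30)))
```

Output:

```
held-out AUC: 0.94
suitable area: 224.0 km2
top-30% counties: [2, 5, 8]
```

The HI layer for this landscape spans 8.1–41.8 (of the theoretical 1–50):
anthropogenic pressure concentrates around the synthetic road network and
settled lowlands. The epiphytic model recovers its precipitation-driven
niche well (AUC 0.94 against 500 background cells), classifies 224 of
3600 km² as suitable, and the sequential screen shortlists counties 2, 5
and 8.

The full run matrix is also available from the shell:

```bash
orchidsdm synth --out out/landscape        # write GeoTIFF/GeoJSON/CSV layers
orchidsdm all --config run.yaml --out out  # synth -> HI -> fit -> maps -> rank
```

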