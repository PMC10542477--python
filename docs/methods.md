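# Methods

This note documents the modelling choices in `orchidsdm`: what each stage
assumes, which knobs matter, what the synthetic study system does and does
not emulate, and where the design was genuinely open.

## Grid and geometry

All layers live on one projected equal-area grid (default 1-km cells), so a
cell is exactly `cell_size²` m² and areas are cell counts. Indexing is
row-major from the top-left origin; a point belongs to a cell through
half-open intervals `[x, x + cell_size)`, so boundary points resolve
deterministically. Nodata propagates: every operation masks its output
wherever any input is masked. The package never reprojects — a CRS or cell
size mismatch is an error, because silent resampling is the classic way to
corrupt an area analysis. The CRS identifier is opaque and must be supplied
by the user or the generator; area arithmetic only requires that it be
equal-area.

## Human-influence scoring

Each index is clamped to its published range on every valid cell.

- **Population** (people/km², cap 1000): the sub-cap curve is
  `3.333 · log10(d + 1)`, which is continuous with the cap rule
  (`3.333 · log10(1001) ≈ 10.0`) and gives 0 at zero density.
- **Grazing**: `x_i` is sheep-equivalents per km² (cattle weighted 5:1).
  The score `log(x_i)/log(x_max) · 10` is base-invariant; natural log is
  used. Scores are clamped to [0, 10] (densities below 1 sheep-equivalent/km²
  would otherwise go negative), and `x_max ≤ 1` is rejected with advice to
  rescale units, because the log ratio is then ill-posed.
- **Road access**: distance bins are half-open, with the boundary values
  (90, 500, 1000, 3000 m) falling in the farther bin; overlapping road
  classes combine by maximum, reading the index as worst-case accessibility.
- **Night light**: decile membership by minimum rank, so every member of a
  tied group lands in the group's lower bin; a constant raster scores 1
  everywhere. Zeros participate in the ranking.
- **Land use**: a pure lookup; unmapped class codes are an error rather
  than a silent 0, since a typo in a class registry should not erase an
  index.

The composite HI is the raw unweighted sum (theoretical range [1, 50];
night light contributes at least 1). It is deliberately not rescaled;
users who want a 0–1 factor can divide by 50, and the downstream models
z-score predictors anyway, so the scale does not affect fits.

## Synthetic study system

The generator emulates the *statistical* structure the analysis needs, not
any real geography:

- continuous predictors are Gaussian random fields smoothed with a
  twice-applied moving average (default correlation length 15 cells),
  standardized per layer;
- temperature-role layers share a −0.5 loading on the elevation field
  (a lapse-rate surrogate) — strong enough to be realistic, weak enough
  that the collinearity filter (|r| < 0.7) keeps all 14 predictors;
- slope and aspect come from finite differences of elevation; vegetation
  and land-use classes are threshold cuts of continuous fields;
  construction land sits on the top 2% of a settlement field, and
  population and night light are increasing functions of that same field,
  so the three are positively associated as in real anthropogenic data;
- counties are a Voronoi partition of seeded centers clipped to the grid
  (guaranteeing a partition for zonal statistics), livestock counts are
  log-normal across counties;
- roads are random polylines crossing the domain, one set per class.

Occurrences are drawn by acceptance sampling: a valid cell is proposed
uniformly and accepted with probability
`logistic(intercept + Σ βᵢ·zᵢ + ε)`, where `zᵢ` are z-scored predictor
surfaces (categorical layers enter through centred class indicators) and
`ε` is per-draw logit noise (s.d. 0.3). Duplicate cells can occur, as in
field data; thinning removes them.

### Default niches and sample sizes

The default presets encode the qualitative biology of the three life
forms: terrestrial orchids have a broad temperature/elevation/soil niche;
mycoheterotrophic orchids track forest vegetation and avoid hot summers
(negative weight on the hottest-quarter temperature role); epiphytic
orchids track wettest-month precipitation, precipitation seasonality and
warmth. Magnitudes were chosen once so that the *generating* model's own
presence-versus-background discrimination is high (AUC ≈ 0.93–0.97 with
intercepts near −2σ of the logit surface, i.e. suitable habitat is rare).
This is the strong-signal regime the adequacy checks assume; weaker
coefficients produce saturated, high-prevalence surfaces on which no
algorithm can separate presences from background well.

Default sample sizes are 2000 terrestrial, 446 mycoheterotrophic and 193
epiphytic records. The two rare life forms use the real published survey
sizes directly (they are desk-scale); the terrestrial count is capped at
2000 for tractability (the real survey had ~10,800). Keeping the rare
datasets at their true sizes matters: best-threshold κ is
prevalence-sensitive, and halving the epiphytic set (e.g. to 80 records
against 2000 pseudo-absences) pushes even the generating model's κ ceiling
to ≈ 0.45, making the κ > 0.4 adequacy bar unreachable by construction.

### What passing tests do and do not show

The synthetic system has independent, smooth, stationary predictor fields
and niches that are exactly logistic in those predictors. Real mountain
data have sharper gradients, non-stationary correlation, observation bias
along roads, and taxonomic noise — none of which are emulated. Green tests
show the pipeline's operators are correct and that the documented
qualitative effects follow from the stated data structure; they do not
certify performance on real rasters.

## Models

- **GLM**: binomial logit by penalized maximum likelihood with a tiny ridge
  (1e-6) for numerical stability, solved by Newton–Cholesky (tolerance 1e-8,
  ≤ 500 iterations; failure to converge with a per-sample gradient norm
  above 1e-4 is an error). Interaction level 1 appends all pairwise
  products of main-effect columns; products of one-hot columns from the
  same categorical are structurally zero and excluded.
- **RF**: 1000 trees (seeded), suitability = forest presence probability.
- **MaxEnt-style**: the presence–background maximum-entropy model in its
  weighted logistic formulation — L1-penalized (weight 1.0) logistic on
  linear + quadratic features, with background rows down-weighted so both
  classes carry equal total weight. This is a same-family re-specification,
  not a port of the original software; with zero signal it collapses to a
  near-uniform map, and doubling the background barely changes cell
  rankings.

Predictors are z-scored with training statistics; unseen categories at
predict time encode as all-zero with a warning. Permutation importance
permutes the *raw* predictor column before the feature transform, so all
derived terms (one-hot, quadratic, interactions) scramble coherently; the
reported value is the mean held-out AUC drop.

## Evaluation

AUC is the Mann–Whitney statistic with half credit for ties. TSS and κ are
reported at the metric-maximizing threshold (scanning all distinct scores
plus 0.5, lowest threshold on ties); fixed-0.5 values are recoverable from
the recorded thresholds. For balanced class margins κ equals TSS — a
useful cross-check the tests assert. Strategy comparisons use a paired
two-sided t-test over runs matched by (pseudo-absence set, repeat); no
multiple-testing correction is applied, matching the figure-level
presentation convention, and this caveat is deliberate.

## Maps, overlay and ranking

Binarization is strict (`> 0.5`). The committee map for a strategy is the
mean suitability over its 15 runs. "Total study area" is the count of
unmasked cells × cell area, computed once per session.

One empirical subtlety is documented here because it shapes the overlay
test: whether the pooled all-data binary map covers more area than the
fused life-form union is a *prevalence* effect, not an algorithmic
constant. When pooled presences far outnumber the background sample
(≈ 5:1, as in the original survey-scale data), the pooled model's baseline
inflates its map while the rare life-form maps deflate under a
prevalence-sensitive vote threshold, and the pooled map dominates. With
presences and background balanced 1:1, near-separable rare-niche models
saturate to their full environmental envelopes and the union wins instead.
The overlay test therefore runs at the survey-scale presence-to-background
ratio with the random forest; the package makes no claim that the
direction holds under other designs.

The double ranking uses ceil for the "top 30%" count, breaks ties by
county id, and defines the selection as the intersection of the two
screens per strategy, then across strategies for the consensus; both
marginal sets are reported so users can apply other joins.

## Problem sizes

The default landscape is 200×200 cells. The test suite and the acceptance
script run proportionally scaled twins (e.g. 100×100 cells with every
sample size scaled by the same factor), which preserves each dataset's
presence-to-background ratio — the quantity the metrics are sensitive to —
while keeping runs to minutes. The tree count (1000) and all penalties are
never scaled.

## Known limitations

- GeoTIFF I/O writes the baseline georeferencing tags (pixel scale,
  tiepoint, nodata) plus a JSON description; full GeoKey CRS encoding is
  out of scope, and the CRS travels as an identifier string.
- MaxEnt feature classes beyond linear+quadratic (hinge, threshold) are
  not implemented.
- The paired t-tests assume approximately normal per-run differences; with
  15 runs this is a convention, not a guarantee.
- County polygons are assumed non-overlapping; overlaps resolve to the
  lowest county id rather than raising.
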