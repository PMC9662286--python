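# Methods

`restoreplan` implements a practice-oriented workflow for mapping where, and
by which silvicultural method, landscape restoration most cost-effectively
rebuilds above-ground biomass (AGB). This note documents the models, the
parameter choices and their rationale, what the synthetic landscape does and
does not emulate, and the numerical decisions a maintainer would want
written down.

## Pipeline overview

1. **Current AGB** — vegetation-plot AGB is regressed on spectral
   reflectance and texture predictors with a random forest and upscaled
   pixel-wise.
2. **Maximum AGB** — closed-canopy reference plots (optionally supplemented
   with stratified pixel samples) are regressed on climate predictors to map
   the climate-constrained biomass ceiling; envelope uncertainty flags
   climatic extrapolation.
3. **Deficit and methods** — percent AGB deficit (relative to maximum)
   drives a threshold rule framework assigning passive regeneration,
   assisted natural regeneration (ANR) or planting per hectare.
4. **Growth, cost, cost-effectiveness** — a piecewise growth model and a
   component cost schedule give per-pixel AGB gain, cost, and gain per
   US$100 for a 5-year and a to-full-recovery horizon.
5. **Ensemble prioritization** — steps 3–4 run under pessimistic / realistic
   / optimistic parameter bundles; pixels in the top quartile of
   cost-effectiveness in *all six* scenario × horizon layers, outside the
   climatically uncertain area, are priority sites (priority 1 overall,
   priority 2 outside protected areas).

## Biomass models

Both regressions are random forests (100 trees, `max_features` tuned over
{sqrt, all} by 10-fold cross-validation with 3 repeats on the training
split; all other hyperparameters at scikit-learn defaults). Data are split
4:1 into training and test; reported R²/RMSE always come from the untouched
test fifth. Candidate predictors are screened before fitting: while any
retained pair has |Pearson r| ≥ 0.6, the worst pair is resolved by dropping
the member correlating less with plot AGB (ties break by predictor name).
This greedy worst-pair-first rule is order-independent when response
correlations are distinct and is idempotent.

Spectral candidates are the four reflectance bands plus two moving-window
textures per band (12 in all). The *average* texture is the window mean;
*dissimilarity* is the mean absolute difference between the window centre
and every window pixel — a quantization-free analogue of grey-level
co-occurrence dissimilarity chosen because it is deterministic and exactly
testable against a per-pixel loop. Edges use reflection padding (no edge
duplication). Default window: 3 × 3.

Maximum-AGB predictions are bounded by the reference response range (a
forest of tree means cannot extrapolate), so degraded-only calibration
would bias the ceiling low — hence the closed-canopy restriction and the
stratified supplements for under-sampled ecosystems.

**Envelope uncertainty** is operationalized per predictor as leaving
`[min − level·range, max + level·range]` of the calibration records, with
`level = 0.1` ("one-tenth" tolerance). A pixel is uncertain if *any*
retained predictor is outside its extended range; increasing `level` is
monotone (can only clear flags). Tail extrapolation *inside* the sampled
range is not flagged.

## Deficit and method rules

Percent deficit = 100 × (maximum − current)/maximum; pixels with deficit
≤ 0 are excluded from planning ("no potential"), and maximum = 0 is
treated as no-data. Method assignment per potential pixel follows severity
precedence — soil improvement + nurse planting ≥ framework planting > ANR >
passive — because the framework's rows overlap and the most intervention-
intensive applicable treatment governs cost. Thresholds per scenario
(pessimistic | realistic | optimistic, % deficit unless noted):

| parameter | pess. | real. | opt. |
|---|---|---|---|
| forest passive below | 40 | 50 | 80 |
| savanna/mosaic passive below | 30 | 40 | 50 |
| planting band (lower–upper) | 50–90 | 65–95 | 80–100 |
| soil + nurse planting at/above | 90 | 95 | 100 |
| min distance from intact habitat for planting (m) | 100 | 200 | 300 |
| Lantana removal: max distance to disturbance (m) | 200 | 100 | disabled |

Fixed limits: vine cutting below 1000 m elevation, Lantana removal below
1400 m. Within forest ANR, Lantana removal is the most specific rule and
wins inside its envelope; otherwise vine cutting below 1000 m, else
herb/shrub cutting. Savanna, agro-ecological mosaic and floodplain ANR is a
joint firebreak + grass-cutting bundle (identical conditions, summed
costs). Floodplain follows the savanna thresholds (configurable).
"Disturbed" for the Lantana rule is the union of road pixels and
agro-mosaic landcover. Planting within the scenario's minimum distance of
intact habitat falls back to ANR/passive: seed dispersal is assumed to
reach it. Distances are Euclidean pixel-centre distances from an exact
distance transform.

## Growth model

Two-phase piecewise-linear trajectory: AGB accumulates at r1 = 7.28 Mg ha⁻¹
yr⁻¹ (range 7.02–7.58) until it reaches p20 × maximum, the proportion of
maximum expected after ~20 years of recovery (p20 = 0.51; range 0.32–0.63),
then at r2 = 2.56 Mg ha⁻¹ yr⁻¹ (1.54–4.11) until maximum. The 20-year stock
and the mean increments are mutually consistent only on average; treating
p20·maximum as the phase-change point and r1/r2 as phase rates is the
reconciliation adopted here, and it reproduces the tabulated 5-year
planting gain exactly (5 × 7.28 = 36.4 Mg ha⁻¹). Gains never exceed the
deficit; recovery time is the analytic inversion of the trajectory and
matches annual stepping within one year. AGC↔AGB conversion uses a carbon
fraction of 0.456 ± 0.02. Scenario bundles pair slow growth (p20 = 0.32,
r1 = 7.02, r2 = 1.54) with pessimistic thresholds and fast growth
(0.63, 7.58, 4.11) with optimistic ones.

## Costs and cost-effectiveness

Per pixel and year: treatment cost × treatments yr⁻¹ plus a transport share
while management is active; staff oversight every year; community
engagement within 2 km of settlements (outside protected areas); land
procurement (waived inside protected areas) and a nursery share (planting
methods) once in year 1. Shared units exhibit economies of scale: the
per-hectare share of a unit cost C with service cap A_max is
C / min(patch area, A_max), with patches being contiguous same-method
regions. Annual totals inflate at 2.2% yr⁻¹ (compounding from year 1), an
administration overhead (default 15%) is added, and the sum over the
horizon is divided by the horizon — costs are reported annualized, USD
ha⁻¹ yr⁻¹ (TZS inputs convert at 2,326 TZS per US$ at load time). Active
years: ANR continues until the pixel's trajectory crosses back below its
ANR onset threshold (per-pixel, capped at the horizon); planting uses a
fixed tending period (default 5 yr); passive incurs monitoring only.

Cost-effectiveness is AGB gain per US$100. Consistent with reporting costs
as USD ha⁻¹ yr⁻¹, the default denominator is the annualized cost (this is
the convention under which the published medians are mutually consistent,
e.g. 100 × 36.4/52 850 = 0.069); a cumulative-cost variant is available by
passing total cost. The two horizons are 5 years (typical donor window) and
per-pixel full recovery.

The default `cost_schedule.yml` magnitudes are illustrative, chosen once to
respect the qualitative ordering passive ≪ ANR < planting in early-year
costs; analyses of real landscapes should substitute project budgets. Tests
deliberately assert structure, ordering and price-homogeneity — never the
default magnitudes.

## Prioritization and statistics

Per ensemble layer, the top-quartile threshold is the 0.75
linear-interpolation quantile of cost-effectiveness over candidate pixels
(restoration potential, finite CE); ties at the threshold are included, so
a degenerate constant layer selects every candidate (documented
behaviour). Priority 1 intersects all six layers ("consistently
cost-effective") minus the uncertainty mask; priority 2 rebuilds the
candidate sets without protected-area pixels first. A union/mean-rank
variant was considered and rejected as default because intersection matches
the "consistently cost-effective" reading.

Summaries report medians and IQRs for costs and cost-effectiveness (heavily
skewed) and means ± SD for AGB quantities (approximately normal). Group
comparisons use Kruskal–Wallis, Dunn post hoc z tests with tie correction,
Holm step-down adjustment (including the cumulative-maximum monotonicity
step), and an insert-and-absorb compact letter display.

## Synthetic landscape

The generator produces what the analysis assumes, with truth layers kept
for validation: 19 spatially autocorrelated climate fields (Gaussian-
filtered white noise, correlation length 1 km by default) of which six
drive a deterministic logistic maximum-AGB surface (30–320 Mg ha⁻¹; the
two leading fields dominate, mirroring landscapes where dry-season
temperature and water deficit control woody biomass) and thirteen are
r ≈ 0.85 collinear nuisance layers for the screen to remove; landcover from
a thresholded moisture proxy with categorical noise (moist forest, savanna,
floodplain, agro-mosaic); a positive degradation field with landscape mean
equal to `degradation_intensity` (default 0.35), inflated within 500 m of
randomly placed roads and settlement blobs and clipped to [0, 1]; current
AGB = maximum × (1 − degradation); four saturating (Michaelis–Menten)
reflectance responses to current AGB with Gaussian noise (default SD 0.01
reflectance units); smooth elevation (100–2500 m) and protected areas
covering 30% of the grid. Plots (default 195, measurement noise 10 Mg ha⁻¹
— a free parameter, as field campaigns rarely publish plot-level error)
fall uniformly at random; the closed-canopy flag means degradation < 0.2;
plot areas are Beta(1.3, 2.1) stretched over 0.08–1.00 ha. All randomness
derives from one `SeedSequence`, so identical seeds give bit-identical
output.

What the generator does **not** emulate: satellite radiometry and
atmospheric effects, real climate covariance structure, soil constraints,
spatially organized land tenure, and — because current = maximum × (1 − d)
with d ≥ 0 — negative deficits. Passing tests therefore demonstrate
internal correctness and recoverability, not real-landscape accuracy;
published landscape percentages (e.g. restorable share, method split) are
not reproduction targets on synthetic terrain.

## Problem sizes and numerics

Default desk-scale runs use a 160–200 pixel square 25 m grid (1600–2500 ha
after 4 × 4 aggregation to hectare cells), 195 plots, and 100-tree
forests — sizes at which the full pipeline completes in seconds while
leaving every statistical behaviour intact. Hectare aggregation is the
mean of the 16 fine densities (= sum of per-cell stocks), conserving
landscape totals to floating point. Degenerate inputs: constant predictors
are dropped from screening with a warning; constant responses yield
constant forests; empty distance masks raise naming the layer; zero or
missing costs give NaN cost-effectiveness with a warning; no-data
propagates through prediction rather than zero-filling.

## Known limitations

- Growth rates do not vary with method, climate or landcover; the scenario
  bundles are the only growth uncertainty represented.
- Cost magnitudes are placeholders with realistic structure, so absolute
  CE values are comparable within a run, not across studies.
- Opportunity costs are out of scope beyond land procurement and community
  engagement; no discounting beyond inflation.
- The envelope rule flags beyond-range extrapolation only.
- Raster I/O writes plain TIFF plus a JSON grid sidecar rather than
  georeferenced GeoTIFF tags; outputs re-read bit-identically but carry no
  CRS metadata.
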