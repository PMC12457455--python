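# Methods

This note records the models and procedures `foresttraj` implements, the
assumptions behind them, the parameter defaults and why they were chosen,
and what the synthetic-data experiments do and do not demonstrate.

## Analysis cells and reclassification

The unit of analysis is a fixed-size square cell of the source raster,
default 18 × 18 = 324 pixels — for a 300 m product this is a 3 arc-minute
cell; 36 × 36 and 180 × 180 give the 6 and 30 arc-minute variants, so scale
is a parameter rather than separate code. Maps are first reclassified to
eight aggregated IPCC-style categories (cropland, forest, grassland,
wetland, settlement, shrubland, bare, water), the level at which categorical
change detection in CCI-type products is considered reliable; sparse
vegetation is folded into bare to avoid false change between semantically
close classes. The shipped 22-class → 8-category table follows the CCI
user-guide aggregation and is fully overridable (`--reclass-table`).
Cells truncated at the raster edge, or containing nodata in *any* year, are
flagged incomplete and excluded — the conservative reading of the
equal-cell-size requirement.

## Dominant transition and certainty

Change is assessed between the first and last maps only. Identity pairs are
excluded from the transition matrix: a "transition" denotes change, and the
certainty measure (dominant count / changed pixels) is only meaningful over
pixels that changed. Ties for the maximum are possible in principle; they
are broken deterministically — forest-involving pairs first, then a fixed
category order — and flagged, so downstream consumers can drop tied cells
if they wish.

## Unlike-adjacency and the LCI

UA counts Queen-adjacent pixel *pairs* mixing the transition LC and its
complement, each pair once; boundary neighbourhoods are truncated (3/5/8
neighbours), no wraparound. Counting pairs (rather than per-pixel counts of
distinct neighbouring class *types*) is forced by internal consistency: a
324-pixel cell with 189 transition pixels can carry UA well above 324,
which only a pair count produces.

LCI normalises UA by the extreme values attainable with the same pixel
count k. `UA_min(k)`/`UA_max(k)` are computed exactly by full enumeration on
grids of ≤ 16 pixels, and constructively otherwise:

- minimum: grow a quasi-square block anchored in a grid corner (boundary
  truncation reduces exposure), adding at each step the candidate with the
  smallest marginal UA, then a steepest single-pixel-move descent;
- maximum: greedy placement of the largest-marginal-gain pixel (isolated
  interior positions first), then a single-pixel-move ascent.

The constructions are certified rather than proved optimal: they agree with
exhaustive enumeration for every k on 4 × 4, thousands of random
arrangements per k never fall outside the claimed bounds on 18 × 18, and
the constructed arrangements attain the tabulated values exactly. The
18 × 18 table (k = 0…324) ships as CSV with the package and is regenerable
(`foresttraj bounds-table`). For k = 0 or k = 324 the bounds collapse and
the LCI is undefined; such cells carry a degenerate-LCI flag and are
excluded from arrangement analyses.

## Interval, rate, classification, filters

With annual forest-pixel counts `c_0 … c_{n−1}`, the interval of change is
S = the last index with `c_t = c_0` for all `t ≤ S` and E = the first index
with `c_t = c_E` for all `t ≥ E`; duration = E − S inter-annual steps. The
relative rate 1/duration reproduces the canonical contrast: 30 pixels lost
evenly over 30 years → 1/30 year⁻¹; the same loss in one step → 1 year⁻¹
(identical absolute rates of 1 pixel/year). Classification reads
monotonicity non-strictly: zero-change plateau years inside the interval do
not break persistence, since stepped loss is still one-directional; both a
loss and a gain step make the cell non-persistent. Amount of change is the
first-vs-last difference *of the interval endpoints* as a grid proportion;
initial conditions (transition-LC amount and LCI) are read from the year-S
grid.

Filters, with defaults on a 324-pixel cell: fewer than 17 changed forest
pixels (≈ ≤ 5 % of the cell; the threshold scales as ⌈17/324 · cell size⌉ at
other scales), non-persistent trajectories, degenerate LCI at year S, and
cells whose dominant transition does not involve forest. The min-change
filter uses the interval endpoints; every exclusion carries its reason and
retained + excluded partition the input.

Pixel areas for reporting use a spherical Earth (R = 6371 km): great-circle
edge lengths divided by the row/column counts, averaging the north and
south cell edges. Areas are a reporting convenience, not an analysis input.

## Group statistics

Summary tables report n, Q1, median, mean, Q3, SD (sample SD, 0 for
single-value groups) and the group mean minus the pooled mean; quantiles use
linear interpolation. Cliff's delta is computed exactly in O(n log n) via
sorting (ties contribute zero). Its variance is the consistent estimate from
the row/column dominance means, and the CI uses Cliff's asymmetric
transformation, which respects the [−1, 1] range and degenerates gracefully
at |δ| = 1; the estimator is verified against brute-force pair counting and
the CI against simulated coverage.

## Smooth-effect models

Responses (amount, rate) are regressed on predictors (initial amount,
initial LCI) with a penalized cubic regression spline: the smooth is a
natural cubic spline parameterized by its values at 4 knots placed at
quantiles of the unique predictor values, with the integrated squared
second derivative as penalty and a sum-to-zero constraint for
identifiability next to the intercept. Errors are Gaussian, identity link,
no response transformation. The smoothing parameter minimises the Gaussian
REML criterion (error variance profiled out); the fit is cross-checked in
the test suite against R's `mgcv` (`gam(y ~ s(x, k=4, bs="cr"),
method="REML")`), with fitted curves agreeing to ~10⁻⁵ on fixtures. The cap
of 4 basis functions limits each curve to at most one interior extremum —
deliberate, since the scientific question is about broad monotone or
hump-shaped mediation, not wiggle-hunting.

Reported per model: edf of the smooth (hat-matrix trace minus the
intercept), proportion of null deviance explained (1 − RSS/TSS, the
Gaussian-identity equivalence), and curve summaries on a 200-point even
grid over the observed predictor range — argmax/argmin of the fitted curve
and the mean of signed and absolute finite-difference slopes (mean effect
and sensitivity per unit predictor). The grid size is configurable; 200
points make the grid discretisation error in argmax ≈ 0.25 % of the range.
Uncertainty bands use the Bayesian posterior covariance (A⁻¹σ̂²), whose
pointwise coverage of a smooth truth is verified by simulation (≥ 90 %).
Interpretation of LCI effects is conventionally restricted to LCI ≤ 0.6
(high LCI occurs almost only at extreme amounts, confounding the two); the
model table reports the share of observations above the cap as a flag, and
the cap never constrains fitting.

## Synthetic landscapes

The generator emulates the structural properties the pipeline assumes: a
cell starts with a chosen transition-LC amount arranged at a target LCI
(steered single-pixel moves from the nearer certified extremal arrangement;
realised LCI within ±0.05 of the target or the closest achievable value),
forest elsewhere, optional background classes. The forest count then
follows the requested trajectory exactly — gradual (even spread), abrupt
(single step), plateaued (interior zero years) or mixed (non-persistent;
gross loss followed by partial regain) — via forest↔transition conversions
placed preferentially at interface pixels so intermediate arrangements stay
plausible. Defaults mirror the study conditions: 29 annual maps, 18 × 18
cells, 8 categories. Everything is seeded; reruns are byte-identical, and a
noise-free generated cell is recovered *exactly* (class, interval, amount,
rate, initial amount) by the pipeline — the core fidelity property of the
test suite.

What the generator does **not** emulate: real geography (spatial
autocorrelation across cells, climate gradients, socio-economic drivers),
multi-class change chains, or sub-annual dynamics. Passing tests therefore
demonstrate correctness of the *computations* under controlled conditions,
not ecological validity of conclusions drawn from any particular real
archive.

### Classification noise

`apply_misclassification` supports two temporal modes. *Independent* mode
relabels each pixel-year independently (probability = rate, uniform over
the other categories) — the literal one-parameter perturbation. *Persistent*
mode draws one seeded error field and applies it to every year: an affected
pixel carries a fixed wrong label for the whole series. Persistent mode is
what the robustness analysis uses, for a substantive reason: classification
errors in products built from a baseline map plus change detection are
strongly correlated in time, whereas independent pixel-year noise makes
every annual forest count jitter, which drives the detected interval to the
full series length in every cell and erases all rate contrasts by
construction — a property of the perturbation model, not of the landscapes.
Under persistent 5 % noise the loss-vs-gain rate contrast keeps its sign in
every replicate while estimated amounts shift slightly (see
`analysis/06_uncertainty.py`).

## Numerical and design choices

- Category codes are 1…8 in a fixed order that also serves as the
  deterministic tie-break order.
- The steered-arrangement search and the bounds refinements use steepest
  single-pixel moves with a fixed iteration cap (500/200); caps were sized
  so the searches converge on 18 × 18 with large margins.
- REML optimisation is a bounded scalar search over log λ spanning 50
  natural-log units around a scale-invariant reference, so results do not
  depend on predictor units.
- NetCDF I/O uses the NetCDF3 (scipy) engine; GeoTIFF reading uses
  `tifffile`. Round-trips are exact for integer class codes.
- Problem sizes in the shipped analyses (120-cell mosaics, 400-cell planted
  experiment, 30 noise replicates, 100–200 model-calibration simulations)
  were chosen as the smallest sizes at which the targeted effects are
  estimated stably; all are parameters.

## Known limitations

- `UA_min`/`UA_max` on 18 × 18 are certified constructive bounds, not
  proven optima; any sharper bound would only widen the LCI denominator
  slightly.
- The Cliff's-delta CI is asymptotic; for very small groups (n < ~10) its
  coverage is approximate.
- With ties in > 75 % of a predictor's values, knot placement falls back to
  even spacing, which can under-resolve dense regions.
- The filter order records all applicable exclusion reasons independently;
  funnel counts per reason therefore overlap and do not sum to the excluded
  total when a cell fails several filters.
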