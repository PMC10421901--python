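# Methods

## Scope and data model

`ctm` operates strictly downstream of tile classification. A sample is a
rectangular grid of tiles (0-based `(row, col)`, row-major, top-left
origin), each carrying one texture label from {blood, cancer, normal,
stroma, other, empty} and optionally a lymphocyte score in [0, 1]. The
five non-empty labels form the tissue list `T`; "empty" is slide
background and never enters tissue denominators. Maps are exchanged as
long-format TSV/CSV; positions inside the declared bounding box that are
absent from a file are filled as "empty", since background dominates real
slides and sparse export is the natural format. Lymphocyte scores may be
missing (typically on background); every density computation ignores
missing scores.

## Majority-vote pooling

Tile classifiers produce tessellated maps: coherent regions broken by
sporadic single-tile labels. A `window × window` block (default 3, odd)
slides at a fixed `stride` (default 2) in raster order; each visited
window's tiles are reassigned to the window's modal label. Ties resolve by
a fixed hierarchy: cancer beats any tied label; stroma beats any tied
label except cancer; remaining ties are drawn uniformly at random among
the tied labels (canonically ordered) from a generator seeded per map from
`(global seed, CRC-32 of sample id)`, so cohort runs are reproducible
sample-by-sample and independent of processing order.

Three conventions the windowing itself does not determine:

- **Counts are taken from the pre-pooling grid** — a single pass over one
  input; windows never see earlier windows' edits.
- **Overlap**: with stride < window, overlapping tiles take the assignment
  of the later window in raster order. This keeps the output the same
  shape as the input so downstream area accounting is unchanged. A
  `downsample` mode (one output tile per window) is exposed for users who
  prefer a stride-2-reduced map; `inplace` is the default.
- **Edges**: final window offsets are clamped so the last row/column of
  windows touches the map edge; every tile is covered.

Maps smaller than the window are returned unchanged with a warning.

## Tumour margin

The margin is defined morphologically: a tile is margin iff it is
non-cancer, non-empty, and within Chebyshev distance `depth_tiles`
(default 2) of a cancer tile — the square dilation of the cancer mask
(`scipy.ndimage.maximum_filter`, footprint side `2·depth+1`) minus the
mask, intersected with tissue. Cancer tiles are the core, background stays
background, remaining tissue is non-margin. Background tiles adjacent to
cancer are *not* margin: the margin is a tissue compartment, and region
compositions are taken over tissue classes. With the default geometry
(256 px tiles at 0.25 µm/px) a two-tile margin is 512 px ≈ 128 µm wide —
roughly thirteen lymphocyte diameters. Margins are computed on the pooled
map by default, matching the smoothing-before-analysis order of the
pipeline. Margin analyses are restricted to samples with ≥1% normal
texture (inclusive bound), because a core-only section has no meaningful
exterior.

## Composition, QC and N-stratification

Per-sample composition is the tile count per texture; proportions default
to the tissue denominator (empty excluded; they then sum to 1), with an
`all_tiles` switch since published per-sample percentages do not state
whether background is included. QC applies, in order: resolution outside
the accepted band (default inclusive 0.1–0.35 µm/px, accepting ~0.25 and
rejecting ~0.50 µm/px scans), cancer proportion below 5% (strict `<`,
computed on the pooled map), then manually listed centres; each sample is
reported once with its first matching reason, and a missing resolution
warns but retains the sample. Samples split at 1% normal tissue into N+
(≥1%) and N− (<1%) as a proxy for the centre's sampling convention
(peritumoural inclusion versus tumour-core-only).

## Lymphocyte harmonisation

Per-texture density `d_t` is the mean score over tiles of texture `t`
(configurable floor `min_texture_tiles`, default 1). The relative
lymphocyte proportion rescales densities over the defined textures to sum
to 100%:

    ρ_t = 100 · d_t / Σ_u d_u

Undefined textures (absent, or under the tile floor) get ρ = 0 and are
excluded from the renormalisation and from α's area sum. Because ρ is a
ratio of densities from the same sample, any multiplicative bias — stain
intensity, scanner gain, a sample-wide infiltration level — cancels
exactly. The harmonised infiltration is the area-weighted mean

    α = Σ_t ρ_t A_t / Σ_t A_t ,

a convex combination of the sample's ρ values (so min ρ ≤ α ≤ max ρ), and
scale-free in the area unit (tiles and px² give identical α). ρ defaults
to per-sample; a `cohort_median` option computes one shared ρ vector from
per-texture cohort median densities rescaled to 100%, which makes α a pure
composition summary.

Centre binarisation assigns High iff a sample's value strictly exceeds its
centre's median (ties to Low, so at most ⌈n/2⌉ of a centre is High),
within centres of more than 20 samples; smaller or manually excluded
centres give NA. Binarisation accepts either α or raw density; the
pipeline uses α.

`harmonisation_report` quantifies what harmonisation removed. Raw density
(a [0, 1] mean score) and α (a percentage) live on different scales, so
between-centre dispersion is compared on the relative scale — the variance
of centre means divided by the squared grand mean (the squared CV of
centre means) — alongside the rank-based, scale-free Kruskal–Wallis
statistic. A ratio `var(α)/var(raw)` below 1 means harmonisation reduced
between-centre differences.

## Margin enrichment

Texture proportions and lymphocyte densities are computed separately in
the margin and non-margin regions (tissue denominator within each
region); enrichment is the margin:non-margin ratio per texture, plus a
total-lymphocyte ratio of region mean scores. Zero denominators yield NA
rather than a pseudocounted value — pseudocounts would silently
manufacture enrichment in sparse regions; an opt-in add-one-tile
`pseudo` mode provides finite ratios when needed. Cohort splits of a
ratio use the linear-interpolation quantile (median by default), High
strictly above the threshold, NA propagated.

## Association layer

Feature–group associations auto-select the conventional nonparametric
test: two groups → Wilcoxon rank-sum (exact when the combined n ≤ 20 with
no ties, otherwise normal approximation with mid-rank tie correction);
three or more → Kruskal–Wallis; two categoricals → χ² without continuity
correction (Yates is available upstream via `scipy` if wanted, but the
plain statistic is the default). Families of p values are adjusted with
Benjamini–Hochberg, one family per analysis table. Survival uses
Kaplan–Meier curves and the log-rank test over a 5-year horizon:
observations beyond 60 months are administratively censored at 60
(events later than the horizon count as censored, not as events).

## Synthetic cohort generator

The generator produces the study conditions every test runs under: a
multi-centre cohort with *known* ground truth and the two batch effects
the harmonisation targets.

- **Geometry.** Each sample is an elliptical cancer core (semi-axes drawn
  per style as a fraction of the interior half-extent) inside an empty
  border. N+-style samples wrap the core in a stroma ring (2–4 tiles)
  and an outer normal-tissue rim; N−-style samples fill the non-core
  interior with a stroma/blood/other mixture drawn per sample from a
  per-centre Dirichlet — and contain no normal tissue, guaranteeing
  N− classification. Single-tile blood/other speckles (rate 0.06) are
  injected everywhere so pooling has realistic work to do. Ellipses are
  not realistic histology; they are sufficient to exercise pooling,
  margins and composition accounting.
- **Centre bias.** Centres differ in the probability of producing an
  N+-style sample (defaults 0.9/0.6/0.3/0.0 across four centres —
  composition bias) and in a multiplicative stain-intensity factor on
  every lymphocyte score (defaults 0.7–1.4). Both effects are
  well-documented features of multi-centre archives. Per-sample ρ cancels
  a multiplicative bias exactly, so the stain spread is what the
  harmonisation property demonstrably removes; composition bias alone
  shifts raw density and α in near-proportion and is handled by the
  N+/N− stratification instead.
- **Scores.** Tile score = clip(b_c · e_t + ε, 0, 1) with shared
  enrichment e = {normal 0.45, cancer 0.35, stroma 0.25, blood 0.15,
  other 0.08} (ordered normal > cancer > stroma > blood > other, the
  ordering observed in real cohorts) and Gaussian noise σ = 0.05 — the
  simplest noise respecting the score range. With σ = 0 and b = 1 the
  per-texture densities recover e exactly. No per-sample infiltration
  level factor is modelled; real cohorts additionally vary strongly in
  overall infiltration, which per-sample ρ would likewise cancel.
- **Survival.** Exponential event times (median 48 months) with
  independent uniform censoring on 12–96 months, optionally linked
  log-linearly to one ground-truth column — enough to exercise the
  KM/log-rank plumbing, with no claim of realism.
- **Determinism.** One `numpy` generator seeded from the config seed
  drives everything; a fixed seed yields byte-identical serialised
  cohorts.

What passing tests on this generator shows: the pipeline's accounting,
invariances and the harmonisation mechanism are correct under controlled
composition and stain bias. What it does not show: performance under real
histology — irregular tumour geometry, texture-dependent classifier
error, non-multiplicative stain effects, or spatially correlated
lymphocyte noise.

## Problem sizes and numerical conventions

Default test/demonstration cohorts use 40×48-tile grids and 10–25 samples
per centre; the harmonisation property is measured over 100 replicates of
a two-centre, 10-samples-per-centre design, which completes in seconds
while leaving the variance comparison far from marginal (observed ratios
≈ 0.003–0.03). Proportion sums are asserted to 1e-9, ρ sums to 1e-6 (%),
α bounds to 1e-9. Ties: pooling follows the hierarchy above; binarisation
and quantile splits send ties to Low. Degenerate inputs are flagged, not
silently imputed: all-empty maps get undefined proportions, empty margin
or non-margin regions give NA ratios, single-centre dispersion reports
are marked degenerate.

## Known limitations

- The in-place overlap semantics of pooling is one of two readings of a
  stride-2, 3-wide sliding window; the `downsample` mode covers the other.
- Whether published per-sample texture percentages include background in
  the denominator is unstated; the `denominator` switch covers both.
- The Benjamini–Hochberg step-up is not idempotent (re-adjusting an
  adjusted family inflates its minimum), so adjusted values are written
  once per family and never re-adjusted.
- Manual-review QC categories (necrosis, atypical histology) are out of
  scope; QC here is purely quantitative plus an explicit centre list.
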