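# Methods

This note documents the models, conventions, and numerical choices behind
`scenerecall`, and what the synthetic generator does and does not emulate.

## Coordinate and geometry conventions

All pixel work uses a top-left origin, x rightward, y downward, 0-based
indices, and half-open boxes. Rasterization marks a pixel inside a polygon
iff its **center** (x + 0.5, y + 0.5) is inside under the even-odd
(ray-casting) rule; the implementation is vectorized per edge over the
polygon's bounding box and is checked against an exhaustive scalar oracle
on small grids. Every derived geometric quantity is expressed as a
proportion of image width/height so that displacement and size metrics are
resolution-independent.

The "true" object ellipse that drawn-object ellipses are compared against
is the axis-aligned ellipse inscribed in the mask's bounding box (center =
bbox center, full axes = bbox extents). The object-inclusion rule keeps
outlines whose mask *equivalent diameter* (2·√(area/π)) is at least 50 px —
boundary inclusive — and always drops space-defining surfaces (wall,
ceiling, floor, sky, ground). The equivalent-diameter reading of the 50-px
rule is a design choice; no shape-specific rule is defined, and the
threshold is a parameter.

Overlapping objects are painted in memory maps with **foreground
priority**: the smallest-area object wins a contested pixel, since small
objects nest inside large ones in labeled scenes. Object clusters are kept
exactly as annotated, never split.

## Crowd aggregation rules

- 3AFC matching: proportion correct over 24 raters; *recalled* requires a
  strict majority (a 12/24 tie fails). Category drawings have no correct
  answer; their score is the mean of two separate runs, one against each
  study exemplar.
- Presence: an object is in a drawing iff ≥ 3 of 5 raters vote yes;
  objects with fewer than 3 total votes are indeterminate and excluded with
  a log message.
- Extra objects: free-text names are trimmed, casefolded,
  whitespace-collapsed, and stripped of one trailing plural "s" (words in
  "-ss" kept); a name counts iff ≥ 3 of 5 raters report it. No synonym
  dictionary is applied by default; a user-supplied map can be passed.
- Ellipses: annotations are linearly mapped from the drawing frame to the
  unit square and averaged (mean, not median — configurable design choice)
  per (drawing, object) across 5 raters. Because both steps are linear,
  transform-then-average equals average-then-transform.
- Boundary-extension ratings (−2…+2) average over raters excluding "can't
  tell"; typicality (1–5) averages over 24 raters per image.

## Spatial metrics and the placement null

Displacement records carry |Δx|/W, |Δy|/H and signed Δw/W, Δh/H per drawn
object. Summaries average within image first, then across images, so each
image contributes one observation per condition. The chance level for
displacement draws 100 uniform centroids per object per image and averages
|Δ| over 1000 iterations; uniformity over the full unit square is the
minimal assumption for "random placement". One-sided p-values (observed
closer than chance) use the add-one rule, so p ≥ 1/(N+1) and p = 0 is
impossible. Useful analytic anchors: a centered object has chance
E|Δx| = 1/4; averaging over uniformly distributed true centroids gives 1/3;
centroids restricted to roughly [0.1, 0.9] (as margins impose) give ≈ 0.30,
matching the ~30% chance level reported for real scenes.

## Maps

Memory maps set each object's pixels to (#recallers who drew it) /
(#recallers); the denominator is the set of participants whose drawing of
that image was scored a successful recall. Zero recallers make the map
undefined (emitted as missing). Grand averages min-max scale each map,
resample (nearest-neighbor) to a common grid, average pixel-wise, divide by
the [0, 1]-scaled object-count map only where the count is nonzero (no
epsilon — no object can be recalled where none exists), and rescale.
Vertical profiles are row means after resampling to 700 rows, min-max
scaled; a constant map degenerates to an all-zero profile. Min-max scaling
treats a numerically constant array (range ≤ 1e−9 relative) as degenerate
rather than amplifying floating-point dust.

## Meaning maps and attention models

Patch grids are uniform and row-major at two scales; the defaults at the
512-px-long-side resolution are 44-px-diameter patches at 22-px spacing
(small) and 100-px at 50-px spacing (large), chosen to approximate the
patch-to-image proportions of the established meaning-map protocol while
guaranteeing full coverage (spacing ≤ diameter/√2). Per scale, per-patch
mean ratings are interpolated to full resolution with a thin-plate spline
(scipy's RBFInterpolator; smoothing 0 = exact interpolation, configurable
for noisy data), evaluated on a stride-4 subgrid and upsampled — the
interpolant is smooth, so the stride loses essentially nothing, and the
exactness contract is tested at the patch centers themselves. The two
scale maps are averaged, multiplied by a centered Gaussian with SD = 0.5 ×
(width, height) by default (the center-bias width is not pinned down by
the protocol and is exposed as a parameter), and min-max scaled.

Object scores are the mean (or peak) of a map over the object's mask.
Correlations with recall use Spearman on tied ranks; the semi-partial
variant regresses the control variable's ranks out of one side only
(default: the predictor; residualizing the outcome and the full partial
correlation are both available, since the published wording does not
disambiguate which was used), with p from the t approximation on n − 3
degrees of freedom. Saliency maps are consumed as data (dense matrices);
no saliency algorithm is reimplemented.

## Statistical toolbox

- Wilcoxon rank-sum: normal approximation on the rank sum with average
  ranks and tie-corrected variance, no continuity correction — immaterial
  at the n = 60 images-per-condition scale this pipeline compares. For tiny
  samples `method="exact"` enumerates all group assignments and returns
  P(|W − E[W]| ≥ |obs − E[W]|) exactly; the normal approximation can
  deviate from enumeration by up to ~0.07 even tie-free at n = 6+6, so
  exactness claims are only made for the exact mode.
- Permutation tests shuffle group labels; two-tailed p uses the add-one
  rule. The default statistic (difference of means) is vectorized; custom
  statistics fall back to a loop.
- Spearman is Pearson on average ranks with the t approximation
  (scipy.stats.spearmanr); paired t delegates to scipy with explicit
  handling of zero-variance differences (t = 0 when the mean difference is
  0; flagged infinite otherwise).
- The JZS Bayes factor integrates the Rouder one-sample marginal likelihood
  over the g-prior by adaptive quadrature (relative tolerance 1e−8, checked
  against an independent implementation in tests). The default Cauchy scale
  is r = 1.0 — the original default, which reproduces the 2.11:1 reference
  value for t(29) = 1.61; the newer √2/2 convention gives 1.62 and is
  available via the `cauchy_scale` argument.

## The synthetic generator

The generator's defaults are the study's conditions, so that the pipeline's
recovered numbers land on the published scale:

| parameter | delayed | immediate | image | category |
|---|---|---|---|---|
| image drawn probability | .403 (.380 low / .429 high) | 1 | 1 | 1 |
| mean object-drawn proportion | .374 | .421 | .515 | .265 |
| E\|Δx\|, E\|Δy\| (image prop.) | .065, .099 | .047, .070 | .045, .066 | .12, .14 |
| size bias w, h (image prop.) | +.021, +.034 | +.013, +.026 | +.020, +.034 | +.03, +.04 |
| extras per drawing | 1.83/12.1 | 1.11/30 | 1.80/30 | 58.4/30 |
| 3AFC rater accuracy | .843 | .960 | .925 | .307 |

Scenes hold 6–50 rectangular/elliptical outlines (clipped normal, mean
21.1, SD 10.4) at a 512×384 canvas, packed with an adaptive minimum
center distance; every generated object passes the 50-px inclusion rule by
construction, and one full-frame "wall" exercises the space-defining
filter. Latent saliency and meaning fields are smoothed Gaussian random
fields with a center-bias bump. Object recall is logistic in the latent
mean saliency and meaning of the object and in its centroid height
(positive weight on y = lower-visual-field bias, so the recall maps are
bottom-heavy while the model maps stay center-biased); the intercept is
solved by root-finding so the mean recall probability over the actual
object-score distribution equals the condition's target — the generator's
headline proportions are therefore exact by construction, not tuned.
Displacement is parameterized by the expected absolute error per axis and
converted to the Gaussian SD via E|N(0, σ)| = σ√(2/π). Extra-object counts
are Poisson per drawing; the delayed-recall rate is per *drawing*, chosen
so the per-participant total over the ~12.1 drawings a participant makes
matches the per-participant benchmark of 1.83.

Worker noise defaults: presence sensitivity/specificity 0.97, ellipse
center and size jitter SD 0.01 (image proportions; with 5 raters averaged,
this inflates recovered displacement by ≈ 0.0001 — negligible), rating SD
0.5 scale units, extra-report sensitivity 0.95 with a 2% spurious-name
rate, 5% "can't tell". These are free parameters, not estimates of any real
crowd (no inter-rater reliability is published to calibrate against).
Recognition uses hit probability logistic(ability + effect·(HR − mean HR))
with ability 2.36 and effect 2.2 (chosen to land the ~90.6%/10.2% HR/FA and
the ~1.2-image high-vs-low recognized difference), and a constant
false-alarm rate to medium-memorability foils.

Randomness is one `numpy` Generator stream per (seed, stage-name) pair, so
stages are individually reproducible and byte-identical under a fixed seed.

**What the generator does not emulate:** actual drawing images (the
pipeline operates on annotation-level content, as the scoring does);
rater-specific quality differences or spam; correlated errors across
raters; non-Gaussian displacement structure such as mirror flips; semantic
structure in scene layouts (object names are drawn from lexicons, and
objects are independent rectangles/ellipses rather than coherent scenes).
Passing parameter-recovery tests therefore shows the *analysis* is correct
and unbiased under the assumed noise model — not that the noise model
captures every property of human drawings.

## Problem sizes

The desk-scale replication used by the acceptance script and the recovery
tests runs 30 scene categories (60 study images + 30 foils), 30 recall
participants per recall condition (24 image-drawing, 15 category-drawing),
the published rater counts (24/5/5/5/7/24), and the published permutation
sizes (100 centroids × 1000 iterations). Unit tests use smaller worlds
(3–8 categories) since every rule they check is scale-free.

## Known limitations

- The exact regridding used for published 700-row vertical profiles is not
  documented; nearest-neighbor resampling is used here.
- Whether the published category-drawing "accounting" was a partial or
  semi-partial correlation, and which side was residualized, is ambiguous;
  all three variants are implemented and the default is declared.
- Chance-displacement levels depend on the true-centroid distribution of
  the scene set; synthetic scenes reproduce the ~30% level because their
  centroid margins resemble real object layouts, not because it is forced.
- Exact WRST enumeration is capped at C(n, n_a) ≤ 5·10⁵ assignments.
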