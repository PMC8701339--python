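# Methods

## Polar representation and cut-throughs

Outlines are closed simple polygons in image pixel coordinates
(origin upper-left, x rightward, y downward). No physical scaling is
applied: every reported quantity is a ratio and therefore
magnification-invariant.

The polar origin for both structures of an eye is the **disc**
centroid. The default centroid is the exact polygon first moment; a
`raster` mode rasterizes the polygon to a supersampled binary mask
(cell centers inside, configurable cells-per-pixel, default 4) and
takes the mask's center of mass, mirroring binary-image
regionprops-style pipelines. Tests bound the analytic/raster
discrepancy below 0.5 px at 4x; because downstream quantities are
ratios of distances ~100 px, the induced CDR error is O(1e-3) at
worst and the analytic default removes it entirely.

Angles follow the fundus clock: 0° at 12 o'clock (screen-up), 90° at
3 o'clock (screen-right), increasing clockwise, with the identical
formula `atan2(dx, -dy)` for OD and OS. Degrees are the integers
0-359; no sub-degree sampling or angular smoothing is performed.

The half cut-through at degree *d* is computed by exact ray-segment
intersection with every boundary edge, not by resampling boundary
pixels. Rays that pass exactly through a polygon vertex are handled by
evaluating both incident edges with a 1e-9 parameter tolerance and
collapsing duplicate hits at equal distance. If a ray crosses the
boundary more than once (the outline is not star-shaped about the
centroid), the **farthest** intersection is kept and the profile is
flagged `non_star_shaped_*`; this keeps a pathological disc boundary
outside the cup rather than letting it dip inside. A cup reaching
outside the disc sets `cup_outside_disc`; values are flagged, never
clipped.

Full cut-throughs are H(d) = h(d) + h((d+180) mod 360), so the full
CDR is 180°-periodic exactly by construction. VCDR ≡ full CDR at 0°,
HCDR ≡ full CDR at 90°.

## Grader averaging

The default combines graders by averaging half cut-throughs per degree
per structure and recomputing CDRs from the averages
(`average_cut_throughs`). Averaging the per-grader CDRs instead
(`average_cdrs`) is exposed as an option; the two agree only when both
graders drew identical discs. The cut-through-first rule was chosen
because cut-throughs, not ratios, are the per-degree measurements
being reconciled; the difference is second-order in the inter-grader
disc disagreement.

The area ratio of an averaged profile is the mean of the two graders'
polygon area ratios: areas are not reconstructible from averaged radii
without assuming star shape, and the mean-of-ratios matches how
per-eye area ratios are tabulated.

## Adjudication

Dice is computed by exact polygon clipping. Flagging uses strict
inequalities: dice < 0.7 on **either** structure, or |ΔVCDR| > 0.2;
boundary values do not flag. Each grader's VCDR for the flag is taken
about that grader's own disc centroid. Dice is made exactly symmetric
by canonicalizing clipping argument order (polygon clipping is
last-ulp order-sensitive). Resolutions: keep grader 1 or 2 (no
averaging), substitute adjudicator outlines (used alone), or declare
the image ungradable, which removes it from every cohort output.

## Cohort structure

VCDR decile bins: bin k covers [(k−1)/10, k/10), left-closed, with
bin 10 closed above so VCDR = 1.0 is representable. Per-degree means
use the sample mean; SDs use the n−1 denominator (0 when n = 1); empty
bins yield n = 0 summaries with NaN moments rather than errors. OS
profiles are mirrored (v'[d] = v[(360−d) mod 360], an involution with
fixed points at 0° and 180°) into the OD nasal/temporal frame before
pooling by default.

The notch window is the peak of the per-degree half CDR (argmax, ties
to the smallest degree) ± 25°, i.e. 51 samples including the center —
"50 surrounding degrees" read as symmetric; the half-width is a
parameter. Peaking on the raw cup half cut-through is available as an
option. The drop statistic is the center value minus the mean of the
two window-edge values.

## Statistics

Spearman rho uses average ranks for ties. The default 95% CI is the
Fisher z-transform with rank-correlation variance 1.06/(n−3); a
pairs-bootstrap percentile CI is provided as an option since no
closed-form CI is canonical for rho.

The allele trend test fits `outcome ~ allele_count + age_c + gender`
(identity link, Gaussian) by generalized estimating equations with an
exchangeable working correlation across the up-to-two eyes of each
subject and robust sandwich SEs; eyes are the rows, subjects the
clusters. Age is centered; gender is a single indicator. The trend
p-value is the Wald test on the continuous allele-count coefficient.
Adjusted means per allele level are linear predictions at that count
with age at its mean and the gender indicator at its sample
proportion; their SEs come from the robust covariance. When every
subject contributes one eye the exchangeable parameter is
unidentified; the fit then degenerates to an independence model (OLS
point estimates with robust SEs) and a warning is recorded. With 300
clusters the null rejection rate at α = 0.05 measures ~0.06-0.07
(robust SEs are mildly anti-conservative at finite cluster counts; no
small-sample correction is applied).

## Synthetic eyes

The generator defines boundaries as star-shaped radial functions:
disc = rotated ellipse (default semi-axes ~100 × 90 px, the scale of a
disc on a 30° fundus photograph) times (1 + a·cos(kθ)) waviness
(default amplitude 0.03, order 5); cup = the proportional ellipse
scaled by the base CDR about an offset center (eccentric cupping),
with its own waviness (order 4, fixed phase) and an optional notch — a
raised-cosine outward bulge of the cup radius (default width 40°,
depth up to 0.18 of the local radius), matching a focal rim loss.
Nesting is validated analytically before generation.

Graders observe each boundary through multiplicative noise
1 + ε(θ) with ε a low-order random Fourier series (SD 2%, angular
correlation length 60°, so neighbouring vertices move together as in
hand tracing) plus an optional systematic per-grader radial bias.
Outlines default to 120 vertices, a realistic hand-trace density.
Ground truth is evaluated on a 3600-vertex noiseless sampling of the
continuous model about its dense-polygon centroid; the discretization
error (~1e-7 px) is negligible against every tolerance used, and a
convergence test at 90/360/1440 observation vertices confirms the
pipeline approaches truth as outlines are refined.

Cohorts draw case base CDRs from a truncated normal (0.65 ± 0.12) and
controls from (0.40 ± 0.10); the two eyes of a subject share a latent
CDR (within-subject SD 0.03); clinician VCDR re-reads truth with
truncated-Gaussian noise (SD 0.05); allele counts are binomial(2, f)
per subject with optional additive effects on base CDR; ~15% of eyes
receive a notch at a random temporal location. A note on closed
forms: a uniform radial shrinkage of one grader's outlines by factor
s yields dice 2s²/(1+s²) — 0.78 at 20% bias — so crossing the 0.7
adjudication threshold requires roughly 27% systematic bias; the
biased-grader fixtures use 30%.

What the generator does **not** emulate: vessel-driven local outline
errors, disc tilt/peripapillary atrophy, blur-induced ungradability,
correlation between grader error and disease severity, or any image
pixels at all. Passing tests therefore demonstrate correctness of the
measurement and statistical machinery given outlines, not robustness
of human grading.

Because the cohort-wide cup waviness has a fixed phase, group-level
peak localization inherits a small systematic offset (~2-3° at the
default settings); the notch-recovery checks use the group mean
against a ±3° bound, which absorbs it.

## Problem sizes used in validation

The self-validation script and acceptance tests use: 100 random star
polygons (polar oracle) and 100 random convex pairs (overlap oracle);
a 200-eye cohort for VCDR recovery and clinical correlation; 40
notched + 40 plain matched eyes for notch analysis; 500 null
replicates of 300 two-eyed subjects for trend-test calibration. These
sizes give Monte-Carlo standard errors comfortably below the
tolerances they are checked against.

## Known limitations

- Non-star-shaped outlines are flagged, not geometrically repaired;
  downstream CDRs for such eyes use the farthest-crossing convention.
- The ImageJ ROI codec supports the polygon family (polygon, freehand,
  traced) with optional subpixel coordinates, header versions ≥ 218;
  composite/shape ROIs are rejected.
- The exchangeable GEE assumes at most modest cluster sizes (two eyes);
  it is not intended for longitudinal repeat imaging.
- Notch *detection* is out of scope: notch status is an input label,
  and the window analysis quantifies, rather than discovers, notches.
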