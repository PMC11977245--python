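# Methods

## Measurement model

The quantity of interest is the areal fraction of desquamated (flaking)
stratum corneum on the lower-lip premucosa, expressed in percent of a
rectangular target region. The model underlying the measurement is that,
in a grayscale lip patch, flake pixels are *bright outliers* of an
otherwise compact intensity distribution: normal lip texture (shading plus
fine wrinkles) occupies a unimodal bulk, and flakes contribute a sparse
long right tail. Under this model a global threshold placed as an outlier
bound,

    T = Mean + k · SD,

separates flakes from background, where Mean and SD are the population
statistics (SD divides by N) of all pixels of the cropped patch and k is a
dimensionless multiplier. Pixels strictly above T are objects; the
desquamation rate is 100 · n_object / n_total.

Assumptions and their consequences:

- *Flakes are a minority of the area.* If flakes dominated, they would
  drag Mean and SD upward until T overtakes them; at the fractions seen on
  lips (well under 10%) the threshold inflation is modest. The inflation
  is visible in the synthetic benchmarks: at 5% planted coverage the
  threshold rises by roughly one background-SD, and recovery of the
  dimmest flakes becomes marginal.
- *The background is light-tailed.* A heavy-tailed background would leak
  false positives above T at any k. This motivates per-patch statistics
  (the crop, not the whole face) and is the reason histogram-shape methods
  are the wrong tool here: Otsu and Triangle assume separable histogram
  structure and, on a long-tailed unimodal histogram, place their cut
  inside the normal-skin bulk.
- *Strict comparison (> T).* Pins the boundary case: a zero-variance patch
  has T = Mean and an empty mask, rate 0.

### Region of interest

The eight face-mesh landmarks 14/15/16/17 (lower-lip midline) and
84/87/314/317 (flanks) define the rectangle: width is the larger of the
two x-spans |x84 − x87| and |x314 − x317|; height is the distance between
the y-midpoints of the 14–15 and 16–17 pairs. The anchor is not dictated
by those formulas, so the package centres the rectangle horizontally on
the mean x of {84, 87, 314, 317} and runs it vertically from the upper to
the lower pair-midpoint — the landmarks bound the centre of the lower lip,
and these choices keep the rectangle inside that area. Geometry is
computed in floating point; bounds are rounded to integers last
(half-open, 0-based). Rectangles that spill past the image after rounding
are clipped with a logged warning rather than rejected. Only x and y are
used; the z of 3D landmarks is ignored. Landmark acquisition is pluggable
(JSON files; an optional external face-mesh adapter in
`lipdesq.detectors`), so nothing in the package requires a face model.

### Grayscale

BT.601 luma (0.299, 0.587, 0.114), kept as reals in [0, 255] without
re-quantization, so threshold comparisons are free of rounding artifacts.
Any fixed luma would serve; this one is pinned for reproducibility.

## Calibration of k

Rates are computed at every k in 1.5–4.5 (step 0.1, 31 values) and
correlated (Pearson by default, Spearman optional) with final visual
scores across a cohort. The empirical shape is rise–plateau–decline: at
small k the threshold admits texture and specular distractors (noise
uncorrelated with severity), at large k genuine flakes fall below T and
the rates compress. Because "maximize correlation while minimizing omitted
flakes" does not pick a unique point on a plateau, the package pins a
deterministic rule: **the smallest grid k whose correlation is within a
tolerance (default 5%) of the grid maximum**. Tolerance 0 recovers the
argmax; ties break toward smaller k by construction. k = 2.5 is shipped as
the measurement default.

## Tape-strip comparator

The instrument model groups corneocyte grayscale values into five classes
over 35-unit intervals starting at 80 (edges 80, 115, 150, 185, 220, 255).
Bins are lower-closed half-open, the last closed at 255 — pinned because
adjacent published ranges share endpoints, and a value of exactly 150 must
be *retained* when everything below 150 (G0, G1) is excluded as quality
control. Values below 80 (a display default, not a physical floor) go to
G0; since G0 never enters the rate, the choice only affects reported
proportions, and it is pinned for determinism. Rate = G2 + G3 + G4, as
percent of the supplied values.

## Visual assessment

Integer scores 0 (none) to 4 (severe), several raters; the final score is
the unrounded arithmetic mean across raters (missing cells: mean over
available raters, with a warning). Inter-rater reliability is the mean of
the upper triangle of the pairwise Pearson matrix; a zero-variance rater's
entries are undefined and excluded.

## Cohort statistics

- *Method agreement*: Pearson r and p of rate vs final score, plus the
  mean squared vertical residual about the OLS line of min–max-normalized
  rate on score. Min–max normalization is pinned for the bounded
  comparison axis; it affects MSE comparability only within-method, which
  is how the comparison is used.
- *Decade groups*: Kruskal–Wallis across decades (20s–60s), pairwise
  two-sided Wilcoxon rank-sum with Holm adjustment (unadjusted values also
  reported, since no adjustment convention is canonical here).
- *Trend*: Spearman rho (primary), with Pearson and the OLS slope always
  reported alongside; Shapiro–Wilk normality p-values are computed and
  logged but never trigger automatic switching — determinism over
  automation.
- *Local regression*: lowess of rate on age, span 0.75 by default,
  evaluated at the observed ages.
- *Breakpoint scan*: at every candidate age a that leaves at least
  `min_side_n` (default 30) records on each side, the slope change is
  tested. Default formulation: one piecewise-linear OLS model
  `rate ~ age + max(age − a, 0)` with a t-test on the hinge coefficient;
  the alternative (`two_fit`) fits independent lines and z-tests the slope
  difference. The breakpoint is the age of minimum p (ties toward the
  younger age); reported segment slopes always come from the two separate
  fits. Because ~dozens of correlated tests are scanned, the minimum p is
  Bonferroni-adjusted by the number of candidates before the significance
  call — without this, a purely linear cohort would "find" a breakpoint at
  the 5% level far too often. Bonferroni is conservative under the scan's
  positive correlation, which is the right direction for an existence
  claim.

## Synthetic data: what it emulates, and what it does not

The generators define the study conditions for every test.

**Lip patches** (default 160 × 96 px, background mean 120, SD 12,
correlation length 4 px): the background is low-pass-filtered Gaussian
noise whose marginal is tanh-squashed — compact, light-tailed — so that
the *flakes* own the right tail, as in real lip patches where normal skin
rarely strays several SD above its mean. Flakes are irregular soft-edged
ellipses (boundary-perturbed, ~70 px mean area, lognormal size spread)
composited by alpha replacement: under a flake the surface *is* the flake
plane at `contrast × SD` above the background mean (default contrast 5.5,
per-flake modulation U(0.9, 1.25)), with a ~1 px blended rim and a
half-normal within-flake brightness relief (amp 0.45) that spreads flake
intensities into a decaying tail. Planted area lands within ±10% of the
requested fraction; everything is bit-reproducible from one seed via
`SeedSequence` spawning. A histogram "mode" is operationally defined as a
local maximum of the smoothed 256-bin histogram with prominence ≥ 10% of
the peak — the judgement a practitioner makes when reading such a
histogram as long-tailed unimodal.

**Scored cohorts** (default 55 subjects, 5 raters): a latent severity
U(0.3, 3.7) drives both the planted flake fraction
(0.002 + 0.010 · severity) and the rater scores (severity + N(0, 0.5),
rounded, clamped to 0–4, giving mean pairwise inter-rater r ≈ 0.75). Each
subject additionally carries a random load of *distractor speckle*
(fraction U(0.005, 0.05) of pixels at 2.2–2.9 SD) uncorrelated with
severity — the specular micro-texture of normal lips. The speckle is what
shapes the calibration curve: it pollutes masks below k ≈ 2.3 and clears
above, producing the rise–plateau–decline with the plateau at
intermediate k.

**Trend cohorts** (10 subjects per sex per year of age, 20–69): female
expected rates rise at 0.019 %/yr from 0.217% at age 20 to a breakpoint at
38, then decline at 0.005 %/yr; male rates decline linearly at 0.005 %/yr
from an intercept (0.5625% at 20) chosen so the male cohort mean is
0.440%. Gaussian noise (SD 0.1) is added and rates truncated at zero.

Not emulated: anatomy, pose, illumination variation, lip colour, camera
noise, rater bias or drift, and any correlation between background texture
and severity. Passing tests therefore demonstrate that the measurement
chain is correct *under its own model* — bright-outlier flakes on
compact-background patches — not that it is robust to uncontrolled
photography.

## Numerical choices and problem sizes

- Population SD everywhere the threshold is involved; tests pin this
  against hand-computed statistics to 1e-9.
- Rate sweeps over the k grid share one sort of the pixel values
  (right-bisection for the strictly-above count), exactly equal to
  thresholding each k separately.
- Otsu/Triangle operate on the patch rounded to uint8 (256-bin
  histograms); a single-valued histogram returns that value as T, which
  with strict comparison yields an empty mask.
- Benchmarks use 50 patches (fractions 0.5/1/2/5%), 20-replicate
  breakpoint simulations, and 20-image monotonicity sweeps — sizes at
  which the checked properties are stable while the whole suite stays
  interactive.

## Known limitations

- At 5% planted coverage (the top of the tested range), threshold
  inflation makes the dimmest flakes marginal and an occasional patch
  shows a secondary histogram ripple just above the 10% prominence bound;
  both effects vanish at the ≤2% coverages typical of real lips.
- The smallest-within-tolerance selection rule assumes a positive
  correlation maximum; with an all-negative calibration curve its
  tolerance band is not meaningful.
- The breakpoint scan tests a single slope change; multiple breaks or
  smooth curvature are summarized only through the loess curve.
- Min–max normalization makes MSE values depend on the observed range;
  they are comparable across methods only on the same subject set.
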