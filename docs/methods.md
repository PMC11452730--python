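# Methods

## Curvature of Bézier contours

Body contours are represented as Bézier curves — single segments of
arbitrary degree, or piecewise-cubic paths (the form produced by SVG `C`
commands and by the synthetic generator).  Signed curvature is computed
from the analytic derivatives of the Bernstein form (the hodograph), never
from finite differences, so there is no step-size parameter:

κ(t) = (x′y″ − y′x″) / (x′² + y′²)^{3/2}.

Coordinates follow the pixel/SVG convention (y increases downward); all
lengths are in px and curvature in 1/px.  The sign of κ flips under
mirroring; only |κ| enters the curviness statistic.

**Curviness** is the arc-length-weighted mean absolute curvature
C = (1/L)∫|κ|ds, evaluated by a composite trapezoid rule on a uniform
parameter grid with weights ds = |B′(t)|dt.  The default grid is n = 2048
points, at which the quarter-circle cubic benchmark recovers 1/r to about
0.01% and halving/doubling n moves the result by less than 1e-6 relative.
An arc-length weighted mean is used rather than a parameter-uniform mean;
for near-arc-length parameterized contours the two agree closely, but the
arc-length version is the geometrically meaningful one (it equals the
average tooth length of the curvature comb divided by the comb scale).

A parameter value where |B′| < 1e-9 × (bounding-box diagonal) is treated
as a cusp and reported as a singular-point error with its location; the
curviness statistic is only defined for regular curves.

**Curvature combs** place teeth at equally spaced arc-length stations along
the unit normal with length scale·|κ|; tooth values are returned for
external color mapping, and the SVG renderer maps them through a heat-map
colormap.  Note that the popular single-cubic 90° circle approximation has
curvature varying by ±1.5% around 1/r, so combs on it are visibly uneven at
high magnification; its *mean* |κ| is still within 0.1% of 1/r.

**Contour RMSD** compares two S-curves after scaling each to unit height
and translating the start points together, by the root mean square of
horizontal offsets at equally spaced height stations.  This requires both
curves to be strictly monotone in height; the violating curve is named in
the error.  The statistic is symmetric and zero iff the normalized curves
coincide at every station.

## Torso synthesis and WHR

A stimulus is built from a single left-side contour (chest → thigh) by
**rigid placement**: translate the contour so its most lateral point sits at
hip_width/2 from the midline, then mirror.  No horizontal rescaling takes
place, so one contour has *identical* curviness at every width — the design
property that decorrelates curviness from width.  The printed width series
210…350 px is consistent with a fixed hip-minus-waist offset D = 105 px
(W = 105/(1 − WHR) for WHR 0.50…0.70), which is how the widths and the
52.5 px lateral range of the curviest default contour are linked.

WHR measurement uses geometry only: cross-section widths follow from the
lateral extrema of x(t), located exactly as real roots of the derivative
polynomial of each segment (Bernstein → monomial conversion, then
polynomial root finding).  Hip width is the maximum separation of the two
sides; waist width the minimum over the *interior* (the chest and thigh end
cross-sections are excluded, so an end edge never counts as the waist; if a
monotone side has no interior extremum the endpoints are admitted as a
fallback).  For rigid-synthesis torsos the measured value agrees with the
closed form 1 − D/W to ≈1e-12.  A feasibility margin requires
hip_width ≥ 2·lateral_range + 1 px so the two sides keep a visible waist
gap.  Top and bottom closure segments in exported SVGs are cosmetic and
never measured; the exported left-side path carries full-precision control
points so a re-imported stimulus re-measures to the manifest WHR within
1e-6.

## Regression models and comparison

All models are ordinary least squares on per-stimulus mean ratings
(n = 25 cells in the default design):

* WHR hypothesis:        A ~ poly(WHR, 2) + W
* curviness hypothesis:  A ~ poly(C, 2) + W
* interaction variants:  A ~ poly(X, 2) * W

`poly` is the centered, unit-norm orthogonal polynomial basis obtained by
QR decomposition of the raw power basis (the construction behind R's
`poly`).  The basis choice never changes fitted values, R², AIC or the
width coefficient (tested to 1e-10); it only decorrelates the polynomial
coefficients, which is why the linear and quadratic terms of one predictor
share a standard error.  A raw-basis option is provided for comparison.
With both sides of the quadratic expressed, dropping the linear term can
change R² drastically even when its coefficient is non-significant — the
classic suppressor pattern when WHR and width are correlated.

AIC uses the full Gaussian-likelihood convention
AIC = n·log(2π·RSS/n) + n + 2(k+1), counting the error variance as a
parameter (the convention of R's `AIC` on `lm` objects; statsmodels' OLS
AIC is exactly 2 lower).

The two hypotheses are non-nested, so they are compared by the
**augmented-prediction test**: refit the base (WHR) design with one extra
column holding the donor (curviness) model's fitted values and test that
single column with F on (1, n − p_base − 2) degrees of freedom.  If the
donor predictions are numerically collinear with the base design (e.g.
donor = base) the comparison is flagged degenerate instead of raising.
ΔAIC between the two additive models is reported alongside.

## Rating-side statistics

* **Cell means**: arithmetic mean per stimulus with grand mean and SD;
  every stimulus must have at least one rating.
* **Two-way fully-within ANOVA**: classical cell-mean decomposition; each
  effect is tested against its own subject-interaction error term.
  Greenhouse–Geisser ε̂ is computed per effect from the covariance of the
  effect's collapsed subject × level matrix projected through orthonormal
  contrasts (Kronecker product of the factor contrasts for the
  interaction); corrected dfs are ε̂·df.  Effect size is generalized eta
  squared with the error denominator pooled over all subject terms, the
  convention for fully-within designs.  Only the GG correction is offered.
* **Pairwise tests**: paired t between the first factor's levels within
  each level of the second, two-sided, Bonferroni-adjusted by the number of
  comparisons within the stratum (p_adj = min(1, m·p)).  The error term is
  per-pair (each t uses its own difference scores), not pooled.
* **ICC(C,k)**: two-way consistency, average of k raters,
  (MS_targets − MS_error)/MS_targets on the complete rater × stimulus
  matrix.
* **Pearson r** is reported with t = r√((n−2)/(1−r²)) on n−2 df; |r| = 1 is
  flagged (infinite t) rather than raised.

## Synthetic-data generator

The generator exists because real body contours traced from photographs are
not redistributable; it emulates their statistical structure, not their
anatomy.

**Contour family.**  Left-side contours are natural cubic splines x(y)
through five anchors — chest, bust, waist, hip, thigh at height fractions
(0, 0.10, 0.38, 0.64, 1.0) of a 300 px body — converted exactly to cubic
Bézier segments.  The waist indentation (px) is the single shape parameter
per level; chest/bust/thigh offsets are fixed fractions (0.70, 0.0, 0.50)
of it.  The default family has 5 levels with indentations geometrically
spaced from 52.5 px down to 8 px; after an exact horizontal rescale the
indentation *is* the lateral range, so the curviest level pairs with the
width series to give WHR 0.50–0.70.  Measured curviness runs ≈0.0122 down
to ≈0.0027 per px, strictly decreasing, the span between a tightly corseted
and a nearly straight outline.  The bust anchor matters: with a bust as
prominent as the hip the S-line turns through enough total angle to reach
realistic curvature at a 52.5 px lateral range, which a chest–waist–hip–
thigh spline alone cannot.

**Attractiveness surface.**  Every rater shares
baseline − penalty·(C − C*)² + slope·W (optional interaction term), clipped
to the 1–100 visual-analog scale.  Defaults: peak C* = 0.0064 (the middle
curviness level), penalty 7e5 rating·px², width slope −0.185 rating/px,
baseline 108 — chosen once so noise-free cell means span ≈20–69 with the
peak in the middle curviness column at every width.

**Rater panel.**  rating = surface + rater intercept + residual noise,
clipped to [1, 100] after noise (the scale is bounded; this is a deliberate
departure from a pure Gaussian model and slightly biases cells near the
bounds).  Defaults: 98 raters, intercept SD 8, residual SD 18, which puts
the panel's ICC(C,98) near 0.98.  Each rater draws from an independent
substream of the seed (`default_rng([seed, rater])`), so enlarging the
panel never changes existing raters' data, and replications extend the key
rather than shifting it.

**What passing tests do and do not show.**  The generator produces exactly
mirror-symmetric outlines, a perfectly factorial design, Gaussian noise and
a shared surface with homogeneous width slope.  Real rating data have
rater-specific surfaces, demographic structure, and contours whose
curviness profile is richer than a single scalar; recovery results here
validate the estimation machinery, not those assumptions.

## Problem sizes and numerical defaults

Quadrature n = 2048 (curviness), 4096-sample arc-length inversion for comb
placement and RMSD stations; polynomial root finding is exact to machine
precision for the degree-3 segments used throughout.  The
parameter-recovery study defaults to the full 98-rater panel and is run at
200 replications in the test suite (≈5 s); the AIC decision between the two
hypothesis models is insensitive to this count, with win rates at 1.0
throughout.  Degenerate inputs (zero-height contours, cusps, incomplete
rating matrices, rank-deficient designs, zero-variance correlations) raise
typed errors naming the offending object rather than returning NaNs.

## Known limitations

* Curviness is a single scalar; two contours with different curvature
  profiles can share it.
* The RMSD alignment (unit height, start-point translation, equal-height
  stations) is one of several defensible choices; it requires
  height-monotone curves.
* The interaction variants inherit strong collinearity from the width
  products (condition numbers ~1e4); they are reported with that
  diagnostic and are not the default comparison.
* Mixed-effects models, Huynh–Feldt correction and Bayesian comparison are
  out of scope.
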