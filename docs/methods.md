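# Methods

## Coordinate conventions

Traces are ordered base-first: the first point is the root–hypocotyl
junction, the last the root tip.  The internal frame is y-up with the
gravity direction **g** = (0, −1) by default, so downward displacement
is a single sign convention everywhere; image-style y-down exports are
flipped once at read time.  All internal coordinates are centimetres;
pixel-to-cm conversion happens only at the I/O boundary and always
requires an explicit scale factor (scanner resolution is never
assumed).  The horizontal unit vector is perp(**g**) = (−g_y, g_x), so
with the default gravity the horizontal growth index is signed with
rightward positive.

## Resampling and the curvature index

The per-root pipeline is fixed as: resample → raw curvature → moving
average → end trim → summaries.

**Resampling.**  The trace is parameterized by cumulative chord length
and each coordinate is fitted with a natural cubic smoothing spline
(Reinsch algorithm; a single penalty shared by both coordinates so the
fit commutes with rigid motions).  The fitted curve is evaluated on a
parameter grid ten times denser than the output, its cumulative arc
length is inverted, and the curve is re-evaluated at exactly uniform
arc-length targets: `round(L·density) + 1` dots, density 1,000 dots
cm⁻¹ by default, with `arc_pos` running from 0 to the measured total
length *L*.

**Click-noise model and penalty selection.**  Manually digitized dots
carry positional error, and unsigned curvature is not robust to it: an
interpolating spline through jittered dots acquires spurious
oscillation whose absolute turning angle does not average away (in
experiments with 0.002 cm isotropic jitter on 250 dots it inflates the
trimmed-mean CI of a gently waving root by an order of magnitude).  The
resampler therefore estimates the noise level from the trace itself:
third divided differences of the coordinates against the chord
parameter annihilate any locally quadratic signal, so their normalized
residual vectors reflect click noise, not root shape; a Rayleigh-median
(MAD-type) scale of those residual norms gives a robust isotropic SD
estimate σ̂ that is exactly invariant under rigid motions.  Noise along
the curve is absorbed into the chord parameter and under-counted, which
is harmless — only transverse noise creates spurious curvature.  The
spline penalty is then chosen by a discrepancy criterion: bisection on
a log scale until the fit's per-point residual RMS equals τ·σ̂·√2.
For noise-free traces σ̂ ≈ 0 and the fit reduces to plain cubic
interpolation, so analytic oracles (straight line → CI exactly 0;
circle of radius r → CI = 1/r) are reproduced without modification.

The discrepancy factor follows the derivative order of the quantity
being measured: curvature (a second-derivative functional) uses
τ = 1.5 — the plain discrepancy fit (τ = 1) tracks residual noise
closely enough to leave curvature bias, and Morozov-style safety
factors in [1, 2] are standard — while arc length and base-to-tip
geometry (first-order functionals) use τ = 1.0, where the upward length
bias of residual noise and the downward bias of smoothing approximately
cancel.  The pipeline therefore fits twice per root: the τ = 1.5 fit
feeds the curvature profile, the τ = 1.0 fit feeds L, the posture
indices and the tip angle.  Both fits are cheap (banded solves).

**Curvature.**  At interior dot *i* the raw CI is the unsigned turning
angle (radians) between chords (p_{i−1}→p_i) and (p_i→p_{i+1}) divided
by the mean of the two chord lengths, converging to |dθ/ds| with units
cm⁻¹; an `endpoint_chord` denominator (half the p_{i−1}→p_{i+1}
distance) is available and differs only at second order.  Endpoint dots
copy their neighbour's value and are always trimmed at defaults.
Curvature is unsigned throughout: the index measures bend magnitude.

**Smoothing and trimming.**  The moving average is an unweighted mean
over all dots within 0.005 cm of arc length on each side (11 dots at
default density; windows truncate at the ends; a zero window is the
identity).  The first and last 20 dots are then marked invalid.  The
order — smooth, then trim — means boundary-truncated windows only ever
affect dots that are about to be discarded.

**Summaries.**  The per-root mean CI is the 1%-trimmed mean of the
valid smoothed values: `floor(n·0.005)` lowest and highest values
dropped on each side (4 dots per side at the canonical 961 valid dots;
below 200 valid dots the trim count floors to zero and the statistic is
the plain mean).  The threshold count uses strict `>` (default
50 cm⁻¹).  Compartment means over [0, 0.5), [0.5, 1.0) and [1.0, ∞) cm
from the basal point are plain (untrimmed) means — trimming is a
whole-root procedure — and empty compartments are reported missing,
never zero.  The CI-versus-distance group curve is a LOWESS fit of the
pooled valid (arc position, CI) dots per group on a uniform grid; the
smoother family is a configurable stand-in (a penalized-spline variant
is provided) since no particular basis or penalty is canonical for this
display.

## Tip angles

The tip direction is the secant from the centerline point at arc
position L − w to the tip, with tip window w = 0.05 cm by default; the
angle is measured against the horizontal plane, positive toward
gravity, in (−180°, 180°].  The window is exposed because a manual
angle tool's effective window is unknowable; for synthetic roots with a
known terminal direction the secant recovers the construction angle to
well under 0.5° at default settings.  Group summaries use arithmetic
mean and sample SD (n − 1) on degrees — appropriate while angles stay
far from the ±180° wrap, as in these assays — with 20° classes anchored
at 0°, half-open [k·20°, (k+1)·20°), +180° falling in the last class.
A circular-statistics option is available but off by default.

## Group statistics

Kruskal–Wallis uses midranks and the standard tie correction, with a
χ²(k−1) p-value; an all-constant input returns H = 0, p = 1.  The
Steel–Dwass procedure re-ranks each pair jointly, computes the
tie-corrected standardized Wilcoxon statistic, and refers √2·|Z| to the
studentized-range distribution with k groups and infinite degrees of
freedom (asymptotic variant; exact and permutation variants are out of
scope).  For k = 2 this reduces to the two-sided tie-corrected normal
approximation of the rank-sum test.  The Brunner–Munzel test estimates
the relative effect P(X<Y) + ½P(X=Y) with the small-sample t
approximation (Satterthwaite degrees of freedom); when the rank
variance degenerates the result is flagged: all values tied gives
p = 1, complete separation gives p → 0.  Bonferroni corrections are
plain multiplication with a recorded family size, and the family-wise
threshold helper returns α/m.  Compact letters use insert-and-absorb:
groups share a letter iff their pairwise p ≥ α, with the minimal letter
set after absorption.

## Synthetic roots

The generator grows roots along gravity with a lateral sinusoid
x(t) = A·sin(2πt/λ) (optionally plus a second, shorter wave), giving
closed-form curvature |x″|/(1+x′²)^{3/2} and arc length by quadrature
of the analytic speed (absolute tolerance well below 1e−8 cm, so
recovery tolerances are meaningful).  Archetypes encode the contrast
between large gradual waves (A = 0.05 cm, λ = 0.5 cm; peak CI
≈ 7.9 cm⁻¹) and small sharp waves (A = 0.02 cm, λ = 0.15 cm; peak CI
≈ 35 cm⁻¹), plus a straight control and a mixed two-wave shape.  An
optional terminal bend turns the tangent to a prescribed tip angle
along a 0.05 cm-radius arc followed by a 0.1 cm straight tip, all with
exact piecewise geometry.

The digitizer emulates manual dot marking: 100–450 dots per root
(default 250), approximately uniform in arc length with a ±20% spacing
jitter, plus isotropic Gaussian positional noise (default SD 0.002 cm,
roughly two pixels at a typical scan resolution — manual clicking error
has no published magnitude, so this is a characterized free parameter,
not a fitted one).  All randomness is seeded and reproducible.  Cohorts
add per-root lognormal amplitude factors (CV 0.1) for within-group
spread; `contrast_cohorts` builds the matched pair used in the contrast
experiment: two groups with identical slope profiles (hence identical
per-root analytic SI, using the same factor sequence in both groups)
but wavelengths differing 4×, scaling mean curvature by exactly 4 and
pushing the sharp group's peaks past the 50 cm⁻¹ threshold.  The
matched (paired) factor design is deliberate: it makes "SI does not
separate the groups" a property of the construction rather than a
seed-dependent coin flip.

What the generator does *not* emulate: root thickness and image
segmentation, curvature drift with growth, spatially correlated
clicking error, or operator-dependent dot density.  Passing recovery
tests therefore validates the geometry pipeline under a plausible noise
model, not the manual tracing step itself.

## Measured behaviour of the defaults

At default parameters, in the package's own test suite: noise-free
450-dot digitizations of every archetype recover analytic SI within
0.5% and the trimmed-mean CI within 5%; with 0.002 cm jitter on 250
dots the gradual-wave mean CI is recovered within 15% (mean over 50
replicates; in practice within a few percent).  The mixed archetype's
short ripple component is partially absorbed by the noise-adaptive
smoothing under the same jitter (its mean CI reads ~13% low on
average), a known cost of suppressing click noise at wavelengths
approaching the dot spacing; denser marking recovers it.  Circle arcs
at radii 0.05–1.0 cm reproduce mean CI within 2% (well within 0.2% in
practice); pointwise accuracy of the curvature operator itself is ~1%
on analytically spaced circles, while the resampler's natural-spline
boundary makes the few dots nearest the trim margin less accurate — the
20-dot trim exists precisely to discard the unreliable ends.

## Problem sizes

The contrast experiment uses 30 roots per group digitized at 450 dots —
the top of the manual-marking range, appropriate for waves at
λ = 0.125 cm where 250 dots would leave only ~11 dots per period —
and the recovery experiment uses 50 replicates at 250 dots.  Both run
in seconds; the per-root pipeline (two spline fits plus curvature) runs
in ~10 ms at default density.

## Known limitations

* 2D centerlines only; signed curvature and 3D are out of scope.
* The noise estimate assumes uncorrelated, approximately isotropic
  click error; smooth systematic tracing bias (e.g. consistently
  cutting corners) is indistinguishable from root shape.
* The asymptotic Steel–Dwass p-values are anti-conservative for very
  small groups (n < ~5 per group).
* The CI-versus-distance smoother is a display aid, not an inferential
  model.
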