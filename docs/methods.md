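# Methods

This note documents the models, the synthetic-data generator, the
numerical choices and the known limitations of `phenoseason`.

## The size variable and trajectory splitting

A shoot's three measured dimensions (upper width w_u, lower width w_l,
vegetative length L, all cm) are combined as a conical frustum,
V = πL/12 · (w_u² + w_u w_l + w_l²), and plant size is V^(1/3).  The
frustum was chosen because it uses all three measurements symmetrically
and interpolates between the cylinder (equal widths) and cone (one width
zero) limits; the volume formula is a pluggable argument of
`trajectory.compute_size`, so an ellipsoid or other solid can be swapped
in without touching the rest of the pipeline.

Each shoot's seasonal trajectory is split into growing and declining
parts at the maximum of a cubic smoothing spline fitted to (day, size).
The roughness penalty is selected by generalized cross-validation
(`scipy.interpolate.make_smoothing_spline`); an explicit penalty can be
given instead.  The argmax is located on a 0.1-day grid with ties broken
toward the earliest day.  Points with day ≤ split form the growth
partition and day ≥ split the decline partition; a measured point within
half a grid step of the split belongs to both and is flagged
(`shared_peak_point`).  Days are integer day-of-year with January 1 = 1
and run continuously past 365 for measurements taken the following
January.

## Spring growth: mixed-effects logistic

For one species, all shoots' growth-phase points are fitted jointly with

x_ij = A + (K + u_Ki − A) / (1 + exp(−b (t_ij − a))) + ε_ij,

ε ~ N(0, σ²), u ~ N(0, τ²) at the shoot level.  K is always random
(shoots genuinely differ in final size); candidates add at most one
further random parameter (A, a or b) to avoid overfitting seven shoots,
and A is either estimated or pinned to zero.  The marginal likelihood is
evaluated by a Laplace approximation with a Gauss–Newton Hessian; for
random effects that enter linearly (A, K) this is exact, so the
work-horse K-only model is fitted by an exact marginal Gaussian
likelihood.  The outer optimization (L-BFGS-B on fixed effects and log
variance components, objective tolerance 1e−10) starts from a coarse
(a, b) grid search by pooled fixed-effects residual sum of squares, with
the shoot split-day median among the grid's inflection candidates; on
failure the starts are jittered (±50 % multiplicative, ±30 d on a) up to
a configurable restart cap (default 5).  Estimates are constrained to
plausible boxes (a within the observed day range ± 60 d, b ∈ (1e−4, 5),
K ∈ (0, 10× max size)); a fit pinned to a fixed-effect bound counts as
non-converged.  The structure with the lowest AIC = −2ℓ + 2k wins, k
counting fixed effects, σ and every τ.

Derived spring phenology: peak day = a (plus the mean of the shoot modes
if a is random), log_b = ln b (natural log; the growth process is
multiplicative), season start = a − ln 3/b (the 25 % crossing of the
logistic, independent of A).  A is excluded from downstream analysis.

## Senescence: spar-parameterised splines and the averaged profile

Each shoot's decline is smoothed with a cubic B-spline with knots at all
data points on the abscissa rescaled to [0, 1], minimizing
Σ(y − g)² + λ ∫ g″², with λ set on the conventional `spar` scale
(λ = r · 256^(3·spar−1), r the interior-diagonal trace ratio of the
basis cross-product and roughness matrices).  At spar = 0.5 (the
default) the fitted values agree with R's
`stats::smooth.spline(all.knots = TRUE)` to ~1e−4 of the data range; a
frozen R-oracle fixture in the test suite pins this equivalence.  Fewer
than four decline points fall back to linear interpolation with a
warning.

Per-shoot splines are evaluated on a common daily grid, normalized by
the maximum of that shoot's own decline spline (so the normalizer and
the crossings come from the same smoothed prediction), and averaged over
the shoots defined at each grid day; shorter shoots are dropped from the
average outside their span rather than extrapolated.  Crossings are
interpolated linearly between grid days to 0.1-day resolution:
senescence date = first 50 % crossing, pace = 1/(first 5 % − last 95 %),
shape = ln(C/D) with C = t(5 %) − t(50 %) and D = t(50 %) − t(95 %),
season end = first 25 % crossing.  The shape convention follows the
printed formula (late over early duration); a negative shape therefore
means senescence accelerates.  Because the printed convention and its
verbal gloss can be read oppositely, `shape_late_over_early=False`
flips the ratio.  A species whose profile never falls below 25 %
overwinters: season end is undefined and season length is assigned
365 d.  A missing 50 % crossing makes the species ineligible for the
senescence parameters (it is reported and excluded, with the exclusion
reason carried in the records table).

### Known bias of the spar = 0.5 spline at biweekly cadence

With a 14-day cadence and a decline whose 95 %→5 % span is ~5 sampling
intervals (steepness s ≈ 0.08/d), the spar = 0.5 penalty is strong
enough to spread the sigmoid's shoulders: on an exact noiseless sigmoid
the 95 % crossing moves ~8 d early and the 5 % crossing ~8 d late
(−17 % pace), identically in R's `smooth.spline`.  Averaging several
noisy shoot splines flattens the profile further, giving a median
relative pace error of ~20 % at the default study conditions, and a
season-end shift of ~+4–5 d.  The date-type parameters (50 % and 25 %
crossings) are much less affected (≤ ~1.5 d and ~4–5 d respectively),
and at daily sampling all parameters are recovered within 1 day / 1 %.
The pace-recovery test at biweekly cadence therefore fails its ≤ 10 %
target; the failure is a property of the prescribed smoothing procedure
at this cadence, not of the implementation, and is deliberately left
visible rather than compensated (e.g. by debiasing or by softening the
generator's steepness).

## Season length

season length = season end − season start, computed per species after a
keyed join of the spring and autumn tables; overwintering species get
365 d and the length is capped at 365.  The self-consistency regression
(z-scored season length on the five z-scored phenological variables,
OLS with t-based 95 % CIs) reproduces the structure that season length
is almost fully determined by the phenology vector (R² > 0.99 on
synthetic records); highly collinear predictor sets trigger a warning
and a pseudo-inverse fit.

## Multimodel inference

All predictor subsets (including intercept-only) are fitted by OLS on
z-scored variables — exhaustive enumeration, feasible for ≤ 12
predictors — and ranked by AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1), with k
counting slopes, intercept and residual variance.  Akaike weights are
renormalized inside the Δ < 3 window of the best model.  Averaging is
conditional: a predictor's estimate is the weighted mean over the window
models that contain it, and its importance is the summed window weight
of those models.  Confidence intervals are combined by weighting the
per-model 95 % CI endpoints; this is one of several published
conventions (model-averaged standard errors are another) and is recorded
in the output metadata.  Covariate conventions applied at load time:
non-clonal species receive the conventional 0.5 cm/yr lateral spread,
and height and lateral spread are natural-log transformed.

PCA operates on the correlation matrix of complete rows; supplementary
variables are projected passively as their correlation with the axis
scores (for an active variable this equals √λ times its loading, which
the tests verify).  SMA regression uses slope = sign(r)·sd(y)/sd(x) with
the correlation-test p-value.

## Piecewise SEM

Endogenous nodes are regressed (OLS, z-scored) on their DAG parents;
standardized partial slopes are the path coefficients.  The d-sep basis
set contains every non-adjacent ordered pair not linked by a correlated
error, conditioned on the parents of the later variable in the causal
order (layer order, ties alphabetical); each claim is tested by the
t-test of the upstream variable added to the downstream parent
regression.  Fisher's C = −2Σ ln p is χ² with 2k df; a numerically zero
claim p-value is reported as a failure naming the claim rather than an
infinite statistic.  Two whole-model AICs are reported side by side: the
sum of component-regression AICs (which drives pruning) and the
C-statistic variant C + 2K.  Refinement adds, per iteration, the
smallest-p significant claim as a directed edge (cross-layer) or
correlated error (same layer), prunes non-protected edges whose removal
lowers the summed AIC, and stops when no claim is significant and the
global p exceeds 0.2 (cap 20 iterations, flagged if hit).

With k true-null claims and α = 0.05 the probability of a refinement run
adding nothing is 0.95^k, so a "adds nothing under the true model in
≥ 90 % of runs" calibration is only meaningful for small basis sets; the
type-I study therefore uses the minimal chain X→M→Y (one claim), for
which the global p is exactly the claim p and exactly uniform.  Larger
graphs are exercised by the power study (an omitted direct path of
standardized strength 0.5 must be the first addition) and the
sign-agreement study (paths fitted on the generator's own cascade at
n = 200 species).

## The synthetic-data generator

The generator emulates the garden protocol: 7 shoots per species,
biweekly sampling from day 7, one 365-day season.  Each species draws
niche scores (independent N(5, 1.5²) clamped to [1, 9], an
indicator-value scale), traits as linear maps of centred niche plus
Gaussian noise (baselines: height 40 cm, lateral spread 2 cm/yr, SLA
20 mm²/mg, LDMC 200 mg/g; species below 1 cm/yr are treated as
non-clonal), and curve parameters as linear maps of (niche, traits) plus
noise, clamped to admissible ranges: growth inflection a (baseline day
120), rate b (0.12/d), final size K (20 cm), senescence midpoint m (day
260, kept ≥ a + 40), steepness s (0.08/d), asymmetry θ (baseline 1,
clamped to [0.3, 3]).  The default path matrices encode a moderate,
sign-definite cascade (e.g. light delays the senescence midpoint, taller
species peak later) used by the sign-agreement study.

The true trajectory is the logistic growth phase joined at its
intersection with the Richards decline K_i·(1 + e^{s(t−m)})^{−θ}; the
piecewise join keeps each phase's crossing days exactly those of its own
sigmoid, i.e. t_q = m + ln(q^{−1/θ} − 1)/s, making recovery tests
analytic.  Shoot-level K_i are lognormal around K_true (CV 0.2);
measurement noise is multiplicative lognormal per dimension (default CV
0.05), chosen because sizes are strictly positive and errors scale with
magnitude — the field protocol states no error model, so this is the
package's convention.  The rendered triplet inverts the frustum formula
(length = 3·size, equal widths), so with zero noise the size round trip
is exact to 1e−9.

What the generator does not emulate: weather forcing and interannual
variation, spatial garden structure, missed measurement dates,
observer-specific error, and within-season regrowth after damage.
Passing recovery tests therefore demonstrate correctness of the
estimation machinery under the stated error model, not robustness to
every feature of real field data.

## Problem sizes and seeds

Simulation studies are sized to run comfortably on one CPU: parameter
recovery uses 20 species at the default conditions (~3 min, dominated by
the 7-candidate mixed-model fits); the noiseless round trip uses 3
species at daily cadence; SEM type-I/power use 100 replicates at n = 200
and the sign study 50 replicates; model-averaging studies use 100
replicates of 32-model subsets.  Unit tests use smaller replicate counts
of the same experiments.  All randomness flows through explicit integer
seeds; identical seeds reproduce byte-identical artifacts, and
`scripts/acceptance.py --seed` drives every stream.
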