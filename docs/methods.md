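# Methods

## Coordinate model

All distances are Euclidean in *work coordinates*. Horizontal position is
the spherical Miller cylindrical projection evaluated in radians with no
Earth-radius multiplier — x = λ, y = (5/4)·ln tan(π/4 + 2φ/5) — so
horizontal coordinates are order-1 and one degree of longitude is
≈ 0.01745 work units. Depth (metres, positive down, surface = 0) is
divided by 1000. The pair of conventions is deliberate: shelf-sea Chl-a
varies two to four orders of magnitude faster per metre of depth than per
metre of horizontal distance, and radian-scale horizontal axes together
with the /1000 vertical rescale bring the per-axis change rates to a
comparable magnitude, which is what makes an isotropic 3D interpolant
behave sensibly on such data. Both constants are frozen configuration
(`vertical_divisor`, default 1000); no per-dataset anisotropy estimation
is attempted. A spherical (not ellipsoidal) projection is used — datum
differences are far below interpolation error at basin scale.

## RBF interpolant

Concentrations are log10-transformed before fitting (they span > 2
decades; multiplicative structure) and back-transformed on output, with
errors always evaluated on the back-transformed μg/L scale. The
interpolant adds a degree-1 polynomial tail to the radial sum and imposes
the orthogonality conditions Pᵀβ = 0, giving the (n+4)×(n+4) symmetric
block system shown in the README. Consequences used by the tests:

* exact interpolation at stations for any kernel;
* exact reproduction of fields affine in (x, y, z′) of log-concentration
  (β = 0, λ equal to the generating coefficients) — which also covers
  constant fields;
* the matrix diagonal is φ(0) (0 for the linear kernel, 1 for
  gaussian/multiquadric), keeping fitting and evaluation consistent.

The system is solved by a dense direct symmetric solve: n is at most a
few hundred stations per survey, so O(n³) is milliseconds and no
compact-support or iterative machinery is warranted. The condition number
is computed per fit and a warning is emitted above 10¹²; if the solve
fails outright a least-squares fallback is used (logged). Back-transform
exponents are clamped to ±300 so that ill-conditioned extrapolations stay
positive finite rather than under/overflowing. The shape constant
defaults to ε = 0.1 and is interpreted in work units — the only units in
which distances exist after the transform. Over a Bohai-sized domain
(≈ 0.1 work units across) gaussian and multiquadric kernels at ε = 0.1
have near-flat kernel matrices and condition numbers ~10¹⁹; their poor
cross-validation scores in the standard scenario are a real property of
that kernel/scale combination, not a solver defect, and the linear kernel
(which has no shape constant) is the robust default.

Duplicate station coordinates make the system singular; they are averaged
before fitting — on the log scale for the RBF path, raw for IDW — with
the merge count logged. Nonpositive concentrations are rejected (log10
undefined); users with detection-limit-censored data can opt into a
configurable floor (default 0.01 μg/L) at read time instead.

## IDW

Eq-of-motion: D̃(q) = Σ C_i d_i^{−α} / Σ d_i^{−α}, α = 3. IDW operates on
raw concentrations by default — the weighting formula is written in
concentration space — with a log-space variant behind a switch. The d = 0
singularity is resolved by snapping to the observation when a query is
within 10⁻¹² work units of a station, the limit of the formula. Outputs
are convex combinations, hence bounded by the observed range; the RBF has
no such bound (documented, not asserted).

## Cross-validation

Records are permuted once per run with a seeded generator; fold k
(k = 1..10) is every 10th record of that order starting at position k, so
fold sizes differ by at most one. Every method is fitted on the 9/10
complement and scored on the held-out tenth with the *same* plan — a
paired comparison. Reported per fold and method: MAE and MRE on μg/L;
pooled across folds: Pearson r between log10 estimates and log10
observations plus the OLS slope/intercept of log-estimate on
log-observation (slope near 1 indicates an unflattened estimator).
Fold-level box summaries (median, quartiles, extremes, mean) support the
usual box-plot comparison. The correlation is defined on log values
because concentration scatter is only interpretable on that scale; a
printed formula that mixes the logarithm into centred deviations does not
define a valid statistic and was read as ordinary Pearson-on-logs.

## Indicators

Cell areas come from the spherical quadrilateral formula
R²·Δλ·(sin φ_n − sin φ_s) with grid nodes at cell centres, so cells tile
the domain exactly and integrated totals are stable under grid refinement
(< 2 % on smooth fields when halving the step; verified). The integrated
total is the per-layer areal integral (μg·L⁻¹·km²) — no multiplication by
layer thickness, so values are comparable across layers of different
nominal thickness; a per-volume variant is a documented extension, off by
default. The bloom criterion is strict (> 10 μg/L). The mean-method total
(station mean × region area) systematically exceeds the integrated total
on right-skewed, coastally-oversampled surveys, because the station mean
is dominated by the high coastal tail; the package computes both so the
bias is visible. Sub-region boxes for BHB/LDB/LZB/CBS are illustrative
rectangles (no authoritative delimitation exists in the public record)
and are replaceable by GeoJSON polygons; all quantitative tests use
synthetic rectangular regions.

## Synthetic data

The generator produces what the pipeline needs to be testable without
restricted survey data, not hydrodynamic realism. The truth field is
log10-additive: baseline −0.5 (≈ 0.32 μg/L), coastal enhancement 1.2
decades decaying over 0.35° from the domain boundary (a stand-in for a
real coastline, keeping the module dependency-free), three estuary-like
Gaussian hotspots of 1.0 decade and 0.25° radius placed nearshore, and a
linear-in-depth decay of one decade per 25 m. Under these defaults
station concentrations span > 2 decades and vertical finite-difference
change rates exceed horizontal ones by ≫ 100× per metre — the anisotropy
regime the coordinate model targets. Surveys default to 368 surface
(< 2 m), 99 middle (~10 m) and 13 bottom (> 15 m) stations — a typical
August survey profile, with the bottom layer deliberately sparse to
exercise the small-n regime — drawn with a coastal density bias
(acceptance-probability floor 0.15 offshore), and observation noise is
multiplicative lognormal with σ = 0.1 on log10 (≈ 26 % relative), the
matching error model for a variable fitted in logs. Everything is
deterministic given (spec, seed).

What passing tests on this generator do **not** show: performance under
real coastline geometry and land masking, tidal/seasonal structure,
spatially correlated measurement error, or preferential sampling aligned
with the bloom itself. Conclusions about method *ordering* (linear kernel
vs ε = 0.1 gaussian/multiquadric) are scenario-dependent and documented
as such.

## Problem sizes and numerical choices

The standard scenario is 480 stations cross-validated ten-fold for four
methods (40 dense solves of ≤ 436+4 equations, ~seconds); indicator grids
use 0.1–0.2° resolution; the recovery experiment uses 100/200/400
stations × 5 seeds on a 0.25° audit grid. These sizes give stable
statistics while keeping the full suite fast. Other choices: duplicate
detection is exact coordinate equality (work coordinates are deterministic
functions of the inputs); region membership is cell-centre point-in-box /
point-in-polygon; fold seeds, sampling seeds and scenario seeds are all
independent `numpy` `default_rng` streams keyed by the user-supplied seed.

## Known limitations

* No uncertainty quantification — the RBF gives a point estimate only.
* No kriging implementation; the cross-validation harness accepts any
  fit/predict object, so an external kriging baseline can be compared,
  but none is shipped.
* The ±300 exponent clamp means a pathologically ill-conditioned fit
  returns astronomically large but finite concentrations; condition
  warnings are the intended signal.
* Regional indicator accuracy inherits the grid resolution and the
  illustrative region boundaries; real assessments must supply surveyed
  polygons.
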