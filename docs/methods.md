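# Methods

## The estimation problem

Subadult stature estimation regresses standing height *y* (cm) on a single
long-bone measurement *x* (mm) in a pooled-sex reference sample aged 0–20
years. Because growth is fast in infancy and decelerates through
adolescence, the length–stature relation is close to linear over much of
its range but curved at the extremes; breadth–stature relations are
distinctly sigmoidal. Three families are therefore fitted per measurement:

- linear, *y = ax + b* (2 parameters);
- asymptotic exponential, *y = a − b·e^(−cx)* (3 parameters; saturating,
  used for lengths);
- three-parameter logistic, *y = a/(1 + b·e^(−cx))* (3 parameters;
  sigmoid, used for breadths).

Twenty measurements are admissible: 18 single-bone ones (the per-bone grid
excludes ulna proximal/distal breadth, femur proximal breadth, and all
fibula breadths) plus two composites, upper limb length (humerus + radius)
and lower limb length (femur + tibia). The attempted model grid is
20 × 2 = 40; the embedded registry carries the 38 published fits (the
nonlinear fits for radius and tibia distal breadth did not converge in the
source analysis and have no published coefficients).

## Units

Inputs are millimetres, outputs centimetres. The printed slopes (≈0.46 cm
stature per unit humerus length) are dimensionally consistent only with mm
inputs, matching standard osteometric practice; record validation enforces
plausible mm/cm ranges (0–700 mm per single bone, doubled for composites;
stature 30–230 cm).

## The published-model registry

Coefficients are stored digit-for-digit as printed (≈3 significant
figures) in a JSON asset whose SHA-256 is verified at load; registry
predictions are defined by the printed values, never by refits. One printed
linear equation lacks its *x* (femur length, "0.309+32.2"); it is read as
slope 0.309, intercept 32.2, which is consistent with its nonlinear
counterpart at adult femur length.

Two printed logistic rate constants (tibia midshaft c=0.017, radius
proximal c=0.021) are an order of magnitude below every sibling model and
produce implausible predictions at typical adult measurements. A registry
sanity check evaluates every entry at a typical adult value of its
measurement and flags entries predicting outside [140, 200] cm; exactly
these two entries are flagged. Flagged models still produce estimates —
forensic users must see every number — but each carries an explicit
warning. Whether those constants are typographic (0.17/0.21 would match
siblings) cannot be resolved from the printed tables; they are flagged,
not corrected.

## Fitting

Linear models are closed-form OLS via the normal equations; the fitted
object stores x̄ and Sxx for exact prediction intervals. Nonlinear models
minimise Σ(yᵢ − f(xᵢ; θ))² with scipy's trust-region reflective
least-squares solver and the analytic Jacobian (xtol/ftol 1e-10, gtol
1e-8, ≤600 residual evaluations). Starting values come from
linearization: with a provisional asymptote a₀ = 1.05·max(y), regress
ln(a₀ − y) on x (asymptotic exponential) or logit(y/a₀) on x (logistic)
to get b₀ and c₀. If the solver fails from that start, a small multi-start
over a₀ inflation factors (1.2, 1.5, 2.0) is tried and the best objective
kept. Non-convergence is reported as a flag on the result, never raised:
the fitted set simply marks the model unusable, mirroring how a real
analysis records failed fits.

Residual SD is √(SSE/(n−p)); the nonlinear parameter covariance is the
delta-method s²·(JᵀJ)⁻¹ at the solution (symmetrised; a singular JᵀJ marks
the covariance unavailable and disables intervals). Wald-t p-values per
coefficient are computed for reporting only. Fits are unweighted; no
heteroscedasticity modelling or robust loss is attempted.

`fit_all` attempts the full 40-cell grid, complete-case per measurement
(per-model sample sizes legitimately differ), and skips a measurement with
fewer than 20 complete pairs.

## Prediction intervals

For a new individual at x₀:

- linear: ŷ ± t_{n−2, 1−α/2} · s · √(1 + 1/n + (x₀−x̄)²/Sxx) (exact under
  the Gaussian model);
- nonlinear: ŷ ± t_{n−p, 1−α/2} · √(s² + g(x₀)ᵀ Ĉ g(x₀)) with g the
  parameter gradient and Ĉ = s²(JᵀJ)⁻¹ — the first-order delta method,
  standard practice for nonlinear regression; a residual-bootstrap
  percentile interval (refit per replicate, new-error draw added) is
  available as an opt-in cross-check and agrees with the delta interval
  within a few percent on well-specified data;
- registry models: the published tables print s but not n, x̄/Sxx or the
  covariance, so a full interval is impossible from the printed values
  alone. Registry intervals use ŷ ± z_{1−α/2}·s, documented as approximate
  and slightly anti-conservative (it omits the parameter-uncertainty term
  and the t correction); every such result carries a warning.

Predictions beyond the training range ±10% of its span are warned, never
refused. Reported points and bounds are rounded to 0.1 cm in case reports
and CSVs; the library keeps full precision.

## Validation battery

All metrics are computed on the hold-out set (default 80/20 split, seeded,
sizes round(n·0.8) and the remainder):

- **test accuracy**: percent of hold-out individuals whose known stature
  falls inside the 95% PI (reported to 0.1);
- **MAD**: mean |predicted − known|, on point estimates;
- **two-sample KS**: D and asymptotic p comparing known vs predicted
  stature distributions (scipy's ks_2samp; exact p is unnecessary at the
  sample sizes involved);
- **Kendall's τ-b** between measurement and stature (tie-corrected, since
  mm-resolution measurements tie);
- **Bland–Altman**: bias = mean(predicted − known) and limits
  bias ± 1.96·sd (sample sd, n−1) — the standard limits-of-agreement
  construct;
- **misclassification cross-tab**: per (family × measurement-type) cell,
  the percent of all predictions that were misclassifications and the
  percent among misclassifications only, with marginal totals and the
  count of individuals with ≥1 miss. The percent-of-all cells sum to the
  overall rate; the percent-of-missed cells sum to 100.

## The synthetic cohort generator

The generator provides data with the statistical structure the estimators
assume — it is the test bench, not a portrait of any real collection.

- **Ages** are integers 0–20 drawn with the published pooled-sample
  weights (24.3% at age 0, thin coverage at 6–14, a heavy late-teen arm).
- **Median stature** follows a monotone piecewise-linear curve through the
  anchors (0, 50), (1, 75), (2, 87), (5, 110), (10, 138), (14, 160),
  (18, 170), (20, 171) cm — the simplest shape preserving the
  infancy-steep / adolescence-flattening pattern the method's argument
  depends on. A parametric growth model would add parameters without
  adding testable structure; the anchors are configuration, not constants.
- **Stature noise** is additive Gaussian with SD 2 + 0.25·age cm
  (heteroscedasticity grows with age, as in real growth data), truncated
  to statures above 45 cm.
- **Measurements** are generated by inverting each measurement's
  generative stature model at the individual's stature (clamped 0.5 cm
  inside the model's attainable range) and applying multiplicative
  Gaussian noise (relative SD 0.02). Generative defaults are the published
  nonlinear coefficients, with four synthetic substitutions: the two
  sanity-flagged rate constants are restored to family scale (0.17, 0.21),
  and the two grid cells with no published nonlinear model (radius/tibia
  distal breadth) get family-plausible synthetic logistic curves. These
  are modelling choices for the generator only, never corrections to the
  registry.
- **Sex** is assigned F/M at 40.5/59.5% but is metadata only: generation
  is pooled-sex, matching the estimators.
- Identical config + seed ⇒ byte-identical cohorts.

What passing tests on this generator do show: the fitting machinery
recovers known parameters, the intervals achieve nominal coverage under a
correctly specified model, and the whole pipeline holds ≥90% per-model
hold-out accuracy on well-specified data. What they do not show: behaviour
under real-data features the generator omits — between-measurement
covariance beyond the shared stature signal, secular trends,
diaphyseal-vs-maximum measurement mixtures, and model misspecification.

## Numerical choices

- Exponentials are computed with the argument clamped at 700 to prevent
  overflow; underflow quietly reaches 0 (no subnormal propagation).
- x = 0 is admitted in model evaluation as the curve's boundary value;
  negative or non-finite x errors. Record-level measurements must be
  strictly positive.
- Model inversion is closed-form per family and errors outside the open
  attainable interval, naming the admissible range.
- The evaluate/invert round trip is exact to <1e-9 cm; analytic gradients
  match central finite differences to ~1e-5 relative.
- Ties in the split permutation and all simulation draws flow from a
  single numpy Generator per operation, seeded explicitly.

## Problem sizes in tests

The default test suite exercises the pipeline at cohort n=1000 (hold-out
200), coverage checks at n_train=500 / n_test=2000, and 200-replicate
parameter-recovery simulations — sizes at which the binomial tolerance on
a 95% coverage estimate is ±1 to ±1.5 points, so the nominal-coverage
band [93.5, 96.5] is a meaningful check rather than noise.

## Known limitations

- No sex-specific models: the registry and the pipeline are pooled-sex.
- No combination of multiple measurements into one pooled interval;
  conflicting per-bone estimates are all reported, ranked by precision.
- Registry intervals are approximate (see above); exact intervals require
  refitting on a reference sample.
- The delta-method interval is first-order; strongly curved posteriors at
  small n would need the bootstrap alternative.
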