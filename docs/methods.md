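# Methods

`fermkin` models the quantitative side of a controlled lactic-acid
fermentation of a cereal (pearl millet) slurry: how fast the matrix
acidifies, how the microbial populations grow, and how starter-culture
dosing shifts the finished beverage's pH, titratable acidity and
viscosity. This note records the models, their assumptions, the
numerical choices, and what the synthetic-data generators do and do not
emulate.

## Acidification kinetics

pH and total titratable acidity (TTA, % lactic acid) are fitted with the
three-parameter exponential

    y(t) = a − b·exp(−c·t)

where `a` is the horizontal asymptote (the value the variable plateaus
at), `b = a − y(0)`, and `c` (h⁻¹) is the first-order rate constant.
For pH, which falls toward its asymptote, `b` is negative; for TTA,
which rises, `b` is positive. The model is empirical — it summarises
the joint effect of acid production and buffering without mechanistic
claims. Goodness of fit is R² = 1 − RSS/CSS on the fitted points, which
may be negative for a bad model.

TTA itself is derived from an NaOH titration:
TTA% = (mL NaOH × M NaOH × 90.08) / (mL sample × 1000) × 100, with
90.08 mg the milligram-equivalent factor of lactic acid.

**Fitting.** Nonlinear least squares (scipy trust-region with the rate
bounded positive), initialised at a₀ = last observation,
b₀ = a₀ − first observation, c₀ = 0.1 h⁻¹, plus 20 deterministic
restarts with the rate jittered log-uniformly over [10⁻³, 10⁰·⁵];
the converged solution with the lowest RSS wins. Tolerances are
xtol = ftol = 1e−10. Standard errors come from the Jacobian-based local
linearisation at the optimum scaled by the residual variance. Fitting
uses the per-time cell means by default; tied (replicate-level) times
are accepted, and for balanced replication the point estimates are
identical to the fit on means (the objective scales by a constant).
No SD weighting is applied by default.

Soluble glucose follows an empirical quadratic in time,
`glucose(t) = c0 + c1·t + c2·t²`, fitted by OLS: amylolysis releases
glucose faster than the bacteria consume it early on, and the quadratic
term captures the late flattening/decline.

## Growth curves

Plate counts (log₁₀ CFU/mL) follow the Zwietering-style modified
Gompertz curve

    log10 N(t) = K + A·exp(−exp(μmax·e·(λ−t)/A + 1))

with K the initial level, A the total rise to the stationary density,
μmax the maximum slope (Δlog₁₀/h) and λ the lag time (h). Closed-form
anchors used as test oracles: the value at t = λ is exactly
K + A·e^(−e), and the curve rises monotonically from just above K to the
asymptote K + A. Fit quality is the mean relative deviation modulus
E% = (100/n)·Σ|O − P|/O, the food-engineering convention (≲10% is
usually read as adequate).

**Fitting.** Bounded nonlinear least squares (A > 0, μmax ≥ 0, λ ≥ 0),
initialised from the data: K₀ = first observation, A₀ = observed rise,
μmax₀ = steepest secant slope, λ₀ = the tangent-intercept construction
clipped at zero, with 20 deterministic jittered restarts. λ is
constrained non-negative rather than allowed to go negative.
Monotone-decreasing inputs collapse to the A lower bound and warn. The
inner double-exponent is clipped at 700 to avoid overflow during
optimisation (above that the curve already evaluates to K exactly).

**Identifiability.** With 3-h sampling, μmax and λ are only well
determined when the exponential phase spans several sampling intervals
(rise duration ≈ A/μmax ≫ 3 h). The seeded recovery suite therefore
uses a truth with A/μmax = 10 h and replicate noise of 0.02 log; at
noise 0.05 log the same design recovers K and A to ~1% but μmax and λ
only to ~15–25%, which is a property of the sampling design, not of the
optimiser.

## Plateau ("optimum fermentation time") detection

The plateau time of a variable is the earliest sampling time after
which no consecutive pair of time points differs significantly, where
each pair is compared with a two-sided Welch test reconstructed from the
stored mean, SD and replicate count (n = 3 by default). If both SDs are
zero the test degenerates to an equality check. This is a deliberately
simple stand-in for multiple-range testing on raw replicates, which
summary tables cannot support; with n = 3 it is conservative
(underpowered), and on the bundled time course it places the pH plateau
at 12 h and the TTA plateau at 21 h, bracketing the conventional 18-h
harvest point.

## Factorial starter-culture model

The 2³ + center inoculum design (three cultures, each at 0.05 or
0.10 % w/w, center at 0.075 %) is analysed with the identity-link
Gaussian model

    Y = β0 + β1X1 + β2X2 + β3X3 + β12X1X2 + β13X1X3 + β23X2X3 (+ β123X1X2X3)

in **natural concentration units**, not the coded ±1 convention — the
interaction coefficients then carry units of response per (% inoculum)²
and take magnitudes in the tens to thousands. The three-way term is off
by default and enabled for viscosity, whose corner fit is saturated.
The fit runs on the nine cell means unweighted by default; balanced
replicate weights give identical coefficients. Inference is Wald:
dispersion scale = RSS/dof, 95% CI = estimate ± 1.96·SE, two-sided
normal p-values. Saturated or zero-residual fits report scale 0 and are
solved in closed form. Because the original experiment's exact
replication layout is not recoverable from cell means, intercepts and
scales are reproducible only approximately; all non-intercept
coefficients are invariant to that ambiguity and reproduce exactly up
to the rounding of the published cell means.

## Monte Carlo propagation and sensitivity

Inoculum triples are drawn i.i.d. uniform over per-factor ranges
(default [0.05, 0.10] % w/w, the experimental range), 1000 cases per
run, and pushed through the fitted model **without residual noise**:
the object of interest is the distribution of the model-predicted
response over feasible dosings, and adding residual noise at the fitted
scale would dominate the signal. Summaries are linear-interpolation
percentiles (1, 5, 50, 95, 99 by default). Sensitivity is tornado-style:
the Spearman rank correlation (Pearson optional) between each factor's
draws and the predictions, plus a normalised contribution share
100·rᵢ²/Σrⱼ² that sums to 100 across the three factors and is invariant
to affine rescaling of the predictions. All randomness flows through a
single integer seed; identical seeds give bitwise-identical results.

## Synthetic-data generators

Both table shapes are generated by forward-evaluating the fitted models
and adding i.i.d. Gaussian replicate noise, then tabulating per-cell
mean/SD/n. Defaults encode the reference study conditions: 13 sampling
times (0–36 h every 3 h), triplicates, acid/growth/glucose truths set to
the reference fitted parameters, replicate noise at the magnitude of the
published cell SDs (pH 0.09, TTA 0.02, glucose 0.06, LAB 0.50, TVC 0.20
log), design truths set to the reference factorial coefficients with
residual SDs √0.027, √0.003 and √12.49. Two deliberate departures from
a pure Gaussian model: draws for physically non-negative quantities
(TTA, glucose, viscosity) are truncated at zero, and the published LAB
growth-parameter set is replaced by a self-consistent truth
(K = 6.97, A = 1.05, μmax = 0.20, λ = 3.9) because a 0.09-log rise
cannot describe a series that climbs a full log unit.

What the generators do **not** emulate: non-Gaussian and heteroscedastic
measurement error, serial correlation along the time course, replicate
dropout, plate-count discreteness, and batch-to-batch variation. Passing
recovery tests therefore demonstrate correctness of the estimators under
the stated noise model, not robustness to real-data pathologies.

## Numerical and design choices

- Exponential/Gompertz multi-start jitters come from fixed internal
  seeds, so fits are bit-reproducible.
- `r_squared` raises on zero corrected sum of squares; E% raises on
  non-positive observations (its denominator).
- Rank-deficient factorial designs raise an error naming the collinear
  terms rather than silently pinning coefficients.
- Correlation strength labels use the conventional 0.2/0.4/0.6/0.8
  bands on |r|.
- The pipeline report is canonical JSON (sorted keys, floats rounded to
  10 significant decimals) so reruns with identical inputs and seeds are
  byte-identical.
- Test problem sizes (30–100 seeded replicates for recovery suites,
  1000-case Monte Carlo averaged over 5 seeds) keep every experiment
  deterministic and fast while leaving Monte Carlo error well below the
  asserted margins.

## Known limitations

- The exponential and quadratic kinetic models are empirical summaries;
  extrapolation beyond the 36-h window is not meaningful (the quadratic
  eventually predicts negative glucose).
- Welch-based plateau detection from summary statistics is underpowered
  at n = 3 and will generally flag plateaus earlier than multiple-range
  tests on raw replicates.
- The published E% of the reference growth fit is reproducible only to
  ~0.07 percentage points from printed (rounded) inputs.
- Factorial intercepts and dispersion scales depend on the original
  replication layout and are not exactly reproducible from cell means.
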