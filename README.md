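# fermkin

Fermentation kinetics, factorial starter-culture models and Monte Carlo
sensitivity analysis for lactic-acid cereal beverages.

`fermkin` is aimed at food microbiologists and process engineers working
on controlled fermentation of cereal matrices (the bundled reference
data come from a pearl-millet slurry fermented 36 h at 37 °C and a
starter-culture dosing experiment on pearl-millet extract). It answers
three questions quantitatively:

1. **How fast does the matrix acidify, and when does it plateau?**
   pH and titratable acidity (TTA, % lactic acid) are fitted with the
   exponential model *y(t) = a − b·e^(−ct)* (asymptote *a*, rate *c* in
   h⁻¹); soluble glucose with a quadratic in time; plateau onset is
   detected by consecutive Welch comparisons of the replicated samples.
2. **How do the microbial populations grow?** Plate counts
   (log₁₀ CFU/mL) follow the modified Gompertz curve
   *K + A·exp(−exp(μmax·e·(λ−t)/A + 1))* with initial level *K*, rise
   *A*, maximum rate *μmax* and lag *λ*; fit quality is the mean
   relative deviation modulus E% = (100/n)·Σ|O−P|/O.
3. **How does starter-culture dosing shift the finished beverage?** A
   2³(+center) inoculum design is fitted with the identity-link Gaussian
   model *Y = β0 + ΣβᵢXᵢ + ΣβᵢⱼXᵢXⱼ (+ β123X1X2X3)* in natural
   concentration units with Wald inference, and the fitted model is
   propagated through 1000-case uniform Monte Carlo draws to give
   response percentiles, tornado correlations and per-factor
   contribution shares.

A seeded synthetic-data module generates both table shapes from known
ground truth, so parameter-recovery experiments and the full pipeline
run without any external data.

## Worked example

```python
import fermkin as fk

ts = fk.builtin_fixture("table1")          # 36-h slurry time course, n=3
fit = fk.fit_exponential(ts.time_h, ts.means("pH"))
print(f"a = {fit.a:.3f} +/- {fit.se_a:.3f}")
print(f"c = {fit.c:.3f} +/- {fit.se_c:.3f} per hour")
print(f"R^2 = {fit.r2:.3f}")
print("plateau:", fk.plateau_time(ts, "pH", alpha=0.05), "h")
```

```
a = 3.382 +/- 0.213
c = 0.071 +/- 0.013 per hour
R^2 = 0.971
plateau: 12.0 h
```

The slurry acidifies at 0.071 h⁻¹ toward a pH asymptote of 3.38, the
model explains 97.1% of the corrected variation, and consecutive Welch
tests stop detecting pH changes from 12 h on (summary-statistics tests
at n = 3 are conservative; the conventional harvest point for this
process is 18 h).

```python
design = fk.builtin_fixture("table6")      # 2^3 + center inoculum design
glm = fk.fit_glm(design, "tta_pct")
ce = glm.coefficients["x1x2"]
print(f"x1x2: {ce.estimate:.1f} (95% CI {ce.ci_lower:.1f} to {ce.ci_upper:.1f})")

mc = fk.run_monte_carlo(glm, n_cases=1000, seed=42)
print({q: round(v, 3) for q, v in mc.percentiles.items()})
print({k: round(v, 1) for k, v in mc.contribution_pct.items()})
```

```
x1x2: 32.0 (95% CI 18.7 to 45.3)
{1.0: 0.554, 5.0: 0.561, 50.0: 0.582, 95.0: 0.596, 99.0: 0.604}
{'x1': 36.8, 'x2': 31.9, 'x3': 31.3}
```

The synergy between the first two cultures raises TTA by 32 %-acid per
(% inoculum)²; over the feasible dosing box [0.05, 0.10]³ % w/w, 95% of
simulated batches stay at or below 0.60% TTA, with influence split
roughly evenly across the three cultures.

## Command line

Every analysis is also exposed as a `fermkin` subcommand:

```sh
fermkin fixtures --out data/                       # export bundled tables
fermkin kinetics --input ts.csv --variable pH --model exponential --out fit.json
fermkin growth   --input ts.csv --variable tvc_log10cfu --out gompertz.json
fermkin glm      --input design.csv --response viscosity_mPas --three-way --out glm.json
fermkin mc       --fit glm.json --n 1000 --seed 42 --range 0.05:0.10 --out mc.json
fermkin synth    timeseries --seed 7 --out synthetic.csv
fermkin run      --timeseries ts.csv --design design.csv --seed 42 --out report.json
```

`fermkin run` chains everything (kinetics → growth → plateau → factorial
models → Monte Carlo → correlation summary) into one deterministic JSON
report with input checksums and a seed registry.

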