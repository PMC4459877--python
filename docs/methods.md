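# Methods

## Model

targetkit implements cumulative Poisson ("k-hit") target theory. The mean
number of complete hits deposited in an effective target of volume `V`
(m³) and density `rho` (kg/m³) by a dose `D` (Gy) is `m = V*rho*D/epsilon`,
with `epsilon` the energy per complete hit. Hit counts are Poisson(m), so
a target tolerating up to `k` hits survives with probability
`S_k(m) = P(N <= k)`, the Poisson CDF. `k = 0` is the classical single-hit
exponential `exp(-m)`; `k >= 1` produces the shouldered curves of
multi-hit theory.

D37 is the dose at which survival reaches `exp(-1)`. Under `k = 0` the
mean hit number at D37 is exactly 1, giving the geometric identities

    V = epsilon / (rho * D37),   d = (6V/pi)^(1/3).

For `k >= 1` the mean hit number at the 37% crossing is the root `x_k` of
`S_k(x) = exp(-1)` (x_0 = 1, x_1 = 2.14619..., x_2 = 3.25825...), found by
bracketed Brent root finding on `[k, k+10]` (the root exists and is unique
by monotonicity; the residual is re-checked against the requested
tolerance, default 1e-10). Because `V` is proportional to the mean hit
number at fixed D37, `x_1/x_0 ≈ 2.146` is the factor by which a two-hit
target's volume must exceed a one-hit target's to produce the same D37.
Note that the conventional two-decimal quotation of this factor, 2.14, is
a truncation of 2.1462 (which rounds to 2.15).

Theoretical dose–response curves are anchored so that every `k` passes
through `exp(-1)` at the same D37 (`rate(D) = S_k(x_k * D / D37)`); model
comparisons therefore isolate curve shape, not scale.

### Physics defaults and units

Doses are Gy (J/kg) throughout; percentages exist only at the CSV/CLI
boundary. Defaults: `rho = 1000 kg/m³` (water) and `epsilon = 1 eV =
1.6e-19 J` — the unique value under which the packaged survey of
published D37-to-diameter conversions (tumour cell lines at ~2.4–6 Gy →
37–50 nm, viruses at 570–2700 Gy → 4.8–8.1 nm, seeds, and the ten
mung-bean groups at 893–8740 Gy → 3.27–6.99 nm) reproduces to the printed
3 significant figures. Published texts in this area sometimes quote
`epsilon = 1000 J`, which is dimensionally usable but inconsistent with
every printed diameter in the survey by ~22 orders of magnitude in
volume; `epsilon` is therefore an explicit, configurable field of
`TargetPhysics`. Poisson pmf/cdf values come from `scipy.stats.poisson`
(log-space, stable for large counts); the test suite cross-checks the
cumulative survival against an explicit `math.fsum` of
`exp(n*ln m - m - lgamma(n+1))` terms.

## D37 estimators

The exact interpolation/extrapolation procedures behind published D37
values are rarely stated, so three named estimators are provided; all
operate on normalized rates (control rate fixed at exactly 1, rates above
1 retained — clipping would bias log fits downward):

* `loglinear_origin` (default): least squares of `ln(rate)` on dose with
  zero intercept; for `k = 0`, `D37 = -1/slope` in closed form; for
  `k >= 1` the same log-scale loss is minimized over `ln(D37)`
  (`scipy.optimize.least_squares`, tolerances 1e-15, initialized at the
  k = 0 estimate). Non-positive rates are dropped with a warning rather
  than failing the fit, since noisy dishes can reach zero length.
* `nonlinear_ls`: least squares of `rate = S_k(x_k D / D37)` on the rate
  scale (keeps non-positive rates; initialized from the log-linear fit).
* `linear_crossing`: the polyline through `(0, ln 1)` and the observed
  `(dose, ln rate)` points, solved where it crosses `ln(exp(-1)) = -1`;
  when the rates never reach 37% the final segment is extrapolated and
  the result is flagged `extrapolated`. The crossing is located on the
  log-rate scale at the exact level `exp(-1)`: on the natural (rate)
  scale, piecewise-linear interpolation of an exponential is biased by
  0.4–30% depending on where the crossing falls on the dose grid, and
  targeting the rounded value 0.37 instead of `exp(-1)` shifts the
  estimate by a further 0.55%; on the log scale the estimator is exact
  for exponential data. The estimate does not depend on `k`.

Non-decreasing rates raise a "no decay detectable" error for all
estimators. All three recover a true D0 of 50–5000 Gy to 1e-6 relative on
the standard dose grid from noiseless data. With multiplicative lognormal
noise of CV 10% on the rates, the median relative error of
`loglinear_origin` at D0 = 1000 Gy over 200 replicates is just under 15%,
consistent with the analytic scale `0.6745 * sigma / (|slope| * sqrt(sum
D^2))`.

`compare_models` fits `k = 0` and `k = 1` with the chosen estimator and
prefers the lower residual sum of squares on the rate scale. Its
`shoulder` flag reports whether the `k = 1` fit describes the points
below its fitted D37 better than the `k = 0` fit — i.e. whether the data
show the low-dose plateau of multi-hit survival. (The naive alternative —
"does the fitted k = 1 curve lie above the fitted k = 0 curve at low
dose" — is uninformative: it is an identity when the curves share one D37
and fails even for noiseless shouldered data when each carries its own
fitted D37.)

## Synthetic experiments

The generator emulates the mung-bean assay's structure: groups of petri
dishes on the fixed grid {0, 1, 2, 5, 10, 20, 50, 100, 200, 400} Gy, one
dish of 50 beans per (group, dose) by default, a 50 mm control mean, and
group-specific true D37 values (the ten-group design uses 985, 1102, 893,
1449, 1684, 1560, 1863, 957, 8058, 8740 Gy). Each dish mean is the
noise-free curve value times a unit-mean lognormal draw
(`sigma² = ln(1+cv²)`, default CV 10% — a calibration choice that visually
matches the scatter of the real elongation table, including rates above
100%); bean lengths scatter normally around the dish mean (default SD
5 mm, ≈10% of the control mean, matching the dish-level CV) and are
truncated at zero. Generation is reproducible per seed
(`numpy.random.default_rng`), with a fixed draw order (group → dose →
dish).

What the generator does not emulate: dose deposition physics, dish
geometry, time-course growth over the 70 h observation window, or the
watering-time biology behind the group differences (those enter only
through the group-specific true D37). Passing recovery tests therefore
show the estimators are correct under the assumed noise model, not that
real sprout data satisfy that model.

A propagation effect worth knowing: because normalized rates divide by
the *measured* control dish, dish-level noise on the control enters every
rate of its group coherently, and a zero-intercept log fit converts that
shared offset into slope error. With one dish per (group, dose), CV 10%
and D0 = 1000 Gy on this grid, the median relative D37 error is ~26% —
noticeably worse than the ~15% obtained when noise is applied to the
rates with the control held at 1, and improved by replicating dishes.
This is a real feature of control-normalized designs, not an estimator
defect.

## Data notes and limitations

* The packaged elongation table and D37 survey are as published. The
  published per-group D37 values cannot be re-derived from the published
  elongation rates by any of the three estimators (the original
  interpolation/extrapolation procedure is unstated), and the printed
  elongation columns for groups 1 and 10 are identical even though their
  attributed D37 values differ by a factor of ~9 — an inconsistency in
  the printed data that the package records but does not resolve. No
  test or reported number claims that derivation.
* The survey's published range row (six *Euphorbia pulcherrima*
  cultivars, 28.0–20.0 Gy) is stored as its two endpoints, giving 30
  (D37, diameter) pairs in total.
* Confidence intervals on D37 and linear-quadratic (`exp(-aD-bD²)`)
  fitting are out of scope.
* Whether the published "2.14× larger" refers to volume or diameter is
  ambiguous in the literature; algebraically the root of the two-hit D37
  condition is a mean-hit (hence volume) ratio at fixed D37, and that is
  what `k_hit_threshold` returns. A diameter reading would correspond to
  the cube root, 1.29; both are obtainable from the returned geometry.

## Problem sizes

The test suite and the acceptance script run closed-form checks, fits on
10-point tables, and a 200-replicate Monte Carlo recovery study; the full
suite completes in a few seconds on one CPU.
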