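# Methods

This note records the modelling choices, numerical conventions and known
limitations of `firbiomass`, in the spirit of a statistical software methods
appendix. Everything quantitative below is computed by the package's tests
or by `scripts/acceptance.py`; nothing here is an empirical claim beyond
what that code measures.

## The model family

All catalogued equations predict whole-tree dry biomass `B` (kg, above plus
below ground) from breast-height diameter `D` (cm), total height `H` (m),
wood density `WD` (kg·m⁻³), basal area `G` (m²), site index `SI`, or stem
volume `V` (m³). Two response scales occur:

* **log forms**, `ln(B) = f(θ, x)` — fitted on the log scale, back-transformed
  by plain exponentiation for evaluation. No lognormal ("Baskerville")
  bias-correction factor `exp(s²/2)` is applied by default: the catalogue's
  reference fit statistics are only consistent with uncorrected
  back-transformation, and the correction is a one-liner for users who want
  it.
* **natural forms**, `B = f(θ, x)` — fitted and evaluated in kg.

The catalogue stores each form's published reference parameters and fit
statistics verbatim, with an errata note wherever the printed source row
needed repair (unbalanced parentheses in forms 2 and 32, a shifted cell in
form 62) or is internally inconsistent (forms 1, 4 and 9 carry parameter
columns that give implausible or negative predictions at the sample-mean
tree; form 19's reference values are consistent with basal area expressed
in cm² although the footnoted unit is m²). Forms 65–74 are recorded as
having misconverged in the reference analysis; several of them are
structurally non-identifiable (71, 72, 74 contain exactly collinear or
cancelling parameters), which is the likely cause. They remain fittable
here — a modern trust-region optimizer happily returns one point of the
optimum ridge — but their `reference_status` preserves the published
outcome.

## Stem volume

The taper integral is evaluated with adaptive Gauss–Kronrod quadrature
(`scipy.integrate.quad`) to an absolute tolerance of 1e-8 m³ (configurable).
Numerical conventions:

* the integrand is computed as `exp(p·ln r)` with
  `r = (H−h)/(H−1.3)`; at the tip (`r → 0`) it is defined as 0, which is the
  correct limit because the exponent `p(h) = 3.482321 − 2.153699·h^0.007`
  stays positive for every realistic height;
* below breast height (`h < 1.3`, hence `r > 1`) the formula is applied as
  written — the integral runs from ground level and no clamping is applied;
* `V` is exactly proportional to `D²`, which the tests exploit as an
  invariant, and is checked against a 10⁶-step midpoint Riemann sum to 1e-6
  relative across the calibration (D, H) range.

Whether the reference analysis obtained its volumes from this taper model
alone or from 1-m sectional (Smalian-type) measurements is not documented;
this package supports only the taper route, so per-tree volumes may differ
from the original data source even when diameters and heights agree.

## Conversion factors

`WD` is implemented as *trunk (stem) dry mass per stem volume*. One printed
variant of the definition divides aboveground mass by stem volume instead;
that quantity is dimensionally a conversion factor, not a density, and using
it would break the identity `BCEF = BEF·WD = aboveground/V` that the rest of
the pipeline relies on. The variant remains available behind an explicit
`printed_variant` flag for comparison with legacy reports. WD and BCEF
outside [50, 1500] kg·m⁻³ trigger warnings, not errors.

## Fitting

* **Loss scale.** Log-response forms are fitted by least squares on
  `ln(B)`; natural forms on `B`. All reported criteria (MAB, RMSE with the
  n−1 denominator, ARE, plain R²) are computed in kg after
  back-transformation. R² is deliberately the unadjusted form to stay
  comparable with the reference table; `adjusted_r2` is provided.
* **Multistart.** A seeded Latin hypercube of 32 starts over [−5, 5] per
  parameter, plus a unit vector and (when available) the catalogue's
  reference values. Winner = lowest RSS, ties broken by smaller parameter
  norm; the winner is polished once with a higher-accuracy (3-point)
  Jacobian so linear-in-parameter forms match the closed-form least-squares
  optimum to near machine precision. Invalid regions (log of a
  non-positive intermediate) are handled by a large residual penalty; a
  start that ends in the penalty region is discarded. If every start fails
  the result is flagged `converged=False` and carries no criteria —
  mirroring the "misconvergence" rows of the reference table.
* **Information criteria.** `AIC = n·ln(RSS) + 2p` and
  `BIC = n·ln(RSS) + p·ln(n)`, with RSS on the fitted response scale. This
  convention reproduces the sign and magnitude of the published values for
  log-scale fits (strongly negative, since log-scale RSS ≪ 1). Other
  conventions differ only by additive constants within one dataset and
  response scale, so rankings are unaffected; comparisons across response
  scales are **not** meaningful and the package never makes them.

## The refined tree model and the stand coefficient

The two refinement steps, `ln(TB) ~ ln(TV) + ln(WD)` and
`ln(TB) ~ ln(TV) + ln(WD) + ln(BCEF)`, are linear in their parameters and
solved exactly by OLS, with coefficient standard errors from the usual
covariance estimate. Because `BCEF = BEF·WD`, the two density regressors
are affinely dependent whenever BEF is nearly constant; the fit warns when
the design's condition number exceeds 1e8 and falls back to the
pseudo-inverse. Coefficient vectors are always labelled by predictor name
(`intercept`, `ln(TV)`, `ln(WD)`, `ln(BCEF)`) — published versions of this
model disagree internally about which letter belongs to which density term,
and naming by predictor removes the ambiguity.

The stand biomass coefficient is `bi = exp(a + b·ln(TV) + c·ln(WD) +
d·ln(BCEF))` with the shipped default coefficient set
(−0.0703, 0.9780, 0.0213, 1.0166); any refitted vector can be injected.
`SB = bi·SV/TV` is exactly linear in stand volume. The reference tree is
user-chosen; the default is the quadratic-mean-diameter tree with
stand-average WD and BCEF, a choice that matters little because the volume
exponent is close to 1 (the per-member `sensitivity_report` quantifies the
residual dependence, and the generator's stand experiments put the
aggregation error of the default choice at a few percent of the summed
per-tree predictions).

## Jackknife

Leave-one-out validation refits the model n times and predicts each held-out
tree. The report exposes (a) held-out MAB/RMSE/ARE/R², (b) the full-data
fit with its AIC/BIC, (c) the mean of the n leave-one-out coefficient
vectors, and (d) every per-fold estimate. Both (b)'s and (c)'s coefficient
vectors are reported because a published jackknife coefficient vector can
mean either; on well-behaved data the two agree to well under 0.01 on the
volume exponent, which the tests assert.

## Synthetic data generator

The generator emulates a 35-tree destructive sample of plantation Chinese
Fir whose published summary is: D mean 17.0, SD 7.3, range [5.1, 38.4] cm;
H range [4.1, 31.8] m; age [6, 38] y; WD mean 304.2, SD 59.7, range
[117.0, 427.1] kg·m⁻³; BCEF mean 391.8, SD 81.4, range [236.3, 613.8]
kg·m⁻³; TB mean 107.8, SD 101.3, range [4.6, 482.4] kg.

Chain and defaults:

* `D` ~ lognormal truncated to [5.1, 38.4] cm. The log-scale spread matches
  the target coefficient of variation (7.3/17.0) and the location is solved
  (Brent's method on the closed-form truncated-lognormal mean) so the
  *truncated* distribution has mean 17.0 — naive moment matching before
  truncation would bias the mean by ~0.2 cm.
* `H = 1.24·D^0.9·exp(ε_H)`, `ε_H ~ N(0, 0.08)`: the power curve maps the
  diameter range onto approximately [5.3, 32.8] m, spanning the published
  height range; heights are not hard-truncated, so rare trees exceed the
  observed maximum.
* `WD` ~ N(304.2, 59.7²) truncated to [117.0, 427.1].
* `BEF` ~ lognormal with mean 1.29 (the ratio of the published mean BCEF to
  mean WD) and log-sd 0.10, truncated per tree — exactly, by inverse-CDF
  sampling — so that `BCEF = BEF·WD` stays inside [236.3, 613.8].
* `TV` from the taper integral; `ln TB = a + b·ln TV + c·ln WD + d·ln BCEF
  + σ·ε` with the refined-model coefficient defaults and `σ = 0.045`.
* Component masses are carved out of the aggregates (trunk = WD·TV with a
  15 % bark share, aboveground = BCEF·TV with the crown split 60/40 between
  branches and foliage, roots = TB − aboveground split over stump/coarse/
  middle/small) so that re-deriving V, WD, BEF and BCEF from the components
  reproduces the generating values exactly. Age is generated uniform over
  [6, 38] (no distribution was published; the choice is arbitrary) and is
  used by no model.

Two defaults deserve justification. `σ = 0.045` is the log-scale residual
spread implied by the refined model's published error statistics (a ~3.5 %
relative MAB and an information-criterion value consistent with log-scale
RSS ≈ 0.067 at n = 35). The BEF log-sd of 0.10 sets how much of the biomass
variation the density-free models cannot explain; at 0.10 the gap between
the two refinement steps reproduces the published pattern (three-term model
R² ≈ 0.97, four-term ≈ 0.997). Both were fixed from those published
statistics when the generator was written.

Mass-balance constraint: a real tree always has `TB > aboveground`, which an
unbounded lognormal residual would occasionally violate. The noise is
therefore a standard normal truncated **symmetrically** to `(z, −z)`, where
`z < 0` is the standardized log-distance from the law's prediction down to
the tree's aboveground mass. Symmetric truncation keeps the conditional
mean of the noise exactly zero — so fitted coefficients remain unbiased,
which the Monte-Carlo suite verifies at n = 200, σ = 0.1 over 100
replicates — while guaranteeing positive root mass. At the default σ the
truncation point sits ~4 SD out and is practically inactive.

What the generator does **not** emulate: measurement error in D/H, sectional
volume measurement, within-stand spatial or competitive structure, any
age–size dependence, site effects on WD, or heteroscedasticity beyond what
the mass-balance truncation induces. Passing tests on synthetic data
therefore demonstrate the correctness and statistical behaviour of the
*procedures*, not the field accuracy of any particular coefficient set.

## Problem sizes and determinism

The test and acceptance workloads use a 35-tree synthetic sample (matching
the reference study's size), 50–200-tree samples for identifiability and
jackknife-consistency checks, 100 replicates for the Monte-Carlo bias
check, and a 100-tree stand for the upscaling experiment — sizes at which
every result is stable to the asserted tolerances while the whole suite
runs in a couple of minutes. All randomness flows through explicit integer
seeds (`numpy.random.default_rng`); identical (config, seed) reproduce
identical datasets byte for byte.

## Known limitations

* The catalogue's reference parameter columns cannot all be reproduced
  row-by-row: several forms are start-point dependent on a 35-tree sample,
  and the flagged rows carry printing defects. Rankings, not parameter
  values, are the comparable output.
* The site-index form (58) is skipped unless the user supplies SI; no
  default exists because the provenance of the reference SI values is
  undocumented.
* `evaluate_fixed` with coefficients fitted elsewhere inherits whatever
  volume/density conventions that source used; unit mismatches (see form
  19's cm² basal area) are the user's responsibility.
* Stand upscaling assumes WD and BCEF are constant within a stand; the
  sensitivity report measures, but cannot remove, the aggregation error
  this introduces for heterogeneous stands.
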