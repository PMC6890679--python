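# Methods

## The risk model

The package estimates the probability of an allergic reaction on a
single eating occasion in the allergic population consuming a
contaminated product,

    p_u = P(Z < X·Y),

with consumption X (kg/occasion), allergen concentration Y (mg/kg =
ppm) and individual reaction threshold Z (mg protein) mutually
independent. Exposure X·Y is in mg protein. The units convention is
fixed package-wide and documented on every relevant type, because the
log-scale parameters are meaningless without it: μ_X = −3.719 log-kg
implies a median intake of e^−3.719 ≈ 24 g, and a Weibull threshold
scale of ~230 mg protein sits on the upper end of the challenge dose
range.

Two Monte Carlo estimators of p_u are provided and are equal in
expectation (law of total expectation):

* **indicator** — draw (X, Y, Z), return the fraction with Z < X·Y.
  The inequality is strict; ties, a measure-zero event for continuous
  inputs, count as no reaction.
* **dose–response** — draw (X, Y), return the mean of the threshold
  CDF F_Z(X·Y), i.e. the average individual reaction probability.

The dose–response estimator has strictly smaller Monte Carlo variance
(it integrates Z analytically), which is visible in the one-at-a-time
decomposition's noise floors.

## Variability vs uncertainty: the second-order scheme

Population variability (different consumers, products, thresholds) and
estimation uncertainty (finite samples behind each input distribution)
are kept on separate axes: the outer loop draws K parameter sets from
the sampling/posterior distributions of the fitted parameters, the
inner loop simulates n individuals per set. Defaults K = 1000,
n = 10 000. The K per-replication risks form a `RiskDistribution`
whose SD and percentiles describe estimation uncertainty only —
except in the plug-in case (A), where parameters are fixed and the
replication spread is pure simulation noise; that case's summary is
flagged `sd_is_simulation_error_only`.

Parameter sampling distributions:

* lognormal inputs (moment fit on natural logs, SD with n−1
  denominator): location ~ N(μ̂, σ̂/√n); variance ~ σ̂²/(n−1)·χ²(n−1),
  its square root used as the scale. The location draw uses the point
  estimate σ̂, not the drawn scale — the two draws are independent,
  matching the scheme the closed-form "calculated" mode assumes.
* regression-style coefficients (exponential rate, Weibull shape and
  scale): independent N(estimate, SE), with positivity enforced by
  rejection-resampling. Rejection preserves the mean to first order
  when the rejected mass is small; if the rejected mass would reach
  ~50% (the estimate is not meaningfully above zero) the draw errors
  out instead of silently biasing, with a 1% numerical margin on the
  boundary so an estimate indistinguishable from zero is also caught.
  Drawing shape and scale independently ignores their (substantial)
  fitted covariance; this is deliberate — it is the scheme the case
  presets define — and a joint-normal alternative can be built from
  the fit's `cov_shape_scale` if wanted.
* Bayesian: the exponential rate's conjugate Gamma posterior is exact;
  Weibull threshold parameters are resampled from pooled MCMC draws.

Sub-streams are spawned deterministically from the case seed
(`SeedSequence.spawn`), one per input's parameter draw plus one per
replication, so results are reproducible and adding replications does
not reshuffle earlier ones.

## Interval-censored threshold fitting

A food challenge reports each subject's threshold only as an interval:
(NOAEL, LOAEL] for reactors, below the first dose (left-censored) or
above the last (right-censored) otherwise. The likelihood is
∏ [F(u_i) − F(l_i)] with F(l) = 0 / F(u) = 1 for the censored ends.
The MLE is found on an unconstrained scale ((log a, log b) for Weibull
shape/scale; (μ, log σ) for lognormal) by Nelder–Mead from three
starts — moment-based, unit, and the best point of a coarse grid scan —
because the censored Weibull likelihood with shape < 1 is flat and a
single start is untrustworthy. Standard errors come from the inverse
of a central-difference observed information, delta-method
back-transformed to the natural scale. Non-convergence raises with
optimizer diagnostics attached; all-left- or all-right-censored data
raise as non-identifiable. Confidence intervals are best formed on the
optimization (log) scale, where the likelihood is closer to quadratic;
the recovery tests do exactly that.

The MCMC posterior targets the same censored likelihood times
independent Gamma(10⁻³, 10⁻³) priors on shape and scale — vague but
proper, applied to the positive parameters directly. The sampler is an
adaptive random-walk Metropolis on (log a, log b) with the Jacobian
correction (+log a + log b): per-coordinate step sizes adapt toward
35% acceptance by Robbins–Monro during burn-in only, then freeze, so
the retained segment targets the exact posterior. Two chains from
over-dispersed starts; split-chain potential scale reduction (R-hat)
is computed per parameter, and R-hat ≥ 1.05 attaches a warning to the
result rather than failing silently. Defaults (20 000 iterations,
5 000 burn-in) are this package's choices; shorter chains (3 000/1 000)
are demonstrably sufficient for the n = 158 worked example and are
used in the repeated-replicate coverage tests.

## Uncertainty decomposition

**Delta method** (triple-lognormal only — the closed form is what gets
differentiated): with d = (μ_z−μ_x−μ_y)/s, s² = Σσ_i², each input
contributes K1·σ_i²/n_i + K2·2σ_i⁴/(n_i−1), where K1 = [φ(d)/s]² and
K2 = [φ(d)(μ_z−μ_x−μ_y)/(2s³)]², φ the standard normal density.
Components are additive by construction. Non-lognormal inputs raise.

**One-at-a-time simulation** (any case): the second-order run is
repeated with the parameter uncertainty of one input active at a time
(the others fixed at point estimates or posterior means) and once with
all three active; each component is the variance (n−1 denominator) of
the K per-replication risks. Each simulated component also carries the
inner loop's Monte Carlo noise floor ≈ p(1−p)/n (indicator) or
Var(F_Z(XY))/n (dose–response), so simulated components sit slightly
above delta-method ones and the sum of three components counts that
floor three times while the joint run counts it once. At the default
K and n this keeps |sum − joint|/joint well inside 20%.

Reports are in units of 10⁻⁴ on the proportion scale, the natural
magnitude when the risk SD is a few percentage points (SD 2.2 pp ⇒
variance ≈ 5 units).

## Synthetic data: what it emulates and what it does not

The generator reproduces the *stated* study world: lognormal
consumption (μ = −3.719, σ = 0.747 log-kg, n = 350 — the maximum
eating occasion per survey respondent), exponential contamination
(rate 0.013/ppm ⇒ mean 77 ppm, n = 24), and Weibull thresholds
(shape 0.38, scale 229.6 mg, n = 158) observed through a dose grid.
The default grid is 10 geometric doses from 0.1 to 1000 mg protein —
the source studies' actual grids are unpublished, so this is a
realistic stand-in spanning the threshold scale, not a reconstruction.
Latent thresholds are retained in a debug column that fitting code
ignores. Per-subject streams are spawned by counter offset, so
enlarging a cohort preserves earlier subjects.

Not emulated: the survey designs and weights behind the consumption
data (only an optional weight column), laboratory censoring of
concentration assays, and the heavy upper tail of real consumption —
the empirical 97.5th percentile (291 g) far exceeds the lognormal
fit's (~105 g). An optional two-component mixture
(`heavy_tail_weight`) lets users mimic that tail, but the default is
the pure lognormal, because that is the world the fitted parameters
describe. Consequently a green test establishes correctness of the
machinery under the stated parametric world, not fidelity of that
world to any particular national survey. This is also why the
Bayesian case's published mean (14.69%, driven by the empirical
consumption tail) is validated here only by proximity to the
frequentist case on shared synthetic data, not by numeric
reproduction.

## Numerical and design choices

* Natural logarithms throughout; lognormal scale uses the n−1
  denominator, matching the χ²(n−1) sampling law used for variance
  draws.
* The exponential rate's SE defaults to the asymptotic λ̂/√n but is
  overridable: the published case C sampling SD (0.001) is far below
  the asymptotic value (≈0.0027) with no stated derivation, so the
  worked-example preset carries the printed value explicitly rather
  than deriving it.
* Empirical quantiles use the median-unbiased interpolation rule; the
  convention is otherwise unstated and differences are within
  stochastic tolerance.
* Censored-likelihood probabilities are floored at 1e-300 before
  logging to keep the optimizer finite in the far tails.
* Case B "calculated" mode evaluates the closed form per parameter
  draw — no inner loop, ~10⁴× faster, and the analytic benchmark the
  simulated mode is tested against (agreement within 0.5 pp in mean).
* The closed form uses the standard normal CDF; the delta-method
  constants use the density. (A reader of the source formulas may note
  the symbols φ/Φ are easy to conflate; the 9.8% plug-in value
  confirms the CDF reading.)
* CSV outputs are written with %.17g and read back with pandas'
  round-trip parser, so write→read is bit-exact; reports carry rounded
  display columns (2 decimals for percentages, 3 for parameters)
  alongside full-precision `_raw` columns.

## Known limitations

* The risk applies to the allergic-user population consuming a
  contaminated product; prevalence of allergy and the proportion of
  contaminated products are deliberately out of scope.
* Thresholds, consumption and concentration are assumed independent;
  individual-level consumption–threshold dependence cannot be assessed
  without linked data.
* Intercept-only threshold models; no covariates, no time-varying
  thresholds, no model selection among candidate families.
* The delta method is first-order: it slightly underestimates the
  spread when the risk function curves over the parameter-draw range
  (visible as the calculated SD 2.16 pp vs the simulated 2.2–2.3 pp).
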