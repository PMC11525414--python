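# Methods

This note documents the models implemented in `analogue_report`, the
assumptions behind them, the defaults that matter, and the choices made
where the design was genuinely open.

## Models

### Contamination mixture for continuous report

Response error on the colour wheel is `e = y ⊖ t` (subtraction on the
circle, canonical interval (−π, π]). The error density is

    p(e) = α φ_VM(e; 0, κ_t) + (1 − α)/2π,

a two-component mixture: target-related responses with von Mises
concentration κ_t, and uniform contaminants with total mass 1 − α. The
model is purely descriptive — no psychological process is attached to
either component, and there is deliberately no swap (non-target) component.
Fitting is by maximum likelihood over (log κ, logit α): the log/logit
transform makes the search unconstrained, κ is bounded in [1e-4, 1e4], and
the optimizer (L-BFGS-B) restarts from a deterministic five-point grid plus
a method-of-moments start because mixture likelihoods are multimodal at
small n. The moments start derives α from the error mass within ±π/2
(uniform responses put exactly half their mass there) and κ from the
resultant length corrected for that α.

Alongside the fit, the package reports cosine dissimilarity,
`mean(1 − cos e)` ∈ [0, 2]: 0 for perfect reproduction, 1 in expectation
for uniform errors, 2 for antipodal responses. It needs no model and is
reported per observer × condition.

### Synchronous report

When the stimulus remains visible during response, errors are assumed
Gaussian: the observer matches a noisy target representation (SD σ_t)
against noisy wheel-colour representations (SD σ_w), with all noises
small, independent and equal, and no lapses. Then σ_y = √(σ_w² + σ_t²) =
√2 σ_t, so σ_t follows from the raw error SD by construction. σ_y is
estimated as the *circular* SD √(−2 ln R̄), which coincides with the
linear SD in the small-error regime this model assumes while remaining
finite under occasional wrap-around; a warning fires if σ_y exceeds 1 rad,
where the linear-Gaussian reading stops being meaningful.

### σ ↔ κ conversion

Synchronous fits (σ_t) and asynchronous fits (κ_t) are compared on one
scale by converting SDs to concentrations with matched mean resultant
length: I₁(κ)/I₀(κ) = exp(−σ²/2), the wrapped-normal equivalence. This is
a convention, not a theorem; it is isolated in a single function pair
(`sigma_to_kappa` / `kappa_to_sigma`) so that an alternative (e.g.
κ = 1/σ²; identical in the high-precision limit, since the mapping
satisfies κ → 1/σ² as σ → 0) can be swapped in one place. Solved by Brent
root-finding on exponentially scaled Bessel ratios; round-trip accurate to
1e-8 or better across σ ∈ [0.05, 2].

### 2-AFC links

Both links give Pr(correct) against foil distance d = |f ⊖ t| ∈ [0, π],
and both equal 1/2 at d = 0 (foil identical to probe — a forced guess).

*Asynchronous*: the observer holds an internal estimate y distributed as
the contamination mixture and picks whichever of probe (= t) and foil is
closer to y on the circle. Integrating the mixture over the arc nearer the
probe gives

    Pr_corr(d) = α [Φ_VM(d/2; 0, κ_t) − Φ_VM(d/2 − π; 0, κ_t)] + (1 − α)/2.

The link is linear in α by construction (lapses contribute chance), a
property the tests verify exactly.

*Synchronous*: target, probe and foil each carry independent N(0, σ_t²)
noise, treated linearly (no wrapping) per the small-noise assumption. The
nearest-to-target rule Pr(|p̂ ⊖ t̂| < |f̂ ⊖ t̂|) is the probability that a
bivariate normal with mean [d/√2, d/√2] and covariance diag(3σ_t², σ_t²)
lies in one of two opposite quadrants: Φ²_{μ,Σ}(0) + Φ²_{−μ,Σ}(0).
Because the two decision coordinates are uncorrelated, this factorizes as
Φ(−d/(σ√6))Φ(−d/(σ√2)) + Φ(d/(σ√6))Φ(d/(σ√2)); the implementation
evaluates the bivariate CDF by Owen's T closed form (exact to machine
precision), and the tests require agreement with the factorized form to
1e-10 on a 20×20 (d, σ) grid, plus agreement with 10⁶-draw Monte-Carlo
decision-rule simulations (which do wrap) within 3 standard errors. The
linear treatment degrades for σ_t ≳ 0.5 rad; the Monte-Carlo comparisons
are run at σ_t ≤ 0.3 where the approximation is far below sampling noise.

Fitting is binomial maximum likelihood on |δ| (both models are symmetric
in the foil offset sign, which the data retain). The asynchronous fit uses
the same restart policy as the mixture fit; the synchronous fit is a 1-D
bounded search over log σ_t seeded from a coarse grid. Designs with fewer
than 20 trials or fewer than 5 distinct |δ| levels are rejected, and
perfectly separable data (all correct) return bound values with an
`at_bound` flag rather than a spurious interior optimum.

### Adaptive PSI

Foils are placed by the Kontsevich–Tyler procedure: a grid posterior over
psychometric parameters, updated by Bayes' rule after each response, with
the next |δ| chosen to minimize the expected entropy of the updated
posterior (expectation over the two possible outcomes under the posterior
predictive). The psychometric family is parameterized directly as (κ, α)
with the asynchronous link, so the online procedure and the retrospective
maximum-likelihood fit share one model. Defaults (all in
`analogue_report.config`, not hard-coded): κ log-spaced on [0.5, 200] with
40 nodes, α linear on [0.5, 1] with 20 nodes, 180 candidate |δ| values on
(0, π], uniform prior, 80 trials per condition. Exact ties in expected
entropy resolve to the smallest |δ|; runs are bit-for-bit reproducible
given a seed.

Two properties of this procedure are worth knowing. First, with a lapse
dimension (α) in the grid, the entropy criterion alternates between
threshold probes and lapse probes at the largest |δ| — roughly half the
trials go to each; this is correct behaviour of joint-entropy PSI, not a
defect. Second, as a consequence, 80 trials leave the κ marginal wide: the
posterior-mean κ lands within a factor of 2 of the generating value in
only ~60–70% of runs at κ = 8, α = 0.95 (the acceptance script reports the
measured coverage as `psi_kappa_factor2_coverage_pct`), while 300-trial
runs land within a factor of 2 essentially always (a property test
asserts this). An information-theoretic bound confirms the 80-trial limit:
even with every trial at the most κ-informative stimulus, sd(log κ̂) ≈
0.33, and the actual allocation shares trials with α. Per-condition κ
estimates from 80 2-AFC trials should therefore be treated as noisy, and
analyses should aggregate across observers — which is how the pipeline
reports them.

### Motor-noise decomposition

Motor noise is constant in display units (dva) and non-motor error is
constant in angular units, so for wheels of physical radius R the angular
projection is σ_ang ≈ σ_motor/R (valid while errors are small relative to
the circumference; a warning fires beyond ~30°). Contrasting angular error
variances on two wheel sizes gives

    σ²_motor = (σ²_small − σ²_large) / (R_small⁻² − R_large⁻²).

The decomposition is exact algebra and invariant to any shared angular
variance. Estimates are computed per observer × condition from squared
circular SDs, then averaged; negative values (sampling noise exceeding the
wheel-size contrast) are preserved and flagged, never clipped, and the SD
is reported as missing in that case. The canonical motor quantity is the
display-space SD in dva; its angular projections in degrees are reported
for the two wheels used plus a typical 8.2 dva wheel for context.

## Synthetic observers

The generator emulates the factorial design the models target: synchronous
report (always a single, visible item, no delay) plus asynchronous report
crossed with set size {1, 4} and delay {0, 1000} ms, each crossed with
chroma radius {25, 50}; analogue report additionally crosses wheel
physical radius {3, 10} dva in the no-delay conditions (delayed conditions
use the large wheel only); 50 analogue and 80 PSI-driven 2-AFC trials per
condition. Colour-wheel geometry (CIE Lab circle at L = 60 centred on
a = b = 12.5) is provided as a coordinate utility.

Responses come from the generative forms of the fitted models: analogue
errors from the contamination mixture, then a motor stage that places the
internal hue on the wheel, displaces the click by isotropic 2-D Gaussian
noise of SD σ_motor dva, and reads back the angle (the radial component is
discarded — clicks report hue only; this is the minimal mechanism
consistent with σ_dva ≈ R σ_ang). 2-AFC outcomes come from the stated
decision rules, with foil signs randomized and PSI driving |δ|. Exact
distance ties (probability-zero events) are broken by a fair coin.

Condition effects enter only through condition-indexed (κ, α) maps — no
process model of memory decay is asserted. The default generating values
(in `config.py`) are plausible for colour report and ordered so that
precision is higher synchronously than asynchronously, with one item than
four, and without delay than with: κ = 50 (sync), 12/6 (async set size 1/4,
no delay), 10/5 (delayed), α from 0.99 down to 0.80, σ_t = 0.15 rad for
the synchronous 2-AFC observer, σ_motor = 0 unless injected. They are
package defaults, not published estimates.

What passing tests on this generator do **not** show about real data: the
generator contains no swap errors, no response biases or hue-dependent
anisotropies of colour space, no sequential dependencies, no
observer-level heterogeneity within a cohort, and no response-time
structure. Recovery results certify the estimators under the models' own
assumptions, not the assumptions themselves.

## Numerical choices

- Angles are radians in (−π, π] everywhere internally; degrees appear only
  in human-facing summaries. The wrap convention maps −π to +π.
- The von Mises CDF is evaluated by its Fourier series with exponentially
  scaled Bessel coefficients and adaptive truncation (tail < 1e-15);
  verified against adaptive quadrature to ~1e-13 across κ ∈ [0.5, 1e4].
  κ = 0 is admitted as the exact uniform case.
- The bivariate normal CDF uses Owen's T (closed form) rather than a
  numerical integrator, so oracle comparisons at 1e-10 are meaningful.
- Likelihood clipping at 1e-12 guards log(0) on separable binomial data.
- The PSI likelihood table is precomputed once per grid configuration and
  cached; posteriors are renormalized after every update.

## Problem sizes

Test and acceptance runs use: 10-observer cohorts at the design's own
trial counts (50/80 per condition), 10⁶ draws for Monte-Carlo oracles,
10⁵ trials per wheel for motor recovery, 100 runs for PSI calibration, 50
replicates for null bands and recovery-bias checks, and 200 replicate fits
at n = 500 for mixture recovery. These sizes make the stochastic
acceptance bands (10–25% on concentrations, 0.03–0.05 on proportions, 5%
on motor SD) comfortably wider than the corresponding Monte-Carlo error.

## Known limitations

- The synchronous 2-AFC model excludes lapses by assumption; a lapsing
  observer in a synchronous condition will inflate σ̂_t rather than show
  up as a separate parameter. The asynchronous model absorbs lapses in α.
- Pooled binomial κ estimates inherit a κ–α likelihood ridge; even at
  ~1600 pooled trials, single-cell κ̂ can deviate from truth by ~30%
  (the acceptance script reports the realized recovery error).
- The motor decomposition assumes additivity of motor and non-motor
  variance and identical non-motor error across wheel sizes; violations
  (e.g. speed–accuracy trade-offs differing by wheel size) bias σ²_motor.
- Group-level inference (ANOVA, Bayes factors) is out of scope; the
  pipeline emits tidy per-observer tables for external tools.
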