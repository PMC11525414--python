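# analogue-report

Modelling machinery for dissecting the components of error in **analogue
(continuous) report** tasks and matched **two-alternative forced choice
(2-AFC)** tasks, as used throughout visual psychophysics and working-memory
research: an observer reproduces a colour hue by clicking on a colour
wheel, or picks which of two colours matches a cued item, and the
distribution of errors is decomposed into representational noise, lapses,
and motor noise.

The package is aimed at researchers analysing trial-level behavioural data
from such designs, and at anyone who wants to simulate and stress-test the
models themselves.

## What it computes

**Contamination mixture (analogue report).** Response errors `y ⊖ t` are
modelled as a mixture of target-related responses (von Mises with
concentration κ_t) and uniform contaminants:

    p(y) = α φ_VM(y; t, κ_t) + (1 − α) / 2π

fitted by maximum likelihood per observer and condition, alongside the
non-parametric cosine dissimilarity `mean(1 − cos(y − t))`.

**Synchronous-report Gaussian model.** When the stimulus stays visible,
errors are treated as Gaussian with `σ_y = √(σ_w² + σ_t²) = √2 σ_t`, where
target and wheel-colour representations carry equal independent noise.
Fitted σ_t values are converted to κ equivalents via mean-resultant-length
matching, `I₁(κ)/I₀(κ) = exp(−σ²/2)`, for comparison across tasks.

**2-AFC psychometric links.** The probability of choosing the probe over a
foil at circular distance `d = |f ⊖ t|` is derived from the same internal
quantities: a contamination-based link for asynchronous (memory) report,

    Pr_corr(d) = α [Φ_VM(d/2; 0, κ_t) − Φ_VM(d/2 − π; 0, κ_t)] + (1 − α)/2,

and a bivariate-normal model for synchronous (perception) report, with
mean `[d/√2, d/√2]` and covariance `diag(3σ_t², σ_t²)`, evaluated exactly
via Owen's T function. Both are fitted by binomial maximum likelihood.

**Adaptive PSI foil placement.** A Kontsevich–Tyler grid posterior over
(κ, α) selects each 2-AFC foil offset to minimize expected posterior
entropy, then updates by Bayes' rule.

**Motor-noise decomposition.** Comparing angular error variance on
response wheels of different physical radii isolates motor noise, which is
constant in display units (dva) and scales as 1/R in angular units:

    σ²_motor = (σ²_small − σ²_large) / (R_small⁻² − R_large⁻²).

**Synthetic observers.** A seeded generator produces full cohorts with the
standard design (set sizes {1, 4}, synchronous/asynchronous report, delays
{0, 1000} ms, chroma radii {25, 50}, wheel radii {3, 10} dva, 50 analogue
and 80 PSI-driven 2-AFC trials per condition) from the generative forms of
the models above, so every pipeline stage is testable end to end.

## Worked example

```python
import numpy as np
from analogue_report import (ObserverParams, DesignSpec, simulate_analogue,
                             fit_contamination, cosine_dissimilarity,
                             estimate_motor_variance, angular_sd_from_motor)
from analogue_report.mixture import response_errors

params = ObserverParams.from_config(observer="demo", seed=7)
trials = simulate_analogue(params, DesignSpec(delays_ms=(0,), chroma_radii=(25,)))
for (timing, ss), grp in trials.groupby(["timing", "set_size"]):
    fit = fit_contamination(grp)
    cd = cosine_dissimilarity(response_errors(grp))
    print(f"{timing:13s} set size {ss}: kappa_t = {fit.kappa_t:6.2f}, "
          f"alpha = {fit.alpha:.3f}, cosine dissimilarity = {cd:.3f} "
          f"(n = {fit.n_trials})")
```

prints

```
asynchronous  set size 1: kappa_t =  11.18, alpha = 1.000, cosine dissimilarity = 0.046 (n = 100)
asynchronous  set size 4: kappa_t =   5.01, alpha = 0.827, cosine dissimilarity = 0.255 (n = 100)
synchronous   set size 1: kappa_t =  46.10, alpha = 1.000, cosine dissimilarity = 0.011 (n = 100)
```

— precision (κ_t) falls and lapses rise from synchronous viewing to
memory report and with larger set size, while cosine dissimilarity tracks
the same ordering model-free. Motor noise is then bounded from the
wheel-size contrast:

```python
est = estimate_motor_variance(0.0065, 0.0006, R_small=3.0, R_large=10.0)
print(f"sigma_motor = {est.sigma_motor_dva:.3f} dva, "
      f"{angular_sd_from_motor(est.sigma_motor_dva, 10.0):.2f} deg on a 10 dva wheel")
# sigma_motor = 0.242 dva, 1.38 deg on a 10 dva wheel
```

A display-space motor SD of ~0.24 dva contributes only ~1.4° of angular
error on a large wheel (~4.6° on a 3 dva wheel) — small next to typical
memory-error SDs of 10–20°.

## Command line

```sh
analogue-report simulate --out data/ --seed 1 --n-observers 10
analogue-report run-all  --input data/ --out results/
analogue-report report   --input results/ --out figures/   # binned figure tables
```

`run-all` writes per-observer fit tables (CSV), a motor-noise summary and
a JSON report with provenance (config hash, seed, version).

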