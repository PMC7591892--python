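# Methods

This note records the statistical models implemented in `otogrow`, the
choices made where the procedure was genuinely open, and what the synthetic
validation does and does not demonstrate.

## Proportionality model and hatch-radius imputation

For one fitting group (a species, or a species at one location) with fish
j = 1..n, capture length is modelled as

    L_cpt,j ~ Normal( L_0p − b·R_0p,j^c + b·R_cpt,j^c , σ )

- `b` (mm·mm⁻ᶜ) and `c` (dimensionless) carry the informative priors
  Normal(200, 200) and Normal(1, 1). Both are truncated at zero: the
  Modified Fry step requires the biological intercept `a = L_0p − b·R_0p^c`
  to stay below `L_0p`, which only `b > 0` guarantees.
- The observation model and its scale are not dictated by the regression
  itself; we use a single pooled Normal σ with a half-Normal(50 mm) prior —
  the simplest structure consistent with a scalar residual. σ enters the
  likelihood as √(σ² + 10⁻⁶ mm²); the tiny floor keeps the noise-free
  limit (simulated data with σ → 0) well-posed instead of collapsing to an
  improper spike.
- Hatch radii form a truncated-normal population on (0, ∞):
  R_0p,j ~ TruncNormal(μ_R, σ_R). Known radii enter as data; missing radii
  are sampled as parameters from the same population, so each acquires its
  own posterior shaped by the known-radius distribution *and* by that
  fish's capture length through the regression. Hyperpriors:
  μ_R ~ Normal(mean of known radii, 0.1 mm), σ_R ~ half-Normal(0.1 mm) —
  weakly informative on the millimetre scale of reef-fish hatch radii
  (observed range ≈ 0.008–0.136 mm).
- A group is fit only when at least two *usable* fish (age at capture ≥ 2)
  have known hatch radii; fish captured at age one (no interior increment)
  or age zero (hatching and capture coincide) are excluded beforehand.

## Back-calculation and uncertainty propagation

For every posterior draw t and fish j: `a_jt = L_0p − b_t·R_0p,jt^c_t`
(using the draw's imputed radius where unmeasured), then for each age i
with a measured ring radius the Modified Fry length

    L_ijt = a_jt + exp( ln(L_0p − a_jt)
            + [ln(L_cpt,j − a_jt) − ln(L_0p − a_jt)]
              · [ln R_ij − ln R_0p,jt] / [ln R_cpt,j − ln R_0p,jt] )

The reported estimate per (fish, age) is the mean and standard deviation
over draws. Draws that violate the log domain (`a ≥ L_cpt`, possible in the
prior tail) are skipped and counted; an estimate supported by fewer than
half the draws (configurable) is flagged unreliable rather than dropped.
Endpoints are exact by construction — at `R_i = R_0p` every draw returns
`L_0p`, at `R_i = R_cpt` every draw returns `L_cpt` — so the posterior sd
is exactly zero there and strictly positive at interior ages whenever the
posterior is non-degenerate.

## Von Bertalanffy growth models

Growth follows `L(t) = L∞(1 − e^(−K(t − t₀)))` with L∞ in mm, K in 1/yr,
t₀ in yr.

**Hierarchical fit (back-calculated size-at-age).** Within-fish
back-calculated points are strongly auto-correlated; the hierarchy models
that by giving each fish its own curve:

- L∞_j ~ Normal(L∞, sd_L∞), log K_j ~ Normal(log K, sd_logK); t₀ is shared
  at the population level (per-fish t₀ is weakly identified with few
  points per fish).
- Population priors come from a per-species config block in the style of
  FishBase reference values: L∞ ~ Normal(mean, sd) and
  K ~ Normal(mean, sd) truncated positive — reference compilations report
  natural-scale means and spreads, which a symmetric truncated normal
  encodes directly (a lognormal centred on the same median would add a
  mean–median skew with no empirical basis). t₀ ~ Normal(0, 1) by default.
  Hyperpriors: sd_L∞ ~ half-Normal(50 mm), sd_logK ~ half-Normal(0.3),
  σ ~ half-Normal(25 mm).
- The likelihood is Normal around the curve; the back-calculation
  uncertainty (per-point length sd) can enter as known additive variance
  (default on). Mean back-calculated lengths are the fitted response;
  posterior draws of lengths are not re-propagated.
- Eligibility: fish with age at capture strictly greater than two years,
  groups with at least five such fish. Age-0 points (length at hatching)
  are retained — they anchor the curve at a biologically known point.

**Raw fit (validation comparison).** The same growth function fitted
non-hierarchically to one (age, length) point per fish, for groups with
strictly more than ten fish. Whether t₀ should be free or pinned is an open
choice; it is free here under its Normal(0, 1) prior and configurable.

**Curve comparison.** Population-curve draws from both posteriors are
evaluated on an integer age grid from 1 to the oldest capture age; at each
age the 95% credible intervals are intersected. Age 0 is excluded from the
overlap grid: the raw fit has no data near hatching, so its age-0 band is
purely prior-driven and a comparison there would test the prior, not the
data. The comparison also reports whether the back-calculated median curve
lies below the raw median at every grid age.

## Sampling machinery

All posteriors are sampled with `emcee` (differential-evolution ensemble
moves, 80/20 DE/snooker mix) over unconstrained coordinates — every
positive parameter on the log scale with the Jacobian in the target — so
all coordinates are O(1) and the moves are scale-free. Walkers start in a
small ball around a MAP estimate found by L-BFGS with a batched
finite-difference gradient (the vectorised log-posterior evaluates the
gradient stencil in one call); per-fish starting values for the
hierarchical fit come from individual least-squares curve fits with robust
(median/MAD) pooling. The hierarchical model uses the centered
parameterization: with several data-pinned points per fish the per-fish
coordinates decouple from the population coordinates, which would instead
form a ridge under the non-centered form that ensemble moves traverse very
slowly.

Convergence is monitored with rank-normalised split R̂ computed over walker
*groups* (walkers pooled into 4 pseudo-chains), which is robust to the
per-walker autocorrelation of ensemble moves. Threshold: R̂ ≤ 1.01 on the
core parameters. The staged protocol on failure: refit at doubled
iterations (the 2,000/1,000 → 4,000/2,000 escalation), then drop the fish
whose individual-level parameters carry the worst R̂ — an automated proxy
for visual chain inspection — one at a time up to three, refitting after
each drop. A requested posterior of C chains × D draws is realised as the
last C·D thinned ensemble states (default thinning 8).

Seeds: every fit derives its RNG stream from a base seed and a CRC of the
group label, so group results are independent of iteration order and the
whole pipeline is bit-reproducible for a fixed config.

## Synthetic data generator

The generator emulates exactly the structure the analysis assumes, so that
parameter recovery is well-posed:

- per-fish von Bertalanffy trajectories with L∞_j ~ Normal(400, 30) mm
  (truncated above hatch length) and K_j lognormal around 0.4/yr
  (sd_log 0.15); t₀_j set from the hatch constraint L_j(0) = L_0p;
- hatch radii Normal(0.05, 0.012) mm truncated positive; ring radii by
  exact inversion of the proportionality at the individual level,
  R = ((L − L_0p)/b + R_0p^c)^(1/c);
- integer ages at capture uniform on [2, max_age = 12] (annual-increment
  reading yields integer ages);
- Gaussian noise (sd 5 mm) on the measured capture length only, mirroring
  the single observed regression; an optional multiplicative radius-noise
  switch exists for robustness studies but is off by default;
- hatch radii masked per-fish Bernoulli(rate 0.3), constrained so every
  species keeps at least two known radii (masking removes both R_0p and
  the age-0 ring).

Ground truth (per-fish parameters, true lengths and radii, masked values)
is retained, enabling the noise-free closure oracle: with σ = 0 and the
generative (b, c) as a point-mass posterior, the pipeline reproduces every
true length-at-age to machine precision.

**What the generator does not emulate** — and therefore what passing tests
do *not* establish about field data: reader error in ring counts and radii,
size-selective sampling (real capture samples under-represent young fish,
the main reason raw-data growth fits overestimate L∞ in practice),
growth–otolith decoupling ("growth effects" where otolith accretion departs
from the proportional model), seasonal check marks, and location effects.
Because both the raw and back-calculated routes are generated from the same
correctly-specified model here, the two growth fits agree in expectation;
the synthetic comparison demonstrates band overlap and the absence of L∞
overestimation, not the real-data direction of raw-fit bias.

## Ageing precision

The two independent age reads per otolith are summarised by the
coefficient of variation 100·s/m with the sample standard deviation
(divisor R − 1 = 1, i.e. s = |a₁ − a₂|/√2) — the standard two-reader
precision convention; the exact formula is a documented choice. Flagging
for a common re-read is strict at CV > 5%; a pair of zero reads has
undefined CV and is flagged conservatively.

## Problem sizes used in validation

The test-suite and acceptance-script runs use 4 chains × 500 kept draws,
20-seed replications, and groups of 20–40 fish — sizes at which every
recovery margin above holds with room to spare (b and c recovered within
~2% against 10%/5% margins; imputation coverage ~88% against 80%) while a
full run stays in the minutes range on a single core. The library defaults
remain the production setting (4 × 1,000 draws after 1,000 warmup).

## Known limitations

- Ensemble MCMC mixes more slowly than gradient-based samplers in high
  dimension; hierarchical fits beyond a few hundred fish per group would
  warrant heavier thinning (or an HMC backend behind the same interfaces).
- The pooled-σ observation model ignores heteroscedasticity across fish
  sizes; a size-dependent error structure is a plausible extension.
- Alternative back-calculation families (Dahl-Lea, Fraser-Lee, SPH/BPH)
  and alternative growth forms (Gompertz, Logistic) are out of scope; the
  data model and draw-propagation machinery would support them.
- The automated drop-worst-R̂ protocol is a heuristic stand-in for expert
  chain inspection; it caps at three dropped fish and errs on the side of
  raising rather than silently continuing.
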